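"""Sequence diversity summaries, neutrality tests and mismatch-distribution
expansion analysis.

Implements the classic per-population mtDNA summaries: number of distinct
haplotypes (H), segregating sites (S), haplotype diversity (h), nucleotide
diversity per site (pi), Tajima's D and Fu's Fs with coalescent-simulation
p-values, and the sudden-expansion (stepwise growth) fit to the mismatch
distribution with SSD and Harpending's raggedness index assessed by
parametric bootstrap.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import _coalescent as coal

__all__ = [
    "Alignment",
    "HaplotypeTable",
    "DiversityStats",
    "NeutralityResult",
    "MismatchSpectrum",
    "ExpansionFit",
    "UndefinedStatisticError",
    "collapse_haplotypes",
    "diversity_stats",
    "tajimas_d",
    "fu_fs",
    "ewens_log_pmf",
    "mismatch_spectrum",
    "expansion_model_probs",
    "fit_sudden_expansion",
    "population_summary",
]

_VALID = set("ACGT")


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is mathematically undefined for the input
    (e.g. Tajima's D with no segregating sites) instead of returning 0."""


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with sample ids and population labels."""

    ids: list[str]
    sequences: list[str]
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("alignment is empty")
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sample ids are not unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        self.sequences = [s.upper() for s in self.sequences]
        if self.populations is not None and len(self.populations) != len(self.ids):
            raise ValueError("population labels do not match sample count")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path, popmap: dict[str, str] | None = None) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        ids = [r.id for r in records]
        seqs = [str(r.seq).upper() for r in records]
        pops = [popmap[i] for i in ids] if popmap else None
        return cls(ids, seqs, pops)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, s in zip(self.ids, self.sequences):
                fh.write(f">{i}\n{s}\n")

    def subset(self, keep: list[int]) -> "Alignment":
        pops = [self.populations[i] for i in keep] if self.populations else None
        return Alignment([self.ids[i] for i in keep],
                         [self.sequences[i] for i in keep], pops)

    def by_population(self) -> dict[str, "Alignment"]:
        if self.populations is None:
            raise ValueError("alignment has no population labels")
        out = {}
        for pop in dict.fromkeys(self.populations):
            keep = [i for i, p in enumerate(self.populations) if p == pop]
            out[pop] = self.subset(keep)
        return out


def read_popmap(path) -> dict[str, str]:
    """Two-column CSV (id, population) -> mapping."""
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def retained_sites(alignment: Alignment) -> np.ndarray:
    """Indices of sites free of gaps/ambiguity codes (complete deletion)."""
    arr = _char_matrix(alignment)
    ok = np.isin(arr, list(_VALID)).all(axis=0)
    return np.nonzero(ok)[0]


def _char_matrix(alignment: Alignment) -> np.ndarray:
    return np.array([list(s) for s in alignment.sequences])


def _retained_matrix(alignment: Alignment, gap_policy: str = "complete") -> np.ndarray:
    arr = _char_matrix(alignment)
    if gap_policy == "complete":
        keep = np.isin(arr, list(_VALID)).all(axis=0)
        return arr[:, keep]
    if gap_policy == "pairwise":
        return arr
    raise ValueError(f"unknown gap_policy: {gap_policy!r}")


@dataclass
class HaplotypeTable:
    """Unique sequences (on retained sites) with counts and memberships."""

    n: int
    haplotypes: list[str]
    counts: np.ndarray
    membership: dict[str, int]
    populations: dict[str, str] | None = None

    @property
    def H(self) -> int:
        return len(self.haplotypes)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n

    def population_composition(self) -> list[dict[str, int]]:
        """Per-haplotype counts of carrying samples by population."""
        comp: list[dict[str, int]] = [dict() for _ in self.haplotypes]
        if self.populations is None:
            return comp
        for sid, h in self.membership.items():
            pop = self.populations[sid]
            comp[h][pop] = comp[h].get(pop, 0) + 1
        return comp


def collapse_haplotypes(
    alignment: Alignment, gap_policy: str = "complete"
) -> HaplotypeTable:
    """Collapse an alignment to unique haplotypes in first-occurrence order."""
    arr = _retained_matrix(alignment, gap_policy)
    strings = ["".join(row) for row in arr]
    order: dict[str, int] = {}
    for s in strings:
        if s not in order:
            order[s] = len(order)
    haps = list(order)
    counts = np.zeros(len(haps), dtype=np.int64)
    membership = {}
    for sid, s in zip(alignment.ids, strings):
        h = order[s]
        counts[h] += 1
        membership[sid] = h
    pops = (dict(zip(alignment.ids, alignment.populations))
            if alignment.populations else None)
    return HaplotypeTable(alignment.n, haps, counts, membership, pops)


@dataclass
class DiversityStats:
    S: int
    h: float
    pi: float


def _pairwise_diff_total(arr: np.ndarray, per_site: bool = False) -> float:
    """Sum of pairwise differences over all unordered sequence pairs."""
    n, L = arr.shape
    total = 0.0
    for j in range(L):
        col = arr[:, j]
        _, cnt = np.unique(col, return_counts=True)
        same = (cnt * (cnt - 1) // 2).sum()
        total += n * (n - 1) // 2 - same
    return total


def diversity_stats(table: HaplotypeTable, alignment: Alignment,
                    gap_policy: str = "complete") -> DiversityStats:
    """S, unbiased haplotype diversity h, and per-site nucleotide diversity pi."""
    n = alignment.n
    if n < 2:
        raise UndefinedStatisticError("h is undefined for n < 2")
    arr = _retained_matrix(alignment, gap_policy)
    L = arr.shape[1]
    if L == 0:
        return DiversityStats(0, _hap_diversity(table), 0.0)
    s = int(sum(len(np.unique(arr[:, j])) > 1 for j in range(L)))
    total = _pairwise_diff_total(arr)
    pi = total / (L * n * (n - 1) / 2.0)
    return DiversityStats(s, _hap_diversity(table), pi)


def _hap_diversity(table: HaplotypeTable) -> float:
    n = table.n
    p = table.proportions
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


@dataclass
class NeutralityResult:
    statistic: float
    p_value: float
    n_replicates: int
    name: str


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = coal.harmonic(n - 1)
    a2 = coal.harmonic2(n - 1)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def _tajima_d_from_counts(n: int, s: int, k_hat: float) -> float:
    c = _tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    return (k_hat - s / c["a1"]) / math.sqrt(var)


def tajimas_d(alignment: Alignment, n_replicates: int = 1000,
              seed: int | None = None,
              gap_policy: str = "complete") -> NeutralityResult:
    """Tajima's D with a two-tailed p-value from neutral coalescent
    simulations conditioned on (n, S)."""
    n = alignment.n
    if n < 4:
        raise UndefinedStatisticError("Tajima's D requires n >= 4")
    arr = _retained_matrix(alignment, gap_policy)
    L = arr.shape[1]
    s = int(sum(len(np.unique(arr[:, j])) > 1 for j in range(L))) if L else 0
    if s == 0:
        raise UndefinedStatisticError("Tajima's D is undefined with S = 0")
    k_hat = _pairwise_diff_total(arr) / (n * (n - 1) / 2.0)
    d_obs = _tajima_d_from_counts(n, s, k_hat)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_replicates)
    for r in range(n_replicates):
        k_sim = coal.segregating_and_pi_conditional(n, s, rng)
        sims[r] = _tajima_d_from_counts(n, s, k_sim)
    lo = float(np.mean(sims <= d_obs))
    hi = float(np.mean(sims >= d_obs))
    p = min(1.0, 2.0 * min(lo, hi))
    return NeutralityResult(d_obs, p, n_replicates, "Tajima's D")


@functools.lru_cache(maxsize=64)
def _log_stirling_first(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    cur = np.full(n + 1, -np.inf)
    cur[0] = 0.0  # |s(0,0)| = 1
    for m in range(n):
        nxt = np.full(n + 1, -np.inf)
        # |s(m+1,k)| = m*|s(m,k)| + |s(m,k-1)|
        with np.errstate(divide="ignore"):
            grown = (np.log(m) + cur) if m > 0 else np.full(n + 1, -np.inf)
        nxt[1:] = np.logaddexp(grown[1:], cur[:-1])
        nxt[0] = -np.inf
        cur = nxt
    return cur


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | n, theta) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    ls = _log_stirling_first(n)
    k = np.arange(n + 1)
    log_rising = sum(math.log(theta + i) for i in range(n))
    logp = ls + k * math.log(theta) - log_rising
    return logp - logsumexp(logp)  # normalise away rounding drift


def _fs_from_k_theta(n: int, k_obs: int, theta: float) -> float:
    logp = ewens_log_pmf(n, theta)
    log_sp = logsumexp(logp[k_obs:])
    log_1msp = logsumexp(logp[:k_obs]) if k_obs > 0 else -np.inf
    if not np.isfinite(log_1msp):
        return -np.inf
    if not np.isfinite(log_sp):
        return np.inf
    return float(log_sp - log_1msp)


def fu_fs(alignment: Alignment, n_replicates: int = 1000,
          seed: int | None = None,
          gap_policy: str = "complete") -> NeutralityResult:
    """Fu's Fs: Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta_hat, n)
    under the Ewens distribution; p-value by coalescent simulation."""
    n = alignment.n
    if n < 3:
        raise UndefinedStatisticError("Fu's Fs requires n >= 3")
    table = collapse_haplotypes(alignment, gap_policy)
    arr = _retained_matrix(alignment, gap_policy)
    k_hat = _pairwise_diff_total(arr) / (n * (n - 1) / 2.0)
    k_obs = table.H
    if k_hat == 0:
        raise UndefinedStatisticError(
            "Fu's Fs is undefined with no pairwise differences")
    fs_obs = _fs_from_k_theta(n, k_obs, k_hat)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_replicates)
    for r in range(n_replicates):
        k_sim, pi_sim = coal.haplotype_count_and_pi(n, k_hat, rng)
        sims[r] = _fs_from_k_theta(n, k_sim, pi_sim) if pi_sim > 0 else np.inf
    p = float(np.mean(sims <= fs_obs))
    return NeutralityResult(fs_obs, p, n_replicates, "Fu's Fs")


@dataclass
class MismatchSpectrum:
    """Counts of sample pairs differing at k = 0..k_max sites."""

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = self.n * (self.n - 1) // 2
        if self.counts.sum() != expected:
            raise ValueError(
                f"spectrum counts sum to {self.counts.sum()}, expected "
                f"n(n-1)/2 = {expected}")

    @property
    def total_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def mismatch_spectrum(alignment: Alignment,
                      gap_policy: str = "complete") -> MismatchSpectrum:
    """Histogram of pairwise differences over all unordered pairs."""
    if alignment.n < 2:
        raise ValueError("mismatch spectrum requires n >= 2")
    arr = _retained_matrix(alignment, gap_policy)
    n = alignment.n
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[i], arr[j]
            if gap_policy == "pairwise":
                ok = np.isin(a, list(_VALID)) & np.isin(b, list(_VALID))
                diffs.append(int(np.sum(a[ok] != b[ok])))
            else:
                diffs.append(int(np.sum(a != b)))
    counts = np.bincount(diffs)
    return MismatchSpectrum(counts, n)


def _poisson_pmf(kmax: int, tau: float) -> np.ndarray:
    """Poisson pmf for k = 0..kmax without scipy call overhead."""
    if tau <= 0:
        out = np.zeros(kmax + 1)
        out[0] = 1.0
        return out
    out = np.empty(kmax + 1)
    out[0] = 1.0
    if kmax:
        out[1:] = np.cumprod(tau / np.arange(1, kmax + 1))
    return out * math.exp(-tau)


def _geometric_equilibrium(theta: float, kmax: int) -> np.ndarray:
    """Equilibrium mismatch probabilities theta^j / (1+theta)^(j+1)."""
    j = np.arange(kmax + 1)
    if theta <= 0:
        out = np.zeros(kmax + 1)
        out[0] = 1.0
        return out
    return np.exp(j * math.log(theta) - (j + 1) * math.log1p(theta))


def expansion_model_probs(kmax: int, tau: float, theta0: float,
                          theta1: float | None) -> np.ndarray:
    """Expected mismatch probabilities for k = 0..kmax under a sudden
    expansion from scaled size theta0 to theta1 at tau mutational units ago.

    Closed form from the exponential-mixture representation of the pairwise
    coalescent with a stepwise size change:

        F_j = G_j(theta1) + exp(-tau/theta1) *
              sum_i Pois(i; tau) * (G_{j-i}(theta0) - G_{j-i}(theta1))

    where G is the geometric equilibrium distribution.  ``theta1 = None``
    requests the infinite post-expansion size limit (pure Poisson shift).
    """
    pois = _poisson_pmf(kmax, tau)
    g0 = _geometric_equilibrium(theta0, kmax)
    if theta1 is None or np.isinf(theta1):
        return np.convolve(pois, g0)[: kmax + 1]
    g1 = _geometric_equilibrium(theta1, kmax)
    decay = math.exp(-tau / theta1) if theta1 > 0 else (1.0 if tau == 0 else 0.0)
    conv = np.convolve(pois, g0 - g1)[: kmax + 1]
    return np.maximum(g1 + decay * conv, 0.0)  # clip float round-off


def raggedness_index(frequencies: np.ndarray) -> float:
    """Harpending's raggedness: sum of squared successive frequency steps."""
    x = np.asarray(frequencies, dtype=float)
    return float(np.sum(np.diff(x) ** 2))


@dataclass
class ExpansionFit:
    tau: float
    theta0: float
    theta1: float
    SSD: float
    Hri: float
    p_SSD: float | None
    p_Hri: float | None
    n_bootstrap: int
    degenerate: bool = False
    bootstrap_SSD: np.ndarray | None = field(default=None, repr=False)
    bootstrap_Hri: np.ndarray | None = field(default=None, repr=False)


def _ssd(x: np.ndarray, tau: float, theta0: float, theta1: float) -> float:
    kmax = len(x) - 1
    model = expansion_model_probs(kmax, tau, theta0, theta1)
    return float(np.sum((x - model) ** 2))


_THETA1_MAX = 1.0e4


def _fit_spectrum(x: np.ndarray) -> tuple[float, float, float, float]:
    """Grid + Nelder-Mead minimisation of the SSD; returns (tau, th0, th1, SSD)."""
    kmax = len(x) - 1
    mean_k = float(np.dot(np.arange(kmax + 1), x))
    tau_hi = max(2.0 * kmax, 1.0)
    taus = np.linspace(0.0, min(tau_hi, 2 * mean_k + 4), 9)
    th0s = [0.0, 0.25 * mean_k, 0.5 * mean_k, mean_k]
    th1s = [1.0, 10.0, 100.0, 1000.0]
    best = (0.0, 0.0, 1.0, np.inf)
    for t in taus:
        for a in th0s:
            for b in th1s:
                if b < a:
                    continue
                v = _ssd(x, t, a, b)
                if v < best[3]:
                    best = (t, a, b, v)

    def objective(p: np.ndarray) -> float:
        t, a, d = p
        t = min(max(t, 0.0), tau_hi)
        a = max(a, 0.0)
        b = min(max(a + max(d, 0.0), a), _THETA1_MAX)
        return _ssd(x, t, a, b)

    res = minimize(objective, x0=[best[0], best[1], best[2] - best[1]],
                   method="Nelder-Mead",
                   options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-10})
    t, a, d = res.x
    t = min(max(t, 0.0), tau_hi)
    a = max(a, 0.0)
    b = min(max(a + max(d, 0.0), a), _THETA1_MAX)
    v = _ssd(x, t, a, b)
    if v <= best[3]:
        return t, a, b, v
    return best


def _simulate_spectrum(n: int, tau: float, theta0: float, theta1: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Pairwise-difference spectrum under the sudden-expansion coalescent."""
    th0 = max(theta0, 1e-6)
    th1 = max(theta1, 1e-6)
    parent, time = coal.sim_two_epoch(n, tau, th0, th1, rng)
    lens = coal.branch_lengths(parent, time)
    total = float(lens.sum())
    n_mut = rng.poisson(total / 2.0)
    muts = np.zeros(len(lens), dtype=np.int64)
    if n_mut:
        picks = rng.choice(len(lens), size=n_mut, p=lens / total)
        muts = np.bincount(picks, minlength=len(lens))
    ind = coal.leaf_indicator(parent, n)
    d = coal.pair_difference_matrix(muts, ind)
    iu = np.triu_indices(n, k=1)
    return np.bincount(d[iu].astype(np.int64))


def fit_sudden_expansion(spec: MismatchSpectrum, n_bootstrap: int = 9000,
                         seed: int | None = None,
                         infinite_theta1: bool = False) -> ExpansionFit:
    """Least-squares fit of the sudden-expansion model with parametric
    bootstrap p-values for SSD and the raggedness index.

    Per replicate, a sample of the same size is simulated under the fitted
    model, the model is re-fitted, and the replicate SSD (against its own
    re-fit) and raggedness are compared with the observed values; p is the
    fraction of replicates with statistic >= observed.
    """
    if spec.total_pairs < 3:
        raise ValueError("need at least 3 sequence pairs to fit")
    x = spec.frequencies
    hri_obs = raggedness_index(x)
    if len(x) == 1 or np.argmax(x) == 0 and x[0] == 1.0:
        warnings.warn("degenerate spectrum (all pairs identical); tau = 0 fit")
        return ExpansionFit(0.0, 0.0, 0.0, 0.0, hri_obs, None, None, 0,
                            degenerate=True)
    if infinite_theta1:
        kmax = len(x) - 1
        taus = np.linspace(0, 2 * kmax, 200)
        ssds = [float(np.sum((x - expansion_model_probs(kmax, t, 0.0, None)) ** 2))
                for t in taus]
        i = int(np.argmin(ssds))
        tau, th0, th1, ssd_obs = float(taus[i]), 0.0, math.inf, float(ssds[i])
    else:
        tau, th0, th1, ssd_obs = _fit_spectrum(x)
    rng = np.random.default_rng(seed)
    boot_ssd = np.empty(n_bootstrap)
    boot_hri = np.empty(n_bootstrap)
    th1_sim = min(th1, _THETA1_MAX) if np.isfinite(th1) else _THETA1_MAX
    for b in range(n_bootstrap):
        sim_counts = _simulate_spectrum(spec.n, tau, th0, th1_sim, rng)
        xb = sim_counts / sim_counts.sum()
        boot_hri[b] = raggedness_index(xb)
        if len(xb) == 1:
            boot_ssd[b] = 0.0
        else:
            _, _, _, boot_ssd[b] = _fit_spectrum(xb)
    p_ssd = float(np.mean(boot_ssd >= ssd_obs)) if n_bootstrap else None
    p_hri = float(np.mean(boot_hri >= hri_obs)) if n_bootstrap else None
    return ExpansionFit(tau, th0, th1, ssd_obs, hri_obs, p_ssd, p_hri,
                        n_bootstrap, bootstrap_SSD=boot_ssd,
                        bootstrap_Hri=boot_hri)


def population_summary(alignment: Alignment, n_replicates: int = 1000,
                       n_bootstrap: int = 1000,
                       seed: int | None = None) -> pd.DataFrame:
    """Per-population summary table: n, H, S, h, pi, D (p), Fs (p),
    SSD (p), Hri (p).  Undefined statistics are reported as NaN."""
    rows = []
    rng = np.random.default_rng(seed)
    for pop, sub in alignment.by_population().items():
        row: dict[str, object] = {"population": pop, "n": sub.n}
        table = collapse_haplotypes(sub)
        row["H"] = table.H
        try:
            stats = diversity_stats(table, sub)
            row.update(S=stats.S, h=stats.h, pi=stats.pi)
        except UndefinedStatisticError:
            row.update(S=np.nan, h=np.nan, pi=np.nan)
        for fn, key in ((tajimas_d, "D"), (fu_fs, "Fs")):
            try:
                res = fn(sub, n_replicates=n_replicates,
                         seed=int(rng.integers(2**31)))
                row[key] = res.statistic
                row[f"p_{key}"] = res.p_value
            except UndefinedStatisticError:
                row[key] = np.nan
                row[f"p_{key}"] = np.nan
        try:
            fit = fit_sudden_expansion(mismatch_spectrum(sub),
                                       n_bootstrap=n_bootstrap,
                                       seed=int(rng.integers(2**31)))
            row.update(SSD=fit.SSD, p_SSD=fit.p_SSD,
                       Hri=fit.Hri, p_Hri=fit.p_Hri)
        except ValueError:
            row.update(SSD=np.nan, p_SSD=np.nan, Hri=np.nan, p_Hri=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
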