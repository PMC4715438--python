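"""Conversion of coalescent-scaled inference output to demographic units,
and comparison of contemporary vs historical migration matrices.

Covers: per-locus mutation rates from per-site rates, avian generation time
T = a + s/(1-s) from age at maturity and adult survival, scaled divergence
time to years (t = B/U), mutation-scaled sizes to effective sizes
(Ne = q / (c * U * T)), MIGRATE's M = m/mu back to migration fractions,
Nem = theta*M/4, and a label-permutation Mantel test for asymmetric
migration matrices.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RateSpec",
    "GenerationTime",
    "MigrationTables",
    "MantelResult",
    "generation_time",
    "divergence_years",
    "effective_size",
    "rescale_ne",
    "m_from_M",
    "nem_from_theta_M",
    "mantel",
    "compare_migration_eras",
]


@dataclass(frozen=True)
class RateSpec:
    """Per-site per-year mutation rate and locus length.

    ``u`` may be given in substitutions/site/year directly, or in
    substitutions/site/My via ``per_my=True``.
    """

    u: float
    locus_length: int
    per_my: bool = False

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("mutation rate u must be > 0")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")

    @property
    def u_per_year(self) -> float:
        return self.u * 1e-6 if self.per_my else self.u

    @property
    def U(self) -> float:
        """Per-locus per-year rate: u * locus length."""
        return self.u_per_year * self.locus_length


@dataclass(frozen=True)
class GenerationTime:
    a: float
    s: float
    T: float


def generation_time(a: float, s: float) -> GenerationTime:
    """T = a + s/(1 - s): age at maturity plus expected adult lifespan."""
    if not 0.0 <= s < 1.0:
        raise ValueError("adult survival s must be in [0, 1)")
    if a <= 0:
        raise ValueError("age at maturity a must be > 0")
    return GenerationTime(a, s, a + s / (1.0 - s))


def divergence_years(t_scaled: float, rate: RateSpec) -> float:
    """Scaled divergence time (mutations per locus) to years: t = B / U."""
    if t_scaled < 0:
        raise ValueError("t_scaled must be >= 0")
    if rate.U == 0:
        raise ValueError("per-locus rate U is zero")
    return t_scaled / rate.U


def effective_size(q: float, rate: RateSpec, gen: GenerationTime,
                   inheritance_scalar: float = 4.0) -> float:
    """Ne = q / (c * U * T) with the per-generation locus rate U*T.

    ``inheritance_scalar`` c = 4 follows the q = 4*Ne*mu convention; use 2
    for strict maternal haploid accounting.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    denom = inheritance_scalar * rate.U * gen.T
    if denom == 0:
        raise ValueError("zero denominator in Ne conversion")
    return q / denom


def rescale_ne(n: float, t_old: float, t_new: float,
               decimals: int = 0) -> float:
    """Re-express an effective size under a different generation time.

    Ne is inversely proportional to T at fixed q and U, so the conversion is
    N * T_old / T_new, rounded half away from zero to ``decimals``.
    """
    if t_old <= 0 or t_new <= 0:
        raise ValueError("generation times must be > 0")
    value = n * t_old / t_new
    factor = 10.0**decimals
    scaled = value * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    out = rounded / factor
    return out if decimals > 0 else float(int(out))


def m_from_M(M: float, mu: float, paper_literal: bool = False) -> float:
    """Migration fraction from MIGRATE's mutation-scaled M = m/mu.

    The definition implies m = M * mu.  ``paper_literal=True`` applies the
    published text's wording (division by mu) verbatim; it yields values
    above 1 and is kept only for transparency, with a warning.
    """
    if M < 0:
        raise ValueError("M must be >= 0")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if paper_literal:
        warnings.warn(
            "paper-literal mode divides M by mu, producing values that are "
            "not interpretable as migration fractions; correlation-based "
            "comparisons are unaffected", stacklevel=2)
        return M / mu
    return M * mu


def nem_from_theta_M(theta: float, M: float) -> float:
    """Effective migrants per generation: Nem = theta * M / 4."""
    if theta < 0 or M < 0:
        raise ValueError("theta and M must be >= 0")
    return theta * M / 4.0


@dataclass
class MigrationTables:
    """Contemporary (proportion, rows = recipients) and historical (scaled
    M = m/mu) 3x3-style migration matrices with population labels."""

    populations: list[str]
    contemporary_m: np.ndarray
    historical_M: np.ndarray
    mu: float = 5e-4
    theta: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.populations)
        self.contemporary_m = np.asarray(self.contemporary_m, dtype=float)
        self.historical_M = np.asarray(self.historical_M, dtype=float)
        for name, mat in (("contemporary_m", self.contemporary_m),
                          ("historical_M", self.historical_M)):
            if mat.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            if (mat[~np.isnan(mat)] < 0).any():
                raise ValueError(f"{name} has negative entries")
        rows = np.nansum(self.contemporary_m, axis=1)
        if not np.allclose(rows, 1.0, atol=0.01):
            raise ValueError("contemporary migration rows must sum to 1 +/- 0.01")

    def historical_m(self, paper_literal: bool = False) -> np.ndarray:
        out = np.full_like(self.historical_M, np.nan)
        k = len(self.populations)
        for i in range(k):
            for j in range(k):
                if i != j and np.isfinite(self.historical_M[i, j]):
                    out[i, j] = m_from_M(self.historical_M[i, j], self.mu,
                                         paper_literal=paper_literal)
        return out

    def nem_matrix(self) -> np.ndarray:
        if self.theta is None:
            raise ValueError("theta per population is required for Nem")
        k = len(self.populations)
        out = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(k):
                if i != j and np.isfinite(self.historical_M[i, j]):
                    out[i, j] = nem_from_theta_M(self.theta[i],
                                                 self.historical_M[i, j])
        return out


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    exact: bool


def _offdiag(mat: np.ndarray) -> np.ndarray:
    k = mat.shape[0]
    mask = ~np.eye(k, dtype=bool)
    return mat[mask]


def mantel(mat_a: np.ndarray, mat_b: np.ndarray, n_perm: int = 5000,
           seed: int | None = None) -> MantelResult:
    """Matrix correlation over off-diagonal cells with a two-tailed p-value
    from simultaneous row/column label permutations of the second matrix.

    Works for asymmetric matrices (e.g. directional migration).  When the
    number of distinct label permutations does not exceed ``n_perm`` the
    null is enumerated exactly and the result is flagged.
    """
    a = np.asarray(mat_a, dtype=float)
    b = np.asarray(mat_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    k = a.shape[0]
    if k < 3:
        raise ValueError("need at least a 3x3 matrix")
    xa = _offdiag(a)
    xb = _offdiag(b)
    if np.nanstd(xa) == 0 or np.nanstd(xb) == 0:
        raise ValueError("constant off-diagonal cells: r undefined")

    def corr(perm: np.ndarray) -> float:
        bp = b[np.ix_(perm, perm)]
        x, y = xa, _offdiag(bp)
        ok = np.isfinite(x) & np.isfinite(y)
        return float(np.corrcoef(x[ok], y[ok])[0, 1])

    r_obs = corr(np.arange(k))
    n_fact = math.factorial(k)
    if n_fact <= n_perm:
        rs = np.array([corr(np.array(p))
                       for p in itertools.permutations(range(k))])
        p = float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))
        return MantelResult(r_obs, p, n_fact, exact=True)
    rng = np.random.default_rng(seed)
    count = 1  # identity permutation included
    for _ in range(n_perm - 1):
        perm = rng.permutation(k)
        if abs(corr(perm)) >= abs(r_obs) - 1e-12:
            count += 1
    return MantelResult(r_obs, count / n_perm, n_perm, exact=False)


def compare_migration_eras(tables: MigrationTables, n_perm: int = 5000,
                           seed: int | None = None,
                           paper_literal: bool = False) -> dict:
    """Mantel comparison of contemporary vs historical migration fractions,
    plus per-pair era ratios (historical / contemporary)."""
    hist_m = tables.historical_m(paper_literal=paper_literal)
    res = mantel(tables.contemporary_m, hist_m, n_perm=n_perm, seed=seed)
    k = len(tables.populations)
    ratios = {}
    for i in range(k):
        for j in range(k):
            if i == j or not np.isfinite(hist_m[i, j]):
                continue
            pair = f"{tables.populations[j]}->{tables.populations[i]}"
            contemp = tables.contemporary_m[i, j]
            ratios[pair] = float(hist_m[i, j] / contemp) if contemp > 0 else np.inf
    return {"mantel": res, "era_ratios": ratios,
            "historical_m": hist_m,
            "contemporary_m": tables.contemporary_m}


def read_ima_table(path) -> pd.DataFrame:
    """CSV with columns: parameter, mean, HPD95Lo, HPD95Hi."""
    df = pd.read_csv(path)
    required = {"parameter", "mean", "HPD95Lo", "HPD95Hi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"IMa table missing columns: {sorted(missing)}")
    return df


def read_migration_matrix(path) -> tuple[list[str], np.ndarray]:
    """CSV with row/column population headers; '-' or blank diagonal -> NaN."""
    df = pd.read_csv(path, index_col=0)
    df = df.replace({"-": np.nan, "–": np.nan})
    return list(df.index), df.astype(float).to_numpy()
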