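"""Synthetic data generators emulating the statistical structure of a
three-population contact-zone study system: mtDNA-like sequence alignments
from a structured coalescent, diploid microsatellite genotypes with a
target differentiation level, occurrence/background climate tables with
controllable occupied-niche offsets, and a clinal plumage trait table.

Every generator takes an explicit seed and is byte-reproducible; there is
no global random state.  Defaults emulate the study system the package was
built around: three populations separated by two biogeographic barriers,
recent divergence with asymmetric gene flow, twelve microsatellite loci,
nineteen bioclimatic variables, and a west-to-east plumage cline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _coalescent as coal
from .clusterpost import MISSING, GenotypeMatrix
from .colourindex import PlumageScheme, default_scheme
from .nichetest import ClimateTable
from .seqstats import Alignment

__all__ = [
    "SimSequenceConfig",
    "SimGenotypeConfig",
    "SimLandscapeConfig",
    "SimPlumageConfig",
    "sim_sequences",
    "sim_microsats",
    "sim_landscape",
    "sim_plumage",
    "wc_fst",
]

_BASES = np.array(list("ACGT"))


def _require(cond: bool, fieldname: str, message: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {message}")


@dataclass
class SimSequenceConfig:
    """Structured-coalescent sequence simulation settings.

    ``theta_per_site`` is the scaled per-site diversity 2*N*mu (haploid,
    uniparental marker convention), so expected pairwise diversity per site
    under panmixia equals it.  ``migration_rate`` is the per-generation
    fraction of lineages exchanged per ordered population pair; a scalar is
    expanded to a symmetric matrix.  ``effective_size`` (haploid N per
    deme) sets the coalescent time scale for the per-generation quantities.
    """

    n_pops: int = 3
    n_per_pop: int = 20
    locus_length: int = 1100
    theta_per_site: float = 0.005
    divergence_generations: float = 50_000.0
    migration_rate: float | np.ndarray = 1e-4
    effective_size: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_pops in (2, 3), "n_pops", "must be 2 or 3")
        _require(self.n_per_pop >= 1, "n_per_pop", "must be >= 1")
        _require(self.locus_length >= 1, "locus_length", "must be >= 1")
        _require(self.theta_per_site >= 0, "theta_per_site", "must be >= 0")
        _require(self.divergence_generations >= 0, "divergence_generations",
                 "must be >= 0")
        _require(self.effective_size > 0, "effective_size", "must be > 0")
        m = self.migration_rate
        if np.isscalar(m):
            _require(m >= 0, "migration_rate", "must be >= 0")
            mat = np.full((self.n_pops, self.n_pops), float(m))
            np.fill_diagonal(mat, 0.0)
            self.migration_matrix = mat
        else:
            mat = np.asarray(m, dtype=float)
            _require(mat.shape == (self.n_pops, self.n_pops),
                     "migration_rate", "matrix must be n_pops x n_pops")
            _require((mat >= 0).all(), "migration_rate", "entries must be >= 0")
            mat = mat.copy()
            np.fill_diagonal(mat, 0.0)
            self.migration_matrix = mat


def sim_sequences(config: SimSequenceConfig) -> Alignment:
    """Simulate a labelled haploid alignment under an island model with a
    split time, Poisson per-site mutations and symmetric substitution."""
    rng = np.random.default_rng(config.seed)
    n = config.n_pops * config.n_per_pop
    pop_of = np.repeat(np.arange(config.n_pops), config.n_per_pop)
    sizes = np.full(config.n_pops, config.effective_size)
    parent, time = coal.sim_structured(
        pop_of, sizes, config.migration_matrix,
        config.divergence_generations, rng)
    L = config.locus_length
    mu = config.theta_per_site / (2.0 * config.effective_size)
    # root sequence, then mutations applied from the root down
    n_nodes = 2 * n - 1
    seqs = np.empty((n_nodes, L), dtype=np.int8)
    root = n_nodes - 1
    seqs[root] = rng.integers(0, 4, size=L)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for node in range(n_nodes - 1):
        children[parent[node]].append(node)
    lens = coal.branch_lengths(parent, time)
    stack = [root]
    while stack:
        node = stack.pop()
        for ch in sorted(children[node]):
            seq = seqs[node].copy()
            n_mut = rng.poisson(mu * L * lens[ch])
            for _ in range(n_mut):
                site = rng.integers(0, L)
                seq[site] = (seq[site] + rng.integers(1, 4)) % 4
            seqs[ch] = seq
            stack.append(ch)
    ids = [f"pop{p + 1}_{i + 1}"
           for p in range(config.n_pops) for i in range(config.n_per_pop)]
    pops = [f"pop{p + 1}" for p in pop_of]
    strings = ["".join(_BASES[row]) for row in seqs[:n]]
    return Alignment(ids, strings, pops)


@dataclass
class SimGenotypeConfig:
    """Balding-Nichols style microsatellite genotypes.

    Cluster allele frequencies are Dirichlet draws around a shared ancestral
    frequency with concentration (1 - F)/F, so the expected Weir-Cockerham
    FST of pure clusters is close to ``fst_target``.  ``admixture_fractions``
    (individuals x clusters) lets contact-zone individuals draw each gene
    copy from a mixture; by default ``n_per_cluster`` pure individuals per
    cluster are produced.  Missing genotypes (whole-locus) are coded -9.
    """

    n_clusters: int = 3
    n_loci: int = 12
    alleles_per_locus: int = 8
    fst_target: float = 0.1
    n_per_cluster: int = 50
    admixture_fractions: np.ndarray | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_clusters >= 1, "n_clusters", "must be >= 1")
        _require(self.n_loci >= 1, "n_loci", "must be >= 1")
        _require(self.alleles_per_locus >= 2, "alleles_per_locus", "must be >= 2")
        _require(0.0 <= self.fst_target < 1.0, "fst_target", "must be in [0, 1)")
        _require(0.0 <= self.missing_rate < 1.0, "missing_rate", "must be in [0, 1)")
        if self.admixture_fractions is not None:
            q = np.asarray(self.admixture_fractions, dtype=float)
            _require(q.ndim == 2 and q.shape[1] == self.n_clusters,
                     "admixture_fractions", "must be individuals x clusters")
            _require(np.allclose(q.sum(axis=1), 1.0),
                     "admixture_fractions", "rows must sum to 1")
            _require((q >= 0).all(), "admixture_fractions",
                     "entries must be >= 0")
            self.admixture_fractions = q
        else:
            _require(self.n_per_cluster >= 1, "n_per_cluster", "must be >= 1")
            q = np.zeros((self.n_clusters * self.n_per_cluster, self.n_clusters))
            for c in range(self.n_clusters):
                q[c * self.n_per_cluster:(c + 1) * self.n_per_cluster, c] = 1.0
            self.admixture_fractions = q


def sim_microsats(config: SimGenotypeConfig) -> GenotypeMatrix:
    rng = np.random.default_rng(config.seed)
    q = config.admixture_fractions
    n_ind = q.shape[0]
    f = config.fst_target
    freqs = np.empty((config.n_loci, config.n_clusters, config.alleles_per_locus))
    for locus in range(config.n_loci):
        ancestral = rng.dirichlet(np.ones(config.alleles_per_locus))
        if f == 0:
            freqs[locus] = np.tile(ancestral, (config.n_clusters, 1))
        else:
            conc = ancestral * (1.0 - f) / f
            for c in range(config.n_clusters):
                freqs[locus, c] = rng.dirichlet(conc)
    alleles = np.empty((n_ind, 2 * config.n_loci), dtype=np.int64)
    for i in range(n_ind):
        for locus in range(config.n_loci):
            for copy in range(2):
                c = rng.choice(config.n_clusters, p=q[i])
                a = rng.choice(config.alleles_per_locus, p=freqs[locus, c])
                alleles[i, 2 * locus + copy] = a + 1  # allele codes 1-based
    if config.missing_rate > 0:
        mask = rng.random((n_ind, config.n_loci)) < config.missing_rate
        for locus in range(config.n_loci):
            alleles[mask[:, locus], 2 * locus] = MISSING
            alleles[mask[:, locus], 2 * locus + 1] = MISSING
    cluster_of = np.argmax(q, axis=1)
    ids = [f"ind_{i + 1}" for i in range(n_ind)]
    pops = [f"cluster{c + 1}" for c in cluster_of]
    loci = [f"locus{j + 1}" for j in range(config.n_loci)]
    return GenotypeMatrix(ids, pops, alleles, loci)


def wc_fst(gm: GenotypeMatrix) -> float:
    """Multilocus Weir-Cockerham theta over populations (missing excluded)."""
    pops = sorted(set(gm.populations))
    pop_idx = {p: np.array([i for i, q in enumerate(gm.populations) if q == p])
               for p in pops}
    num = den = 0.0
    r = len(pops)
    if r < 2:
        raise ValueError("FST needs >= 2 populations")
    for locus in range(gm.n_loci):
        calls = gm.alleles[:, 2 * locus: 2 * locus + 2]
        valid = (calls != MISSING).all(axis=1)
        alleles = np.unique(calls[valid])
        if len(alleles) < 2:
            continue
        n_i, p_i, h_i = [], [], []
        for p in pops:
            sel = pop_idx[p][valid[pop_idx[p]]]
            if len(sel) == 0:
                continue
            sub = calls[sel]
            n_i.append(len(sel))
            p_i.append([(sub == a).mean() for a in alleles])
            h_i.append([((sub[:, 0] == a) ^ (sub[:, 1] == a)).mean()
                        for a in alleles])
        n_i = np.array(n_i, dtype=float)
        p_i = np.array(p_i)
        h_i = np.array(h_i)
        ri = len(n_i)
        if ri < 2:
            continue
        nbar = n_i.mean()
        nc = (ri * nbar - (n_i**2).sum() / (ri * nbar)) / (ri - 1)
        for ai in range(len(alleles)):
            pbar = (n_i * p_i[:, ai]).sum() / (ri * nbar)
            s2 = (n_i * (p_i[:, ai] - pbar) ** 2).sum() / ((ri - 1) * nbar)
            hbar = (n_i * h_i[:, ai]).sum() / (ri * nbar)
            a = nbar / nc * (s2 - (pbar * (1 - pbar) - (ri - 1) / ri * s2
                                   - hbar / 4.0) / (nbar - 1))
            b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (ri - 1) / ri * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2.0
            num += a
            den += a + b + c
    if den == 0:
        raise ValueError("no polymorphic loci: FST undefined")
    return float(num / den)


@dataclass
class SimLandscapeConfig:
    """Per-group climate landscapes with controllable occupied offsets.

    Groups occupy disjoint longitude bands (west to east).  Background
    candidates are multivariate-normal climate draws around each group's
    centroid; occurrences come from the same distribution displaced by
    ``occupied_offset``, so a zero offset means the occupied niche matches
    the available background exactly.
    """

    n_groups: int = 3
    n_vars: int = 19
    group_centroids: np.ndarray | None = None
    background_spread: float | np.ndarray = 1.0
    occupied_offset: np.ndarray | None = None
    n_occurrences: int = 100
    n_background_candidates: int = 1000
    elevation_means: tuple = (1375.0, 921.0, 542.0)
    elevation_sds: tuple = (700.0, 526.0, 585.0)
    lon_west: float = -110.0
    lon_east: float = -83.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_groups >= 1, "n_groups", "must be >= 1")
        _require(self.n_vars >= 1, "n_vars", "must be >= 1")
        _require(self.n_occurrences >= 1, "n_occurrences", "must be >= 1")
        _require(self.n_background_candidates >= 1,
                 "n_background_candidates", "must be >= 1")
        if self.group_centroids is None:
            # partially overlapping niches: 1.5 sd spacing on the first two axes
            cent = np.zeros((self.n_groups, self.n_vars))
            for g in range(self.n_groups):
                cent[g, 0] = 1.5 * g
                if self.n_vars > 1:
                    cent[g, 1] = 0.75 * g
            self.group_centroids = cent
        else:
            cent = np.asarray(self.group_centroids, dtype=float)
            _require(cent.shape == (self.n_groups, self.n_vars),
                     "group_centroids", "must be n_groups x n_vars")
            _require(np.isfinite(cent).all(), "group_centroids",
                     "must be finite")
            self.group_centroids = cent
        if self.occupied_offset is None:
            self.occupied_offset = np.zeros((self.n_groups, self.n_vars))
        else:
            off = np.asarray(self.occupied_offset, dtype=float)
            _require(off.shape == (self.n_groups, self.n_vars),
                     "occupied_offset", "must be n_groups x n_vars")
            self.occupied_offset = off
        sp = self.background_spread
        if np.isscalar(sp):
            _require(sp > 0, "background_spread", "must be > 0")
            self.covariance = float(sp) ** 2 * np.eye(self.n_vars)
        else:
            cov = np.asarray(sp, dtype=float)
            _require(cov.shape == (self.n_vars, self.n_vars),
                     "background_spread", "covariance must be n_vars x n_vars")
            eig = np.linalg.eigvalsh((cov + cov.T) / 2.0)
            _require(bool((eig > 0).all()), "background_spread",
                     "covariance must be positive-definite")
            self.covariance = cov


def sim_landscape(config: SimLandscapeConfig) -> tuple[ClimateTable, ClimateTable]:
    """Returns (occurrence table, background-candidate table)."""
    rng = np.random.default_rng(config.seed)
    var_cols = [f"BIO{i + 1}" for i in range(config.n_vars)]
    band_edges = np.linspace(config.lon_west, config.lon_east,
                             config.n_groups + 1)
    occ_rows, bg_rows = [], []
    for g in range(config.n_groups):
        name = f"group{g + 1}"
        lo, hi = band_edges[g], band_edges[g + 1]
        emean = config.elevation_means[g % len(config.elevation_means)]
        esd = config.elevation_sds[g % len(config.elevation_sds)]
        for kind, count, offset, rows in (
                ("bg", config.n_background_candidates,
                 np.zeros(config.n_vars), bg_rows),
                ("occ", config.n_occurrences,
                 config.occupied_offset[g], occ_rows)):
            clim = rng.multivariate_normal(
                config.group_centroids[g] + offset, config.covariance,
                size=count)
            lons = rng.uniform(lo, hi, size=count)
            lats = rng.uniform(10.0, 25.0, size=count)
            elev = rng.normal(emean, esd, size=count)
            for i in range(count):
                row = {"id": f"{kind}_{name}_{i + 1}", "group": name,
                       "longitude": lons[i], "latitude": lats[i],
                       "elevation": elev[i]}
                row.update(dict(zip(var_cols, clim[i])))
                rows.append(row)
    occ = ClimateTable(pd.DataFrame(occ_rows), var_cols)
    bg = ClimateTable(pd.DataFrame(bg_rows), var_cols)
    return occ, bg


@dataclass
class SimPlumageConfig:
    """Clinal plumage states: maximal scores west of the first barrier,
    zero east of the second, linear in between, with optional score noise."""

    n_specimens: int = 145
    cline_midpoints: tuple = (-94.0, -85.5)
    noise_sd: float = 0.0
    lon_west: float = -110.0
    lon_east: float = -83.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_specimens >= 2, "n_specimens", "must be >= 2")
        w, e = self.cline_midpoints
        _require(w < e, "cline_midpoints", "must be ordered west -> east")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.lon_west < self.cline_midpoints[0],
                 "lon_west", "must lie west of the first barrier")
        _require(self.lon_east > self.cline_midpoints[1],
                 "lon_east", "must lie east of the second barrier")


def sim_plumage(config: SimPlumageConfig,
                scheme: PlumageScheme | None = None) -> pd.DataFrame:
    """Trait table (id, longitude, ten character-state columns).

    Longitudes are evenly spaced across the range so both cline endpoints
    are represented; the expected per-character score falls linearly from
    its maximum at the western barrier to 0 at the eastern barrier.
    """
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(config.seed)
    lons = np.linspace(config.lon_west, config.lon_east, config.n_specimens)
    w, e = config.cline_midpoints
    frac = np.clip((e - lons) / (e - w), 0.0, 1.0)
    rows = []
    for i, (lon, f) in enumerate(zip(lons, frac)):
        row: dict[str, object] = {"id": f"spec_{i + 1}", "longitude": lon}
        for char in scheme.character_names:
            mx = scheme.maximum(char)
            score = f * mx + (rng.normal(0.0, config.noise_sd)
                              if config.noise_sd > 0 else 0.0)
            score = int(np.clip(round(score), 0, mx))
            row[char] = scheme.state_for_score(char, score)
        rows.append(row)
    return pd.DataFrame(rows)
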