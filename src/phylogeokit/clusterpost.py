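"""Post-processing of Bayesian assignment output: the Evanno second-order
rate-of-change statistic (DeltaK) on Ln P(K) tables, and mean-centred PCA
of one-hot-encoded microsatellite genotypes."""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "LnPTable",
    "DeltaKResult",
    "GenotypeMatrix",
    "evanno_delta_k",
    "genotype_pca",
    "read_genotype_table",
    "read_structure_logs",
]

MISSING = -9


@dataclass
class LnPTable:
    """Rows of (K, replicate, lnP) from repeated assignment runs."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"K", "replicate", "lnP"}
        if not required <= set(self.df.columns):
            raise ValueError(f"LnPTable needs columns {sorted(required)}")
        ks = sorted(self.df["K"].unique())
        if ks != list(range(min(ks), max(ks) + 1)):
            raise ValueError("K values must be contiguous")


@dataclass
class DeltaKResult:
    per_k: pd.DataFrame  # K, mean_lnP, sd_lnP, abs_l2, delta_k
    best_k: int


def evanno_delta_k(table: LnPTable | pd.DataFrame) -> DeltaKResult:
    """DeltaK(K) = mean_r |lnP_r(K+1) - 2 lnP_r(K) + lnP_r(K-1)| / sd_r(lnP(K)).

    Replicates are paired by their replicate id across K.  DeltaK is defined
    only at interior K; the best K is the interior argmax.
    """
    df = table.df if isinstance(table, LnPTable) else LnPTable(table).df
    ks = sorted(df["K"].unique())
    if len(ks) < 3:
        raise ValueError("DeltaK needs at least 3 contiguous K values")
    piv = df.pivot_table(index="replicate", columns="K", values="lnP")
    if piv.isna().any().any():
        raise ValueError("every replicate must have an lnP for every K")
    if len(piv) < 2:
        raise ValueError("DeltaK needs >= 2 replicates per K")
    mean = piv.mean(axis=0)
    sd = piv.std(axis=0, ddof=1)
    rows = []
    for k in ks:
        row = {"K": k, "mean_lnP": mean[k], "sd_lnP": sd[k],
               "abs_l2": np.nan, "delta_k": np.nan}
        if ks[0] < k < ks[-1]:
            if sd[k] == 0:
                raise ValueError(f"sd of lnP is zero at K = {k}")
            l2 = piv[k + 1] - 2 * piv[k] + piv[k - 1]
            row["abs_l2"] = float(np.mean(np.abs(l2)))
            row["delta_k"] = row["abs_l2"] / sd[k]
        rows.append(row)
    per_k = pd.DataFrame(rows)
    interior = per_k.dropna(subset=["delta_k"])
    best = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return DeltaKResult(per_k, best)


@dataclass
class GenotypeMatrix:
    """Diploid allele calls: individuals x (2 * loci), missing coded -9."""

    ids: list[str]
    populations: list[str]
    alleles: np.ndarray  # (n, 2*n_loci) integer
    locus_names: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, cols = self.alleles.shape
        if cols != 2 * len(self.locus_names):
            raise ValueError("allele columns must be 2 per locus")
        if len(self.ids) != n or len(self.populations) != n:
            raise ValueError("ids/populations must match individual count")
        bad = (self.alleles <= 0) & (self.alleles != MISSING)
        if bad.any():
            raise ValueError("allele codes must be positive integers or -9")

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)


def read_genotype_table(path) -> GenotypeMatrix:
    """Tab-separated: id, pop, then two columns per locus."""
    df = pd.read_csv(path, sep="\t")
    ids = df.iloc[:, 0].astype(str).tolist()
    pops = df.iloc[:, 1].astype(str).tolist()
    allele_cols = df.columns[2:]
    loci = []
    for c in allele_cols[::2]:
        loci.append(re.sub(r"(_[12]|\.[12])$", "", str(c)))
    return GenotypeMatrix(ids, pops, df[allele_cols].to_numpy(), loci)


def write_genotype_table(gm: GenotypeMatrix, path) -> None:
    cols = {}
    for li, name in enumerate(gm.locus_names):
        cols[f"{name}_1"] = gm.alleles[:, 2 * li]
        cols[f"{name}_2"] = gm.alleles[:, 2 * li + 1]
    df = pd.DataFrame({"id": gm.ids, "pop": gm.populations, **cols})
    df.to_csv(path, sep="\t", index=False)


def read_structure_logs(paths) -> LnPTable:
    """Scrape 'Estimated Ln Prob of Data' and the K setting from run logs."""
    rows = []
    for rep, path in enumerate(paths):
        text = open(path).read()
        mk = re.search(r"(\d+)\s+populations assumed", text)
        mp = re.search(r"Estimated Ln Prob of Data\s*=\s*(-?[\d.]+)", text)
        if not (mk and mp):
            raise ValueError(f"could not parse STRUCTURE log: {path}")
        rows.append({"K": int(mk.group(1)), "replicate": rep,
                     "lnP": float(mp.group(1))})
    return LnPTable(pd.DataFrame(rows))


def _one_hot_counts(gm: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Allele-count encoding: one column per (locus, allele); missing -> NaN."""
    n = len(gm.ids)
    blocks, names = [], []
    for li, locus in enumerate(gm.locus_names):
        calls = gm.alleles[:, 2 * li: 2 * li + 2]
        alleles = np.unique(calls[calls != MISSING])
        if len(alleles) == 0:
            warnings.warn(f"locus {locus} is entirely missing; dropped")
            continue
        block = np.full((n, len(alleles)), np.nan)
        for ai, a in enumerate(alleles):
            counts = (calls == a).sum(axis=1).astype(float)
            counts[(calls == MISSING).any(axis=1)] = np.nan
            block[:, ai] = counts
        blocks.append(block)
        names.extend(f"{locus}.{a}" for a in alleles)
    return np.hstack(blocks), names


@dataclass
class GenotypePCAResult:
    coordinates: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray
    feature_names: list[str]
    ids: list[str]
    populations: list[str]


def genotype_pca(gm: GenotypeMatrix, n_components: int | None = None) -> GenotypePCAResult:
    """Mean-centred PCA of the one-hot allele-count matrix.

    Missing genotypes are imputed to the column mean (so they sit at the
    centroid and do not drive any axis).  Components follow a deterministic
    sign convention: the largest-magnitude loading of each axis is positive.
    """
    if len(gm.ids) < 3:
        raise ValueError("PCA needs at least 3 individuals")
    if gm.n_loci < 2:
        raise ValueError("PCA needs at least 2 loci")
    x, names = _one_hot_counts(gm)
    col_mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(col_mean, idx[1])
    if n_components is None:
        n_components = min(x.shape[0] - 1, x.shape[1], 10)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)  # sklearn centres, no scaling
    load = pca.components_
    for c in range(load.shape[0]):
        j = int(np.argmax(np.abs(load[c])))
        if load[c, j] < 0:
            load[c] *= -1
            coords[:, c] *= -1
    return GenotypePCAResult(coords, pca.explained_variance_ratio_, load,
                             names, list(gm.ids), list(gm.populations))
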