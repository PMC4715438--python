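"""Background-vs-occupied niche divergence testing on PCA axes.

The test asks, per principal component of environmental space, whether two
taxa's occupied niches differ more (divergence) or less (conservatism) than
the available environmental backgrounds inside their ranges.  Backgrounds
are delimited by minimum convex polygons around occurrences, characterised
by random points inside them, and the null distribution of the background
divergence score is built by jackknife resampling (75% of points without
replacement per replicate by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import kruskal, norm, pearsonr, rankdata
from shapely.geometry import Point, Polygon
from sklearn.decomposition import PCA

__all__ = [
    "ClimateTable",
    "ConvexPolygon",
    "NicheAxes",
    "AxisTestResult",
    "select_uncorrelated_vars",
    "minimum_convex_polygon",
    "sample_background",
    "fit_niche_axes",
    "background_divergence_null",
    "classify_axis",
    "niche_divergence_test",
    "axis_geo_correlation",
    "elevation_comparison",
]

BIOCLIM_VARS = [f"BIO{i}" for i in range(1, 20)]


@dataclass
class ClimateTable:
    """Occurrence or background records with coordinates, elevation and
    bioclimatic variables."""

    df: pd.DataFrame
    var_cols: list[str] | None = None

    def __post_init__(self) -> None:
        required = {"id", "group", "longitude", "latitude"}
        if not required <= set(self.df.columns):
            raise ValueError(f"climate table needs columns {sorted(required)}")
        if self.df["id"].duplicated().any():
            raise ValueError("duplicated record ids")
        coords = self.df[["longitude", "latitude"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        if self.var_cols is None:
            self.var_cols = [c for c in self.df.columns if c.upper().startswith("BIO")]

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.df["group"].astype(str)))

    def values(self, columns: list[str] | None = None) -> np.ndarray:
        return self.df[columns or self.var_cols].to_numpy(dtype=float)

    def for_group(self, group: str) -> "ClimateTable":
        sub = self.df[self.df["group"].astype(str) == str(group)].reset_index(drop=True)
        return ClimateTable(sub, list(self.var_cols))

    @classmethod
    def from_csv(cls, path) -> "ClimateTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def select_uncorrelated_vars(table: ClimateTable, threshold: float = 0.7,
                             priority: list[str] | None = None) -> list[str]:
    """Greedy scan in priority order keeping variables whose |Pearson r|
    against every already-kept variable stays below the threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if len(table.df) < 3:
        raise ValueError("need at least 3 records")
    order = priority or list(table.var_cols)
    unknown = set(order) - set(table.var_cols)
    if unknown:
        raise ValueError(f"unknown variables in priority list: {sorted(unknown)}")
    kept: list[str] = []
    for var in order:
        x = table.df[var].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"variable {var} is constant; excluded")
            continue
        ok = True
        for prev in kept:
            r = np.corrcoef(x, table.df[prev].to_numpy(dtype=float))[0, 1]
            if abs(r) >= threshold:
                ok = False
                break
        if ok:
            kept.append(var)
    return kept


@dataclass
class ConvexPolygon:
    vertices: np.ndarray  # (k, 2) counter-clockwise (longitude, latitude)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if len(self.vertices) < 3:
            raise ValueError("polygon needs >= 3 vertices")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return float(self.shapely.area)

    def contains(self, lon: float, lat: float) -> bool:
        p = Point(lon, lat)
        poly = self.shapely
        return poly.contains(p) or poly.touches(p)


def minimum_convex_polygon(points: np.ndarray) -> ConvexPolygon:
    """Convex hull of occurrence coordinates, counter-clockwise order."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need >= 3 points for a convex polygon")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) points") from exc
    return ConvexPolygon(pts[hull.vertices])  # Qhull returns CCW order in 2D


def sample_background(poly: ConvexPolygon, n: int,
                      climate_field: ClimateTable,
                      seed: int | None = None,
                      group: str | None = None) -> ClimateTable:
    """Uniform points inside the polygon (rejection from the bounding box)
    with climate attached from the nearest record of ``climate_field``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if poly.area <= 0:
        raise ValueError("polygon has zero area")
    rng = np.random.default_rng(seed)
    lo = poly.vertices.min(axis=0)
    hi = poly.vertices.max(axis=0)
    pts = []
    shp = poly.shapely
    while len(pts) < n:
        cand = rng.uniform(lo, hi, size=(max(4 * (n - len(pts)), 16), 2))
        for c in cand:
            if shp.contains(Point(c)) or shp.touches(Point(c)):
                pts.append(c)
                if len(pts) == n:
                    break
    pts = np.array(pts)
    ref_xy = climate_field.df[["longitude", "latitude"]].to_numpy(dtype=float)
    ref_vals = climate_field.values()
    d2 = ((pts[:, None, :] - ref_xy[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    grp = group if group is not None else (
        climate_field.groups[0] if climate_field.groups else "bg")
    out = pd.DataFrame({
        "id": [f"bg_{grp}_{i}" for i in range(n)],
        "group": grp,
        "longitude": pts[:, 0],
        "latitude": pts[:, 1],
    })
    if "elevation" in climate_field.df.columns:
        out["elevation"] = climate_field.df["elevation"].to_numpy()[nearest]
    for ci, col in enumerate(climate_field.var_cols):
        out[col] = ref_vals[nearest, ci]
    return ClimateTable(out, list(climate_field.var_cols))


@dataclass
class NicheAxes:
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    occurrence_scores: np.ndarray
    background_scores: np.ndarray
    occurrence_groups: np.ndarray
    background_groups: np.ndarray
    var_cols: list[str]
    mean_: np.ndarray
    scale_: np.ndarray


def fit_niche_axes(occurrences: ClimateTable, backgrounds: ClimateTable,
                   standardize: bool = True,
                   n_axes: int | None = None) -> NicheAxes:
    """PCA fitted on pooled background records; occurrences are projected
    onto the same axes.  Variables are standardised to unit variance by
    default (bioclim units are incommensurable)."""
    var_cols = [c for c in occurrences.var_cols if c in backgrounds.var_cols]
    if not var_cols:
        raise ValueError("no shared climate variables")
    bg = backgrounds.values(var_cols)
    occ = occurrences.values(var_cols)
    if len(bg) + len(occ) < 3:
        raise ValueError("need at least 3 records")
    if n_axes is None:
        n_axes = min(4, len(var_cols))
    if n_axes > len(var_cols):
        raise ValueError("fewer variables than requested axes")
    mean = bg.mean(axis=0)
    scale = bg.std(axis=0, ddof=0) if standardize else np.ones(len(var_cols))
    scale = np.where(scale == 0, 1.0, scale)
    zb = (bg - mean) / scale
    zo = (occ - mean) / scale
    pca = PCA(n_components=n_axes, svd_solver="full")
    bg_scores = pca.fit_transform(zb)
    load = pca.components_
    occ_scores = zo @ load.T
    for c in range(load.shape[0]):
        j = int(np.argmax(np.abs(load[c])))
        if load[c, j] < 0:
            load[c] *= -1
            bg_scores[:, c] *= -1
            occ_scores[:, c] *= -1
    return NicheAxes(load, pca.explained_variance_ratio_, occ_scores,
                     bg_scores,
                     occurrences.df["group"].astype(str).to_numpy(),
                     backgrounds.df["group"].astype(str).to_numpy(),
                     var_cols, mean, scale)


def background_divergence_null(bg_a: np.ndarray, bg_b: np.ndarray,
                               n_rep: int = 1000, fraction: float = 0.75,
                               seed: int | None = None, alpha: float = 0.05,
                               replace: bool = False
                               ) -> tuple[float, float, np.ndarray]:
    """Jackknife null for the background divergence score.

    Per replicate, ceil(fraction * n) points are drawn from each group
    (without replacement unless ``replace``), and |mean(A*) - mean(B*)| is
    recorded; returns the empirical (alpha/2, 1 - alpha/2) quantiles and the
    replicate scores.
    """
    a = np.asarray(bg_a, dtype=float)
    b = np.asarray(bg_b, dtype=float)
    if len(a) < 10 or len(b) < 10:
        raise ValueError("each background needs >= 10 points")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if n_rep < 100:
        warnings.warn("n_rep < 100 gives unstable null quantiles")
    rng = np.random.default_rng(seed)
    na = int(np.ceil(fraction * len(a)))
    nb = int(np.ceil(fraction * len(b)))
    scores = np.empty(n_rep)
    for r in range(n_rep):
        sa = rng.choice(a, size=na, replace=replace)
        sb = rng.choice(b, size=nb, replace=replace)
        scores[r] = abs(sa.mean() - sb.mean())
    lo, hi = np.quantile(scores, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi), scores


def classify_axis(d_occ: float, lo: float, hi: float) -> str:
    """'divergence' iff the occupied score exceeds the null upper bound,
    'conservatism' iff it falls below the lower bound, else 'none'."""
    if lo > hi:
        raise ValueError("malformed null interval: lo > hi")
    if d_occ > hi:
        return "divergence"
    if d_occ < lo:
        return "conservatism"
    return "none"


@dataclass
class AxisTestResult:
    axis: int
    d_occ: float
    d_bg: float
    null_lo: float
    null_hi: float
    classification: str
    explained_variance: float
    n_jackknife: int
    fraction: float


def niche_divergence_test(occ_a: ClimateTable, occ_b: ClimateTable,
                          bg_a: ClimateTable | None = None,
                          bg_b: ClimateTable | None = None,
                          n_axes: int = 4, n_rep: int = 1000,
                          fraction: float = 0.75, alpha: float = 0.05,
                          seed: int | None = None,
                          n_background: int = 1000,
                          standardize: bool = True) -> list[AxisTestResult]:
    """Full per-axis divergence/conservatism test between two groups.

    If backgrounds are not supplied they are generated with
    ``n_background`` random points inside each group's minimum convex
    polygon, with climate looked up from the group's own records.
    """
    rng = np.random.default_rng(seed)
    if bg_a is None:
        poly = minimum_convex_polygon(
            occ_a.df[["longitude", "latitude"]].to_numpy(dtype=float))
        bg_a = sample_background(poly, n_background, occ_a,
                                 seed=int(rng.integers(2**31)))
    if bg_b is None:
        poly = minimum_convex_polygon(
            occ_b.df[["longitude", "latitude"]].to_numpy(dtype=float))
        bg_b = sample_background(poly, n_background, occ_b,
                                 seed=int(rng.integers(2**31)))
    occ_pool = ClimateTable(pd.concat([occ_a.df, occ_b.df], ignore_index=True),
                            list(occ_a.var_cols))
    bg_pool = ClimateTable(pd.concat([bg_a.df, bg_b.df], ignore_index=True),
                           list(bg_a.var_cols))
    n_axes = min(n_axes, len(occ_pool.var_cols))
    axes = fit_niche_axes(occ_pool, bg_pool, standardize=standardize,
                          n_axes=n_axes)
    ga, gb = occ_a.groups[0], occ_b.groups[0]
    occ_is_a = axes.occurrence_groups == ga
    bg_is_a = axes.background_groups == ga
    results = []
    for ax in range(n_axes):
        occ_sa = axes.occurrence_scores[occ_is_a, ax]
        occ_sb = axes.occurrence_scores[~occ_is_a, ax]
        bgs_a = axes.background_scores[bg_is_a, ax]
        bgs_b = axes.background_scores[~bg_is_a, ax]
        d_occ = abs(occ_sa.mean() - occ_sb.mean())
        d_bg = abs(bgs_a.mean() - bgs_b.mean())
        lo, hi, _ = background_divergence_null(
            bgs_a, bgs_b, n_rep=n_rep, fraction=fraction,
            seed=int(rng.integers(2**31)), alpha=alpha)
        results.append(AxisTestResult(
            ax + 1, float(d_occ), float(d_bg), lo, hi,
            classify_axis(d_occ, lo, hi),
            float(axes.explained_variance_ratio[ax]), n_rep, fraction))
    _ = gb
    return results


def axis_geo_correlation(axes: NicheAxes, coords: np.ndarray) -> pd.DataFrame:
    """Pearson r of each occurrence axis score against latitude/longitude."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) != len(axes.occurrence_scores):
        raise ValueError("coordinate count must match occurrence count")
    if len(coords) < 3:
        raise ValueError("need >= 3 occurrences")
    rows = []
    for ax in range(axes.occurrence_scores.shape[1]):
        s = axes.occurrence_scores[:, ax]
        row = {"axis": ax + 1}
        for name, col in (("longitude", 0), ("latitude", 1)):
            if np.std(s) == 0 or np.std(coords[:, col]) == 0:
                row[f"r_{name}"] = np.nan
            else:
                row[f"r_{name}"] = pearsonr(s, coords[:, col]).statistic
        rows.append(row)
    return pd.DataFrame(rows)


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-sum z tests with tie correction and Bonferroni adjustment."""
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    ranks = rankdata(all_vals)
    n_tot = len(all_vals)
    offsets = np.cumsum([0] + [len(groups[g]) for g in names])
    mean_rank = {g: ranks[offsets[i]:offsets[i + 1]].mean()
                 for i, g in enumerate(names)}
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            na, nb = len(groups[a]), len(groups[b])
            se = np.sqrt((n_tot * (n_tot + 1) / 12.0 -
                          tie_term / (12.0 * (n_tot - 1))) *
                         (1.0 / na + 1.0 / nb))
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2.0 * norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": float(z),
                         "p": float(p),
                         "p_bonferroni": float(min(1.0, p * n_pairs))})
    return pd.DataFrame(rows)


def elevation_comparison(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis H (tie-corrected) plus pairwise Dunn z statistics
    with Bonferroni adjustment."""
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(np.unique(np.concatenate(arrays))) == 1:
        raise ValueError("all values identical: rank test degenerate")
    h, p = kruskal(*arrays)
    dunn = _dunn_pairwise({k: np.asarray(v, dtype=float)
                           for k, v in groups.items()})
    return {"H": float(h), "p": float(p), "dunn": dunn}


def results_table(results: list[AxisTestResult], pair: str = "") -> pd.DataFrame:
    rows = []
    label = {"divergence": "D", "conservatism": "C", "none": ""}
    for r in results:
        rows.append({"pair": pair, "axis": f"PC{r.axis}", "D_occ": r.d_occ,
                     "D_bg": r.d_bg, "null_lo": r.null_lo, "null_hi": r.null_hi,
                     "classification": label[r.classification],
                     "pct_variance": 100.0 * r.explained_variance})
    return pd.DataFrame(rows)
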