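"""Geometry, variable selection and the background-vs-niche jackknife test."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPoint

from phylogeokit.nichetest import (
    ClimateTable,
    axis_geo_correlation,
    background_divergence_null,
    classify_axis,
    elevation_comparison,
    fit_niche_axes,
    minimum_convex_polygon,
    niche_divergence_test,
    sample_background,
    select_uncorrelated_vars,
)
from phylogeokit.synthdata import SimLandscapeConfig, sim_landscape


def climate_frame(data: dict, n: int) -> ClimateTable:
    base = {"id": [f"p{i}" for i in range(n)], "group": ["g"] * n,
            "longitude": np.linspace(-100, -90, n),
            "latitude": np.linspace(10, 20, n)}
    base.update(data)
    return ClimateTable(pd.DataFrame(base))


class TestVariableSelection:
    def test_identical_columns_keep_higher_priority(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        t = climate_frame({"BIO1": x, "BIO2": x.copy(),
                           "BIO3": rng.normal(size=30)}, 30)
        kept = select_uncorrelated_vars(t, threshold=0.7,
                                        priority=["BIO1", "BIO2", "BIO3"])
        assert kept == ["BIO1", "BIO3"]

    def test_all_uncorrelated_all_kept(self):
        rng = np.random.default_rng(1)
        t = climate_frame({f"BIO{i}": rng.normal(size=200)
                           for i in range(1, 6)}, 200)
        kept = select_uncorrelated_vars(t, threshold=0.7)
        assert kept == [f"BIO{i}" for i in range(1, 6)]

    def test_matches_greedy_rule_on_correlation_blocks(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        data = {
            "BIO1": a,
            "BIO2": a + 0.1 * rng.normal(size=500),   # correlated with BIO1
            "BIO3": b,
            "BIO4": b + 0.1 * rng.normal(size=500),   # correlated with BIO3
            "BIO5": rng.normal(size=500),
        }
        t = climate_frame(data, 500)
        order = ["BIO1", "BIO2", "BIO3", "BIO4", "BIO5"]
        kept = select_uncorrelated_vars(t, threshold=0.7, priority=order)
        # brute-force verification of the greedy rule
        expected = []
        for var in order:
            if all(abs(np.corrcoef(data[var], data[p])[0, 1]) < 0.7
                   for p in expected):
                expected.append(var)
        assert kept == expected == ["BIO1", "BIO3", "BIO5"]

    def test_constant_variable_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        t = climate_frame({"BIO1": np.ones(30),
                           "BIO2": rng.normal(size=30)}, 30)
        with pytest.warns(UserWarning):
            kept = select_uncorrelated_vars(t)
        assert kept == ["BIO2"]


class TestConvexPolygon:
    def test_unit_square_hull_excludes_centre(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        poly = minimum_convex_polygon(pts)
        assert len(poly.vertices) == 4
        assert poly.area == pytest.approx(1.0)

    def test_counter_clockwise_orientation(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 2))
        poly = minimum_convex_polygon(pts)
        v = poly.vertices
        signed = 0.5 * np.sum(v[:, 0] * np.roll(v[:, 1], -1)
                              - np.roll(v[:, 0], -1) * v[:, 1])
        assert signed > 0

    def test_area_matches_shapely_oracle_and_contains_points(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 2))
        poly = minimum_convex_polygon(pts)
        assert poly.area == pytest.approx(MultiPoint(pts).convex_hull.area)
        for p in pts:
            assert poly.contains(*p)

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]])
        with pytest.raises(ValueError):
            minimum_convex_polygon(pts)


class TestBackgroundSampling:
    def setup_method(self):
        self.poly = minimum_convex_polygon(
            np.array([[-100, 10], [-90, 10], [-90, 20], [-100, 20]]))
        rng = np.random.default_rng(6)
        self.field = climate_frame(
            {"BIO1": rng.normal(size=50), "BIO2": rng.normal(size=50)}, 50)

    def test_all_points_inside_polygon(self):
        bg = sample_background(self.poly, 200, self.field, seed=0)
        for _, row in bg.df.iterrows():
            assert self.poly.contains(row["longitude"], row["latitude"])

    def test_mean_near_centroid(self):
        bg = sample_background(self.poly, 1000, self.field, seed=1)
        c = self.poly.shapely.centroid
        # uniform on a 10 x 10 box: sd of the mean ~ 10/sqrt(12)/sqrt(1000)
        se = 10 / np.sqrt(12) / np.sqrt(1000)
        assert abs(bg.df["longitude"].mean() - c.x) < 3 * se
        assert abs(bg.df["latitude"].mean() - c.y) < 3 * se

    def test_seed_reproducible(self):
        b1 = sample_background(self.poly, 50, self.field, seed=2)
        b2 = sample_background(self.poly, 50, self.field, seed=2)
        pd.testing.assert_frame_equal(b1.df, b2.df)


class TestNicheAxes:
    def test_dominant_variable_loads_on_first_axis(self):
        rng = np.random.default_rng(7)
        n = 300
        data = {"BIO1": 10 * rng.normal(size=n),
                "BIO2": rng.normal(size=n),
                "BIO3": rng.normal(size=n)}
        bg = climate_frame(data, n)
        occ = climate_frame({k: v[:20] for k, v in data.items()}, 20)
        axes = fit_niche_axes(occ, bg, standardize=False, n_axes=3)
        assert abs(axes.loadings[0, 0]) > 0.9

    def test_background_mean_projects_to_origin(self):
        rng = np.random.default_rng(8)
        n = 100
        bg = climate_frame({f"BIO{i}": rng.normal(size=n)
                            for i in range(1, 4)}, n)
        axes = fit_niche_axes(bg, bg, n_axes=2)
        mean_score = axes.background_scores.mean(axis=0)
        assert np.allclose(mean_score, 0.0, atol=1e-10)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(9)
        bg = climate_frame({f"BIO{i}": rng.normal(size=80)
                            for i in range(1, 6)}, 80)
        axes = fit_niche_axes(bg, bg, n_axes=4)
        assert (np.diff(axes.explained_variance_ratio) <= 1e-12).all()

    def test_too_many_axes_rejected(self):
        rng = np.random.default_rng(10)
        bg = climate_frame({"BIO1": rng.normal(size=30),
                            "BIO2": rng.normal(size=30)}, 30)
        with pytest.raises(ValueError):
            fit_niche_axes(bg, bg, n_axes=5)


class TestJackknifeNull:
    def test_fraction_one_gives_zero_width_interval(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 50), rng.normal(1, 1, 50)
        lo, hi, scores = background_divergence_null(a, b, n_rep=200,
                                                    fraction=1.0, seed=0)
        d = abs(a.mean() - b.mean())
        assert lo == pytest.approx(hi) == pytest.approx(d)
        assert np.allclose(scores, d)

    def test_lower_bound_non_negative(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=40), rng.normal(size=40)
        lo, hi, _ = background_divergence_null(a, b, n_rep=300, seed=1)
        assert 0 <= lo <= hi

    def test_matches_duplicate_implementation_same_seed_stream(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=30), rng.normal(size=30)
        lo, hi, scores = background_divergence_null(a, b, n_rep=150,
                                                    fraction=0.75, seed=99)
        # independent re-implementation drawing from the same seed stream
        rng2 = np.random.default_rng(99)
        na = int(np.ceil(0.75 * len(a)))
        expected = np.empty(150)
        for r in range(150):
            sa = rng2.choice(a, size=na, replace=False)
            sb = rng2.choice(b, size=na, replace=False)
            expected[r] = abs(sa.mean() - sb.mean())
        assert np.allclose(scores, expected)
        assert (lo, hi) == tuple(np.quantile(expected, [0.025, 0.975]))

    def test_small_n_rep_warns(self):
        rng = np.random.default_rng(14)
        with pytest.warns(UserWarning):
            background_divergence_null(rng.normal(size=20),
                                       rng.normal(size=20), n_rep=50, seed=0)


class TestClassification:
    @pytest.mark.parametrize("d, lo, hi, expected", [
        (0.88, 1.25, 1.44, "conservatism"),
        (0.59, 0.05, 0.33, "divergence"),
        (0.30, 0.16, 0.53, "none"),
    ])
    def test_rule(self, d, lo, hi, expected):
        assert classify_axis(d, lo, hi) == expected

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            classify_axis(1.10, 0.93, 0.17)


class TestNicheDivergenceTest:
    def test_label_swap_leaves_classifications_unchanged(self):
        occ, bg = sim_landscape(SimLandscapeConfig(
            n_groups=2, n_vars=5, n_occurrences=40,
            n_background_candidates=150, seed=20))
        kwargs = dict(n_axes=3, n_rep=200, seed=7)
        r12 = niche_divergence_test(occ.for_group("group1"),
                                    occ.for_group("group2"),
                                    bg.for_group("group1"),
                                    bg.for_group("group2"), **kwargs)
        r21 = niche_divergence_test(occ.for_group("group2"),
                                    occ.for_group("group1"),
                                    bg.for_group("group2"),
                                    bg.for_group("group1"), **kwargs)
        assert [r.classification for r in r12] == \
            [r.classification for r in r21]
        assert [r.d_occ for r in r12] == pytest.approx([r.d_occ for r in r21])

    def test_backgrounds_generated_from_polygons_when_absent(self):
        occ, _ = sim_landscape(SimLandscapeConfig(
            n_groups=2, n_vars=4, n_occurrences=30,
            n_background_candidates=10, seed=21))
        results = niche_divergence_test(occ.for_group("group1"),
                                        occ.for_group("group2"),
                                        n_axes=2, n_rep=150,
                                        n_background=60, seed=3)
        assert len(results) == 2
        assert all(r.classification in
                   {"divergence", "conservatism", "none"} for r in results)

    def test_null_interval_tightens_with_replicates(self):
        rng = np.random.default_rng(22)
        a, b = rng.normal(0, 1, 300), rng.normal(0.5, 1, 300)
        spans = []
        for n_rep in (100, 1000):
            widths = []
            for s in range(20):
                lo, hi, _ = background_divergence_null(a, b, n_rep=n_rep,
                                                       seed=s)
                widths.append(hi - lo)
            spans.append(np.std(widths))
        assert spans[1] < spans[0]


class TestGeoCorrelation:
    def _axes_with_scores(self, scores: np.ndarray, coords: np.ndarray):
        from phylogeokit.nichetest import NicheAxes
        k = scores.shape[1]
        return NicheAxes(np.eye(k), np.full(k, 1.0 / k), scores,
                         scores.copy(), np.array(["g"] * len(scores)),
                         np.array(["g"] * len(scores)),
                         [f"BIO{i}" for i in range(1, k + 1)],
                         np.zeros(k), np.ones(k))

    def test_scores_equal_longitude_correlate_perfectly(self):
        rng = np.random.default_rng(23)
        coords = np.column_stack([np.linspace(-100, -90, 40),
                                  rng.normal(15, 2, 40)])
        axes = self._axes_with_scores(coords[:, :1].copy(), coords)
        out = axis_geo_correlation(axes, coords)
        assert out.loc[0, "r_longitude"] == pytest.approx(1.0)

    def test_independent_scores_rarely_correlate(self):
        rng = np.random.default_rng(24)
        hits = 0
        for _ in range(100):
            coords = rng.normal(size=(100, 2))
            scores = rng.normal(size=(100, 1))
            axes = self._axes_with_scores(scores, coords)
            out = axis_geo_correlation(axes, coords)
            if (abs(out.loc[0, "r_longitude"]) < 0.3
                    and abs(out.loc[0, "r_latitude"]) < 0.3):
                hits += 1
        assert hits >= 95

    def test_invariant_to_affine_coordinate_rescaling(self):
        rng = np.random.default_rng(25)
        coords = rng.normal(size=(50, 2))
        scores = rng.normal(size=(50, 2))
        axes = self._axes_with_scores(scores, coords)
        out1 = axis_geo_correlation(axes, coords)
        out2 = axis_geo_correlation(axes, coords * 3.7 + 11.0)
        pd.testing.assert_frame_equal(out1, out2)


class TestElevation:
    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(26)
        groups = {g: rng.normal(i, 1, 30) for i, g in enumerate("abc")}
        h1 = elevation_comparison(groups)["H"]
        h2 = elevation_comparison(
            {g: np.exp(v) for g, v in groups.items()})["H"]
        assert h1 == pytest.approx(h2)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(27)
        rejections = 0
        n_sims = 300
        for _ in range(n_sims):
            groups = {g: rng.normal(0, 1, 20) for g in "abc"}
            rejections += elevation_comparison(groups)["p"] < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_shifted_medians_detected(self):
        rng = np.random.default_rng(28)
        all_sig = 0
        for _ in range(30)[:30]:
            groups = {g: rng.normal(2 * i, 1, 30)
                      for i, g in enumerate("abc")}
            out = elevation_comparison(groups)
            if (out["dunn"]["p_bonferroni"] < 0.05).all():
                all_sig += 1
        assert all_sig >= 27

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            elevation_comparison({"a": np.ones(5), "b": np.ones(5)})
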