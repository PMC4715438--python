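"""Diversity summaries, neutrality tests and the sudden-expansion fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylogeokit import seqstats
from phylogeokit.seqstats import (
    Alignment,
    UndefinedStatisticError,
    collapse_haplotypes,
    diversity_stats,
    ewens_log_pmf,
    expansion_model_probs,
    fit_sudden_expansion,
    fu_fs,
    mismatch_spectrum,
    tajimas_d,
)

from conftest import brute_force_pi


class TestHaplotypes:
    def test_identical_sequences_collapse_to_one(self):
        aln = Alignment(list("abc"), ["ACGT"] * 3)
        table = collapse_haplotypes(aln)
        assert table.H == 1
        assert table.counts.tolist() == [3]

    def test_two_identical_pairs(self):
        aln = Alignment(list("abcd"), ["ACGT", "ACGA", "ACGT", "ACGA"])
        table = collapse_haplotypes(aln)
        assert table.H == 2
        assert sorted(table.counts.tolist()) == [2, 2]

    def test_matches_set_oracle_on_random_sequences(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, 8)]) for _ in range(50)]
        aln = Alignment([f"x{i}" for i in range(50)], seqs)
        assert collapse_haplotypes(aln).H == len(set(seqs))

    def test_gap_sites_removed_under_complete_deletion(self):
        aln = Alignment(list("ab"), ["A-GT", "ACGT"])
        table = collapse_haplotypes(aln, gap_policy="complete")
        assert table.haplotypes == ["AGT"]

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            Alignment([], [])


class TestDiversity:
    def test_no_variation(self):
        aln = Alignment(list("abc"), ["ACGT"] * 3)
        stats = diversity_stats(collapse_haplotypes(aln), aln)
        assert (stats.S, stats.h, stats.pi) == (0, 0.0, 0.0)

    def test_unbiased_h_hand_value(self):
        # n = 4, haplotype counts (2, 1, 1):
        # h = (4/3) * (1 - (0.5^2 + 0.25^2 + 0.25^2)) = 0.8333...
        aln = Alignment(list("abcd"), ["AAAA", "AAAA", "AAAT", "AATT"])
        stats = diversity_stats(collapse_haplotypes(aln), aln)
        assert stats.h == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_pi_two_sequences(self):
        aln = Alignment(list("ab"), ["AAAAAAAAAA", "AAAAAAAATT"])
        stats = diversity_stats(collapse_haplotypes(aln), aln)
        assert stats.pi == pytest.approx(0.2)

    def test_pi_h_s_match_brute_force(self, random_alignment):
        stats = diversity_stats(collapse_haplotypes(random_alignment),
                                random_alignment)
        assert stats.pi == pytest.approx(brute_force_pi(random_alignment))
        cols = list(zip(*random_alignment.sequences))
        assert stats.S == sum(len(set(c)) > 1 for c in cols)

    def test_h_undefined_for_single_sequence(self):
        aln = Alignment(["a"], ["ACGT"])
        with pytest.raises(UndefinedStatisticError):
            diversity_stats(collapse_haplotypes(aln), aln)

    @given(st.permutations(list(range(12))))
    @settings(max_examples=20, deadline=None)
    def test_h_pi_invariant_under_reordering(self, order):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, 40)]) for _ in range(12)]
        aln = Alignment([f"p{i}" for i in range(12)], seqs)
        shuffled = aln.subset(order)
        s1 = diversity_stats(collapse_haplotypes(aln), aln)
        s2 = diversity_stats(collapse_haplotypes(shuffled), shuffled)
        assert s1.h == pytest.approx(s2.h)
        assert s1.pi == pytest.approx(s2.pi)


def _textbook_tajima_d(alignment: Alignment) -> float:
    """Independent straight-from-the-textbook reimplementation."""
    seqs = alignment.sequences
    n = len(seqs)
    cols = list(zip(*seqs))
    s = sum(len(set(c)) > 1 for c in cols)
    k = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            k += sum(a != b for a, b in zip(seqs[i], seqs[j]))
    k /= n * (n - 1) / 2
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


class TestTajimasD:
    def test_undefined_with_no_segregating_sites(self):
        aln = Alignment(list("abcd"), ["ACGT"] * 4)
        with pytest.raises(UndefinedStatisticError):
            tajimas_d(aln, n_replicates=10, seed=0)

    def test_matches_independent_reimplementation(self, toy_alignment,
                                                  random_alignment):
        for aln in (toy_alignment, random_alignment):
            res = tajimas_d(aln, n_replicates=10, seed=0)
            assert res.statistic == pytest.approx(_textbook_tajima_d(aln),
                                                  abs=1e-10)

    def test_p_value_seed_reproducible(self, toy_alignment):
        p1 = tajimas_d(toy_alignment, n_replicates=200, seed=11).p_value
        p2 = tajimas_d(toy_alignment, n_replicates=200, seed=11).p_value
        assert p1 == p2

    def test_neutral_mean_near_zero(self):
        """Mean D over neutral coalescent samples sits near 0."""
        from phylogeokit import _coalescent as coal
        rng = np.random.default_rng(5)
        ds = []
        for _ in range(500):
            parent, time = coal.sim_kingman(30, rng)
            lens = coal.branch_lengths(parent, time)
            total = lens.sum()
            n_mut = rng.poisson(5 / 2 * total)
            if n_mut == 0:
                continue
            picks = rng.choice(len(lens), size=n_mut, p=lens / total)
            muts = np.bincount(picks, minlength=len(lens))
            ind = coal.leaf_indicator(parent, 30)
            counts = ind.sum(axis=1)
            k = float(np.dot(muts, counts * (30 - counts))) / (30 * 29 / 2)
            s = int(n_mut)  # infinite sites: every mutation is its own site
            from phylogeokit.seqstats import _tajima_d_from_counts
            ds.append(_tajima_d_from_counts(30, s, k))
        assert -0.3 < np.mean(ds) < 0.3


def _crp_tail_probability(n: int, k_obs: int, theta: float) -> float:
    """P(K >= k_obs) by the Chinese-restaurant-process recursion: an
    independent route to the Ewens distribution of the allele count."""
    p = {1: 1.0}
    for m in range(1, n):
        q = {}
        for k, pk in p.items():
            q[k] = q.get(k, 0.0) + pk * m / (theta + m)
            q[k + 1] = q.get(k + 1, 0.0) + pk * theta / (theta + m)
        p = q
    return sum(pk for k, pk in p.items() if k >= k_obs)


class TestFuFs:
    @pytest.mark.parametrize("n", [4, 6, 8])
    @pytest.mark.parametrize("theta", [0.5, 2.0, 5.0])
    def test_ewens_tail_matches_crp_enumeration(self, n, theta):
        logp = ewens_log_pmf(n, theta)
        for k_obs in range(1, n + 1):
            tail = float(np.exp(logp[k_obs:]).sum())
            assert tail == pytest.approx(
                _crp_tail_probability(n, k_obs, theta), abs=1e-10)

    def test_many_haplotypes_small_theta_gives_negative_fs(self):
        # every sequence distinct but pairwise differences tiny
        aln = Alignment(
            list("abcde"),
            ["AAAAAAAAAA", "TAAAAAAAAA", "ATAAAAAAAA", "AATAAAAAAA",
             "AAATAAAAAA"])
        res = fu_fs(aln, n_replicates=10, seed=0)
        assert res.statistic < -1.0

    def test_invariant_to_relabelling(self, random_alignment):
        res1 = fu_fs(random_alignment, n_replicates=10, seed=0)
        order = list(reversed(range(random_alignment.n)))
        res2 = fu_fs(random_alignment.subset(order), n_replicates=10, seed=0)
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_undefined_without_differences(self):
        aln = Alignment(list("abc"), ["ACGT"] * 3)
        with pytest.raises(UndefinedStatisticError):
            fu_fs(aln, n_replicates=10, seed=0)


class TestMismatch:
    def test_identical_sequences_all_mass_at_zero(self):
        aln = Alignment(list("abc"), ["ACGT"] * 3)
        spec = mismatch_spectrum(aln)
        assert spec.counts.tolist() == [3]

    def test_hand_counted_spectrum(self):
        # pairwise distances {1, 1, 2} -> spectrum {1: 2, 2: 1}
        aln = Alignment(list("abc"), ["AAAA", "AAAT", "AATA"])
        spec = mismatch_spectrum(aln)
        assert spec.counts.tolist() == [0, 2, 1]

    def test_pair_count_conservation(self, random_alignment):
        spec = mismatch_spectrum(random_alignment)
        n = random_alignment.n
        assert spec.counts.sum() == n * (n - 1) // 2


class TestExpansionModel:
    def test_model_probabilities_sum_toward_one(self):
        probs = expansion_model_probs(400, tau=3.0, theta0=1.0, theta1=50.0)
        assert probs.min() >= 0
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_tau_zero_reduces_to_equilibrium(self):
        # no expansion: the ancestral geometric distribution applies
        j = np.arange(50)
        expected = 2.0**j / 3.0 ** (j + 1)
        got = expansion_model_probs(49, tau=0.0, theta0=2.0, theta1=50.0)
        assert np.allclose(got, expected, atol=1e-12)

    def test_large_theta1_approaches_poisson_shift(self):
        got = expansion_model_probs(60, tau=4.0, theta0=0.0, theta1=1e7)
        limit = expansion_model_probs(60, tau=4.0, theta0=0.0, theta1=None)
        assert np.allclose(got, limit, atol=1e-4)

    def test_degenerate_spectrum_returns_zero_tau(self):
        aln = Alignment(list("abc"), ["ACGT"] * 3)
        with pytest.warns(UserWarning):
            fit = fit_sudden_expansion(mismatch_spectrum(aln), n_bootstrap=0)
        assert fit.degenerate
        assert fit.tau == 0.0
        assert fit.SSD == 0.0

    def test_bootstrap_seed_reproducible(self, random_alignment):
        spec = mismatch_spectrum(random_alignment)
        f1 = fit_sudden_expansion(spec, n_bootstrap=30, seed=9)
        f2 = fit_sudden_expansion(spec, n_bootstrap=30, seed=9)
        assert f1.p_SSD == f2.p_SSD
        assert f1.p_Hri == f2.p_Hri


class TestPopulationSummary:
    def test_summary_layout(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, 30)]) for _ in range(10)]
        aln = Alignment([f"i{k}" for k in range(10)], seqs,
                        ["north"] * 5 + ["south"] * 5)
        df = seqstats.population_summary(aln, n_replicates=20,
                                         n_bootstrap=10, seed=0)
        assert list(df["population"]) == ["north", "south"]
        for col in ("n", "H", "S", "h", "pi", "D", "p_D", "Fs", "p_Fs",
                    "SSD", "p_SSD", "Hri", "p_Hri"):
            assert col in df.columns
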