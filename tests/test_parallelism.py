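"""Null-W rank-sum test, BH adjustment, hypergeometric overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clinescan.io_binning import GeneBin
from clinescan.parallelism import (
    _w_against_panel,
    bh_adjust,
    build_control_panel,
    hypergeom_overlap,
    null_z_distribution,
    nullw_test,
    rank_sum_z,
)


def brute_force_w(gene, control):
    """All-pairs oracle: W = #(gene>control) + 0.5 #(ties)."""
    w = 0.0
    for g in gene:
        for c in control:
            if g > c:
                w += 1.0
            elif g == c:
                w += 0.5
    return w


def z_from_w(w, n1, n2):
    return (2 * w - n1 * n2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 3)


class TestRankSumZ:
    def test_worked_example(self):
        w, z = rank_sum_z([0.25, 0.35], [0.1, 0.2, 0.3])
        assert w == 5.0
        assert z == pytest.approx(4 / np.sqrt(12), abs=1e-12)

    def test_null_center(self):
        # symmetric interleaving -> W = n1*n2/2 -> Z = 0
        w, z = rank_sum_z([1.0, 4.0], [2.0, 3.0])
        assert w == 2.0
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_extreme_low(self):
        w, z = rank_sum_z([0.0, 0.1], [1.0, 2.0, 3.0])
        assert w == 0.0
        assert z == pytest.approx(-6 / np.sqrt(12), abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rank_sum_z([], [1.0])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(1, 50, size=2)
            # coarse grid provokes plenty of ties
            c = rng.integers(0, 8, size=n1) / 4.0
            g = rng.integers(0, 8, size=n2) / 4.0
            w, z = rank_sum_z(g, c)
            w_ref = brute_force_w(g, c)
            assert w == pytest.approx(w_ref, abs=1e-9)
            assert z == pytest.approx(z_from_w(w_ref, n1, n2), abs=1e-12)

    def test_fast_panel_path_equals_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            panel = rng.integers(0, 12, size=40) / 6.0
            g = rng.integers(0, 12, size=7) / 6.0
            drop = rng.choice(40, size=4, replace=False)
            keep = np.setdiff1d(np.arange(40), drop)
            w_ref, z_ref = rank_sum_z(g, panel[keep])
            w, z, n1 = _w_against_panel(g, np.sort(panel), panel[drop])
            assert n1 == 36
            assert w == pytest.approx(w_ref, abs=1e-9)
            assert z == pytest.approx(z_ref, abs=1e-12)


def _bins_and_scores(rng, n_bins=2000, snps_per_bin=5):
    ids = np.arange(n_bins * snps_per_bin)
    scores = pd.Series(rng.chisquare(1, size=ids.size), index=[f"s{i}" for i in ids])
    bins = [
        GeneBin(
            bin_id=f"b{b}", kind="genic", chrom="chr01", start=1, end=2,
            snp_ids=tuple(f"s{i}" for i in ids[b * snps_per_bin : (b + 1) * snps_per_bin]),
        )
        for b in range(n_bins)
    ]
    return bins, scores


class TestNullDistribution:
    def test_exchangeable_scores_standardized(self):
        rng = np.random.default_rng(2)
        bins, scores = _bins_and_scores(rng)
        panel = build_control_panel(bins, set(), scores, size=5000, seed=0)
        z = null_z_distribution(bins, scores, panel)
        assert len(z) == 2000
        assert -0.1 < z.mean() < 0.1
        assert 0.8 < z.std() < 1.2

    def test_deterministic_given_panel(self):
        rng = np.random.default_rng(3)
        bins, scores = _bins_and_scores(rng, n_bins=50)
        panel = build_control_panel(bins, set(), scores, size=100, seed=1)
        z1 = null_z_distribution(bins, scores, panel)
        z2 = null_z_distribution(bins, scores, panel)
        np.testing.assert_array_equal(z1, z2)

    def test_bin_of_only_panel_snps_still_defined(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=["a", "b", "c", "d"])
        bins = [
            GeneBin("x", "genic", "chr01", 1, 2, ("a", "b")),
            GeneBin("y", "genic", "chr01", 3, 4, ("c", "d")),
        ]
        z = null_z_distribution(bins, scores, ["a", "b", "c", "d"])
        assert len(z) == 2 and np.isfinite(z).all()


class TestControlPanel:
    def test_seed_reproducible_and_excludes_candidates(self):
        rng = np.random.default_rng(4)
        bins, scores = _bins_and_scores(rng, n_bins=100)
        cand = {"b0", "b1"}
        p1 = build_control_panel(bins, cand, scores, size=200, seed=7)
        p2 = build_control_panel(bins, cand, scores, size=200, seed=7)
        assert p1 == p2
        banned = {s for b in bins if b.bin_id in cand for s in b.snp_ids}
        assert not (set(p1) & banned)

    def test_short_pool_returns_all(self):
        rng = np.random.default_rng(5)
        bins, scores = _bins_and_scores(rng, n_bins=10)
        panel = build_control_panel(bins, set(), scores, size=10000, seed=0)
        assert len(panel) == 50


class TestNullWTest:
    def test_empirical_p_floor(self):
        rng = np.random.default_rng(6)
        bins, scores = _bins_and_scores(rng, n_bins=40)
        null_z = rng.normal(size=2000)
        big = GeneBin("big", "genic", "chr01", 1, 2, bins[0].snp_ids)
        scores.loc[list(big.snp_ids)] = 1e6  # beats every null Z
        panel = build_control_panel(bins[1:], set(), scores, size=150, seed=0)
        res = nullw_test([big], scores, panel, null_z)
        assert res["p"].iloc[0] == pytest.approx(1 / 2000)

    def test_median_of_null_gives_half(self):
        rng = np.random.default_rng(7)
        bins, scores = _bins_and_scores(rng, n_bins=200)
        panel = build_control_panel(bins, set(), scores, size=400, seed=0)
        null_z = null_z_distribution(bins, scores, panel)
        res = nullw_test(bins[:50], scores, panel, null_z)
        # bins are themselves draws from the null: p should center near 0.5
        assert 0.3 < res["p"].median() < 0.7

    def test_null_p_superuniform(self):
        """Empirical p of exchangeable genes is (super)uniform: KS should not
        reject uniformity against the 'too small' alternative."""
        rng = np.random.default_rng(8)
        bins, scores = _bins_and_scores(rng, n_bins=4000)
        panel = build_control_panel(bins, set(), scores, size=5000, seed=0)
        null_z = null_z_distribution(bins[2000:], scores, panel)
        res = nullw_test(bins[:2000], scores, panel, null_z)
        assert stats.kstest(res["p"], "uniform", alternative="greater").pvalue > 0.01
        assert res["parallel"].mean() < 0.02


_scores = st.lists(
    st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=30
)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(gene=_scores, control=_scores)
def test_w_stays_within_pair_count_bounds(gene, control):
    w, z = rank_sum_z(gene, control)
    assert 0.0 <= w <= len(gene) * len(control)
    assert np.isfinite(z)
    # reversing the roles mirrors W around its midpoint
    w_rev, z_rev = rank_sum_z(control, gene)
    assert w + w_rev == pytest.approx(len(gene) * len(control))
    assert z_rev == pytest.approx(-z, abs=1e-9)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.floats(1e-9, 1.0, allow_nan=False), min_size=1, max_size=40
    )
)
def test_bh_bounds_and_monotonicity(p):
    p = np.asarray(p)
    q = bh_adjust(p)
    assert (q >= p - 1e-12).all()
    assert (q <= 1.0 + 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


class TestBhAdjust:
    def test_step_up_oracle(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)

    def test_matches_manual_step_up(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=25)
        m = len(p)
        order = np.argsort(p)
        manual = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            manual[i] = running
        np.testing.assert_allclose(bh_adjust(p), manual, atol=1e-12)


class TestHypergeomOverlap:
    def test_published_height_row(self):
        assert hypergeom_overlap(42970, 170, 186, 2)["p"] == pytest.approx(
            0.168, abs=5e-4
        )

    def test_zero_overlap_is_one(self):
        assert hypergeom_overlap(1000, 50, 30, 0)["p"] == 1.0

    def test_complete_overlap_combinatorial(self):
        assert hypergeom_overlap(10, 5, 5, 5)["p"] == pytest.approx(1 / 252)

    def test_symmetry_in_set_sizes(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_univ = int(rng.integers(50, 500))
            small, big = sorted(rng.integers(1, 40, size=2))
            k = int(rng.integers(0, small + 1))
            a = hypergeom_overlap(n_univ, big, small, k)["p"]
            b = hypergeom_overlap(n_univ, small, big, k)["p"]
            assert a == pytest.approx(b, rel=1e-12)

    def test_binomial_limit(self):
        n_univ, big = 10**6, 10**5  # K/N = 0.1
        p_hyp = hypergeom_overlap(n_univ, big, 50, 10)["p"]
        p_bin = stats.binom.sf(9, 50, 0.1)
        assert abs(p_hyp - p_bin) / p_bin < 0.01

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(100, 50, 30, 40)
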