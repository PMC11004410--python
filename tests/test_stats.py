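"""All-pairs Change sets, fold change, and the binomial sign-test null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transcyt import (FluorescenceDataset, binomial_p_value, change_set,
                      fold_reduction_display, pairwise_fold_change, summarize)


def dataset(blank, ctrl, cond, n_reps=1):
    """Replicate identical blank/ctrl/cond groups across n_reps."""
    return FluorescenceDataset(
        blank={k: np.array(blank, float) for k in range(n_reps)},
        ctrl={k: np.array(ctrl, float) for k in range(n_reps)},
        conditions={"cond": {k: np.array(cond, float) for k in range(n_reps)}},
    )


def naive_change_set(blank, ctrl, cond):
    """Brute-force oracle: explicit double loop over (cond_i, ctrl_j)."""
    b = np.mean(blank)
    out = []
    for x in cond:
        for y in ctrl:
            if y - b > 0:
                out.append((x - b) / (y - b))
    return out


class TestChangeSet:
    def test_identity_ratio(self):
        cs = change_set(dataset([0.0], [2.0], [2.0]), "cond")
        assert cs.values.tolist() == [1.0]
        assert cs.n_all == 1 and cs.n_trial == 1

    def test_all_pairs_in_ij_order(self):
        cs = change_set(dataset([1.0], [3.0, 5.0], [5.0, 9.0]), "cond")
        assert cs.values.tolist() == [2.0, 1.0, 4.0, 2.0]

    def test_two_replicates_pool_without_reweighting(self):
        cs = change_set(dataset([1.0], [3.0, 5.0], [5.0, 9.0], n_reps=2), "cond")
        assert cs.n_all == 8
        assert cs.values.tolist() == [2.0, 1.0, 4.0, 2.0] * 2
        assert cs.n_trial == 4  # 2 condition cells per replicate

    def test_ctrl_label_builds_the_control_set(self):
        cs = change_set(dataset([0.0], [2.0, 4.0], [9.0]), "ctrl")
        assert cs.values.tolist() == [1.0, 0.5, 2.0, 1.0]

    def test_nonpositive_denominators_excluded_and_counted(self):
        # blank mean 10 makes ctrl cell 8 a negative denominator
        cs = change_set(dataset([10.0], [8.0, 20.0], [30.0, 40.0]), "cond")
        assert cs.n_excluded_pairs == 2
        assert cs.values.tolist() == [2.0, 3.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        blank = rng.uniform(0, 2, rng.integers(1, 5))
        ctrl = rng.uniform(5, 50, rng.integers(1, 20))
        cond = rng.uniform(5, 50, rng.integers(1, 20))
        cs = change_set(dataset(blank, ctrl, cond), "cond")
        assert cs.values.tolist() == pytest.approx(
            naive_change_set(blank, ctrl, cond))


class TestPairwiseFoldChange:
    def test_uniform_sets(self):
        c = change_set(dataset([0.0], [1.0, 1.0], [2.0, 2.0]), "cond")
        d = change_set(dataset([0.0], [1.0, 1.0], [1.0, 1.0]), "cond")
        fc = pairwise_fold_change(c, d)
        assert np.all(fc.points == 2.0) and fc.median == 2.0

    def test_enumeration_order_and_median(self):
        c = change_set(dataset([0.0], [1.0], [1.0, 2.0]), "cond")
        fc = pairwise_fold_change(c, c)
        assert sorted(fc.points.tolist()) == [0.5, 1.0, 1.0, 2.0]
        assert fc.median == 1.0

    def test_identical_sets_have_unit_median(self):
        c = change_set(dataset([0.5], [3.0, 7.0, 11.0], [4.0, 6.0, 9.0]), "cond")
        fc = pairwise_fold_change(c, c)
        assert fc.median == 1.0  # self-control null: inversion-symmetric set

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_cross_division_matches_quadruple_loop(self, seed):
        rng = np.random.default_rng(seed)
        blank = rng.uniform(0, 1, 2)
        ctrl = rng.uniform(5, 50, rng.integers(2, 20))
        cond = rng.uniform(5, 50, rng.integers(2, 20))
        cset = change_set(dataset(blank, ctrl, cond), "cond")
        dset = change_set(dataset(blank, ctrl, cond), "ctrl")
        fc = pairwise_fold_change(cset, dset)
        assert fc.exact
        naive = [ci / dj for ci in cset.values for dj in dset.values]
        assert fc.points.tolist() == pytest.approx(naive)
        assert fc.median == pytest.approx(np.median(naive))

    def test_cap_triggers_seeded_subsampling(self):
        c = change_set(dataset([0.0], np.arange(1.0, 41.0),
                               np.arange(1.0, 41.0)), "cond")
        fc_a = pairwise_fold_change(c, c, cap=1000, rng=7)
        fc_b = pairwise_fold_change(c, c, cap=1000, rng=7)
        assert not fc_a.exact
        assert len(fc_a.points) == 1000
        assert np.array_equal(fc_a.points, fc_b.points)
        # subsampled median approximates the exact one
        exact = pairwise_fold_change(c, c, cap=10 ** 9)
        assert fc_a.median == pytest.approx(exact.median, rel=0.2)

    def test_empty_set_rejected(self):
        c = change_set(dataset([0.0], [1.0], [1.0]), "cond")
        c_empty = type(c)(np.array([]), np.array([]), {})
        with pytest.raises(ValueError):
            pairwise_fold_change(c, c_empty)


class TestBinomialP:
    def test_no_failures_tail_is_single_term(self):
        p, f = binomial_p_value(np.array([2.0, 3.0, 4.0, 5.0]), "increase", 4)
        assert f == 0.0
        assert p == pytest.approx(0.5 ** 4)

    def test_quarter_failures_exact_tail_sum(self):
        # f_fail = 0.25, n_trial = 8 -> k = 2 -> (1 + 8 + 28) / 256
        points = np.array([0.5, 0.9] + [2.0] * 6)
        p, f = binomial_p_value(points, "increase", 8)
        assert f == 0.25
        assert p == pytest.approx(37 / 256)

    def test_all_failures_single_trial(self):
        p, f = binomial_p_value(np.array([0.5]), "increase", 1)
        assert f == 1.0 and p == 1.0

    def test_direction_none_returns_one(self):
        p, _ = binomial_p_value(np.array([1.0, 1.0]), "none", 5)
        assert p == 1.0

    def test_decrease_counts_points_at_or_above_one(self):
        points = np.array([0.2, 0.4, 1.0, 3.0])
        _, f = binomial_p_value(points, "decrease", 4)
        assert f == 0.5

    def test_pmf_mode_differs_from_tail(self):
        points = np.array([0.5, 0.9] + [2.0] * 6)
        p_tail, _ = binomial_p_value(points, "increase", 8, mode="tail")
        p_pmf, _ = binomial_p_value(points, "increase", 8, mode="pmf")
        assert p_pmf == pytest.approx(28 / 256)
        assert p_tail > p_pmf

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=50),
           st.sampled_from(["increase", "decrease"]),
           st.integers(1, 500))
    def test_p_value_in_unit_interval(self, points, direction, n_trial):
        p, f = binomial_p_value(np.array(points), direction, n_trial)
        assert 0.0 <= p <= 1.0
        assert 0.0 <= f <= 1.0


class TestSummarize:
    def test_reporting_arithmetic(self):
        assert fold_reduction_display(0.51) == 1.96
        assert round(np.log2(0.51), 2) == -0.97
        assert fold_reduction_display(0.347) == 2.9
        assert round(np.log2(0.347), 2) == -1.53
        assert fold_reduction_display(1.0) == 1.0

    def test_summary_composition(self):
        ds = dataset([1.0], [3.0, 5.0], [5.0, 9.0])
        s = summarize(ds, "cond")
        assert s.median == 2.0
        assert s.direction == "increase"
        assert s.n_trial == 2
        assert s.fold_reduction == pytest.approx(0.5)
        assert s.log2_median == pytest.approx(1.0)
        assert s.band95[0] <= s.median <= s.band95[1]
        assert s.band68[0] <= s.median <= s.band68[1]

    def test_self_control_gives_unit_median_and_p_one(self):
        ds = dataset([0.0], [2.0, 4.0, 8.0], [2.0, 4.0, 8.0])
        s = summarize(ds, "cond")
        assert s.median == 1.0
        assert s.direction == "none"
        assert s.p_value == 1.0

    def test_pipeline_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(8)
        blank = rng.uniform(1, 3, 5)
        ctrl = rng.uniform(20, 80, 12)
        cond = rng.uniform(10, 60, 12)
        s1 = summarize(dataset(blank, ctrl, cond), "cond")
        c = 37.5
        s2 = summarize(dataset(blank * c, ctrl * c, cond * c), "cond")
        assert s2.median == pytest.approx(s1.median)
        assert s2.p_value == pytest.approx(s1.p_value)
        assert s2.band95 == pytest.approx(s1.band95)
        assert s2.f_fail == s1.f_fail
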