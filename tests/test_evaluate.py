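"""Redundancy/error scoring, rank-sum comparator, SVM accuracy and the
exact permutation test."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaboot import (
    AbundanceTable,
    ConsistencyError,
    DegenerateDataError,
    GroundTruth,
    ParameterError,
    SampleMetadata,
    count_positive,
    permutation_exact_test,
    score_selection,
    svm_cv_accuracy,
    wilcoxon_select,
)


@pytest.fixture
def truth():
    """5 positive groups x 2 features + 4 negatives."""
    fids = [f"p{g}{i}" for g in range(5) for i in range(2)] + [f"n{i}" for i in range(4)]
    gids = [f"g{g}" for g in range(5) for _ in range(2)] + ["neg"] * 4
    return GroundTruth(fids, gids, np.r_[np.ones(10, bool), np.zeros(4, bool)])


class TestScoreSelection:
    def test_one_per_group_is_fully_nonredundant(self, truth):
        rep = score_selection([f"p{g}0" for g in range(5)], truth)
        assert rep.non_redundancy_rate == 100.0
        assert rep.error_rate == 0.0
        assert rep.positive_count == 5

    def test_all_from_one_group_is_maximally_redundant(self):
        fids = [f"f{i}" for i in range(10)]
        truth10 = GroundTruth(fids, ["g1"] * 10, np.ones(10, bool))
        rep = score_selection(fids, truth10)
        assert rep.non_redundancy_rate == pytest.approx(10.0)
        assert rep.redundancy_rate == pytest.approx(90.0)

    def test_mixed_selection_counts_redundant_positives_only(self, truth):
        # 8 positives covering 5 groups (3 repeat picks) + 2 negatives
        selected = [f"p{g}0" for g in range(5)] + ["p00", "p10", "p20", "n0", "n1"]
        rep = score_selection(selected, truth)
        assert rep.redundancy_rate == pytest.approx(30.0)
        assert rep.non_redundancy_rate == pytest.approx(70.0)
        assert rep.error_rate == pytest.approx(20.0)

    def test_unknown_feature_is_consistency_error(self, truth):
        with pytest.raises(ConsistencyError):
            score_selection(["ghost"], truth)

    @settings(max_examples=40, deadline=None)
    @given(picks=st.lists(st.integers(0, 13), min_size=1, max_size=14, unique=True))
    def test_identity_and_bounds_hold_for_any_selection(self, picks):
        fids = [f"p{g}{i}" for g in range(5) for i in range(2)] + [
            f"n{i}" for i in range(4)
        ]
        gids = [f"g{g}" for g in range(5) for _ in range(2)] + ["neg"] * 4
        truth = GroundTruth(fids, gids, np.r_[np.ones(10, bool), np.zeros(4, bool)])
        selected = [truth.feature_ids[i] for i in picks]
        rep = score_selection(selected, truth)
        assert rep.non_redundancy_rate + rep.redundancy_rate == pytest.approx(100.0)
        assert 0 <= rep.redundancy_rate <= 100
        assert 0 <= rep.error_rate <= 100
        assert rep.positive_count <= rep.n_selected
        assert rep.positive_count == count_positive(selected, truth)


class TestWilcoxonSelect:
    def _table(self, values, classes):
        values = np.asarray(values, dtype=float)
        t = AbundanceTable(
            [f"f{i}" for i in range(values.shape[0])],
            [f"s{j}" for j in range(values.shape[1])],
            values,
            is_normalized=True,
        )
        return t, SampleMetadata(t.sample_ids, classes)

    def test_separated_triples_attain_minimal_exact_p(self):
        # exact two-sided p for full separation at n=(3,3) is 2/C(6,3) = 0.1;
        # the normal approximation must land within its stated tolerance
        t, m = self._table([[1, 2, 3, 4, 5, 6]], ["a"] * 3 + ["b"] * 3)
        [(fid, p)] = wilcoxon_select(t, m, 1)
        assert fid == "f0"
        assert p == pytest.approx(0.1, abs=0.02)

    def test_constant_feature_has_p_one(self):
        t, m = self._table(
            [[1.0] * 6, [1, 2, 3, 6, 5, 4]], ["a"] * 3 + ["b"] * 3
        )
        pairs = dict(wilcoxon_select(t, m, 2))
        assert pairs["f0"] == 1.0

    def test_returns_k_entries_sorted_by_p(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(12, 10))
        values[3, 5:] += 4  # one strong feature
        t, m = self._table(values, ["a"] * 5 + ["b"] * 5)
        pairs = wilcoxon_select(t, m, 6)
        assert len(pairs) == 6
        ps = [p for _, p in pairs]
        assert ps == sorted(ps)
        assert pairs[0][0] == "f3"

    @pytest.mark.parametrize("na,nb", [(3, 4), (5, 5), (4, 3)])
    def test_approximation_close_to_exact_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        x = rng.normal(0, 1, na)
        yv = rng.normal(1.0, 1, nb)
        t, m = self._table([np.r_[x, yv]], ["a"] * na + ["b"] * nb)
        [(_, p_approx)] = wilcoxon_select(t, m, 1)
        # exact null distribution of the rank-sum by full enumeration
        pooled = np.r_[x, yv]
        ranks = np.argsort(np.argsort(pooled)) + 1.0
        obs = ranks[:na].sum()
        mean = na * (na + nb + 1) / 2
        stats_all = [
            sum(ranks[list(c)]) for c in combinations(range(na + nb), na)
        ]
        p_exact = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stats_all])
        assert p_approx == pytest.approx(p_exact, abs=0.02)

    def test_three_classes_rejected(self):
        t, m = self._table([[1, 2, 3]], ["a", "b", "c"])
        with pytest.raises(DegenerateDataError):
            wilcoxon_select(t, m, 1)

    def test_type_one_error_uniform_p_on_null_features(self):
        # exchangeable features: p-values near-uniform across many features
        from scipy import stats as ss

        ps = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            values = rng.gamma(2.0, 1.0, size=(300, 40))
            t, m = self._table(values, ["a"] * 20 + ["b"] * 20)
            ps += [p for _, p in wilcoxon_select(t, m, 300)]
        stat = ss.kstest(ps, "uniform").statistic
        assert stat < 1.63 / np.sqrt(len(ps))  # 1% KS critical value


class TestSvmAccuracy:
    def _dataset(self, shift, n_per_class=12, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1, size=(3, 2 * n_per_class))
        values[:2, n_per_class:] += shift
        t = AbundanceTable(
            ["f0", "f1", "f2"],
            [f"s{j}" for j in range(2 * n_per_class)],
            values,
            is_normalized=True,
        )
        m = SampleMetadata(t.sample_ids, ["a"] * n_per_class + ["b"] * n_per_class)
        return t, m

    def test_well_separated_classes_reach_full_accuracy(self):
        t, m = self._dataset(shift=8.0)
        acc = svm_cv_accuracy(
            t, ["f0", "f1"], m, folds=3, seed=0,
            c_grid=(1.0, 8.0), gamma_grid=(0.5, 0.125),
        )
        assert acc == 100.0

    def test_label_shuffled_data_near_chance(self):
        rng = np.random.default_rng(42)
        t, m = self._dataset(shift=0.0, n_per_class=15)
        accs = [
            svm_cv_accuracy(
                t, ["f0", "f1", "f2"], m, folds=3, seed=s,
                c_grid=(1.0,), gamma_grid=(0.25,),
            )
            for s in range(4)
        ]
        # chance level 50%, binomial 3-SE band over 4x30 verdicts
        se = 100 * np.sqrt(0.25 / (4 * 30))
        assert abs(np.mean(accs) - 50.0) < 4 * se + 10

    def test_fold_count_beyond_class_size_rejected(self):
        t, m = self._dataset(shift=1.0, n_per_class=3)
        with pytest.raises(ParameterError):
            svm_cv_accuracy(t, ["f0"], m, folds=5)


class TestPermutationExactTest:
    def test_identical_groups_give_p_one(self):
        assert permutation_exact_test([1.0, 2.0, 3.0], [2.0, 1.0, 3.0]) == 1.0

    def test_three_vs_three_full_separation(self):
        p = permutation_exact_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert p == pytest.approx(2 / 20)

    def test_seven_vs_seven_separation_hits_floor(self):
        a = np.arange(1.0, 8.0)
        b = np.arange(100.0, 107.0)
        p = permutation_exact_test(a, b)
        assert p == pytest.approx(2 / 3432, rel=1e-12)
        assert round(p, 5) == 0.00058

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            permutation_exact_test([], [1.0])

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.lists(st.floats(-50, 50), min_size=1, max_size=6),
        b=st.lists(st.floats(-50, 50), min_size=1, max_size=6),
        shift=st.floats(-100, 100),
    )
    def test_symmetric_in_group_order_and_shift_invariant(self, a, b, shift):
        p1 = permutation_exact_test(a, b)
        assert p1 == pytest.approx(permutation_exact_test(b, a), abs=1e-12)
        p2 = permutation_exact_test(
            [v + shift for v in a], [v + shift for v in b]
        )
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_monte_carlo_fallback_for_large_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0, 1, 15)
        p = permutation_exact_test(a, b, seed=1)
        assert 0 < p <= 1
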