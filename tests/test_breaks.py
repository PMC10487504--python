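import numpy as np
import pytest
from sklearn.base import clone

from gcscape import (
    FisherJenksBreaks,
    NaturalBreaksKSelector,
    WeightedValues,
    fisher_jenks,
    gvf,
    select_k,
)
from gcscape.breaks import gvf_path

from conftest import brute_force_sdcm, random_weighted_set


class TestFisherJenks:
    def test_two_separated_triplets(self):
        res = fisher_jenks([1, 2, 3, 10, 11, 12], 2)
        assert res.class_assignment.tolist() == [0, 0, 0, 1, 1, 1]
        assert res.break_values.tolist() == [6.5]
        # minimal SDCM is the two within-triplet variances: 2 + 2
        assert res.sdcm == pytest.approx(4.0)
        assert res.sdcm == pytest.approx(brute_force_sdcm([1, 2, 3, 10, 11, 12], np.ones(6), 2))

    def test_k1_puts_everything_in_one_class(self):
        res = fisher_jenks([3.0, 7.0, 9.0, 20.0], 1)
        assert res.sdcm == pytest.approx(res.sdam)
        assert res.gvf == 0.0
        assert res.break_values.size == 0

    def test_k_equals_n_is_perfect(self):
        res = fisher_jenks([3.0, 7.0, 9.0, 20.0], 4)
        assert res.sdcm == pytest.approx(0.0)
        assert res.gvf == 1.0

    def test_matches_exhaustive_oracle_on_random_sets(self):
        rng = np.random.default_rng(2023)
        for _ in range(60):
            values, weights = random_weighted_set(rng)
            k = int(rng.integers(1, min(4, values.size) + 1))
            res = fisher_jenks(WeightedValues(values, weights), k)
            assert res.sdcm == pytest.approx(
                brute_force_sdcm(values, weights, k), abs=1e-9
            ), f"DP != oracle for values={values} weights={weights} k={k}"

    def test_weighted_equals_expanded_multiset(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            values, weights = random_weighted_set(rng, max_distinct=10)
            wv = WeightedValues(values, weights)
            for k in range(1, min(3, wv.n_distinct) + 1):
                a = fisher_jenks(wv, k)
                b = fisher_jenks(WeightedValues.from_raw(wv.expand(), bin_resolution=0), k)
                assert a.sdcm == pytest.approx(b.sdcm, abs=1e-9)
                assert a.break_values.tolist() == pytest.approx(b.break_values.tolist())

    def test_classes_are_contiguous_and_breaks_ascending(self):
        rng = np.random.default_rng(9)
        values, weights = random_weighted_set(rng)
        k = min(4, values.size)
        res = fisher_jenks(WeightedValues(values, weights), k)
        assert (np.diff(res.class_assignment) >= 0).all()
        assert (np.diff(res.break_values) > 0).all()
        # every value falls in exactly one class via the break boundaries
        assert res.assign(values).tolist() == res.class_assignment.tolist()

    def test_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            fisher_jenks([1.0, 2.0], 3)
        with pytest.raises(ValueError, match="empty"):
            fisher_jenks([], 1)
        with pytest.raises(ValueError):
            fisher_jenks([1.0, 2.0], 0)

    def test_binning_collapses_near_identical_values(self):
        wv = WeightedValues.from_raw([41.0001, 41.0002, 50.0], bin_resolution=0.01)
        assert wv.n_distinct == 2
        assert wv.weights.tolist() == [2, 1]


class TestGVF:
    def test_constant_array_gvf_zero_by_convention(self):
        assert gvf([5.0, 5.0, 5.0], [0, 0, 0]) == 0.0

    def test_perfect_two_group_partition(self):
        values = [1.0, 1.0, 9.0, 9.0]
        assert gvf(values, np.array([0, 1])) == pytest.approx(1.0)  # 2 distinct after binning

    def test_hand_computed_example(self):
        values = [1, 2, 3, 10, 11, 12]
        res = fisher_jenks(values, 2)
        sdam = sum((v - 6.5) ** 2 for v in values)
        assert gvf(values, res.class_assignment) == pytest.approx(1 - 4.0 / sdam)

    def test_monotone_nondecreasing_in_k(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            values, weights = random_weighted_set(rng)
            path = gvf_path(WeightedValues(values, weights), k_max=min(6, values.size))
            assert (np.diff(path) >= -1e-12).all()

    def test_invalid_assignment_rejected(self):
        with pytest.raises(ValueError):
            gvf([1.0, 2.0, 3.0], [0, 1, 0])
        with pytest.raises(ValueError):
            gvf([1.0, 2.0, 3.0], [0, 1])


class TestSelectK:
    def test_two_well_separated_groups_select_k2(self):
        values = np.r_[np.full(50, 30.0), np.full(50, 60.0)]
        res = select_k(values, gvf_threshold=0.9)
        assert res.k == 2
        assert res.threshold_reached
        assert res.gvf == pytest.approx(1.0)

    def test_smallest_k_crossing_threshold_matches_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            values, weights = random_weighted_set(rng, max_distinct=12)
            wv = WeightedValues(values, weights)
            sdam = float(np.sum(weights * (values - np.average(values, weights=weights)) ** 2))
            expected = None
            for k in range(1, min(8, values.size) + 1):
                g = 1 - brute_force_sdcm(values, weights, k) / sdam if sdam > 0 else 0.0
                if g >= 0.9:
                    expected = k
                    break
            res = select_k(wv, gvf_threshold=0.9, k_max=8)
            if expected is not None:
                assert res.k == expected and res.threshold_reached
            else:
                assert not res.threshold_reached

    def test_constant_array_flagged_k1(self):
        res = select_k([42.0] * 10)
        assert res.k == 1
        assert not res.threshold_reached
        assert res.gvf == 0.0

    def test_unreachable_threshold_returns_kmax_flagged(self):
        # three distinct values cap k at 3; force an unreachable threshold
        res = select_k([1.0, 2.0, 3.0], gvf_threshold=0.999, k_max=2)
        assert res.k == 2
        assert not res.threshold_reached

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            select_k([1.0, 2.0], gvf_threshold=1.5)
        with pytest.raises(ValueError):
            select_k([1.0, 2.0], k_max=0)


class TestEstimators:
    def test_fisher_jenks_estimator_fit_predict(self):
        X = np.r_[np.random.default_rng(0).normal(35, 1, 200),
                  np.random.default_rng(1).normal(55, 1, 200)]
        est = FisherJenksBreaks(n_classes=2).fit(X)
        assert est.breaks_.size == 1
        assert 40 < est.breaks_[0] < 50
        assert set(est.labels_) == {0, 1}
        assert est.predict([30.0, 60.0]).tolist() == [0, 1]
        # a value exactly on a break belongs to the lower class
        assert est.predict([est.breaks_[0]]).tolist() == [0]

    def test_column_vector_input_accepted(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        est = FisherJenksBreaks(n_classes=2).fit(X)
        assert est.labels_.tolist() == [0, 0, 1, 1]

    def test_selector_attributes_and_clone(self):
        X = np.r_[np.full(30, 35.0), np.full(30, 55.0)]
        sel = NaturalBreaksKSelector(gvf_threshold=0.9, k_max=6)
        cloned = clone(sel)  # sklearn param contract
        assert cloned.get_params() == sel.get_params()
        sel.fit(X)
        assert sel.k_ == 2 and sel.threshold_reached_
        assert sel.gvf_path_.size <= 6
        assert (np.diff(sel.gvf_path_) >= -1e-12).all()
        assert sel.fit_predict(X).tolist() == sel.labels_.tolist()

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            FisherJenksBreaks().predict([1.0])
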