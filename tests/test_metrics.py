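"""RE/CC metrics, sweep machinery and the K-selection rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from headbem import (compare_leadfields, correlation_coefficient,
                     relative_error, select_optimal_K)
from headbem.metrics import MetricSummary, SweepResult


class TestRelativeError:
    def test_identical_is_zero(self):
        d = np.array([1.0, -2.0, 3.0])
        assert relative_error(d, d) == 0.0

    def test_zero_test_is_one(self):
        assert relative_error([1.0, 2.0], [0.0, 0.0]) == 1.0

    def test_doubled_test_is_one(self):
        d = np.array([1.0, -2.0, 3.0])
        assert relative_error(d, 2 * d) == pytest.approx(1.0)

    def test_zero_reference_flagged_not_infinite(self):
        assert np.isnan(relative_error([0.0, 0.0], [1.0, 2.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(float, 8, elements=st.floats(-1e3, 1e3)),
           arrays(float, 8, elements=st.floats(-1e3, 1e3)),
           st.floats(1e-3, 1e3))
    def test_common_scaling_invariance(self, a, b, c):
        if np.linalg.norm(a) == 0:
            return
        assert relative_error(c * a, c * b) == pytest.approx(relative_error(a, b),
                                                             rel=1e-9, abs=1e-12)


class TestCorrelationCoefficient:
    def test_positive_scaling_gives_exactly_one(self):
        d = np.array([0.3, -1.2, 4.0, 0.01])
        assert correlation_coefficient(d, 3.7 * d) == 1.0

    def test_negated_copy_gives_minus_one(self):
        d = np.array([0.3, -1.2, 4.0, 0.01])
        assert correlation_coefficient(d, -d) == -1.0

    def test_centered_orthogonal_vectors_give_zero(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert correlation_coefficient(a, b) == pytest.approx(0.0, abs=1e-15)

    def test_constant_vector_flagged(self):
        assert np.isnan(correlation_coefficient([2.0, 2.0], [1.0, 3.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(float, 10, elements=st.floats(-1e2, 1e2)),
           st.floats(1e-2, 1e2), st.floats(1e-2, 1e2))
    def test_scale_invariance_each_argument(self, d, a, b):
        if np.ptp(d) == 0:
            return
        base = correlation_coefficient(d, d ** 2 + d)
        if np.isnan(base):
            return
        assert correlation_coefficient(a * d, b * (d ** 2 + d)) == pytest.approx(
            base, rel=1e-9, abs=1e-12)


class TestCompareLeadfields:
    def test_identical_leadfields(self):
        m = np.random.default_rng(0).standard_normal((6, 4))
        s = compare_leadfields(m, m)
        assert s.median_re == 0.0
        assert s.median_cc == 1.0

    def test_halved_copy(self):
        m = np.random.default_rng(1).standard_normal((6, 4))
        s = compare_leadfields(m, 0.5 * m)
        assert s.median_re == pytest.approx(0.5)
        assert s.median_cc == pytest.approx(1.0)

    def test_matches_per_column_brute_force(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((5, 4))
        b = rng.standard_normal((5, 4))
        s = compare_leadfields(a, b)
        for j in range(4):
            assert s.re[j] == pytest.approx(relative_error(a[:, j], b[:, j]))
            assert s.cc[j] == pytest.approx(correlation_coefficient(a[:, j], b[:, j]))
        p16, p50, p84 = s.percentiles("re")
        assert p16 <= p50 <= p84

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_leadfields(np.ones((3, 2)), np.ones((4, 2)))


def _sweep_from_grids(k_ref, k_test, med_re, med_cc):
    """Build a SweepResult with per-source arrays that reproduce the given
    median grids exactly (all sources identical)."""
    summaries = []
    for i in range(len(k_ref)):
        row = []
        for j in range(len(k_test)):
            row.append(MetricSummary(re=np.full(3, med_re[i][j]),
                                     cc=np.full(3, med_cc[i][j]),
                                     flagged=np.zeros(3, bool)))
        summaries.append(row)
    return SweepResult(np.asarray(k_ref, float), np.asarray(k_test, float),
                       summaries, "EEG", "4C", "3S")


class TestSelectOptimalK:
    def test_strictly_dominant_column_wins(self):
        k_test = [20.0, 40.0, 60.0]
        med_re = [[0.5, 0.2, 0.6], [0.4, 0.25, 0.5]]
        med_cc = [[0.9, 0.99, 0.9], [0.9, 0.99, 0.9]]
        sel = select_optimal_K(_sweep_from_grids([30.0, 50.0], k_test, med_re, med_cc))
        assert sel["K_best"] == 40.0

    def test_tie_broken_by_cc(self):
        # expected REs 0.200 and 0.205 are within one percentage point;
        # the second has the better CC and must win
        k_test = [80.0, 100.0]
        med_re = [[0.200, 0.205]]
        med_cc = [[0.990, 0.994]]
        sel = select_optimal_K(_sweep_from_grids([50.0], k_test, med_re, med_cc))
        assert sel["K_best"] == 100.0

    def test_invariant_to_grid_reordering(self):
        rng = np.random.default_rng(3)
        k_test = np.array([20.0, 50.0, 80.0, 110.0])
        med_re = rng.uniform(0.1, 0.6, (3, 4))
        med_cc = rng.uniform(0.9, 1.0, (3, 4))
        sel = select_optimal_K(_sweep_from_grids([20.0, 50.0, 80.0], k_test,
                                                 med_re, med_cc))
        perm = [2, 0, 3, 1]
        sel_p = select_optimal_K(_sweep_from_grids([20.0, 50.0, 80.0], k_test[perm],
                                                   med_re[:, perm], med_cc[:, perm]))
        assert sel["K_best"] == sel_p["K_best"]

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError):
            select_optimal_K(_sweep_from_grids([], [], [], []))


class TestExpectedErrorProperties:
    def test_expectation_bounds_minimum(self):
        """Mean over references can never beat the best single reference."""
        rng = np.random.default_rng(4)
        per_ref = rng.uniform(0.0, 1.0, (5, 30))  # refs x sources
        expected = per_ref.mean(axis=0)
        assert np.all(expected >= per_ref.min(axis=0) - 1e-15)

    def test_single_reference_identity_is_zero(self, compensation_study):
        """With K_ref == K_test, same kind / mesh / method, error vanishes."""
        sweep4 = compensation_study["sweep_4c"]
        diag = np.diag(sweep4.median_re())
        assert np.abs(diag).max() < 1e-10
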