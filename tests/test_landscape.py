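import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import netlandscape as nl
from netlandscape.landscape import Verdict, _minima_indices


def brute_force_minima(u):
    """Oracle: all-points neighbour scan (no plateau handling needed when
    values are distinct)."""
    out = []
    n = len(u)
    for i in range(n):
        left_ok = i == 0 or u[i] < u[i - 1]
        right_ok = i == n - 1 or u[i] < u[i + 1]
        if left_ok and right_ok:
            out.append(i)
    return out


class TestToLandscape:
    def test_uniform_grid_has_constant_potential(self):
        ls = nl.to_landscape(np.arange(10), np.full(10, 0.1))
        np.testing.assert_allclose(ls.potential, np.log(10))

    def test_single_node_two_state_case(self):
        p = nl.IsingParameters(encoding="01", tau=np.zeros(1),
                               omega=np.zeros((1, 1)))
        k = nl.active_count_distribution(nl.exact_distribution(p))
        ls = nl.to_landscape(k.counts, k.probabilities)
        np.testing.assert_allclose(ls.potential, [np.log(2), np.log(2)])

    def test_scaling_mass_leaves_potential_differences_unchanged(self, rng):
        p = rng.random(12) + 0.05
        a = nl.to_landscape(np.arange(12), p)
        b = nl.to_landscape(np.arange(12), 7.3 * p)
        np.testing.assert_allclose(np.diff(a.potential), np.diff(b.potential),
                                   atol=1e-12)

    def test_zero_probability_gets_infinite_potential(self):
        ls = nl.to_landscape(np.arange(4), np.array([0.5, 0.0, 0.25, 0.25]))
        assert np.isinf(ls.potential[1])
        report = nl.find_stable_states(ls)
        assert all(np.isfinite(u) for _, u in report.minima)

    def test_all_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            nl.to_landscape(np.arange(3), np.zeros(3))

    def test_continuous_axis_normalised_by_trapezoid(self):
        grid = np.linspace(-4, 4, 201)
        density = np.exp(-grid**2 / 2)  # unnormalised Gaussian
        ls = nl.to_landscape(grid, density, nl.AxisKind.SUM_SCORE)
        assert np.trapezoid(ls.probability, grid) == pytest.approx(1.0, abs=1e-9)


class TestFindStableStates:
    def test_hand_computed_double_well(self):
        ls = nl.to_landscape(np.arange(5), np.exp(-np.array([3, 1, 2, 0.5, 4.0])))
        r = nl.find_stable_states(ls)
        assert [m[0] for m in r.minima] == [1.0, 3.0]
        assert [t[0] for t in r.tipping_points] == [2.0]
        assert r.barrier_heights == pytest.approx((1.0, 1.5))
        assert r.deepest_state == 3.0
        assert r.n_stable == 2

    def test_monotone_potential_single_boundary_minimum(self):
        ls = nl.to_landscape(np.arange(6), np.exp(-np.arange(6.0)))
        r = nl.find_stable_states(ls)
        assert r.n_stable == 1
        assert r.minima[0][0] == 0.0  # U = -ln p is increasing, valley at left edge
        assert np.isnan(r.barrier_heights[0])

    def test_symmetric_double_well_equal_barriers(self):
        u = np.array([0.0, 2.0, 0.0])
        ls = nl.to_landscape(np.arange(3), np.exp(-u))
        r = nl.find_stable_states(ls)
        assert r.n_stable == 2
        assert r.barrier_heights[0] == pytest.approx(r.barrier_heights[1])

    def test_plateau_counts_once_at_midpoint(self):
        p = np.exp(-np.array([3.0, 1.0, 1.0, 1.0, 3.0, 0.5, 4.0]))
        r = nl.find_stable_states(nl.to_landscape(np.arange(7), p))
        assert [m[0] for m in r.minima] == [2.0, 5.0]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            nl.find_stable_states(nl.to_landscape(np.arange(2), [0.5, 0.5]))

    def test_oracle_agreement_on_random_landscapes(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            u = rng.normal(size=rng.integers(3, 25))
            mins = _minima_indices(u)
            assert mins == brute_force_minima(u)

    def test_half_depths_track_probability_mass(self):
        # all mass low -> deep healthy side; shifting mass raises unhealthy depth
        lo = nl.find_stable_states(nl.to_landscape(
            np.arange(10), np.array([0.8, 0.1] + [0.0125] * 8)))
        hi = nl.find_stable_states(nl.to_landscape(
            np.arange(10), np.array([0.4, 0.1] + [0.0125] * 6 + [0.1, 0.3])))
        assert lo.healthy_depth > hi.healthy_depth
        assert lo.unhealthy_depth < hi.unhealthy_depth


class TestClassifySweep:
    @staticmethod
    def _report(mass):
        return nl.find_stable_states(nl.to_landscape(np.arange(len(mass)),
                                                     np.asarray(mass, float)))

    def test_gvar_style_sweep_fails_both_predictions(self):
        grid = np.linspace(-4, 4, 101)
        reports = {}
        for mult, sd in [(0.5, 1.0), (1.0, 1.5), (1.2, 2.0)]:
            d = np.exp(-grid**2 / (2 * sd**2))
            reports[mult] = nl.find_stable_states(
                nl.to_landscape(grid, d, nl.AxisKind.SUM_SCORE))
        c = nl.classify_sweep(reports)
        assert c.prediction1_severity is False
        assert c.prediction2_discontinuity is Verdict.NO

    def test_mass_shift_with_emerging_second_state_is_yes_yes(self):
        reports = {
            0.9: self._report([0.7, 0.2, 0.04, 0.03, 0.02, 0.01]),
            1.0: self._report([0.6, 0.25, 0.05, 0.04, 0.035, 0.025]),
            2.0: self._report([0.4, 0.2, 0.05, 0.04, 0.01, 0.3]),
        }
        c = nl.classify_sweep(reports)
        assert c.prediction1_severity is True
        assert c.prediction2_discontinuity is Verdict.YES

    def test_both_basins_deepening_fails_prediction1(self):
        reports = {
            1.0: self._report([0.5, 0.2, 0.1, 0.1, 0.02, 0.08]),
            2.0: self._report([0.55, 0.1, 0.05, 0.05, 0.01, 0.24]),
        }
        assert nl.classify_sweep(reports).prediction1_severity is False

    def test_appear_then_vanish_is_partial(self):
        reports = {
            0.9: self._report([0.7, 0.2, 0.04, 0.03, 0.02, 0.01]),
            1.0: self._report([0.5, 0.2, 0.05, 0.04, 0.01, 0.2]),
            2.0: self._report([0.3, 0.25, 0.2, 0.1, 0.08, 0.07]),
        }
        assert nl.classify_sweep(reports).prediction2_discontinuity is Verdict.PARTIAL

    def test_mixed_axis_kinds_rejected(self):
        a = self._report([0.7, 0.2, 0.1])
        grid = np.linspace(-1, 1, 51)
        b = nl.find_stable_states(nl.to_landscape(
            grid, np.exp(-grid**2), nl.AxisKind.SUM_SCORE))
        with pytest.raises(ValueError, match="axis"):
            nl.classify_sweep({1.0: a, 2.0: b})


class TestClassifyModel:
    def test_all_yes_no_and_mixed_aggregation(self):
        def sweep(p1, p2):
            return nl.SweepClassification(prediction1_severity=p1,
                                          prediction2_discontinuity=p2,
                                          n_stable_by_multiplier={})
        both = {"a": sweep(True, Verdict.YES), "b": sweep(True, Verdict.YES)}
        c = nl.classify_model(both)
        assert c.prediction1_severity is Verdict.YES
        assert c.prediction2_discontinuity is Verdict.YES
        mixed = {"a": sweep(True, Verdict.YES), "b": sweep(False, Verdict.NO)}
        c = nl.classify_model(mixed)
        assert c.prediction1_severity is Verdict.NO
        assert c.prediction2_discontinuity is Verdict.PARTIAL
        c = nl.classify_model(mixed, theory_conditions=["a"])
        assert c.prediction1_severity is Verdict.YES

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            nl.classify_model({}, theory_conditions=["a"])


class TestMeanField:
    def test_zero_coupling_zero_field_single_root(self):
        roots = nl.mean_field_fixed_points(0.0, 0.0, 9)
        np.testing.assert_allclose(roots, [0.0], atol=1e-9)

    def test_supercritical_symmetric_three_roots(self):
        # (n-1) c = 2, h = 0: known roots of tanh(2m) = m
        roots = nl.mean_field_fixed_points(2.0 / 8.0, 0.0, 9)
        np.testing.assert_allclose(roots, [-0.957504, 0.0, 0.957504], atol=1e-5)

    def test_saturating_field_single_positive_root(self):
        roots = nl.mean_field_fixed_points(0.25, 5.0, 9)
        assert roots.size == 1 and roots[0] > 0.99

    def test_calibration_regimes_bracket_the_bifurcation(self):
        # {-1,1} baseline mean coupling 0.14: monostable at multiplier 1,
        # bistable at multiplier 2 under mean tau = -0.2
        assert nl.mean_field_fixed_points(0.14, -0.2, 9).size == 1
        assert nl.mean_field_fixed_points(0.28, -0.2, 9).size == 3


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_pm1_zero_threshold_landscape_mirror_symmetric(seed):
    rng = np.random.default_rng(seed)
    n = 6
    w = rng.normal(size=(n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    p = nl.IsingParameters(encoding="pm1", tau=np.zeros(n), omega=w)
    k = nl.active_count_distribution(nl.exact_distribution(p))
    ls = nl.to_landscape(k.counts, k.probabilities)
    report = nl.find_stable_states(ls)
    locs = np.array([m[0] for m in report.minima])
    np.testing.assert_allclose(np.sort(n - locs), np.sort(locs), atol=0)
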