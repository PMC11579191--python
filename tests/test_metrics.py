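import math

import numpy as np
import pytest

from multidose import (
    PKParameters,
    auc_cycle,
    auc_single_infinite,
    bateman_single,
    concentration,
    cycle_metrics,
    make_equidose,
    n_epsilon,
    periodicity_gap,
    remainder,
    steady_state_bounds,
    steady_state_summary,
    t_max_cycle,
    therapeutic_width,
    therapeutic_width_limit,
    x_max_cycle,
)
from multidose.oracle import auc_numeric

D, TAU = 600.0, 5.0


class TestAUC:
    def test_cycle_auc_matches_quadrature(self, oral_params):
        reg = make_equidose(D, TAU, 6)
        for n in (1, 2, 5):
            numeric = auc_numeric(
                lambda t: concentration(oral_params, reg, t),
                (n - 1) * TAU, n * TAU, tol=1e-12,
            )
            assert auc_cycle(oral_params, D, TAU, n) == pytest.approx(numeric, rel=1e-8)

    def test_limit_equals_single_dose_auc(self, oral_params):
        assert auc_cycle(oral_params, D, TAU, 10**6) == pytest.approx(
            auc_single_infinite(oral_params, D), rel=1e-10
        )

    def test_zero_dose(self, oral_params):
        assert auc_cycle(oral_params, 0, TAU, 3) == 0.0
        assert auc_single_infinite(oral_params, 0) == 0.0

    def test_single_dose_auc_matches_quadrature(self, oral_params):
        T = 50 / oral_params.ke
        numeric = auc_numeric(
            lambda t: bateman_single(oral_params, D, t), 0.0, T, tol=1e-10
        )
        assert auc_single_infinite(oral_params, D) == pytest.approx(numeric, rel=1e-6)

    def test_simplifies_to_gamma_d_over_ke(self, oral_params):
        """k (1/ke - 1/ka) collapses to gamma/ke — absorption-rate free."""
        assert auc_single_infinite(oral_params, D) == pytest.approx(
            oral_params.gamma * D / oral_params.ke, rel=1e-13
        )

    def test_equal_areas_identity_random_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            ka, ke = np.exp(rng.uniform(np.log(0.05), np.log(2.0), 2))
            if abs(ka - ke) / max(ka, ke) < 0.01:
                continue
            p = PKParameters(ka=ka, ke=ke, gamma=rng.uniform(1e-4, 1e-2))
            d = rng.uniform(1, 1000)
            s = steady_state_summary(p, d, rng.uniform(1, 24), eps=1e-3)
            assert s.auc_ss == pytest.approx(auc_single_infinite(p, d), rel=1e-12)


class TestPeak:
    def test_first_cycle_is_classic_single_dose_peak(self, oral_params):
        expected = math.log(oral_params.ka / oral_params.ke) / (
            oral_params.ka - oral_params.ke
        )
        assert t_max_cycle(oral_params, D, TAU, 1) == pytest.approx(expected, rel=1e-12)

    def test_matches_numerical_argmax(self, oral_params):
        """Closed-form peak time vs golden-section refinement of a dense grid."""
        from scipy.optimize import minimize_scalar

        reg = make_equidose(D, TAU, 6)
        n = 5
        res = minimize_scalar(
            lambda t: -concentration(oral_params, reg, t),
            bounds=((n - 1) * TAU, n * TAU), method="bounded",
            options={"xatol": 1e-10},
        )
        assert t_max_cycle(oral_params, D, TAU, n) == pytest.approx(res.x, abs=1e-6)

    def test_offset_decreases_toward_positive_limit(self, oral_params):
        offsets = [
            t_max_cycle(oral_params, D, TAU, n) - (n - 1) * TAU for n in range(1, 51)
        ]
        # nonincreasing up to rounding once the geometric terms underflow
        assert all(a >= b - 1e-12 for a, b in zip(offsets, offsets[1:]))
        assert offsets[-1] > 0

    def test_power_form_equals_direct_evaluation(self, oral_params):
        reg = make_equidose(D, TAU, 12)
        for n in (1, 4, 12):
            t_pk = t_max_cycle(oral_params, D, TAU, n)
            assert x_max_cycle(oral_params, D, TAU, n) == pytest.approx(
                concentration(oral_params, reg, t_pk), rel=1e-12
            )

    def test_single_dose_cmax_closed_form(self, oral_params):
        r = oral_params.ka / oral_params.ke
        q = oral_params.ke / (oral_params.ka - oral_params.ke)
        expected = oral_params.k * D * (r**(-q) - r**(-q - 1))
        assert x_max_cycle(oral_params, D, TAU, 1) == pytest.approx(expected, rel=1e-12)

    def test_x_max_increases_to_upper_bound(self, oral_params):
        xm = [x_max_cycle(oral_params, D, TAU, n) for n in range(1, 201)]
        assert all(a < b for a, b in zip(xm[:15], xm[1:16]))  # strict while resolvable
        assert all(a <= b for a, b in zip(xm, xm[1:]))
        _, upper = steady_state_bounds(oral_params, D, TAU)
        assert xm[-1] == pytest.approx(upper, rel=1e-6)


class TestRemainder:
    def test_equals_concentration_at_cycle_end(self, oral_params):
        reg = make_equidose(D, TAU, 8)
        for n in (1, 3, 7):
            assert remainder(oral_params, D, TAU, n) == pytest.approx(
                concentration(oral_params, reg, n * TAU), rel=1e-12
            )

    def test_positive_under_flip_flop(self, flipflop_params):
        vals = [remainder(flipflop_params, 100, 6, n) for n in range(1, 101)]
        assert all(v > 0 for v in vals)

    def test_increasing_toward_lower_bound(self, oral_params):
        vals = [remainder(oral_params, D, TAU, n) for n in range(1, 300)]
        assert all(a < b for a, b in zip(vals[:15], vals[1:16]))  # strict while resolvable
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        lower, _ = steady_state_bounds(oral_params, D, TAU)
        assert vals[-1] == pytest.approx(lower, rel=1e-9)


class TestSteadyState:
    def test_bounds_match_long_simulation(self, oral_params):
        """Min/max over a deep cycle of the closed-form trajectory."""
        n_cycles = 300
        reg = make_equidose(D, TAU, n_cycles)
        t = np.linspace((n_cycles - 1) * TAU, n_cycles * TAU, 20001)
        x = concentration(oral_params, reg, t)
        lower, upper = steady_state_bounds(oral_params, D, TAU)
        assert x.min() == pytest.approx(lower, rel=1e-6)
        assert x.max() == pytest.approx(upper, rel=1e-6)

    def test_linear_in_dose(self, oral_params):
        lo1, up1 = steady_state_bounds(oral_params, D, TAU)
        lo2, up2 = steady_state_bounds(oral_params, 2 * D, TAU)
        assert lo2 == pytest.approx(2 * lo1, rel=1e-13)
        assert up2 == pytest.approx(2 * up1, rel=1e-13)

    def test_long_interval_limits(self, oral_params):
        """tau -> inf: trough bound -> 0, peak bound -> single-dose Cmax."""
        tau_long = 1e3 / min(oral_params.ka, oral_params.ke)
        lower, upper = steady_state_bounds(oral_params, D, tau_long)
        assert lower == pytest.approx(0.0, abs=1e-12)
        assert upper == pytest.approx(x_max_cycle(oral_params, D, tau_long, 1), rel=1e-9)

    def test_monotone_in_dose_and_interval(self, oral_params):
        doses = np.linspace(100, 1000, 20)
        taus = np.linspace(2, 48, 20)
        for tau in taus:
            bounds = [steady_state_bounds(oral_params, d, tau) for d in doses]
            assert all(a[0] < b[0] and a[1] < b[1] for a, b in zip(bounds, bounds[1:]))
        for d in doses:
            bounds = [steady_state_bounds(oral_params, d, tau) for tau in taus]
            assert all(a[0] > b[0] and a[1] > b[1] for a, b in zip(bounds, bounds[1:]))

    def test_upper_exceeds_lower_on_random_draws(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ka, ke = np.exp(rng.uniform(np.log(0.05), np.log(2.0), 2))
            if abs(ka - ke) / max(ka, ke) < 0.01:
                continue
            p = PKParameters(ka=ka, ke=ke, gamma=1e-3)
            lo, up = steady_state_bounds(p, rng.uniform(1, 1000), rng.uniform(1, 48))
            assert up > lo > 0


class TestWidth:
    def test_positive_on_grid(self, oral_params):
        for d in np.linspace(50, 1000, 20):
            for tau in np.linspace(1, 48, 20):
                assert therapeutic_width(oral_params, d, tau) > 0

    def test_linear_in_dose(self, oral_params):
        assert therapeutic_width(oral_params, 2 * D, TAU) == pytest.approx(
            2 * therapeutic_width(oral_params, D, TAU), rel=1e-13
        )

    def test_long_interval_limit(self, oral_params):
        assert therapeutic_width(oral_params, D, 1e3) == pytest.approx(
            therapeutic_width_limit(oral_params, D), rel=1e-6
        )

    def test_increasing_in_dose_and_interval(self, oral_params):
        widths_tau = [therapeutic_width(oral_params, D, tau) for tau in np.linspace(1, 48, 30)]
        assert all(a < b for a, b in zip(widths_tau, widths_tau[1:]))


class TestPeriodicityGap:
    def test_decay_ratio_approaches_slowest_mode(self, oral_params):
        """gap(n+1)/gap(n) -> max(alpha, beta) within 1% by n = 50."""
        alpha = math.exp(-oral_params.ka * TAU)
        beta = math.exp(-oral_params.ke * TAU)
        g50 = periodicity_gap(oral_params, D, TAU, 50)
        g51 = periodicity_gap(oral_params, D, TAU, 51)
        assert g51 / g50 == pytest.approx(max(alpha, beta), rel=0.01)

    def test_closed_form_sup_matches_dense_grid(self, oral_params):
        from multidose.metrics import _equi_c1_c2

        for n in (2, 5, 20):
            dc1 = _equi_c1_c2(oral_params, D, TAU, n)[0] - _equi_c1_c2(oral_params, D, TAU, n - 1)[0]
            dc2 = _equi_c1_c2(oral_params, D, TAU, n)[1] - _equi_c1_c2(oral_params, D, TAU, n - 1)[1]
            s = np.linspace(0, TAU, 100001)
            grid_max = np.max(np.abs(
                dc1 * np.exp(-oral_params.ke * s) - dc2 * np.exp(-oral_params.ka * s)
            ))
            assert periodicity_gap(oral_params, D, TAU, n) == pytest.approx(
                grid_max, rel=1e-8
            )

    def test_zero_dose_gap_is_zero(self, oral_params):
        assert periodicity_gap(oral_params, 0, TAU, 5) == 0.0

    def test_needs_two_cycles(self, oral_params):
        with pytest.raises(IndexError):
            periodicity_gap(oral_params, D, TAU, 1)


class TestNEpsilon:
    def test_immediate_satisfaction(self, oral_params):
        g2 = periodicity_gap(oral_params, D, TAU, 2)
        assert n_epsilon(oral_params, D, TAU, 10 * g2) <= 2

    def test_certified_threshold(self, oral_params):
        """gap(n) < eps <= gap(n-1) at the returned index, and the tail stays
        below eps on an exhaustive scan 100 cycles deep."""
        eps = 1e-6
        n = n_epsilon(oral_params, D, TAU, eps)
        assert periodicity_gap(oral_params, D, TAU, n) < eps
        assert periodicity_gap(oral_params, D, TAU, n - 1) >= eps
        assert all(
            periodicity_gap(oral_params, D, TAU, m) < eps for m in range(n, n + 100)
        )

    def test_monotone_in_eps(self, oral_params):
        eps = 1e-3
        assert n_epsilon(oral_params, D, TAU, eps / 2) >= n_epsilon(oral_params, D, TAU, eps)


class TestSummary:
    def test_bounds_bracket_deep_cycle(self, oral_params):
        s = steady_state_summary(oral_params, D, TAU, eps=1e-6)
        deep = s.n_eps + 50
        reg = make_equidose(D, TAU, deep)
        t = np.linspace((deep - 1) * TAU, deep * TAU, 4001)
        x = concentration(oral_params, reg, t)
        assert np.all(x >= s.ss_lower - s.eps)
        assert np.all(x <= s.ss_upper + s.eps)

    def test_zero_dose_flagged_degenerate(self, oral_params):
        s = steady_state_summary(oral_params, 0, TAU)
        assert s.degenerate and s.width == 0.0

    def test_gaps_recorded_up_to_n_eps(self, oral_params):
        s = steady_state_summary(oral_params, D, TAU, eps=1e-4)
        assert len(s.gaps) == s.n_eps - 1
        assert s.gaps[-1] < s.eps

    def test_cycle_metrics_bundle(self, oral_params):
        m = cycle_metrics(oral_params, D, TAU, 3)
        assert m.n == 3 and m.auc > 0 and m.x_max > m.remainder > 0
        assert 2 * TAU <= m.t_max <= 3 * TAU
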