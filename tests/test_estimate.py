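"""Estimators: bound-fraction conversion, Hill fits, association kinetics,
two-window analysis, and constrained model fitting."""

import numpy as np
import pytest

from tsh2bind import (
    EstimationError,
    KineticTrace,
    ParameterError,
    TitrationData,
    derived_kds,
    double_exponential_fit,
    experimental_bound_fraction,
    fit_association,
    fit_model_to_dose_response,
    hill_fit,
    hill_plot_slope,
    two_step_rates,
    zap70_reference,
)
from tsh2bind.simulate import dose_response


def hill_law(x, kd, nh, bmax):
    x = np.asarray(x, float)
    return bmax * x**nh / (kd**nh + x**nh)


class TestExperimentalBoundFraction:
    @pytest.mark.parametrize(
        "F, expected", [(2.0, 0.0), (1.0, 1.0), (1.5, 0.5)]
    )
    def test_fluorescence_endpoints_and_midpoint(self, F, expected):
        assert experimental_bound_fraction(F, Fmax=2.0, Fmin=1.0) == expected

    def test_clamping_is_optional(self):
        assert experimental_bound_fraction(0.5, 2.0, 1.0) == 1.5
        assert experimental_bound_fraction(0.5, 2.0, 1.0, clamp=True) == 1.0

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(ParameterError):
            experimental_bound_fraction(1.0, 1.0, 1.0)


class TestHillFit:
    @pytest.mark.parametrize(
        "kd, nh, bmax", [(10.0, 1.0, 2.0), (100.0, 2.0, 1.0), (65.0, 0.9, 1.5)]
    )
    def test_noiseless_round_trip(self, kd, nh, bmax):
        x = np.logspace(-1, 4, 25)
        fit = hill_fit(TitrationData(x, hill_law(x, kd, nh, bmax)))
        assert fit.kd == pytest.approx(kd, rel=1e-6)
        assert fit.n_h == pytest.approx(nh, rel=1e-6)
        assert fit.bmax == pytest.approx(bmax, rel=1e-6)

    def test_flat_signal_rejected(self):
        with pytest.raises(EstimationError):
            hill_fit(TitrationData(np.logspace(0, 3, 10), np.ones(10)))

    def test_too_few_points_rejected(self):
        with pytest.raises(EstimationError):
            hill_fit(TitrationData([1, 10, 100], [0.1, 0.5, 0.9]))


class TestHillPlot:
    @pytest.mark.parametrize("nh", [1.0, 3.4])
    def test_slope_recovers_the_hill_exponent(self, nh):
        x = np.logspace(0, 3, 30)
        data = TitrationData(x, hill_law(x, 50.0, nh, 1.0))
        assert hill_plot_slope(data, bmax=1.0) == pytest.approx(nh, abs=1e-6)

    def test_slope_invariant_to_ligand_unit_rescaling(self):
        x = np.logspace(0, 3, 30)
        y = hill_law(x, 50.0, 2.0, 1.0)
        s_nM = hill_plot_slope(TitrationData(x, y), bmax=1.0)
        s_uM = hill_plot_slope(TitrationData(x * 1e3, y), bmax=1.0)
        assert s_nM == pytest.approx(s_uM, rel=1e-9)

    def test_agrees_with_hill_fit_on_noiseless_data(self):
        x = np.logspace(0, 4, 30)
        data = TitrationData(x, hill_law(x, 200.0, 1.7, 2.0))
        assert hill_plot_slope(data) == pytest.approx(hill_fit(data).n_h, rel=0.1)

    def test_too_few_admissible_points_rejected(self):
        x = np.array([1e-3, 1e4, 1e5, 1e6])  # occupancies outside (0.1, 0.9)
        data = TitrationData(x, hill_law(x, 50.0, 1.0, 1.0))
        with pytest.raises(EstimationError):
            hill_plot_slope(data, bmax=1.0)


def exp_trace(t_end, n, k, a=1.0, y0=0.0, window="custom"):
    t = np.linspace(0.0, t_end, n)
    return KineticTrace(t, y0 + a * (1.0 - np.exp(-k * t)), window=window)


class TestFitAssociation:
    def test_unit_rate_round_trip(self):
        fit = fit_association(exp_trace(5.0, 100, 1.0))
        assert fit.kobs == pytest.approx(1.0, rel=1e-8)

    def test_affine_signal_rescaling_leaves_kobs_unchanged(self):
        t = np.linspace(0, 5, 80)
        y = 1.0 - np.exp(-0.7 * t)
        k1 = fit_association(KineticTrace(t, y)).kobs
        k2 = fit_association(KineticTrace(t, 3.0 - 5.0 * y)).kobs
        assert k1 == pytest.approx(k2, rel=1e-7)

    def test_fast_window_isolates_the_fast_rate_of_a_two_phase_trace(self):
        # rates separated 50x: the windowed protocol (slow-phase ramp
        # subtracted from the fast window) recovers the fast rate within 5%
        def y(t):
            return 0.6 * (1 - np.exp(-10.0 * t)) + 0.4 * (1 - np.exp(-0.2 * t))

        t_fast = np.linspace(0, 1.0, 101)
        t_slow = np.linspace(0, 200.0, 1500)
        res = two_step_rates(
            KineticTrace(t_fast, y(t_fast), window="fast"),
            KineticTrace(t_slow, y(t_slow), window="slow"),
        )
        assert res.kobs_fast == pytest.approx(10.0, rel=0.05)

    def test_too_short_trace_rejected(self):
        with pytest.raises(EstimationError):
            fit_association(exp_trace(1.0, 5, 1.0))


class TestTwoStepRates:
    @staticmethod
    def two_phase(kf_, ks_, af_=0.6, as_=0.4):
        tf = np.linspace(0, 1.0, 101)
        ts = np.linspace(0, 200.0, 1500)

        def y(t):
            return 1.0 - af_ * (1 - np.exp(-kf_ * t)) - as_ * (1 - np.exp(-ks_ * t))

        return (KineticTrace(tf, y(tf), window="fast"),
                KineticTrace(ts, y(ts), window="slow"))

    def test_round_trip_of_table_like_rates(self):
        fast, slow = self.two_phase(24.0, 0.26)
        res = two_step_rates(fast, slow)
        assert not res.fast_absent and not res.slow_absent
        assert res.kobs_fast == pytest.approx(24.0, rel=0.05)
        assert res.kobs_slow == pytest.approx(0.26, rel=0.05)

    def test_slow_phase_reported_absent_for_single_fast_exponential(self):
        fast, slow = self.two_phase(24.0, 0.26, af_=1.0, as_=0.0)
        res = two_step_rates(fast, slow)
        assert res.slow_absent and res.kobs_slow is None
        assert res.kobs_fast == pytest.approx(24.0, rel=0.05)

    def test_fast_phase_reported_absent_for_slow_only_binding(self):
        # C-SH2 pocket mutant regime: only a very slow phase exists
        fast, slow = self.two_phase(24.0, 0.006, af_=0.0, as_=1.0)
        res = two_step_rates(fast, slow)
        assert res.fast_absent and res.kobs_fast is None
        assert res.kobs_slow == pytest.approx(0.006, rel=0.1)

    def test_window_order_enforced(self):
        fast, slow = self.two_phase(24.0, 0.26)
        with pytest.raises(ParameterError):
            two_step_rates(slow, fast)


class TestDoubleExponentialFit:
    def test_recovers_well_separated_rates(self):
        t = np.linspace(0, 200, 1500)
        y = 0.5 * (1 - np.exp(-24.0 * t)) + 0.5 * (1 - np.exp(-0.26 * t))
        fit = double_exponential_fit(KineticTrace(t, y))
        assert fit.k_fast == pytest.approx(24.0, rel=0.05)
        assert fit.k_slow == pytest.approx(0.26, rel=0.05)
        assert not fit.ambiguous

    def test_close_rates_are_flagged_ambiguous(self):
        t = np.linspace(0, 10, 300)
        y = 0.5 * (1 - np.exp(-1.0 * t)) + 0.5 * (1 - np.exp(-0.6 * t))
        fit = double_exponential_fit(KineticTrace(t, y))
        assert fit.ambiguous


class TestFitModelToDoseResponse:
    def test_self_consistency_with_fixed_kds(self, ref_rates):
        grid = np.logspace(-1, 5, 15)
        truth = dose_response(ref_rates, "full", grid, method="direct")
        kds = derived_kds(ref_rates)
        fit = fit_model_to_dose_response(
            grid, truth.phi_b, (kds.kd1, kds.kd2, kds.kd1star),
            variant="full", n_starts=2, seed=1,
        )
        # residual at the noise floor and constraints honored exactly
        assert fit.rss < 1e-6
        got = derived_kds(fit.rates)
        assert got.kd1 == pytest.approx(kds.kd1, rel=1e-9)
        assert got.kd2 == pytest.approx(kds.kd2, rel=1e-9)
        assert got.kd1star == pytest.approx(kds.kd1star, rel=1e-9)
        np.testing.assert_allclose(fit.phi_model, truth.phi_b, atol=1e-3)

    def test_reduced_variant_round_trip(self, reduced_rates):
        from tsh2bind.simulate import reduced_steady_state, bound_fraction
        grid = np.logspace(0, 5, 15)
        phi = np.array([
            bound_fraction(reduced_steady_state(reduced_rates, L), "reduced")
            for L in grid
        ])
        fit = fit_model_to_dose_response(
            grid, phi, (reduced_rates.kd1, np.nan, np.nan),
            variant="reduced", n_starts=2, seed=2,
        )
        assert fit.rss < 1e-5
        assert fit.rates.kd1 == pytest.approx(reduced_rates.kd1, rel=1e-9)
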