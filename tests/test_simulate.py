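"""Integration, steady states, dose-response curves and kinetic profiles."""

import numpy as np
import pytest

from tsh2bind import (
    ParameterError,
    ReducedStateVector,
    StateVector,
    apply_variant,
    bound_fraction,
    dose_response,
    integrate,
    kinetic_profile,
    reduced_closed_form,
    reduced_reference,
    reduced_steady_state,
    steady_state,
    zap70_reference,
)
from tsh2bind.estimate import fit_association

from .conftest import random_rates, random_reduced_rates


class TestIntegrate:
    def test_apo_without_ligand_stays_constant(self, ref_rates):
        rates = ref_rates.replace(kclose_prime=0.0)
        traj = integrate(rates, "full", L=0.0, initial=StateVector(500.0),
                         t_end=100.0, n_points=50)
        np.testing.assert_allclose(
            traj.states - traj.states[0], 0.0, atol=1e-10
        )

    def test_first_state_equals_initial(self, ref_rates):
        x0 = StateVector(500.0, 1.0, 2.0, 3.0, 4.0, 5.0)
        traj = integrate(ref_rates, "full", 100.0, x0, t_end=10.0, n_points=20)
        np.testing.assert_allclose(traj.states[0], x0.to_array())

    def test_total_receptor_conserved_on_random_draws(self, rng):
        for _ in range(10):
            rates = random_rates(rng)
            x0 = rng.uniform(0.0, 200.0, 6)
            traj = integrate(rates, "full", float(rng.uniform(0, 1e4)), x0,
                             t_end=1000.0, n_points=60)
            rel = np.abs(traj.total - x0.sum()) / x0.sum()
            assert rel.max() < 1e-8

    def test_nonnegativity_preserved(self, rng):
        for _ in range(10):
            traj = integrate(random_rates(rng), "full", 1e3,
                             StateVector(500.0), t_end=1e4, n_points=80)
            assert traj.states.min() > -1e-9

    def test_expm_and_bdf_routes_agree(self, ref_rates):
        # the exponential propagator against an independent stiff integrator
        x0 = StateVector(500.0)
        a = integrate(ref_rates, "full", 1e3, x0, t_end=200.0, n_points=40,
                      method="expm")
        b = integrate(ref_rates, "full", 1e3, x0, t_end=200.0, n_points=40,
                      method="bdf")
        np.testing.assert_allclose(a.states, b.states, rtol=1e-6, atol=1e-6)


class TestSteadyState:
    def test_no_ligand_all_receptor_stays_apo(self, ref_rates):
        rates = ref_rates.replace(kclose_prime=0.0)
        ss = steady_state(rates, "full", 0.0, StateVector(500.0))
        assert ss.Ropen00 == pytest.approx(500.0)
        assert sum(ss) == pytest.approx(500.0)

    def test_ode_and_direct_routes_agree(self, rng):
        for _ in range(5):
            rates = random_rates(rng)
            L = float(rng.uniform(1.0, 1e4))
            a = np.asarray(steady_state(rates, "full", L, method="ode"))
            b = np.asarray(steady_state(rates, "full", L, method="direct"))
            np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-6 * 500)

    def test_encounter_only_matches_two_state_equilibrium(self, ref_rates):
        # at fixed L the chain Ropen00 <-> Ropen01 <-> Rclosed01 equilibrates
        # with ratios L/Kd1 and kclose/kopen
        enc = apply_variant(ref_rates, "encounter_only")
        L = 1000.0
        ss = steady_state(enc, "full", L, StateVector(500.0))
        x = L * enc.kf / enc.kb
        kc = enc.kclose / enc.kopen
        denom = 1.0 + x + x * kc
        assert ss.Ropen00 / 500.0 == pytest.approx(1.0 / denom, rel=1e-6)
        assert ss.Ropen01 / 500.0 == pytest.approx(x / denom, rel=1e-6)
        assert ss.Rclosed01 / 500.0 == pytest.approx(x * kc / denom, rel=1e-6)
        # saturating ligand empties the apo state
        ss_sat = steady_state(enc, "full", 1e6, StateVector(500.0))
        assert ss_sat.Ropen00 < 1.0
        assert ss_sat.Ropen01 + ss_sat.Rclosed01 == pytest.approx(500.0, rel=1e-3)


class TestBoundFraction:
    def test_pure_states(self):
        assert bound_fraction(StateVector(500.0)) == 0.0
        assert bound_fraction(StateVector(0, 0, 0, 0, 0, 500.0)) == 1.0
        # a partially bound closed intermediate counts one half
        assert bound_fraction(StateVector(0, 0, 0, 500.0, 0, 0)) == 0.5

    def test_encounter_only_counts_singly_bound_species(self):
        state = StateVector(100.0, 200.0, 0.0, 100.0, 0.0, 0.0)
        assert bound_fraction(state, "encounter_only") == pytest.approx(0.75)

    def test_reduced_counts_open_encounter_at_half(self):
        state = ReducedStateVector(0.0, 500.0, 0.0, 0.0)
        assert bound_fraction(state, "reduced") == 0.5

    def test_zero_total_rejected(self):
        with pytest.raises(ParameterError):
            bound_fraction(StateVector(0.0))


class TestDoseResponse:
    def test_reference_curve_is_monotone_and_starts_near_zero(self, ref_rates):
        curve = dose_response(ref_rates, "full",
                              np.logspace(-1, 5, 30), method="direct")
        assert curve.phi_b[0] < 0.05
        assert np.all(np.diff(curve.phi_b) > -1e-9)
        assert np.all((curve.phi_b >= 0) & (curve.phi_b <= 1))

    def test_smaller_kd1_binds_more_at_low_ligand(self, ref_rates):
        # off-rate variation: Kd1 = 2 nM versus 10 nM
        tight, loose = ref_rates, ref_rates.replace(kb=10 * ref_rates.kf)
        grid = np.logspace(-1, 2, 10)
        pt = dose_response(tight, "full", grid, method="direct").phi_b
        pl = dose_response(loose, "full", grid, method="direct").phi_b
        assert np.all(pt >= pl - 1e-12)

    def test_grid_validation(self, ref_rates):
        with pytest.raises(ParameterError):
            dose_response(ref_rates, "full", [10.0, 5.0])


class TestKineticProfile:
    def test_starts_fully_unbound_and_decays(self, ref_rates):
        trace = kinetic_profile(ref_rates, "full", L0=10_000.0, R0=500.0,
                                window="slow")
        assert trace.value[0] == pytest.approx(1.0)
        assert np.all(np.diff(trace.value) <= 1e-9)
        assert trace.time_s.size == 1500 and trace.time_s[-1] == 200.0

    def test_fast_window_geometry(self, ref_rates):
        trace = kinetic_profile(ref_rates, "full", L0=30_000.0, R0=100.0,
                                window="fast")
        assert trace.time_s.size == 101 and trace.time_s[-1] == 1.0

    def test_subsaturating_ligand_warns(self, ref_rates):
        with pytest.warns(UserWarning, match="below 5x"):
            kinetic_profile(ref_rates, "full", L0=1000.0, R0=500.0,
                            window="fast")

    def test_encounter_only_is_single_exponential(self, ref_rates):
        enc = apply_variant(ref_rates, "encounter_only")
        trace = kinetic_profile(enc, "full", L0=10_000.0, R0=500.0,
                                t_end=2.0, n_points=200, window="custom")
        fit = fit_association(trace)
        rms = np.sqrt(fit.rss / trace.value.size)
        assert rms < 0.05 * abs(fit.ymax - fit.y0)


class TestReducedClosedForm:
    def test_without_ligand_only_apo_is_populated(self, reduced_rates):
        ss = reduced_closed_form(reduced_rates, 0.0, 500.0)
        assert ss == (500.0, 0.0, 0.0, 0.0)

    def test_matches_ode_steady_state_on_random_draws(self, rng):
        for _ in range(20):
            rates = random_reduced_rates(rng)
            L = float(rng.uniform(0.1, 1e4))
            ode = np.asarray(
                steady_state(rates, "reduced", L, method="ode")
            )
            closed = np.asarray(reduced_steady_state(rates, L, ode.sum()))
            np.testing.assert_allclose(closed, ode, rtol=2e-6, atol=1e-6 * 500)

    def test_hand_evaluated_ratios(self, reduced_rates):
        r, L = reduced_rates, 100.0
        ss = reduced_closed_form(r, L, 1.0)
        x = L * r.kf / r.kb
        denom = 2 * r.k_minus + r.w2 * r.kf * L
        assert ss.Ropen01 == pytest.approx(x)
        assert ss.Rclosed01_10 == pytest.approx(
            (2 * r.k_plus + r.w1 * r.kf * L) / denom * x
        )
        assert ss.Rclosed11 == pytest.approx(
            (r.w1 * r.k_minus + r.w2 * (r.k_plus + r.w1 * r.kf * L)) / denom * x * x
        )

    def test_zero_denominator_rejected(self):
        rates = reduced_reference().replace(k_minus=0.0, w2=0.0)
        with pytest.raises(ParameterError):
            reduced_closed_form(rates, 0.0, 500.0)
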