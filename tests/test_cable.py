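"""Unit tests for the modified Hodgkin-Huxley cable model."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chanevo.cable import (
    CableParams,
    Conductances,
    Excitability,
    analyze_trace,
    classify_excitability,
    gating_capacitance,
    rate_constants,
    simulate,
    solve_leak_potential,
    steady_state_gates,
)


class TestRateConstants:
    def test_alpha_n_removable_singularity(self):
        # limit of 0.01 x / (1 - exp(-x/10)) as x -> 0 is 0.1; Q10(6.3) = 1
        a_n, *_ = rate_constants(-55.0, 6.3)
        assert a_n == pytest.approx(0.1, rel=1e-9)

    def test_alpha_m_removable_singularity(self):
        a_m = rate_constants(-40.0, 6.3)[2]
        assert a_m == pytest.approx(1.0, rel=1e-9)

    def test_beta_m_at_rest(self):
        b_m = rate_constants(-65.0, 6.3)[3]
        assert b_m == pytest.approx(4.0, rel=1e-12)

    def test_q10_scaling_at_18_5(self):
        # every rate at 18.5 degC is its 6.3 degC value times 3**1.22
        base = np.array(rate_constants(-65.0, 6.3))
        warm = np.array(rate_constants(-65.0, 18.5))
        np.testing.assert_allclose(warm, base * 3.0 ** 1.22, rtol=1e-12)

    def test_continuity_across_singularities(self):
        for v_sing in (-55.0, -40.0):
            near = np.array(rate_constants(v_sing + 1e-6, 6.3))
            at = np.array(rate_constants(v_sing, 6.3))
            np.testing.assert_allclose(near, at, rtol=1e-5)

    @given(v=st.floats(-120, 60))
    @settings(max_examples=50, deadline=None)
    def test_rates_positive(self, v):
        assert all(r > 0 for r in rate_constants(v, 18.5))


class TestSteadyStateGates:
    @given(v=st.floats(-100, 60), tc=st.floats(0.0, 30.0))
    @settings(max_examples=50, deadline=None)
    def test_in_unit_interval_and_temperature_free(self, v, tc):
        gates = np.array(steady_state_gates(v, tc))
        assert np.all(gates >= 0) and np.all(gates <= 1)
        np.testing.assert_allclose(gates, steady_state_gates(v, 6.3), rtol=1e-9)

    def test_matches_rate_ratio(self):
        a_n, b_n, *_ = rate_constants(-65.0, 6.3)
        n_inf = steady_state_gates(-65.0)[0]
        assert n_inf == pytest.approx(a_n / (a_n + b_n), rel=1e-12)

    def test_m_opens_with_strong_depolarization(self):
        assert steady_state_gates(120.0)[1] > 0.999


class TestLeakPotential:
    def test_passive_membrane_rests_at_leak_reversal(self):
        assert solve_leak_potential(0.0, 0.0, 0.3) == pytest.approx(-65.0)

    def test_current_balance_at_rest(self):
        v_l = solve_leak_potential(120.0, 36.0, 0.3)
        n_inf, m_inf, h_inf = steady_state_gates(-65.0)
        residual = (
            36.0 * n_inf**4 * (-65.0 + 77.0)
            + 120.0 * m_inf**3 * h_inf * (-65.0 - 50.0)
            + 0.3 * (-65.0 - v_l)
        )
        assert residual == pytest.approx(0.0, abs=1e-10)

    def test_rejects_zero_leak(self):
        with pytest.raises(ValueError):
            solve_leak_potential(120.0, 36.0, 0.0)

    @pytest.mark.parametrize("g_na,g_k", [(120.0, 36.0), (300.0, 10.0), (85.0, 80.0)])
    def test_unstimulated_axon_is_stationary(self, g_na, g_k):
        params = CableParams(t_total_ms=20.0, stim_amplitude_ua=0.0)
        cond = Conductances.fitted(g_na, g_k, params)
        trace = simulate(params, cond)
        assert np.max(np.abs(trace.v_mv + 65.0)) < 0.1


class TestGatingCapacitance:
    def test_open_channels_contribute_nothing(self):
        assert gating_capacitance(1.0, 120.0) == pytest.approx(0.0)

    def test_reference_maximum(self):
        assert gating_capacitance(0.0, 120.0) == pytest.approx(0.13)

    def test_linear_scaling_in_g_na(self):
        assert gating_capacitance(0.0, 240.0) == pytest.approx(0.26)


class TestSimulate:
    def test_default_ap_propagates_full_length(self, default_params, default_conductances):
        metrics = analyze_trace(simulate(default_params, default_conductances))
        assert metrics.conducted
        assert metrics.spike_count == 1
        assert 10.0 < metrics.velocity_m_per_s < 40.0

    def test_gates_stay_in_unit_interval(self, default_params, default_conductances):
        trace = simulate(default_params, default_conductances)
        for gate in ("n", "m", "h"):
            g = trace.final_state[gate]
            assert np.all(g >= 0.0) and np.all(g <= 1.0)

    def test_velocity_independent_of_stimulus_amplitude(self, default_params, default_conductances):
        v = {}
        for amp in (20.0, 40.0):
            tr = simulate(default_params, default_conductances, stim_amplitude_ua=amp)
            v[amp] = analyze_trace(tr).velocity_m_per_s
        assert abs(v[40.0] / v[20.0] - 1.0) < 0.005

    def test_grid_convergence_of_velocity(self, default_conductances):
        coarse = CableParams(t_total_ms=12.0)
        fine = CableParams(t_total_ms=12.0, dt_ms=5e-4, dx_cm=5e-3)
        v_coarse = analyze_trace(simulate(coarse, default_conductances)).velocity_m_per_s
        v_fine = analyze_trace(simulate(fine, default_conductances)).velocity_m_per_s
        assert abs(v_fine / v_coarse - 1.0) < 0.01

    def test_rejects_off_cable_recording(self, default_params, default_conductances):
        with pytest.raises(ValueError):
            simulate(default_params, default_conductances, record_positions=[11.0])

    def test_trace_export_columns(self, default_params, default_conductances):
        trace = simulate(default_params, default_conductances, record_positions=[2.5, 7.5])
        frame = trace.to_frame()
        assert list(frame.columns) == ["time_ms", "v_2.5cm_mv", "v_7.5cm_mv"]
        assert len(frame) == default_params.n_steps + 1


class TestCableParamsValidation:
    def test_rejects_non_dividing_dx(self):
        with pytest.raises(ValueError):
            CableParams(dx_cm=3e-2)

    def test_rejects_nonpositive_steps(self):
        with pytest.raises(ValueError):
            CableParams(dt_ms=0.0)

    def test_rejects_negative_conductance_phenotype(self):
        with pytest.raises(ValueError):
            Conductances(-1.0, 36.0, -54.0)


class TestConductionCriterion:
    """Conduction requires a full-amplitude AP at 26 degC, the temperature
    at which failure thresholds are defined."""

    @pytest.fixture(scope="class")
    def hot_params(self):
        return CableParams(temperature_c=26.0, t_total_ms=30.0)

    def test_marginal_wave_below_threshold_not_conducted(self, hot_params):
        cond = Conductances.fitted(75.0, 36.0, hot_params)
        assert not analyze_trace(simulate(hot_params, cond)).conducted

    def test_observed_conductances_conduct_with_safety_margin(self, hot_params):
        cond = Conductances.fitted(120.0, 36.0, hot_params)
        assert analyze_trace(simulate(hot_params, cond)).conducted

    def test_no_sodium_means_no_spike(self, hot_params):
        cond = Conductances.fitted(0.0, 36.0, hot_params)
        metrics = analyze_trace(simulate(hot_params, cond))
        assert not metrics.conducted
        assert metrics.spike_count == 0

    def test_apd_ordering(self, default_params, default_conductances):
        metrics = analyze_trace(simulate(default_params, default_conductances))
        assert 0.0 < metrics.apd50_ms <= metrics.apd90_ms
        assert metrics.na_flux_nc_per_cm2 > 0.0


class TestExcitability:
    def test_normal_conductances_fire_once(self, default_params):
        cond = Conductances.fitted(120.0, 36.0, default_params)
        assert classify_excitability(default_params, cond) is Excitability.TYPE3

    def test_low_potassium_fires_repetitively(self, default_params):
        cond = Conductances.fitted(120.0, 20.0, default_params)
        assert classify_excitability(default_params, cond) is Excitability.TYPE2
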