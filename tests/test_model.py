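"""Gating functions, currents, right-hand sides and closed-form steady states."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from sacburst import (
    ModelParameters,
    SystemState,
    activation_functions,
    clamp_steady_state,
    ionic_currents,
    rhs_fast,
    rhs_full,
    timescale_summary,
)


class TestActivationFunctions:
    def test_half_activation_points(self, defaults):
        M, _, _ = activation_functions(defaults.V_1, defaults)
        assert M == pytest.approx(0.5)
        _, Lam, N = activation_functions(defaults.V_3, defaults)
        assert Lam == pytest.approx(1.0)
        assert N == pytest.approx(0.5)

    def test_calcium_activation_at_zero_mv(self, defaults):
        # independent arithmetic: (1 + tanh((0+20)/20)) / 2
        M, _, _ = activation_functions(0.0, defaults)
        assert M == pytest.approx((1 + math.tanh(1.0)) / 2, abs=1e-12)
        assert M == pytest.approx(0.88080, abs=5e-6)

    def test_ranges_and_monotonicity(self, defaults):
        V = np.linspace(-120.0, 80.0, 401)
        vals = np.array([activation_functions(v, defaults) for v in V])
        M, Lam, N = vals[:, 0], vals[:, 1], vals[:, 2]
        assert np.all((M > 0) & (M < 1))
        assert np.all((N > 0) & (N < 1))
        assert np.all(Lam >= 1.0)
        assert np.all(np.diff(M) > 0)
        assert np.all(np.diff(N) > 0)

    def test_nonfinite_voltage_rejected(self, defaults):
        with pytest.raises(ValueError, match="finite"):
            activation_functions(float("nan"), defaults)


class TestIonicCurrents:
    def test_zero_at_reversal_and_closed_gates(self, defaults):
        s = SystemState(V=defaults.V_C, N=0.3, C=100.0, S=0.2, R=0.4)
        assert ionic_currents(s, defaults).I_C == pytest.approx(0.0)
        s = SystemState(V=defaults.V_K, N=0.3, C=100.0, S=0.2, R=0.4)
        cur = ionic_currents(s, defaults)
        assert cur.I_K == pytest.approx(0.0)
        assert cur.I_sAHP == pytest.approx(0.0)
        s = SystemState(V=-40.0, N=0.0, C=100.0, S=0.2, R=0.0)
        cur = ionic_currents(s, defaults)
        assert cur.I_K == pytest.approx(0.0)
        assert cur.I_sAHP == pytest.approx(0.0)

    def test_calcium_current_at_rest(self, defaults):
        # M_inf(-70) = (1 - tanh(2.5))/2, then I_C = -g_C M_inf (V - V_C)
        s = SystemState(V=-70.0, N=0.0, C=0.0, S=0.0, R=0.0)
        M_expected = (1 - math.tanh(2.5)) / 2
        expected = -12.0 * M_expected * (-70.0 - 50.0)
        cur = ionic_currents(s, defaults)
        assert cur.I_C == pytest.approx(expected, rel=1e-12)
        assert cur.I_C == pytest.approx(9.64, abs=0.01)

    def test_sahp_fourth_power_gating(self, defaults):
        V = -60.0
        base = SystemState(V=V, N=0.0, C=0.0, S=0.0, R=0.5)
        cur = ionic_currents(base, defaults)
        expected = -defaults.g_sAHP * 0.5**4 * (V - defaults.V_K)
        assert cur.I_sAHP == pytest.approx(expected, rel=1e-12)


class TestRhs:
    def test_clamped_steady_state_zeroes_slow_drift(self, defaults):
        rng = np.random.default_rng(42)
        for V0 in rng.uniform(-90.0, 40.0, size=100):
            s = clamp_steady_state(V0, defaults)
            d = rhs_full(s, 0.0, defaults)
            assert np.all(np.abs(d[1:]) < 1e-12), f"drift {d} at V0={V0}"

    def test_gate_equilibrium(self, defaults):
        for V in (-80.0, -25.0, 10.0):
            _, _, N_inf = activation_functions(V, defaults)
            s = SystemState(V=V, N=N_inf, C=50.0, S=0.1, R=0.1)
            assert rhs_full(s, 0.0, defaults)[1] == pytest.approx(0.0, abs=1e-15)

    def test_calcium_drift_at_rest(self, defaults):
        s = SystemState(V=-70.0, N=0.0, C=0.0, S=0.0, R=0.0)
        I_C = ionic_currents(s, defaults).I_C
        expected = (88.0 + 10.503 * I_C) / 2000.0
        assert rhs_full(s, 0.0, defaults)[2] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0946, abs=2e-4)

    def test_voltage_drift_dimensional_consistency(self, defaults):
        # nS*mV = pA and pA/pF = mV/ms: hand-computed dV/dt at V=-60,
        # rest gates, I_ext = 10 pA
        V = -60.0
        M, _, N_inf = activation_functions(V, defaults)
        s = clamp_steady_state(V, defaults)
        by_hand = (
            -2.0 * (V + 70.0)
            - 12.0 * M * (V - 50.0)
            - 10.0 * s.N * (V + 90.0)
            - 2.0 * s.R**4 * (V + 90.0)
            + 10.0
        ) / 22.0
        assert rhs_full(s, 10.0, defaults)[0] == pytest.approx(by_hand, rel=1e-12)

    def test_fast_subsystem_matches_full_system(self, defaults):
        rng = np.random.default_rng(7)
        for _ in range(100):
            s = SystemState(
                V=rng.uniform(-90, 40), N=rng.uniform(0, 1),
                C=rng.uniform(0, 500), S=rng.uniform(0, 1), R=rng.uniform(0, 1),
            )
            I_ext = rng.uniform(-20, 20)
            I_tot = ionic_currents(s, defaults).I_sAHP + I_ext
            dV, dN = rhs_fast(s.V, s.N, I_tot, defaults)
            full = rhs_full(s, I_ext, defaults)
            assert dV == pytest.approx(full[0], abs=1e-12)
            assert dN == pytest.approx(full[1], abs=1e-12)


class TestClampSteadyState:
    def test_rest_calcium_level(self, defaults):
        s = clamp_steady_state(-70.0, defaults)
        # (C_0 + delta_C I_C(-70)) H_X / alpha_C, independent arithmetic
        I_C = 12.0 * (1 - math.tanh(2.5)) / 2 * 120.0
        assert s.C == pytest.approx((88.0 + 10.503 * I_C) * 1800.0 / 4865.0, rel=1e-12)
        assert s.C == pytest.approx(70.0, abs=0.1)

    def test_half_saturated_calmodulin_at_200_nM(self, defaults):
        # alpha_S C^4 = 1 exactly at C = 200 nM; find the clamp voltage that
        # produces C* = 200 and check S* = 1/2 there
        def C_star(V0):
            return clamp_steady_state(V0, defaults).C - 200.0

        V0 = brentq(C_star, -70.0, 0.0, xtol=1e-12)
        s = clamp_steady_state(V0, defaults)
        assert s.S == pytest.approx(0.5, abs=1e-9)

    def test_terminal_binding_at_full_saturation(self, defaults):
        # with S* -> 1, R* -> alpha_R/(1+alpha_R) = 4.25/5.25
        p = defaults.replace(alpha_S=1e12)
        s = clamp_steady_state(-20.0, p)
        assert s.S == pytest.approx(1.0, abs=1e-6)
        assert s.R == pytest.approx(4.25 / 5.25, abs=1e-5)

    def test_invalid_clamp_above_calcium_reversal(self, defaults):
        with pytest.raises(ValueError, match="clamp"):
            clamp_steady_state(120.0, defaults.replace(C_0=0.0))


class TestTimescales:
    def test_membrane_time_and_separation(self, defaults):
        ts = timescale_summary(defaults)
        assert ts["tau_L"] == pytest.approx(11.0)
        assert ts["inv_tilde_tau_C"] == pytest.approx(5.5e-3)
        assert ts["inv_tilde_tau_R"] == pytest.approx(11.0 / 8300.0)

    def test_leak_scaling(self, defaults):
        doubled = timescale_summary(defaults.replace(g_L=4.0))
        assert doubled["tau_L"] == pytest.approx(5.5)

    def test_zero_leak_rejected(self, defaults):
        with pytest.raises(ValueError, match="g_L"):
            timescale_summary(defaults.replace(g_L=0.0))


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"g_C": -1.0},
            {"tau_N": 0.0},
            {"C_m": -22.0},
            {"V_2": -20.0},
            {"V_K": -60.0},  # breaks V_K < V_L
            {"sigma": -1.0},
        ],
    )
    def test_parameter_invariants(self, kwargs):
        with pytest.raises(ValueError):
            ModelParameters(**kwargs)

    def test_unknown_parameter_key_rejected(self):
        with pytest.raises(KeyError, match="g_X"):
            ModelParameters.from_dict({"g_X": 1.0})

    @pytest.mark.parametrize(
        "state",
        [
            {"V": -60.0, "N": 1.5, "C": 10.0, "S": 0.0, "R": 0.0},
            {"V": -60.0, "N": 0.5, "C": -1.0, "S": 0.0, "R": 0.0},
            {"V": float("inf"), "N": 0.5, "C": 10.0, "S": 0.0, "R": 0.0},
        ],
    )
    def test_state_invariants(self, state):
        with pytest.raises(ValueError):
            SystemState(**state)
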