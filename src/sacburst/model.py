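"""Gating functions, ionic currents and right-hand sides of the SAC model.

The model couples a fast Morris-Lecar-type (V, N) pair with three slow
calcium-related variables:

    C_m dV/dt = I_L + I_C + I_K + I_sAHP + I_ext   (+ noise, handled by the
                                                    integrator)
    tau_N dN/dt = Lambda(V) (N_inf(V) - N)
    tau_C dC/dt = -(alpha_C/H_X) C + C_0 + delta_C I_C(V)
    tau_S dS/dt = alpha_S C^4 (1 - S) - S
    tau_R dR/dt = alpha_R S (1 - R) - R

with the signed currents

    I_L    = -g_L (V - V_L)
    I_C    = -g_C M_inf(V) (V - V_C)
    I_K    = -g_K N (V - V_K)
    I_sAHP = -g_sAHP R^4 (V - V_K)

Freezing the slow variables reduces the dynamics to the planar fast
subsystem driven by the frozen current I_tot = I_sAHP + I_ext, which is the
object of the bifurcation analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ModelParameters

__all__ = [
    "SystemState",
    "CurrentBreakdown",
    "activation_functions",
    "ionic_currents",
    "rhs_full",
    "rhs_fast",
    "clamp_steady_state",
    "timescale_summary",
]

STATE_FIELDS = ("V", "N", "C", "S", "R")


@dataclass(frozen=True)
class SystemState:
    """The five dynamical variables.

    V: membrane potential (mV); N: fast K+ gating fraction; C: intracellular
    calcium (nM); S: saturated-calmodulin fraction; R: bound-terminal
    fraction. Gating fractions live in [0, 1], calcium is nonnegative.
    """

    V: float
    N: float
    C: float
    S: float
    R: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(getattr(self, f)) for f in STATE_FIELDS):
            raise ValueError(f"non-finite state: {self}")
        for name in ("N", "S", "R"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gating fraction {name}={x} outside [0, 1]")
        if self.C < 0.0:
            raise ValueError(f"calcium must be >= 0, got {self.C}")

    def to_array(self) -> np.ndarray:
        return np.array([self.V, self.N, self.C, self.S, self.R], dtype=np.float64)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        return cls(*(float(x) for x in y))


@dataclass(frozen=True)
class CurrentBreakdown:
    """The four signed membrane currents (pA); hyperpolarizing terms < 0."""

    I_L: float
    I_C: float
    I_K: float
    I_sAHP: float

    @property
    def total(self) -> float:
        return self.I_L + self.I_C + self.I_K + self.I_sAHP


def activation_functions(V: float, params: ModelParameters) -> tuple[float, float, float]:
    """Evaluate the dimensionless gating functions at potential ``V``.

    Returns ``(M_inf, Lambda, N_inf)`` where

        M_inf(V)  = (1 + tanh((V - V_1)/V_2)) / 2      (Ca2+ activation)
        Lambda(V) = cosh((V - V_3)/(2 V_4))            (K+ gate rate factor)
        N_inf(V)  = (1 + tanh((V - V_3)/V_4)) / 2      (K+ gate steady state)
    """
    if not math.isfinite(V):
        raise ValueError(f"membrane potential must be finite, got {V}")
    M_inf = 0.5 * (1.0 + math.tanh((V - params.V_1) / params.V_2))
    Lambda = math.cosh((V - params.V_3) / (2.0 * params.V_4))
    N_inf = 0.5 * (1.0 + math.tanh((V - params.V_3) / params.V_4))
    return M_inf, Lambda, N_inf


def ionic_currents(state: SystemState, params: ModelParameters) -> CurrentBreakdown:
    """Signed ionic currents (pA) at the given state.

    The sAHP conductance is g_sAHP * R^4: four calmodulin-bound terminals
    are needed to open one channel.
    """
    M_inf, _, _ = activation_functions(state.V, params)
    return CurrentBreakdown(
        I_L=-params.g_L * (state.V - params.V_L),
        I_C=-params.g_C * M_inf * (state.V - params.V_C),
        I_K=-params.g_K * state.N * (state.V - params.V_K),
        I_sAHP=-params.g_sAHP * state.R**4 * (state.V - params.V_K),
    )


def rhs_full(state: SystemState, I_ext: float, params: ModelParameters) -> np.ndarray:
    """Deterministic drift of the full 5D system, per ms.

    Returns ``[dV, dN, dC, dS, dR]``; the stochastic current is added by the
    integrator, not here.
    """
    p = params
    M_inf, Lambda, N_inf = activation_functions(state.V, p)
    cur = ionic_currents(state, p)
    dV = (cur.total + I_ext) / p.C_m
    dN = Lambda * (N_inf - state.N) / p.tau_N
    dC = (-(p.alpha_C / p.H_X) * state.C + p.C_0 + p.delta_C * cur.I_C) / p.tau_C
    dS = (p.alpha_S * state.C**4 * (1.0 - state.S) - state.S) / p.tau_S
    dR = (p.alpha_R * state.S * (1.0 - state.R) - state.R) / p.tau_R
    return np.array([dV, dN, dC, dS, dR])


def rhs_fast(V: float, N: float, I_tot: float, params: ModelParameters) -> tuple[float, float]:
    """Drift of the planar fast subsystem with frozen current ``I_tot``."""
    p = params
    M_inf, Lambda, N_inf = activation_functions(V, p)
    dV = (
        -p.g_L * (V - p.V_L)
        - p.g_C * M_inf * (V - p.V_C)
        - p.g_K * N * (V - p.V_K)
        + I_tot
    ) / p.C_m
    dN = Lambda * (N_inf - N) / p.tau_N
    return dV, dN


def clamp_steady_state(V0: float, params: ModelParameters) -> SystemState:
    """Stationary state of the N, C, S, R sub-dynamics at clamped V = V0.

    Closed form: N* = N_inf(V0); C* = (C_0 + delta_C I_C(V0)) H_X/alpha_C;
    S* = alpha_S C*^4 / (1 + alpha_S C*^4); R* = alpha_R S*/(1 + alpha_R S*).

    Raises
    ------
    ValueError
        If the clamp point yields a negative stationary calcium level
        (possible only for V0 well above the calcium reversal potential).
    """
    p = params
    M_inf, _, N_inf = activation_functions(V0, p)
    I_C = -p.g_C * M_inf * (V0 - p.V_C)
    C_star = (p.C_0 + p.delta_C * I_C) * p.H_X / p.alpha_C
    if C_star < 0.0:
        raise ValueError(
            f"invalid clamp point V0={V0} mV: stationary calcium {C_star:.3g} nM < 0"
        )
    x = p.alpha_S * C_star**4
    S_star = x / (1.0 + x)
    R_star = p.alpha_R * S_star / (1.0 + p.alpha_R * S_star)
    return SystemState(V=V0, N=N_inf, C=C_star, S=S_star, R=R_star)


def timescale_summary(params: ModelParameters) -> dict[str, float]:
    """Characteristic membrane time and slow/fast timescale ratios.

    tau_L = C_m/g_L is the membrane (leak) time; the ratios tau_L/tau_X for
    X in {N, C, S, R} quantify the timescale separation that justifies
    freezing the slow variables in the fast-subsystem analysis.
    """
    if params.g_L <= 0:
        raise ValueError("timescale summary requires g_L > 0")
    tau_L = params.C_m / params.g_L
    return {
        "tau_L": tau_L,
        "inv_tilde_tau_N": tau_L / params.tau_N,
        "inv_tilde_tau_C": tau_L / params.tau_C,
        "inv_tilde_tau_S": tau_L / params.tau_S,
        "inv_tilde_tau_R": tau_L / params.tau_R,
    }
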