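"""Model parameters for the starburst amacrine cell (SAC) bursting model.

All quantities use a single consistent unit system: time in ms, potential in
mV, capacitance in pF, current in pA, conductance in nS, concentration in nM.
In these units nS*mV = pA and pA/pF = mV/ms, so the equations of motion need
no hidden conversion factors.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ModelParameters", "PARAM_ORDER", "params_to_array"]

#: Fixed field order used to pass parameters to compiled kernels.
PARAM_ORDER = (
    "C_m", "g_L", "g_C", "g_K", "g_sAHP",
    "V_L", "V_C", "V_K",
    "V_1", "V_2", "V_3", "V_4",
    "tau_N", "tau_R", "tau_S", "tau_C",
    "delta_C", "alpha_S", "alpha_C", "alpha_R",
    "H_X", "C_0",
)


@dataclass(frozen=True)
class ModelParameters:
    """Biophysical constants of the SAC bursting model.

    Defaults are the published calibration for an immature (stage II) SAC.
    The calcium and fast-potassium conductances ``g_C``/``g_K`` only have
    biophysical ranges ([3, 20] and [1, 20] nS); the defaults (12, 10) are
    the canonical working point used throughout the bifurcation analysis.

    Attributes
    ----------
    C_m : membrane capacitance (pF).
    g_L, g_C, g_K, g_sAHP : leak, voltage-gated Ca2+, fast voltage-gated K+
        and slow afterhyperpolarization (sAHP) conductances (nS).
    V_L, V_C, V_K : reversal potentials (mV), ordered V_K < V_L < V_C.
    V_1, V_2 : half-activation and slope of the Ca2+ activation sigmoid (mV).
    V_3, V_4 : half-activation and slope of the fast K+ gating sigmoid (mV).
    tau_N, tau_R, tau_S, tau_C : time constants of the fast K+ gate, bound
        sAHP terminals, saturated calmodulin and calcium (ms).
    delta_C : calcium influx gain, concentration per unit current (nM/pA).
    alpha_S : calmodulin association factor (nM^-4); four Ca2+ ions saturate
        one calmodulin, hence the fourth power in the S kinetics.
    alpha_C : calcium extrusion factor of the linearized Na+/Ca2+ exchanger
        (nM).
    alpha_R : terminal binding ratio (dimensionless).
    H_X : exchanger half-activation concentration (nM).
    C_0 : rest calcium production (nM).
    sigma : white-noise current amplitude (pA ms^{1/2}).
    I_ext_baseline : constant external current (pA).
    """

    C_m: float = 22.0
    g_L: float = 2.0
    g_C: float = 12.0
    g_K: float = 10.0
    g_sAHP: float = 2.0
    V_L: float = -70.0
    V_C: float = 50.0
    V_K: float = -90.0
    V_1: float = -20.0
    V_2: float = 20.0
    V_3: float = -25.0
    V_4: float = 7.0
    tau_N: float = 5.0
    tau_R: float = 8300.0
    tau_S: float = 8300.0
    tau_C: float = 2000.0
    delta_C: float = 10.503
    alpha_S: float = 1.0 / 200.0**4
    alpha_C: float = 4865.0
    alpha_R: float = 4.25
    H_X: float = 1800.0
    C_0: float = 88.0
    sigma: float = 4.0
    I_ext_baseline: float = 0.0

    def __post_init__(self) -> None:
        for name in ("g_L", "g_C", "g_K", "g_sAHP"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0, got {getattr(self, name)}")
        for name in ("tau_N", "tau_R", "tau_S", "tau_C"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be > 0, got {getattr(self, name)}")
        if self.C_m <= 0:
            raise ValueError(f"C_m must be > 0, got {self.C_m}")
        if self.V_2 <= 0 or self.V_4 <= 0:
            raise ValueError("gating slopes V_2, V_4 must be > 0")
        if not (self.V_K < self.V_L < self.V_C):
            raise ValueError(
                f"reversal potentials must satisfy V_K < V_L < V_C, got "
                f"{self.V_K}, {self.V_L}, {self.V_C}"
            )
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        for name in PARAM_ORDER + ("sigma", "I_ext_baseline"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} is not finite")

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParameters":
        """Build from a mapping; unknown keys raise, missing keys default."""
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


def params_to_array(params: ModelParameters) -> np.ndarray:
    """Pack parameters into a float64 array in :data:`PARAM_ORDER`."""
    return np.array([getattr(params, k) for k in PARAM_ORDER], dtype=np.float64)
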