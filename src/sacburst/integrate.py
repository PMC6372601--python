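"""Reproducible fixed-step integration of the SAC model.

The full 5-variable system is integrated with an Euler-Maruyama scheme:
additive white-noise current in the voltage equation only, amplitude
``sigma`` in pA ms^{1/2}, per-step voltage kick ``(sigma/C_m) sqrt(dt) z``
with z ~ N(0, 1). The scheme is fixed-step (default dt = 0.05 ms) so that a
(parameters, protocol, dt, seed, init) tuple reproduces a trajectory
bit-identically. The planar fast subsystem is integrated deterministically
with plain Euler.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .model import SystemState, clamp_steady_state
from .params import ModelParameters, params_to_array

__all__ = [
    "StimulusProtocol",
    "Trajectory",
    "FastTrajectory",
    "constant_protocol",
    "make_pulse_protocol",
    "simulate",
    "simulate_fast",
    "DEFAULT_DT",
]

logger = logging.getLogger(__name__)

DEFAULT_DT = 0.05  # ms; resolves tau_N = 5 ms and the ~30 ms fast cycle


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant external current, contiguous on [0, T].

    ``segments`` is an ordered list of ``(t_start, t_end, I_ext)`` in
    (ms, ms, pA); segments must be sorted, non-overlapping and gapless.
    """

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        segs = tuple(tuple(float(x) for x in s) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        if segs[0][0] != 0.0:
            raise ValueError("protocol must start at t = 0")
        for (a0, a1, _), (b0, _, _) in zip(segs, segs[1:]):
            if a1 != b0:
                raise ValueError(f"protocol has a gap/overlap at t={a1} vs {b0}")
        for t0, t1, _ in segs:
            if t1 <= t0:
                raise ValueError(f"empty or reversed segment ({t0}, {t1})")

    @property
    def duration(self) -> float:
        return self.segments[-1][1]

    def current_at(self, t: float) -> float:
        for t0, t1, I in self.segments:
            if t0 <= t < t1:
                return I
        return self.segments[-1][2]

    def integral(self) -> float:
        """Time integral of I_ext over the protocol (pA ms)."""
        return sum((t1 - t0) * I for t0, t1, I in self.segments)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ends = np.array([t1 for _, t1, _ in self.segments])
        currs = np.array([I for _, _, I in self.segments])
        return ends, currs


def constant_protocol(I_ext: float, T: float) -> StimulusProtocol:
    return StimulusProtocol(((0.0, float(T), float(I_ext)),))


def make_pulse_protocol(
    baseline: float, pulse: float, t_on: float, duration: float, T: float
) -> StimulusProtocol:
    """Baseline current with a rectangular pulse of extra amplitude ``pulse``.

    The pulse spans [t_on, t_on + duration]; outside it the current is
    ``baseline``. A zero-amplitude or zero-length pulse degenerates to a
    constant protocol.
    """
    if t_on < 0 or t_on + duration > T:
        raise ValueError("pulse must lie within [0, T]")
    if pulse == 0.0 or duration == 0.0:
        return constant_protocol(baseline, T)
    segs = []
    if t_on > 0:
        segs.append((0.0, t_on, baseline))
    segs.append((t_on, t_on + duration, baseline + pulse))
    if t_on + duration < T:
        segs.append((t_on + duration, T, baseline))
    return StimulusProtocol(tuple(segs))


@dataclass(frozen=True)
class Trajectory:
    """Sampled time course of the full system plus run metadata."""

    times: np.ndarray  # ms, shape (n,)
    states: np.ndarray  # shape (n, 5), columns V, N, C, S, R
    params: ModelParameters
    dt: float
    seed: int
    protocol: StimulusProtocol
    stride: int
    n_clamps: int = 0

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def N(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def C(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def S(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def R(self) -> np.ndarray:
        return self.states[:, 4]

    @property
    def sample_dt(self) -> float:
        return self.dt * self.stride

    def state_at(self, i: int) -> SystemState:
        return SystemState.from_array(self.states[i])


@dataclass(frozen=True)
class FastTrajectory:
    """Sampled time course of the planar fast subsystem."""

    times: np.ndarray
    V: np.ndarray
    N: np.ndarray
    I_tot: float
    dt: float


def simulate(
    params: ModelParameters,
    protocol: StimulusProtocol | None = None,
    T: float | None = None,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    init: SystemState | str = "auto",
    stride: int | None = None,
) -> Trajectory:
    """Integrate the full stochastic system under a current protocol.

    Parameters
    ----------
    protocol : stimulus protocol; if omitted, constant ``I_ext_baseline``
        over ``T`` (which must then be given).
    dt : step (ms), must lie in (0, 0.5].
    seed : RNG seed; identical inputs give bit-identical trajectories.
    init : initial :class:`SystemState`, or ``"auto"`` for the voltage-clamp
        steady state at -70 mV.
    stride : sampling stride in steps; defaults to a ~1 ms sample interval.

    Raises
    ------
    FloatingPointError
        If the state becomes non-finite during integration.
    """
    if not 0.0 < dt <= 0.5:
        raise ValueError(f"dt must be in (0, 0.5] ms, got {dt}")
    if protocol is None:
        if T is None:
            raise ValueError("either a protocol or T must be given")
        protocol = constant_protocol(params.I_ext_baseline, T)
    T = protocol.duration
    if T < dt:
        raise ValueError("T must be at least one step")
    if stride is None:
        stride = max(1, round(1.0 / dt))

    if init == "auto":
        init_state = clamp_steady_state(-70.0, params)
    elif isinstance(init, SystemState):
        init_state = init
    else:
        raise TypeError("init must be a SystemState or 'auto'")

    n_steps = int(round(T / dt))
    n_out = n_steps // stride + 1
    out = np.empty((n_out, 5))
    seg_ends, seg_currs = protocol.arrays()
    n_clamps, abort = _kernels.em_full(
        init_state.to_array(),
        params_to_array(params),
        seg_ends,
        seg_currs,
        dt,
        n_steps,
        stride,
        params.sigma,
        seed,
        out,
    )
    if abort >= 0:
        raise FloatingPointError(
            f"non-finite state at step {abort} (t={abort * dt:.3f} ms); "
            f"last sampled state: {out[abort // stride]}"
        )
    if n_clamps:
        logger.debug("clamped %d of %d steps to the invariant set", n_clamps, n_steps)
    times = np.arange(n_out) * (dt * stride)
    return Trajectory(
        times=times,
        states=out,
        params=params,
        dt=dt,
        seed=seed,
        protocol=protocol,
        stride=stride,
        n_clamps=n_clamps,
    )


def simulate_fast(
    I_tot: float,
    params: ModelParameters,
    T: float,
    dt: float = DEFAULT_DT,
    init: tuple[float, float] = (-70.0, 0.0),
    stride: int = 1,
) -> FastTrajectory:
    """Deterministically integrate the fast (V, N) subsystem at frozen I_tot."""
    if not 0.0 < dt <= 0.5:
        raise ValueError(f"dt must be in (0, 0.5] ms, got {dt}")
    n_steps = int(round(T / dt))
    if n_steps < 1:
        raise ValueError("T must be at least one step")
    out = np.empty((n_steps // stride + 1, 2))
    abort = _kernels.euler_fast(
        float(init[0]), float(init[1]), params_to_array(params), float(I_tot),
        dt, n_steps, stride, out,
    )
    if abort >= 0:
        raise FloatingPointError(f"non-finite state at step {abort}")
    times = np.arange(out.shape[0]) * (dt * stride)
    return FastTrajectory(times=times, V=out[:, 0], N=out[:, 1], I_tot=I_tot, dt=dt)
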