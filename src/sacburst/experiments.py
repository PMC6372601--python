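"""Scripted in-silico experiments on the SAC model.

Two families of experiments, mirroring classical bench protocols on
developing retina:

* a depolarizing current-pulse test (150 pA for 60 ms), with and without a
  cadmium-like blockade of all calcium-related conductances (g_C and g_sAHP
  zeroed), which shows that the fast sub-threshold oscillations and the
  after-pulse hyperpolarization require the calcium pathway;
* developmental / pharmacological presets (postnatal ages P4 to P22, with
  and without the potassium-channel blocker TEA) in which only g_K, the
  fast-potassium half-activation V_3, and the baseline external current
  change, reproducing the loss of spontaneous bursting with maturation and
  its pharmacological restoration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .bifurcation import limit_cycle_probe
from .bursts import BurstConfig, detect_bursts, interburst_intervals
from .integrate import Trajectory, constant_protocol, make_pulse_protocol, simulate
from .params import ModelParameters

__all__ = [
    "ScenarioPreset",
    "ExperimentReport",
    "SCENARIOS",
    "run_pulse_experiment",
    "run_developmental_scenario",
    "measure_fast_frequency",
    "burst_firing_frequency",
]


@dataclass(frozen=True)
class ScenarioPreset:
    """Named parameter override set for a developmental stage."""

    name: str
    overrides: dict[str, float]
    expected_bursting: bool
    description: str = ""


#: Developmental presets: only g_K, V_3 and the external current vary;
#: everything else stays at the immature-SAC defaults (g_C = 12 nS).
SCENARIOS: dict[str, ScenarioPreset] = {
    "P4": ScenarioPreset(
        "P4", {"g_K": 8.0, "V_3": -16.0, "I_ext_baseline": 0.0}, True,
        "isolated P4 cell, spontaneous bursting",
    ),
    "P8": ScenarioPreset(
        "P8", {"g_K": 10.0, "V_3": -34.0, "I_ext_baseline": 0.0}, False,
        "isolated P8 cell, silent",
    ),
    "P8_TEA": ScenarioPreset(
        "P8_TEA", {"g_K": 8.0, "V_3": -34.0, "I_ext_baseline": 0.0}, True,
        "P8 cell with TEA lowering g_K, bursting restored",
    ),
    "P22_TEA": ScenarioPreset(
        "P22_TEA", {"g_K": 4.5, "V_3": -35.0, "I_ext_baseline": -10.0}, False,
        "P22 cell with TEA but intact synaptic inhibition, silent",
    ),
    "P22_restored": ScenarioPreset(
        "P22_restored", {"g_K": 4.5, "V_3": -35.0, "I_ext_baseline": 0.0}, True,
        "P22 cell with TEA and inhibition removed, bursting restored",
    ),
}


@dataclass(frozen=True)
class ExperimentReport:
    """Outcome of a scripted experiment, recomputable from the trajectory."""

    name: str
    trajectory: Trajectory
    bursting: bool
    oscillations_during_pulse: bool | None
    ahp_after_pulse: bool | None
    max_V: float
    fast_frequency_hz: float | None
    n_bursts: int = 0
    mean_ibi_ms: float = math.nan


def _count_oscillation_peaks(t: np.ndarray, V: np.ndarray, ptp: float = 5.0) -> int:
    if V.size < 3 or V.max() - V.min() < ptp:
        return 0
    peaks, _ = find_peaks(V, prominence=ptp / 2)
    return int(len(peaks))


def run_pulse_experiment(
    variant: str = "control",
    params: ModelParameters | None = None,
    seed: int = 0,
    baseline: float = -4.0,
    pulse: float = 150.0,
    t_on: float = 500.0,
    duration: float = 60.0,
    T: float = 3000.0,
    sigma: float = 1.0,
    dt: float = 0.05,
) -> ExperimentReport:
    """Current-pulse test: oscillations during the pulse, AHP afterwards.

    ``variant="control"`` keeps the calcium pathway intact;
    ``variant="cadmium"`` zeroes both g_C and g_sAHP, emulating a Cd2+
    blockade of all calcium-related channels. The baseline current of -4 pA
    holds the cell in its noise-driven rest regime; noise is kept small so
    the pulse, not a fluctuation, triggers the response.

    Oscillations are scored as >= 3 voltage peaks with > 5 mV peak-to-peak
    during the pulse window; the AHP flag records whether the voltage dips
    below the pre-pulse baseline after the pulse.
    """
    if variant not in ("control", "cadmium"):
        raise ValueError(f"unknown variant {variant!r}")
    params = params or ModelParameters()
    overrides: dict[str, float] = {"sigma": sigma, "I_ext_baseline": baseline}
    if variant == "cadmium":
        overrides.update(g_C=0.0, g_sAHP=0.0)
    p = params.replace(**overrides)
    protocol = make_pulse_protocol(baseline, pulse, t_on, duration, T)
    traj = simulate(p, protocol=protocol, dt=dt, seed=seed, stride=1)

    in_pulse = (traj.times >= t_on) & (traj.times <= t_on + duration)
    pre = traj.times < t_on
    post = traj.times > t_on + duration
    n_peaks = _count_oscillation_peaks(traj.times[in_pulse], traj.V[in_pulse])
    V_pre = float(traj.V[pre].mean())
    # AHP: sustained post-pulse dip below the pre-pulse baseline (beyond
    # the noise floor)
    post_min = float(traj.V[post].min()) if post.any() else math.nan
    ahp = post.any() and post_min < V_pre - 2.0
    return ExperimentReport(
        name=f"pulse_{variant}",
        trajectory=traj,
        bursting=False,
        oscillations_during_pulse=n_peaks >= 3,
        ahp_after_pulse=bool(ahp),
        max_V=float(traj.V.max()),
        fast_frequency_hz=None,
    )


def run_developmental_scenario(
    name: str,
    seed: int = 0,
    params: ModelParameters | None = None,
    T: float = 600_000.0,
    sigma: float = 4.0,
    dt: float = 0.1,
    config: BurstConfig | None = None,
) -> ExperimentReport:
    """Run a developmental preset for 600 s and score bursting."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    preset = SCENARIOS[name]
    params = params or ModelParameters()
    p = params.replace(sigma=sigma, **preset.overrides)
    traj = simulate(p, T=T, dt=dt, seed=seed)
    events = detect_bursts(traj, config)
    ibis = interburst_intervals(events)
    return ExperimentReport(
        name=name,
        trajectory=traj,
        bursting=len(events) > 0,
        oscillations_during_pulse=None,
        ahp_after_pulse=None,
        max_V=float(traj.V.max()),
        fast_frequency_hz=None,
        n_bursts=len(events),
        mean_ibi_ms=float(ibis.mean()) if ibis.size else math.nan,
    )


def measure_fast_frequency(I_tot: float, params: ModelParameters | None = None) -> float:
    """Limit-cycle firing frequency (Hz) of the fast subsystem at ``I_tot``.

    Raises
    ------
    ValueError
        If no limit cycle exists at the queried current.
    """
    params = params or ModelParameters()
    probe = limit_cycle_probe(I_tot, params)
    if not probe.exists:
        raise ValueError(f"no limit cycle at I_tot={I_tot} pA")
    return 1000.0 / probe.period


def burst_firing_frequency(
    params: ModelParameters | None = None,
    T: float = 200_000.0,
    dt: float = 0.05,
    seed: int = 0,
    config: BurstConfig | None = None,
) -> float:
    """Mean fast-firing frequency (Hz) within bursts of the full model.

    Runs the deterministic (sigma = 0) model at the baseline external
    current, detects bursts from calcium, and averages the inter-peak
    frequency of the voltage oscillations inside each burst. This is the
    observable a microelectrode sees during a burst: the cell fires on the
    fast limit cycle while the slowly growing sAHP current sweeps I_tot
    across the oscillatory range, so the measured rate is the dwell-time
    average over that sweep.
    """
    params = params or ModelParameters()
    p = params.replace(sigma=0.0)
    traj = simulate(p, T=T, dt=dt, seed=seed, stride=max(1, round(1.0 / dt)))
    events = detect_bursts(traj, config)
    if not events:
        raise ValueError("no bursts in the deterministic run; cannot measure firing")
    periods = []
    for ev in events:
        mask = (traj.times >= ev.t_onset) & (traj.times <= ev.t_offset)
        V = traj.V[mask]
        t = traj.times[mask]
        peaks, _ = find_peaks(V, prominence=5.0)
        if len(peaks) >= 3:
            periods.append(np.diff(t[peaks]).mean())
    if not periods:
        raise ValueError("bursts contain no resolvable voltage oscillations")
    return float(1000.0 / np.mean(periods))
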