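"""Burst detection and interburst-interval (IBI) statistics.

A burst is a calcium excursion above 150 nM lasting more than 1 s. The mean
interburst interval tau_IBI (onset-to-onset) diverges near the saddle-node
as the inverse square root of the distance to a critical current,

    tau_IBI(I_ext) = K / sqrt(I_ext - I_c),   I_ext > I_c,

and is set to 0 below I_c by convention (no bursting). Both the plain
square-root form and the variant with an explicit 1/2 prefactor
(K / (2 sqrt(I_ext - I_c))) are available, since both appear in the
literature for this law; the two fitted K values differ exactly by a factor
of two.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import skew

from . import _kernels
from .integrate import DEFAULT_DT, Trajectory, constant_protocol, simulate
from .params import ModelParameters

__all__ = [
    "BurstConfig",
    "BurstEvent",
    "IBIStatistics",
    "SqrtLawFit",
    "DistributionFit",
    "detect_bursts",
    "interburst_intervals",
    "ibi_ensemble",
    "ibi_heatmap",
    "ibi_vs_iext",
    "fit_sqrt_law",
    "fit_ibi_distribution",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BurstConfig:
    """Burst definition: calcium threshold (nM) and minimum duration (ms)."""

    calcium_threshold: float = 150.0
    min_duration: float = 1000.0

    def __post_init__(self) -> None:
        if self.calcium_threshold <= 0 or self.min_duration <= 0:
            raise ValueError("threshold and min_duration must be > 0")


@dataclass(frozen=True)
class BurstEvent:
    """A maximal above-threshold calcium excursion."""

    t_onset: float  # ms
    t_offset: float  # ms

    @property
    def duration(self) -> float:
        return self.t_offset - self.t_onset


@dataclass(frozen=True)
class IBIStatistics:
    """Pooled onset-to-onset intervals from a trajectory ensemble."""

    ibis: np.ndarray  # ms
    n_bursts: int
    n_trajectories: int
    n_silent_trajectories: int
    total_time: float  # ms
    duty_fraction: float = math.nan  # fraction of time calcium sits above threshold

    @property
    def mean(self) -> float:
        return float(self.ibis.mean()) if self.ibis.size else math.nan


@dataclass(frozen=True)
class SqrtLawFit:
    """Fitted interburst-interval law tau_IBI = K / sqrt(I - I_c)."""

    K: float  # s pA^{1/2}
    I_c: float  # pA
    residual_norm: float
    form: Literal["plain", "halved"]
    K_stderr: float
    I_c_stderr: float
    n_points: int

    @property
    def K_ci95(self) -> tuple[float, float]:
        return (self.K - 1.96 * self.K_stderr, self.K + 1.96 * self.K_stderr)

    def predict(self, I_ext: np.ndarray) -> np.ndarray:
        I_ext = np.asarray(I_ext, dtype=float)
        denom = 2.0 if self.form == "halved" else 1.0
        out = np.zeros_like(I_ext)
        mask = I_ext > self.I_c
        out[mask] = self.K / (denom * np.sqrt(I_ext[mask] - self.I_c))
        return out


@dataclass(frozen=True)
class DistributionFit:
    """Least-squares histogram fit of the IBI distribution."""

    model: Literal["gaussian", "gaussian_plus_exponential"]
    params: dict[str, float]
    residual: float
    competing_residual: float
    n_bins: int

    @property
    def selected(self) -> bool:
        """Whether this model beats the competing one.

        Comparison uses the degree-of-freedom-adjusted mean squared
        residual (3 parameters for the Gaussian, 5 for the composite), so
        the larger model is selected only when the exponential component
        genuinely improves the fit.
        """
        k_self = 5 if self.model == "gaussian_plus_exponential" else 3
        k_other = 8 - k_self
        own = self.residual**2 / max(self.n_bins - k_self, 1)
        other = self.competing_residual**2 / max(self.n_bins - k_other, 1)
        return own <= other


def detect_bursts(trace: Trajectory, config: BurstConfig | None = None) -> list[BurstEvent]:
    """Maximal above-threshold calcium runs of at least the minimum duration.

    Runs touching either trace boundary are discarded (their true extent is
    unknown); sub-threshold dips are never merged across.
    """
    config = config or BurstConfig()
    if trace.states.shape[0] < 2:
        raise ValueError("trace too short for burst detection")
    sample_dt = trace.sample_dt
    min_samples = max(1, int(math.ceil(config.min_duration / sample_dt)))
    starts, stops = _kernels.burst_bounds(
        np.ascontiguousarray(trace.C), config.calcium_threshold, min_samples
    )
    return [
        BurstEvent(t_onset=trace.times[a], t_offset=trace.times[b])
        for a, b in zip(starts, stops)
    ]


def interburst_intervals(events: Sequence[BurstEvent]) -> np.ndarray:
    """Onset-to-onset differences (ms) of time-sorted burst events."""
    onsets = np.sort(np.array([e.t_onset for e in events], dtype=float))
    return np.diff(onsets)


def ibi_ensemble(
    params: ModelParameters,
    n_traj: int = 5,
    T: float = 500_000.0,
    base_seed: int = 0,
    config: BurstConfig | None = None,
    dt: float = 0.1,
) -> IBIStatistics:
    """Pool IBIs over ``n_traj`` independent runs with consecutive seeds."""
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    cfg = config or BurstConfig()
    all_ibis = []
    n_bursts = 0
    n_silent = 0
    duty = 0.0
    for k in range(n_traj):
        traj = simulate(params, T=T, dt=dt, seed=base_seed + k)
        events = detect_bursts(traj, cfg)
        n_bursts += len(events)
        if not events:
            n_silent += 1
        duty += float((traj.C > cfg.calcium_threshold).mean())
        all_ibis.append(interburst_intervals(events))
    ibis = np.concatenate(all_ibis) if all_ibis else np.empty(0)
    return IBIStatistics(
        ibis=ibis,
        n_bursts=n_bursts,
        n_trajectories=n_traj,
        n_silent_trajectories=n_silent,
        total_time=n_traj * T,
        duty_fraction=duty / n_traj,
    )


def ibi_heatmap(
    gC_values: np.ndarray,
    gK_values: np.ndarray,
    params: ModelParameters,
    n_traj: int = 5,
    T: float = 500_000.0,
    base_seed: int = 0,
    config: BurstConfig | None = None,
    dt: float = 0.1,
) -> np.ndarray:
    """Grid of mean tau_IBI (ms) over (g_C, g_K); NaN where no bursts.

    Cells without any detected burst are missing (NaN), not zero: they are
    the black cells of the published heat maps, where the sample contains no
    burst at all.
    """
    out = np.full((len(gK_values), len(gC_values)), np.nan)
    for i, gK in enumerate(gK_values):
        for j, gC in enumerate(gC_values):
            stats = ibi_ensemble(
                params.replace(g_C=float(gC), g_K=float(gK)),
                n_traj=n_traj, T=T, base_seed=base_seed, config=config, dt=dt,
            )
            if stats.ibis.size:
                out[i, j] = stats.mean
    return out


def ibi_vs_iext(
    I_values: Sequence[float],
    params: ModelParameters,
    n_traj: int = 5,
    T: float = 500_000.0,
    base_seed: int = 0,
    config: BurstConfig | None = None,
    dt: float = 0.1,
    tonic_duty: float = 0.9,
) -> np.ndarray:
    """Mean tau_IBI (ms) per external current; 0 where bursting is absent.

    Returns an array of rows ``(I_ext, mean_tau_IBI_ms, n_ibis)``. tau_IBI
    is set to 0 both below the critical current (no bursts at all) and in
    the tonic regime at strong depolarization, where calcium sits above the
    burst threshold more than ``tonic_duty`` of the time: there the cell
    fires without a refractory period, bursts merge, and an interburst
    interval is no longer defined. Zero rows are excluded from the
    square-root-law fit.
    """
    rows = []
    for I in I_values:
        stats = ibi_ensemble(
            params.replace(I_ext_baseline=float(I)),
            n_traj=n_traj, T=T, base_seed=base_seed, config=config, dt=dt,
        )
        if not stats.ibis.size or stats.duty_fraction > tonic_duty:
            rows.append((float(I), 0.0, 0))
        else:
            rows.append((float(I), stats.mean, stats.ibis.size))
    return np.array(rows)


def fit_sqrt_law(
    curve: np.ndarray,
    form: Literal["plain", "halved"] = "plain",
    window: tuple[float, float] = (-20.0, 40.0),
) -> SqrtLawFit:
    """Nonlinear least-squares fit of tau_IBI = K / (c sqrt(I - I_c)).

    ``curve`` holds rows ``(I_ext_pA, tau_IBI_ms, ...)``; only points with
    tau_IBI > 0 inside ``window`` are used (at least 4 required). ``form``
    selects c = 1 ("plain") or c = 2 ("halved"); K is reported in
    s pA^{1/2} with its standard error.
    """
    curve = np.asarray(curve, dtype=float)
    I = curve[:, 0]
    tau_s = curve[:, 1] / 1000.0  # ms -> s
    mask = (tau_s > 0) & (I >= window[0]) & (I <= window[1])
    if mask.sum() < 4:
        raise ValueError(
            f"need >= 4 positive-tau points in window {window}, got {mask.sum()}"
        )
    I_fit, tau_fit = I[mask], tau_s[mask]
    denom = 2.0 if form == "halved" else 1.0

    def f(i, K, I_c):
        d = np.clip(i - I_c, 1e-9, None)
        return K / (denom * np.sqrt(d))

    I_min = I_fit.min()
    K0 = float(tau_fit.max() * denom * math.sqrt(max(I_fit.max() - I_min + 1.0, 1.0)))
    try:
        popt, pcov = curve_fit(
            f, I_fit, tau_fit, p0=(K0, I_min - 1.0),
            bounds=([0.0, -np.inf], [np.inf, I_min - 1e-6]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise ValueError(f"square-root-law fit failed: {err}") from err
    K, I_c = float(popt[0]), float(popt[1])
    resid = tau_fit - f(I_fit, K, I_c)
    perr = np.sqrt(np.diag(pcov))
    return SqrtLawFit(
        K=K,
        I_c=I_c,
        residual_norm=float(np.linalg.norm(resid)),
        form=form,
        K_stderr=float(perr[0]),
        I_c_stderr=float(perr[1]),
        n_points=int(mask.sum()),
    )


def _gauss(x, a, mu, s):
    return a * np.exp(-0.5 * ((x - mu) / s) ** 2)


def _gauss_exp(x, a, mu, s, b, lam):
    return _gauss(x, a, mu, s) + b * np.exp(-lam * x)


def fit_ibi_distribution(
    ibis: np.ndarray,
    model: Literal["gaussian", "gaussian_plus_exponential"] = "gaussian",
    bin_width: float = 1000.0,
) -> DistributionFit:
    """Histogram-density fit of the IBI distribution; compares both models.

    Histograms use 1 s bins. The returned fit is for ``model``; the residual
    of the competing model is reported so callers can select the better one
    (narrow noise gives a Gaussian; strong noise develops an exponential
    tail).
    """
    ibis = np.asarray(ibis, dtype=float)
    if ibis.size < 20:
        raise ValueError(f"need >= 20 IBIs, got {ibis.size}")
    lo = 0.0
    hi = ibis.max() + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    dens, edges = np.histogram(ibis, bins=edges, density=True)
    x = 0.5 * (edges[:-1] + edges[1:])

    mu0, s0 = float(ibis.mean()), float(ibis.std() or bin_width)
    a0 = float(dens.max() or 1.0)

    def try_fit(fn, p0, bounds):
        try:
            popt, _ = curve_fit(fn, x, dens, p0=p0, bounds=bounds, maxfev=50000)
            r = float(np.linalg.norm(dens - fn(x, *popt)))
            return popt, r
        except RuntimeError:
            return None, math.inf

    pg, rg = try_fit(_gauss, (a0, mu0, s0), ([0, 0, 1e-9], [np.inf] * 3))
    pge, rge = try_fit(
        _gauss_exp,
        (a0 / 2, mu0, s0, a0 / 2, 1.0 / max(mu0, bin_width)),
        ([0, 0, 1e-9, 0, 1e-12], [np.inf] * 5),
    )
    if model == "gaussian":
        if pg is None:
            raise ValueError("gaussian fit failed")
        return DistributionFit(
            model=model,
            params={"amplitude": pg[0], "mean": pg[1], "std": pg[2]},
            residual=rg,
            competing_residual=rge,
            n_bins=len(x),
        )
    if pge is None:
        raise ValueError("gaussian-plus-exponential fit failed")
    return DistributionFit(
        model=model,
        params={
            "amplitude": pge[0], "mean": pge[1], "std": pge[2],
            "exp_amplitude": pge[3], "exp_rate": pge[4],
        },
        residual=rge,
        competing_residual=rg,
        n_bins=len(x),
    )
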