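"""Equilibria and bifurcations of the fast (V, N) subsystem.

With the slow variables frozen, equilibria satisfy N* = N_inf(V*) and the
scalar current balance

    Phi(V) = -g_L (V - V_L) - g_C M_inf(V) (V - V_C)
             - g_K N_inf(V) (V - V_K) + I_tot = 0.

All physical equilibria lie between the reversal potentials, so a dense
sign-scan of Phi on [-90, 60] mV followed by bisection finds every root.
Stability comes from the analytic 2x2 Jacobian. Three bifurcations organize
the dynamics as I_tot varies: a homoclinic connection (birth of the stable
fast-oscillation cycle), a saddle-node (loss of the rest state, onset of
repetitive firing) and a Hopf at high current (loss of the cycle into a
depolarized state). The homoclinic point is located by bisecting on cycle
existence probed by direct simulation; standard continuation tooling is not
needed for this planar problem.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .integrate import simulate_fast
from .model import activation_functions, rhs_fast
from .params import ModelParameters

__all__ = [
    "FixedPoint",
    "BifurcationDiagram1D",
    "RegionMap2D",
    "phi",
    "find_fixed_points",
    "classify_fixed_point",
    "fast_jacobian",
    "continue_in_current",
    "locate_saddle_node",
    "locate_hopf",
    "limit_cycle_probe",
    "locate_homoclinic",
    "region_map_2d",
]

logger = logging.getLogger(__name__)

V_SCAN = (-90.0, 60.0)
N_SCAN_NODES = 1501

StabilityClass = Literal["sink", "saddle", "stable_focus", "unstable_focus"]


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium of the fast subsystem with its linearization."""

    V_star: float
    N_star: float
    eigenvalues: tuple[complex, complex]
    stability_class: StabilityClass

    @property
    def stable(self) -> bool:
        return self.stability_class in ("sink", "stable_focus")


@dataclass(frozen=True)
class CycleProbe:
    exists: bool
    V_min: float
    V_max: float
    period: float  # ms; nan when no cycle


@dataclass(frozen=True)
class BifurcationEvent:
    kind: Literal["saddle_node", "hopf", "homoclinic"]
    parameter_value: float


@dataclass(frozen=True)
class BifurcationDiagram1D:
    """One-parameter sweep: equilibria, cycle extremes, detected events."""

    parameter: str
    grid: np.ndarray
    fixed_points: list[list[FixedPoint]]
    cycles: list[CycleProbe]
    events: list[BifurcationEvent]


@dataclass(frozen=True)
class RegionMap2D:
    """Per-cell phase-portrait signatures over a 2-parameter grid.

    ``signatures[i, j]`` corresponds to x_grid[j], y_grid[i] and holds
    (n_stable, n_unstable, has_cycle); ``labels`` holds the figure-legend
    letter for known signatures, "other" otherwise.
    """

    axis_x: str
    axis_y: str
    x_grid: np.ndarray
    y_grid: np.ndarray
    n_stable: np.ndarray
    n_unstable: np.ndarray
    has_cycle: np.ndarray
    labels: np.ndarray


def phi(V: float, I_tot: float, params: ModelParameters) -> float:
    """Scalar current balance of the fast subsystem at N = N_inf(V)."""
    p = params
    M_inf, _, N_inf = activation_functions(V, p)
    return (
        -p.g_L * (V - p.V_L)
        - p.g_C * M_inf * (V - p.V_C)
        - p.g_K * N_inf * (V - p.V_K)
        + I_tot
    )


def _phi_prime(V: float, params: ModelParameters) -> float:
    p = params
    th1 = math.tanh((V - p.V_1) / p.V_2)
    th3 = math.tanh((V - p.V_3) / p.V_4)
    M_inf = 0.5 * (1.0 + th1)
    N_inf = 0.5 * (1.0 + th3)
    dM = (1.0 - th1 * th1) / (2.0 * p.V_2)
    dN = (1.0 - th3 * th3) / (2.0 * p.V_4)
    return (
        -p.g_L
        - p.g_C * (dM * (V - p.V_C) + M_inf)
        - p.g_K * (dN * (V - p.V_K) + N_inf)
    )


def fast_jacobian(V: float, N: float, params: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of the fast subsystem at (V, N)."""
    p = params
    th1 = math.tanh((V - p.V_1) / p.V_2)
    th3 = math.tanh((V - p.V_3) / p.V_4)
    M_inf = 0.5 * (1.0 + th1)
    N_inf = 0.5 * (1.0 + th3)
    dM = (1.0 - th1 * th1) / (2.0 * p.V_2)
    dN_inf = (1.0 - th3 * th3) / (2.0 * p.V_4)
    Lam = math.cosh((V - p.V_3) / (2.0 * p.V_4))
    dLam = math.sinh((V - p.V_3) / (2.0 * p.V_4)) / (2.0 * p.V_4)
    a11 = (-p.g_L - p.g_C * (dM * (V - p.V_C) + M_inf) - p.g_K * N) / p.C_m
    a12 = -p.g_K * (V - p.V_K) / p.C_m
    a21 = (dLam * (N_inf - N) + Lam * dN_inf) / p.tau_N
    a22 = -Lam / p.tau_N
    return np.array([[a11, a12], [a21, a22]])


def classify_fixed_point(
    V_star: float, N_star: float, I_tot: float, params: ModelParameters
) -> FixedPoint:
    """Classify an equilibrium by the eigenvalues of the analytic Jacobian."""
    J = fast_jacobian(V_star, N_star, params)
    ev = np.linalg.eigvals(J)
    if abs(ev[0].imag) > 1e-12:
        cls = "stable_focus" if ev.real.max() < 0 else "unstable_focus"
    else:
        re = np.sort(ev.real)
        if re[1] < 0:
            cls = "sink"
        elif re[0] < 0 < re[1]:
            cls = "saddle"
        else:
            # both real parts positive: an unstable node; rendered as an
            # unstable focus class for map purposes (does not occur for the
            # published parameter ranges)
            cls = "unstable_focus"
    return FixedPoint(
        V_star=V_star,
        N_star=N_star,
        eigenvalues=(complex(ev[0]), complex(ev[1])),
        stability_class=cls,
    )


def _root_scan(I_tot: float, params: ModelParameters, nodes: int = N_SCAN_NODES) -> list[float]:
    Vg = np.linspace(V_SCAN[0], V_SCAN[1], nodes)
    f = np.array([phi(v, I_tot, params) for v in Vg])
    roots: list[float] = []
    for i in range(nodes - 1):
        if f[i] == 0.0:
            roots.append(float(Vg[i]))
        elif f[i] * f[i + 1] < 0.0:
            roots.append(
                brentq(phi, Vg[i], Vg[i + 1], args=(I_tot, params), xtol=1e-10)
            )
    if f[-1] == 0.0:
        roots.append(float(Vg[-1]))
    return roots


def find_fixed_points(
    I_tot: float, params: ModelParameters, nodes: int = N_SCAN_NODES
) -> list[FixedPoint]:
    """All equilibria of the fast subsystem at the given frozen current.

    Dense sign-scan of Phi on [-90, 60] mV (``nodes`` grid points) plus
    bisection to |dV| < 1e-8 mV; each root is classified. Phi has opposite
    signs at the window ends for the published parameter ranges, so at least
    one equilibrium always exists.
    """
    roots = _root_scan(I_tot, params, nodes)
    if not roots:
        logger.warning(
            "no equilibrium found for I_tot=%g: Phi(%g)=%g, Phi(%g)=%g",
            I_tot, V_SCAN[0], phi(V_SCAN[0], I_tot, params),
            V_SCAN[1], phi(V_SCAN[1], I_tot, params),
        )
    out = []
    for V in roots:
        _, _, N_inf = activation_functions(V, params)
        out.append(classify_fixed_point(V, N_inf, I_tot, params))
    return out


def locate_saddle_node(
    params: ModelParameters,
    bracket: tuple[float, float] = (-10.0, 0.0),
    tol: float = 0.01,
) -> float:
    """Fold current at which the rest state and the middle branch collide.

    Bisects on the equilibrium count over ``bracket``, then refines by
    solving the fold conditions Phi = Phi' = 0: Phi' is current-independent,
    so the fold voltage is a root of Phi' and the fold current follows in
    closed form.
    """
    lo, hi = bracket
    n_lo, n_hi = len(_root_scan(lo, params)), len(_root_scan(hi, params))
    if n_lo == n_hi:
        raise ValueError(
            f"equilibrium count does not change over bracket {bracket} "
            f"({n_lo} at both ends)"
        )
    while hi - lo > tol / 4:
        mid = 0.5 * (lo + hi)
        if len(_root_scan(mid, params)) == n_lo:
            lo = mid
        else:
            hi = mid
    # two nearly coincident roots exist on the many-root side; their
    # midpoint brackets the Phi' zero
    many = lo if n_lo > n_hi else hi
    roots = sorted(_root_scan(many, params))
    gaps = [b - a for a, b in zip(roots, roots[1:])]
    i = int(np.argmin(gaps))
    a, b = roots[i] - 2.0, roots[i + 1] + 2.0
    V_fold = brentq(_phi_prime, a, b, args=(params,), xtol=1e-12)
    return -phi(V_fold, 0.0, params)


def locate_hopf(
    params: ModelParameters,
    bracket: tuple[float, float] = (200.0, 310.0),
    tol: float = 0.1,
) -> float:
    """Current at which the focus branch changes stability (trace zero).

    Bisects the sign of the Jacobian trace along the (unique, for the
    default bracket) equilibrium branch, requiring a positive determinant.
    """

    def trace_at(I: float) -> tuple[float, float]:
        fps = find_fixed_points(I, params)
        if not fps:
            raise RuntimeError(f"no equilibrium at I_tot={I}")
        fp = max(fps, key=lambda f: f.V_star)
        J = fast_jacobian(fp.V_star, fp.N_star, params)
        return float(np.trace(J)), float(np.linalg.det(J))

    lo, hi = bracket
    t_lo, _ = trace_at(lo)
    t_hi, _ = trace_at(hi)
    if t_lo * t_hi > 0:
        raise ValueError(f"Jacobian trace does not change sign over {bracket}")
    I_h = brentq(lambda I: trace_at(I)[0], lo, hi, xtol=tol / 10)
    _, det = trace_at(I_h)
    if det <= 0:
        raise RuntimeError(
            f"trace zero at I_tot={I_h:.3f} pA has determinant {det:.3g} <= 0 "
            "(degenerate, not a Hopf point)"
        )
    return I_h


def limit_cycle_probe(
    I_tot: float,
    params: ModelParameters,
    T: float = 5000.0,
    transient: float = 2000.0,
    dt: float = 0.02,
    ptp_threshold: float = 5.0,
) -> CycleProbe:
    """Detect a stable limit cycle by direct simulation.

    Runs the fast subsystem from every unstable equilibrium, perturbed by
    +/-1 mV, over a 5 s horizon with a 2 s transient discarded; a cycle
    exists iff the post-transient voltage peak-to-peak amplitude exceeds
    5 mV. The period is the mean inter-peak interval.
    """
    fps = find_fixed_points(I_tot, params)
    unstable = [f for f in fps if not f.stable]
    # probe foci first: a stable cycle surrounds the unstable focus
    unstable.sort(key=lambda f: f.stability_class != "unstable_focus")
    for fp in unstable:
        for dV in (1.0, -1.0):
            traj = simulate_fast(
                I_tot, params, T=T, dt=dt, init=(fp.V_star + dV, fp.N_star)
            )
            mask = traj.times >= transient
            V = traj.V[mask]
            if V.max() - V.min() > ptp_threshold:
                peaks, _ = find_peaks(V, prominence=ptp_threshold / 2)
                if len(peaks) >= 3:
                    t = traj.times[mask]
                    period = float(np.diff(t[peaks]).mean())
                    return CycleProbe(
                        exists=True,
                        V_min=float(V.min()),
                        V_max=float(V.max()),
                        period=period,
                    )
    return CycleProbe(exists=False, V_min=math.nan, V_max=math.nan, period=math.nan)


def locate_homoclinic(
    params: ModelParameters,
    bracket: tuple[float, float] = (-7.0, -5.0),
    tol: float = 0.05,
) -> float:
    """Current at which the limit cycle is born/destroyed on the saddle.

    Bisects on cycle existence (from :func:`limit_cycle_probe`). The
    diverging period as the boundary is approached distinguishes a
    homoclinic loss from a Hopf; the period trend near the returned point is
    logged as supporting evidence.
    """
    lo, hi = bracket
    e_lo = limit_cycle_probe(lo, params).exists
    e_hi = limit_cycle_probe(hi, params).exists
    if e_lo == e_hi:
        raise ValueError(f"cycle existence does not change over bracket {bracket}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if limit_cycle_probe(mid, params).exists == e_lo:
            lo = mid
        else:
            hi = mid
    I_hc = 0.5 * (lo + hi)
    near = limit_cycle_probe(I_hc + 0.1, params)
    far = limit_cycle_probe(I_hc + 2.0, params)
    if near.exists and far.exists:
        logger.info(
            "period near boundary %.1f ms vs %.1f ms at +2 pA "
            "(divergence supports a homoclinic, not Hopf, loss)",
            near.period, far.period,
        )
    return I_hc


def continue_in_current(
    params: ModelParameters,
    I_range: tuple[float, float] = (-70.0, 310.0),
    step: float = 1.0,
    probe_cycles: bool = True,
) -> BifurcationDiagram1D:
    """Sweep I_tot: equilibrium branches, cycle extremes, detected events."""
    if step <= 0:
        raise ValueError("step must be > 0")
    grid = np.arange(I_range[0], I_range[1] + step / 2, step)
    fps = [find_fixed_points(I, params) for I in grid]
    cycles = [
        limit_cycle_probe(I, params) if probe_cycles
        else CycleProbe(False, math.nan, math.nan, math.nan)
        for I in grid
    ]
    events: list[BifurcationEvent] = []
    for i in range(len(grid) - 1):
        a, b = float(grid[i]), float(grid[i + 1])
        if len(fps[i]) != len(fps[i + 1]):
            try:
                events.append(
                    BifurcationEvent("saddle_node", locate_saddle_node(params, (a, b)))
                )
            except ValueError:
                pass
        tr_a = sum(e.real for e in fps[i][-1].eigenvalues)
        tr_b = sum(e.real for e in fps[i + 1][-1].eigenvalues)
        if tr_a * tr_b < 0 and len(fps[i]) == len(fps[i + 1]) == 1:
            events.append(BifurcationEvent("hopf", locate_hopf(params, (a, b))))
        if probe_cycles and cycles[i].exists != cycles[i + 1].exists:
            # a homoclinic connection needs a saddle; cycle loss without one
            # is the amplitude shrinking into a Hopf point
            has_saddle = any(
                f.stability_class == "saddle" for f in fps[i] + fps[i + 1]
            )
            if has_saddle:
                try:
                    events.append(
                        BifurcationEvent("homoclinic", locate_homoclinic(params, (a, b)))
                    )
                except ValueError:
                    pass
    events.sort(key=lambda e: e.parameter_value)
    return BifurcationDiagram1D(
        parameter="I_tot", grid=grid, fixed_points=fps, cycles=cycles, events=events
    )


_LABELS_ITOT_GK = {
    # (n_stable, n_unstable, has_cycle, high_V_stable): region letter in the
    # (I_tot, g_K) map
    (1, 2, False, False): "A",
    (1, 0, False, False): "A",
    (1, 2, True, False): "B",
    (2, 1, False, True): "C",
    (0, 1, True, False): "D",
    (1, 0, False, True): "E",
    (1, 2, False, True): "E",
}

_LABELS_V3_GK = {
    # (V_3, g_K) map
    (1, 0, False, False): "A",
    (1, 2, False, False): "A",
    (2, 1, False, False): "B",
    (1, 0, True, False): "C",
    (1, 2, True, False): "C",
    (2, 2, True, False): "D",
    (2, 2, True, True): "D",
    (2, 1, False, True): "E",
    (2, 3, False, True): "F",
    (2, 3, False, False): "F",
    (2, 1, True, True): "G",
}

_LABELS_BY_AXIS = {"I_tot": _LABELS_ITOT_GK, "V_3": _LABELS_V3_GK, "g_C": _LABELS_ITOT_GK}


def region_map_2d(
    axis_x: str,
    axis_y: str,
    x_grid: np.ndarray,
    y_grid: np.ndarray,
    params: ModelParameters,
    I_tot: float = 0.0,
    probe_T: float = 3000.0,
) -> RegionMap2D:
    """Phase-portrait signature map over a 2-parameter grid.

    ``axis_x`` is one of ``I_tot``, ``g_C``, ``V_3``; ``axis_y`` is ``g_K``.
    Each cell records (number of stable equilibria, number of unstable
    equilibria, cycle presence) and a figure-legend letter where the
    signature is one the published maps name; unmatched signatures get
    "other".
    """
    if axis_x not in ("I_tot", "g_C", "V_3"):
        raise ValueError(f"unsupported x axis {axis_x!r}")
    if axis_y != "g_K":
        raise ValueError(f"unsupported y axis {axis_y!r}")
    x_grid = np.asarray(x_grid, dtype=float)
    y_grid = np.asarray(y_grid, dtype=float)
    shape = (len(y_grid), len(x_grid))
    n_stable = np.zeros(shape, dtype=int)
    n_unstable = np.zeros(shape, dtype=int)
    has_cycle = np.zeros(shape, dtype=bool)
    labels = np.full(shape, "other", dtype=object)
    label_dict = _LABELS_BY_AXIS[axis_x]
    for i, y in enumerate(y_grid):
        for j, x in enumerate(x_grid):
            overrides = {"g_K": float(y)}
            I = I_tot
            if axis_x == "I_tot":
                I = float(x)
            else:
                overrides[axis_x] = float(x)
            p = params.replace(**overrides)
            fps = find_fixed_points(I, p)
            cyc = limit_cycle_probe(I, p, T=probe_T, transient=probe_T - 2000.0)
            ns = sum(f.stable for f in fps)
            nu = len(fps) - ns
            high = any(f.stable and f.V_star > -40.0 for f in fps)
            n_stable[i, j] = ns
            n_unstable[i, j] = nu
            has_cycle[i, j] = cyc.exists
            labels[i, j] = label_dict.get((ns, nu, cyc.exists, high), "other")
    return RegionMap2D(
        axis_x=axis_x,
        axis_y=axis_y,
        x_grid=x_grid,
        y_grid=y_grid,
        n_stable=n_stable,
        n_unstable=n_unstable,
        has_cycle=has_cycle,
        labels=labels,
    )
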