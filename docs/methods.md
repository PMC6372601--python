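# Methods

## Model

The cell is a single isopotential compartment with four ionic currents, all
in a fixed unit system (ms, mV, pF, pA, nS, nM — so nS·mV = pA and
pA/pF = mV/ms, with no hidden conversion factors):

- leak `I_L = -g_L (V - V_L)`;
- voltage-gated Ca²⁺, `I_C = -g_C M∞(V)(V - V_C)`, with
  `M∞(V) = (1 + tanh((V - V_1)/V_2))/2` — the depolarizing drive of the
  fast oscillation;
- fast voltage-gated K⁺, `I_K = -g_K N (V - V_K)`, with first-order gating
  `τ_N dN/dt = Λ(V)(N∞(V) - N)`, `N∞(V) = (1 + tanh((V - V_3)/V_4))/2`,
  `Λ(V) = cosh((V - V_3)/(2V_4))` — the fast hyperpolarizing partner
  (Na⁺ channels are deliberately absent: they play no role in this cell's
  bursting);
- slow afterhyperpolarization (sAHP), `I_sAHP = -g_sAHP R⁴ (V - V_K)`, a
  calcium-gated K⁺ current. Calcium enters through `I_C`
  (`τ_C dC/dt = -(α_C/H_X) C + C_0 + δ_C I_C`, the linearized
  Na⁺/Ca²⁺-exchanger form, valid for C ≪ H_X), four Ca²⁺ saturate
  calmodulin (`S`, fourth-order kinetics), calmodulin binds the four channel
  terminals (`R`), and four bound terminals open the channel (the `R⁴`).

Default parameters are the published calibration for an immature SAC
(C_m = 22 pF, g_L = 2 nS, g_sAHP = 2 nS, V_L = −70, V_C = 50, V_K = −90,
V_1 = −20, V_2 = 20, V_3 = −25, V_4 = 7 mV, τ_N = 5 ms,
τ_C = 2 s, τ_R = τ_S = 8.3 s, δ_C = 10.503 nM/pA, α_S = 200⁻⁴ nM⁻⁴,
α_C = 4865 nM, α_R = 4.25, H_X = 1800 nM, C_0 = 88 nM). The calcium and
fast-K⁺ conductances have physiological ranges ([3, 20] and [1, 20] nS)
rather than single values; the package default (g_C, g_K) = (12, 10) nS is
the canonical working point of the bifurcation analysis. Defaults σ = 4
pA·ms^1/2 and I_ext = 0 correspond to the dynamically driven bursting
condition; I_ext = −4 pA is the canonical noise-driven condition.

Timescales separate cleanly (τ_L = C_m/g_L = 11 ms; τ_L/τ_C = 5.5·10⁻³;
τ_L/τ_R ≈ 1.3·10⁻³), which justifies analyzing the fast (V, N) pair with
the slow current I_tot = I_sAHP + I_ext frozen as a parameter.

## Numerics

**Integration.** Fixed-step Euler–Maruyama, default dt = 0.05 ms (stochastic
runs in the test suite and burst ensembles use 0.1 ms). Additive noise rules
out naive adaptive steppers, and 0.05 ms resolves both τ_N = 5 ms and the
~32 ms fast cycle by large margins; halving dt changes a deterministic 10 s
voltage trace by < 0.5 mV. Noise enters only the V equation as
`(σ/C_m)·sqrt(dt)·z`, z ~ N(0,1), so the injected current has spectral
density σ². A run is fully determined by (parameters, protocol, dt, seed,
initial state); the default initial state is the voltage-clamp steady state
at −70 mV, the least-informative reproducible choice. Discretization can
push gates marginally outside [0, 1] (and C below 0); such steps are clamped
and counted — at default settings clamps are absent in 10⁶-step runs.
Trajectories are subsampled to a 1 ms grid by default.

**Equilibria.** With N eliminated (N = N∞(V)), equilibria of the fast pair
are roots of a scalar current balance Φ(V); a 1501-node sign scan of
Φ on V ∈ [−90, 60] mV plus bisection finds all of them (verified against a
20001-node scan on 100 random parameter draws), and the analytic 2×2
Jacobian classifies them (verified against central finite differences).
The scan window is the physically meaningful one — between the K⁺ and above
the Ca²⁺ reversal — but note that for frozen currents below about −42 pA
the rest branch leaves the window; frozen currents that negative are not
reached by the sAHP in the regimes analyzed here.

**Bifurcation location.** The saddle-node is refined from the fold
conditions Φ = Φ' = 0 (Φ' is current-independent, so the fold voltage is a
root of Φ' and the fold current follows in closed form); tolerance 0.01 pA.
The Hopf point is the zero of the Jacobian trace along the focus branch
(determinant checked positive); tolerance 0.1 pA. The homoclinic point is
located by bisection on limit-cycle existence (0.05 pA), with the cycle
probed by direct simulation: 5 s from each unstable equilibrium perturbed
by ±1 mV, 2 s transient discarded, cycle deemed present when the sustained
peak-to-peak voltage exceeds 5 mV. Cycle-existence boundaries are classified
homoclinic only when a saddle is present (otherwise the cycle is shrinking
into the Hopf point); the diverging period near the boundary is logged as
supporting evidence. Formal two-parameter continuation is deliberately
avoided — the planar problem is handled exhaustively by scanning, which is
also robust where continuation packages struggle with the homoclinic.

**Region maps.** Two-parameter maps record per cell the counts of stable and
unstable equilibria and cycle presence; cells are labeled with the letters
used in the published phase diagrams where the signature matches a known
legend entry, and "other" otherwise (no forced assignment).

## Burst statistics

A burst is a maximal excursion of C above 150 nM lasting at least 1 s;
excursions touching a trace boundary are discarded (their extent is
unknown), and sub-threshold dips are never bridged. The interburst interval
is onset-to-onset — the "bursting period" — matching how the published
numbers are quoted; offset-to-onset can be derived from the event list.
Ensemble statistics pool IBIs over independent seeded trajectories
(consecutive seeds from a base seed). In heat maps, cells with no detected
burst are *missing* (serialized as an explicit NA sentinel), not zero.

In the τ_IBI(I_ext) curve, τ_IBI is set to 0 by convention where bursting is
absent — below the critical current, and also in the tonic regime at strong
depolarization, flagged when calcium exceeds the threshold more than 90% of
the time: there the cell fires without a refractory period, bursts merge,
and an onset-to-onset interval is no longer meaningful (without this guard
the merge boundary contributes a few diverging intervals that destabilize
the law fit; the duty fraction jumps from 0.66 at 16 pA to 0.995 at 19 pA,
so the flag is insensitive to its exact threshold).

The square-root law is fitted by nonlinear least squares over positive-τ
points within I_ext ∈ [−20, 40] pA. Two algebraic forms circulate for this
law, `K/sqrt(I-I_c)` ("plain", the default) and `K/(2 sqrt(I-I_c))`
("halved"); they recover identical I_c and K values differing exactly by a
factor 2, so both are implemented and the form is always reported with the
fit, together with parameter standard errors and a 95% CI. Interval
distributions are fitted on 1 s histogram bins by least squares, comparing a
Gaussian against a Gaussian-plus-decaying-exponential with a
degrees-of-freedom-penalized residual, so the richer model is selected only
when the exponential component genuinely improves the fit.

## Scripted experiments

The pulse experiment applies +150 pA for 60 ms over a −4 pA baseline
(noise-driven rest regime) with small noise (σ = 1) so the pulse, not a
fluctuation, triggers the response; "oscillations" means ≥ 3 voltage peaks
with > 5 mV peak-to-peak during the pulse, and the afterhyperpolarization
flag records a post-pulse dip > 2 mV below the pre-pulse mean. The
cadmium variant zeroes g_C *and* g_sAHP (a Cd²⁺-like blockade of all
calcium-related channels); an audit guarantees the two variants differ in
nothing else.

Developmental presets override only (g_K, V_3, I_ext): P4 = (8 nS, −16 mV,
0), P8 = (10, −34, 0), P8+TEA = (8, −34, 0), P22+TEA = (4.5, −35, −10 pA),
P22 restored = (4.5, −35, 0); 600 s at σ = 4, bursting scored by the burst
detector. g_C stays at 12 nS — the presets specify nothing else, and this is
recorded as an assumption. Under that assumption the TEA/P22 contrasts
reproduce, but two published outcomes do not: the P4 configuration settles
into a permanently depolarized state (a stable high-voltage focus that
survives even maximal sAHP conductance g_sAHP·R⁴ ≈ 0.86 nS), and the P8
configuration bursts deterministically. A systematic scan shows no single
g_C (nor noise level) yields all five published flags simultaneously — the
g_K = 10 vs 8 contrast at V_3 = −34 mV is not separable by g_C — so the
corresponding checks are left failing rather than repaired by undocumented
parameter changes.

**Firing frequency.** On the fast-subsystem cycle the firing rate rises from
~10 Hz near the homoclinic point to 31.5 Hz at I_tot = 0 (the latter checked
against a high-accuracy adaptive integrator). A bursting cell never fires at
the I_tot = 0 rate: during a burst the growing sAHP sweeps I_tot across
[I_Hc, I_SN], and the dwell-time-averaged inter-peak rate measured on the
full deterministic model at I_ext = 0 is ≈ 18.9 Hz. That full-model
measurement is what `burst_firing_frequency` reports and what the ~20 Hz
observable refers to; `measure_fast_frequency(I_tot)` gives the
frozen-current cycle rate at any current.

## What the reported numbers do and do not show

The acceptance script recomputes, per seed: the fold (−3.69 pA) and Hopf
(250.2 pA) currents; the in-burst firing rate (18.9 Hz); the square-root-law
fit from a scaled-down sweep (16 currents in [−5, 40] pA, 5 × 500 s
trajectories each at σ = 4 — the full published protocol used 20 × 2000 s
ensembles and finer grids; the scaled version leaves I_c stable at
≈ −4.6 ± 0.3 pA); and the maximal depolarization in the restored-bursting
configuration (−27.1 mV at g_K = 8, V_3 = −34; the fast-subsystem cycle
peaks at −29.5 mV, so the published −20 mV is not reached by these equations
at g_C = 12). The fitted prefactor K ≈ 32 s·pA^1/2 with these IBIs in the
tens of seconds; a published value of 0.657 for the same quantity implies
sub-second intervals at I_ext = 0 and is consistent with a seconds/minutes
unit discrepancy (0.657 min·pA^1/2 = 39.4 s·pA^1/2, within ~20% of the fit
here); K is therefore always reported with its confidence interval.

There is no external data anywhere: every number is generated by the model
itself, so agreement demonstrates internal consistency of the implementation
with the published analysis, not validity of the model for real SACs. The
synthetic test fixtures (square-wave calcium traces, synthetic square-root
curves, Gaussian/exponential samples) exercise the detectors and estimators
on known ground truth only.

## Known limitations

- Single compartment, no Na⁺ channels, no network/cholinergic coupling —
  single-cell bursting only, not wave propagation.
- The linearized calcium-extrusion law holds for C ≪ H_X = 1800 nM;
  strongly depolarized regimes (e.g. the P4 preset, C ≈ 1.9 µM) approach
  that bound.
- The frozen-current fast subsystem misrepresents very negative I_tot
  (the physical sAHP current vanishes at V = V_K); conclusions drawn from
  it are restricted to the oscillatory range.
- Euler–Maruyama is order-1; stochastic quantities carry scheme and step
  dependence of a few percent, well within the stated tolerances.
- The published developmental scenario figure is only partially
  reproducible from its stated parameter changes (see above).
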