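# sacburst

Conductance-based modeling of the spontaneous bursting of developing
**starburst amacrine cells (SACs)** — the retinal interneurons that, during
stage II of retinal development, burst autonomously and drive the cholinergic
retinal waves that wire the early visual system. The package is aimed at
computational neuroscientists who want to simulate this cell type, map its
dynamical regimes as conductances change (development, pharmacology), and
quantify its burst statistics.

## The model

Five variables with three timescales: a fast Morris–Lecar-type pair — the
membrane potential `V` (mV) and the fast K⁺ gating fraction `N` — coupled to
intracellular calcium `C` (nM, ~2 s) and the slow gating of
calcium-activated K⁺ channels, `S` (saturated calmodulin fraction) and `R`
(bound-terminal fraction, ~10 s):

    C_m dV/dt = -g_L (V - V_L) - g_C M∞(V) (V - V_C) - g_K N (V - V_K)
                - g_sAHP R⁴ (V - V_K) + I_ext + σ ξ_t
    τ_N dN/dt = Λ(V) (N∞(V) - N)
    τ_C dC/dt = -(α_C/H_X) C + C_0 + δ_C I_C(V)
    τ_S dS/dt = α_S C⁴ (1 - S) - S
    τ_R dR/dt = α_R S (1 - R) - R

with `M∞, N∞` tanh sigmoids, `Λ` a cosh rate factor, and `ξ_t` white noise
of amplitude `σ` (pA ms^1/2). Four Ca²⁺ ions saturate one calmodulin and four
bound terminals open one sAHP channel, hence the fourth powers.

Bursting is slow–fast: the `(V, N)` subsystem, driven by the frozen current
`I_tot = I_sAHP + I_ext`, has a saddle-node bifurcation at
`I_SN ≈ -3.7 pA` (onset of repetitive firing), a homoclinic connection at
`I_Hc ≈ -5.8 pA` (end of the spiking phase, diverging period), and a Hopf
point at `≈ 250 pA`. During a burst, calcium loads, the sAHP conductance
`g_sAHP R⁴` grows, and `I_tot` is swept leftwards across this diagram until
firing stops; the interburst interval is set by the slow sAHP decay back
across the fold. Near the fold the mean interburst interval follows

    τ_IBI(I_ext) = K / sqrt(I_ext - I_c),    I_ext > I_c,

and is zero (no bursting) below the critical current `I_c`.

The package provides:

- `sacburst.model` / `sacburst.params` — equations, currents, closed-form
  voltage-clamp steady states, literature-calibrated defaults;
- `sacburst.integrate` — seeded Euler–Maruyama integration of the full
  system (numba-compiled) and deterministic integration of the fast pair;
- `sacburst.bifurcation` — equilibria with stability classes, saddle-node /
  Hopf / homoclinic location, one-parameter continuation, two-parameter
  phase-portrait region maps;
- `sacburst.bursts` — burst detection (calcium > 150 nM for > 1 s),
  interburst statistics, heat maps, the square-root law fit, interval
  distribution fits;
- `sacburst.experiments` — scripted current-pulse (with Cd²⁺-like calcium
  blockade) and developmental/TEA scenarios;
- `sacburst.io` / `sacburst.cli` / `sacburst.plotting` — configs, text
  serialization, the `sacburst` command line, figure helpers.

## Worked example

```python
import sacburst as sb

params = sb.ModelParameters(sigma=0.0)          # deterministic cell
traj = sb.simulate(params, T=200_000.0, dt=0.05, seed=0)   # 200 s
events = sb.detect_bursts(traj)
ibis = sb.interburst_intervals(events)
print(len(events), round(ibis[1:].mean() / 1000, 2))

print(round(sb.locate_saddle_node(params), 2),
      round(sb.locate_homoclinic(params), 2))
```

prints

```
12 16.86
-3.69 -5.7
```

With zero noise and zero external current the cell bursts periodically —
12 bursts in 200 s, one every 16.86 s (each a ~2.6 s calcium-loaded spiking
episode) — because its rest state sits just past the saddle-node at
−3.69 pA, and the sAHP cycle repeatedly carries it across the fold and back
through the homoclinic point near −5.7 pA. The same machinery is available
from the shell:

```bash
sacburst fixed-points --itot -10
sacburst continuation --from -20 --to 310 --step 5 --out diagram.tsv
sacburst ibi-sweep --iext -5:40:3 --out sweep.tsv
sacburst experiment --kind scenario --name P8_TEA
```

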