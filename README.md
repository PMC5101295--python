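# gradientpn

Morphogen-gradient formation simulated as a Place/Transition Petri net with
activator arcs, executed under maximally concurrent step semantics, with all
net parameters derived from the discretization of a one-dimensional
reaction–diffusion equation.

## The problem

A morphogen is a signaling molecule whose graded concentration across a
tissue directs cell fate. A source at one boundary produces molecules that
spread through the tissue (effective diffusion, coefficient *D*) while being
degraded everywhere (first-order rate *k*), establishing a steady
exponential gradient with decay length 1/μ, μ = √(k/D). The continuum
description is

    ∂C/∂t = D ∂²C/∂r² − k C     on (0, L),

with constant influx areal density J₀ at r = 0 (−D ∂C/∂r = J₀) and zero
flux at r = L.

This package realizes the same process as a discrete, token-based model: a
row of *n* cells becomes a chain of places x₁…x_n; tokens are molecules;
transitions move tokens between neighbor places in a deterministic 5-phase
cycle scheduled by a ring of control places and activator arcs (arcs that
test a place for a token *a priori*, without consuming it). One cycle of 5
maximally concurrent steps advances time by Δt and implements exactly the
explicit finite-difference update

    Δm_i = (DΔt/ℓ²)(m_{i−1} − m_i) − (DΔt/ℓ²)(m_i − m_{i+1}) − kΔt·m_i,

with the boundary rows carrying the influx J₀hΔt and the zero-flux
condition. Transport in a cycle moves ⌊pDΔt(m_i − m_{i+1}) / pℓ²⌋ tokens
from x_i to x_{i+1}, and degradation removes ⌊bkΔt·m_i / b⌋ tokens from
x_i; the integer scalers *p* and *b* keep the arc weights natural numbers
without rounding away the small rates. Everything is integer arithmetic —
the model is an exact, deterministic token game whose cycle-boundary
markings track the PDE solution.

The package validates this correspondence quantitatively on gradient
formation of Decapentaplegic (Dpp) in the *Drosophila* wing disc, using
FRAP-derived rates for the wild-type (`Dpp`: D = 0.10 µm²/s,
k = 2.52·10⁻⁴ s⁻¹) and an endocytosis-impaired mutant with rescued source
(`Dpp-rescue`: D = 0.06 µm²/s, k = 1.53·10⁻⁴ s⁻¹), on 30 cells of
2.6 µm × 2.6 µm.

## What is in the box

| module | contents |
| --- | --- |
| `gradientpn.pta` | general PTA-net engine: enabling, step execution, maximal steps with auto-concurrency, conflict detection, an array-compiled fast path |
| `gradientpn.builder` | gradient-net construction from physical parameters; integer arc-weight scaling; initial markings from density profiles |
| `gradientpn.reference` | explicit finite-difference recurrence, phase-faithful integer oracle, closed-form steady states, refined transient solver, density→count conversion |
| `gradientpn.simulate` | trajectory recording, steady-state detection, deviation statistics, the Dpp case studies |
| `gradientpn.pnml`, `gradientpn.config`, `gradientpn.cli` | PNML import/export, YAML configs, trajectory CSV, command-line interface |

## Worked example

```python
import numpy as np
from gradientpn import run_case_study

result = run_case_study("Dpp")
print("steady state at cycle", result.steady_cycle,
      f"(t = {result.steady_cycle * result.params.dt:g} s)")
print("cell 1 / cell 30 counts:",
      result.steady_counts[0], "/", result.steady_counts[-1])
print(f"steady-state max per-cell deviation: {result.steady_local.max_dev:.3f} %")
print(f"transient (600 s, 2400 s) max deviation: "
      f"{result.transient_amplitude.max_dev:.3f} %")
```

prints

```
steady state at cycle 9463 (t = 47315 s)
cell 1 / cell 30 counts: 12618725 / 538238
steady-state max per-cell deviation: 0.133 %
transient (600 s, 2400 s) max deviation: 0.235 %
```

The net starts empty, the source emits J₀hΔt tokens per cycle, and after
9463 cycles the marking repeats exactly — the steady state. Each of the 30
cells then deviates from the closed-form finite-domain steady state
(converted to molecule counts per cell) by at most 0.133 %; during gradient
build-up (t = 600 s and 2400 s) the counts deviate from a refined transient
solution by at most 0.235 % of the gradient amplitude. The token counts
scale linearly with J₀; the deviations do not (they are relative), so the
validation is insensitive to the absolute influx.

The same works from the shell:

```sh
gradientpn validate --condition Dpp --out report.json        # exit 1 if bounds exceeded
gradientpn build-net --n 30 --out gradient.pnml              # 124 places, 242 transitions
gradientpn simulate --condition Dpp-rescue --cycles 500 --out traj.csv
gradientpn steady-state --condition Dpp                      # closed-form profile CSV
```

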