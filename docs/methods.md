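# Methods

## Model

The simulator realizes the 1-D reaction–diffusion equation
∂C/∂t = D ∂²C/∂r² − kC with influx J₀ at r = 0 and zero flux at r = L as a
Place/Transition net with activator arcs (PTA-net), executed under the
maximally concurrent step semantics. Places x₁…x_n hold integer molecule
counts m_i of the n cells (each ℓ long and h high, so m_i ≈ h∫_cell C dr).
The net computes the explicit finite-difference (FTCS) update of these
counts once per *cycle* of five maximal steps, scheduled by a control token
hopping through places w¹…w⁵; every working transition is gated on its
phase place through an activator arc (a-priori test, non-consuming):

1. counter places x′_i (i < n) and x″_i (i > 1) are filled with
   w_fill·m_i tokens by transitions c_i, whose auto-concurrency is capped
   at m_i by a weight-1 self-loop with x_i; drain transitions e′/e″ clear
   counter residue from the previous cycle; if the toggle place f is
   marked, the source transition s emits w_source tokens into x₁;
2. d_i removes token pairs from (x′_i, x″_{i+1}), leaving
   α_i = w_fill·(m_i − m_{i+1}) in x′_i;
3. t′_i moves β_i = ⌊α_i / w_move_cost⌋ tokens from x_i to x_{i+1}
   (each firing costs w_move_cost counter tokens, so maximality produces
   the floor automatically);
4. g_i fills r_i with w_deg_fill·m_i tokens (from the post-transport
   counts); q_i clears residue;
5. g′_i removes δ_i = ⌊w_deg_fill·m_i / b⌋ tokens from x_i.

The five arc weights come from one place only
(`gradientpn.builder.scaled_weights`):

    w_fill      = round(p·D·Δt)     w_move_cost = round(p·ℓ²)
    w_deg_fill  = round(b·k·Δt)     w_deg_cost  = b
    w_source    = round(J₀·h·Δt)

Rounding therefore happens once, at the weight level; the scalers p and b
bound the relative rounding error of the rates by 1/(2pDΔt) and 1/(2bkΔt).
The net is conflict-free by construction (each consumed place has a single
consumer type per phase), so the maximal step at every reachable marking is
unique and the whole run is deterministic.

## Engine

`maximal_step` assigns every transition the maximal multiplicity it could
fire alone (activator arcs tested against the pre-step marking) and checks
that the joint demand fits the marking. When it fits — always, on
conflict-free nets — that assignment is itself the unique maximal step: each
transition is at its individual ceiling, so no occurrence can be added. When
it does not fit, the engine emits `ConflictWarning` and rebuilds the step
greedily in sorted identifier order; activator tests keep using the pre-step
marking (a-priori semantics), token consumption tracks the shrinking
remainder. The greedy result is max-enabled but order-dependent, hence the
warning. Long runs go through `CompiledNet`, an array layout of the same
rules (~20 µs per maximal step on the 30-cell net); the engine/oracle
equality test pins both paths to the mapping-based reference semantics.

## Case-study parameters

| symbol | meaning | Dpp | Dpp-rescue | origin |
| --- | --- | --- | --- | --- |
| n | cells | 30 | 30 | case study |
| ℓ, h | cell size (µm) | 2.6 | 2.6 | case study |
| D | diffusion (µm²/s) | 0.10 | 0.06 | FRAP estimate |
| k | degradation (1/s) | 2.52·10⁻⁴ | 1.53·10⁻⁴ | FRAP estimate (read at the 10⁻⁴ scale; at order 1 s⁻¹ the decay length would be 0.2 µm, incompatible with a 30-cell gradient) |
| p, b | accuracy scalers | 10², 10⁵ | 10², 10⁵ | case study |
| Δt | cycle step (s) | 5 | 20 | numerical choice, below |
| J₀ | influx (molecules µm⁻¹ s⁻¹) | 10⁴ | 10⁴ | numerical choice, below |

### Choice of Δt

Two systematic biases of the cycle compete, and both have closed forms.

*Operator splitting.* The 5-phase schedule applies degradation to the
post-transport counts, so a cycle computes (1 − kΔt)·(m + T(m)) instead of
m + T(m) − kΔt·m. At the fixed point this acts as an effective degradation
rate k/(1 − kΔt) ≈ k(1 + kΔt), i.e. a relative decay-length error of
+kΔt/2 per unit μ (tail counts biased low, linearly in cell index).

*Grid dispersion.* The steady state of the discrete Laplacian decays per
cell by μ̂ℓ = arccosh(1 + (μℓ)²/2) ≈ μℓ(1 − (μℓ)²/24) instead of μℓ (tail
counts biased high).

The two cancel at Δt = ℓ²/(12D) — 5.6 s for Dpp, 9.4 s for Dpp-rescue.
Admissible Δt must also divide the comparison times (600/2400/12000 s) and
make p·D·Δt, b·k·Δt and J₀·h·Δt exactly integer, so that the arc weights
carry no rounding error at all. For Dpp this selects Δt = 5 s. For
Dpp-rescue the nearest admissible value to the cancellation point is 10 s,
but its steady-state accuracy budget (the reported bound is 1.4 %) is
loose while its transient budget (0.2 %) is tight, so the rescue default is
Δt = 20 s: DΔt/ℓ² = 0.178 ≈ 1/6, the classic third-order-accurate ratio of
the FTCS scheme, which minimizes the transient error instead. Both values
are defaults of `CASE_STUDIES`, not constraints; any Δt satisfying the
stability conditions DΔt/ℓ² < 1 and kΔt < 1 is accepted.

### Choice of J₀

J₀ only sets the token scale — all reported statistics are relative — but
the *integer* dynamics quantize every per-cycle flow at one token. A cell's
degradation outflow is ⌊kΔt·m_i⌋ per cycle, so the frozen steady state can
sit anywhere inside a dead band of ~1/(kΔt) ≈ 400–800 tokens. At small
scales this band dominates: with J₀ = 10 the tail cells hold ~500 tokens
and freeze up to ~30 % away from the continuum profile. The default
J₀ = 10⁴ puts ≥ 5·10⁵ tokens in the weakest cell, keeping the quantization
band below 0.1 % of the local count everywhere (and token counts far below
int64 limits: the largest intermediate, w_fill·m₁, stays < 10¹⁰). Doubling
J₀ moves every steady-state deviation by < 0.1 percentage points (tested).

## Steady-state detection

The criterion is exact repetition of the marking over two consecutive
cycles — legitimate because the net is deterministic and integer-valued.
Dpp reaches an exact fixed point (cycle 9463, t = 47315 s). Dpp-rescue
instead locks into a period-2 flicker in which a handful of single tokens
shuttle between neighbor cells (floor rounding alternately over- and
under-shoots by one). `detect_steady_state(traj, tol=1)` accepts this as
steady when the per-cycle change is ≤ 1 token *and* the marking two cycles
back repeats exactly; requiring the period-2 match prevents firing during
slow monotone relaxation, where per-cycle changes also pass through ±1.
`run_case_study` tries the exact criterion first and falls back to the
tolerant one. The default cycle cap is 12 000.

## References and deviation statistics

*Steady state.* The closed-form finite-domain profile
C*(r) = (J₀/√(kD)) e^(−μr) · (1 + e^(2μ(r−L)))/(1 − e^(−2μL)) (it
satisfies −DC′(0) = J₀ and C′(L) = 0 exactly) is converted to per-cell
counts by `counts_from_density`: the trapezoidal rule on the field's own
grid. On a grid holding only the cell edges this is the basic per-cell
trapezium ½hℓ[C((i−1)ℓ) + C(iℓ)]; the case study evaluates it on an
8×-refined grid, where the composite rule approximates N_i = h∫C dr to
< 0.01 % (the edge-only trapezium of an exponential overshoots the integral
by a uniform (μℓ)²/12 ≈ 0.14 %, a conversion artifact worth avoiding at
this accuracy level). Steady-state deviations are reported per cell,
|m_i − N_i|/N_i, with max and mean over the 30 cells — every cell is well
resolved at steady state.

*Transients.* A refined FTCS solve (node spacing ℓ/8, time step a quarter
of the stability limit, influx via a second-order ghost node) provides
C(·, t) at t = 600 s and 2400 s; halving the spacing moves the per-cell
counts by < 0.01 % of the amplitude (tested at < 0.05 %). Ahead of the
spreading front the reference counts fall below one molecule per cell while
the net necessarily holds 0 or 1 tokens, so per-cell relative deviations
are undefined-in-practice there (they saturate at 100 % however accurate
the simulation is). Transient deviations are therefore normalized by the
profile amplitude, max_i N_i: per-cell values |m_i − N_i|/max N_i, with max
and mean pooled over all 30 cells and both time points, plus per-time
breakdowns. Per-cell-relative deviations over the resolved cells
(N_i ≥ 1 molecule) are also computed and carried in the report.

Measured under the defaults above (`scripts/acceptance.py`):

* steady state: max 0.13 % (Dpp), 0.53 % (Dpp-rescue);
* transients: max 0.24 % / mean 0.027 % (Dpp), max 0.16 % / mean 0.020 %
  (Dpp-rescue).

The transient means are floored at ~0.02 % of amplitude by the spatial
discretization of the cell-sized grid (mostly the first few cells, where
curvature is largest); no admissible Δt reduces them further.

## What the validation does and does not show

The comparison exercises the full pipeline — net construction, maximal-step
execution, integer rounding, steady-state detection, continuum references —
under the case study's homogeneous, one-dimensional, source-at-one-end
conditions with constant parameters. It does not probe inhomogeneous
tissues, time-varying sources, non-monotone initial profiles (supported,
with counter residue handled by the drain transitions, but only lightly
tested), or the two-directional transport variant, which is out of scope.
Agreement with the references is agreement between two discretizations and
a closed form, not with experimental data; D and k are taken as given.

## Known limitations

* The maximal-step engine resolves genuine conflicts greedily in sorted
  identifier order — deterministic but arbitrary; it flags such markings
  with `ConflictWarning` rather than enumerating alternatives. The gradient
  net never conflicts.
* `detect_steady_state(tol=1)` recognizes period-2 flicker only; longer
  quantization cycles (not observed) would hit the cycle cap.
* The transient reference is itself an explicit scheme; its accuracy is
  checked by grid-refinement and against the closed form at large t, not
  against an independent solver family.
* Counts are Python/NumPy int64 end to end; J₀·scale choices beyond ~10⁷
  would overflow the w_fill·m₁ intermediates in the counters.
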