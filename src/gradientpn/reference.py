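"""Reference computations for validating the gradient net.

Three independent references are provided:

* :func:`explicit_step` — the real-valued explicit (FTCS) update of the
  per-cell molecule counts, i.e. the recurrence the net discretizes:

      dm_i = (D*dt/l^2) (m_{i-1} - m_i) - (D*dt/l^2) (m_i - m_{i+1}) - k*dt m_i

  with influx ``J0*h*dt`` into the first cell and zero flux past the last.

* :func:`phase_oracle_cycle` — a *phase-faithful integer oracle*: the exact
  integer recurrence realized by one 5-phase cycle of the net (counter fill
  from the pre-cycle marking, scaled difference, floor-division transport,
  degradation-counter fill from the post-transport marking, floor-division
  decay).  Cycle-boundary markings of the Petri engine must equal this
  oracle exactly; the equality is the package's central correctness test.

* closed-form steady states (:func:`steady_state_infinite`,
  :func:`steady_state_finite`) and a refined finite-difference transient
  solver (:func:`solve_transient`) for the continuum equation, converted to
  per-cell molecule counts by :func:`counts_from_density`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .builder import GradientParams, ScaledWeights
from .errors import AccuracyWarning, InputError, NumericError, ParameterError

__all__ = [
    "CellState",
    "DensityField",
    "CycleTrace",
    "explicit_step",
    "phase_oracle_cycle",
    "steady_state_infinite",
    "steady_state_finite",
    "counts_from_density",
    "solve_transient",
]


@dataclass(frozen=True)
class CellState:
    """Per-cell molecule numbers at time ``t = j*dt``."""

    counts: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 1 or arr.size < 1:
            raise InputError("counts must be a 1-D vector")
        if np.any(arr < 0):
            raise InputError("cell counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def n(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class DensityField:
    """An areal density profile ``C(r, t)`` sampled on a grid over [0, L]."""

    grid: np.ndarray
    values: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.shape != values.shape or grid.ndim != 1:
            raise InputError("grid and values must be matching 1-D arrays")
        if np.any(np.diff(grid) <= 0):
            raise InputError("grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    @property
    def L(self) -> float:
        return float(self.grid[-1])


@dataclass(frozen=True)
class CycleTrace:
    """Per-cycle diagnostics of the 5-phase recurrence.

    ``alpha[i]`` — scaled count difference left in ``x'_{i+1}`` after phase 2;
    ``beta[i]`` — transport firings of ``t'_{i+1}`` (tokens moved rightward);
    ``delta[i]`` — degradation firings of ``g'_{i+1}`` (tokens destroyed);
    ``source_in`` — tokens emitted into cell 1.
    """

    alpha: np.ndarray
    beta: np.ndarray
    delta: np.ndarray
    source_in: int


def explicit_step(state: CellState, params: GradientParams) -> CellState:
    """One real-valued explicit (FTCS) update of the cell counts."""
    params.check_stability()
    m = np.asarray(state.counts, dtype=float)
    if m.size != params.n:
        raise InputError(f"state has {m.size} cells, params.n = {params.n}")
    c = params.D * params.dt / params.ell**2
    kd = params.k * params.dt
    dm = np.empty_like(m)
    dm[0] = -c * (m[0] - m[1]) - kd * m[0]
    if params.source_on:
        dm[0] += params.J0 * params.h * params.dt
    dm[1:-1] = c * (m[:-2] - 2.0 * m[1:-1] + m[2:]) - kd * m[1:-1]
    dm[-1] = c * (m[-2] - m[-1]) - kd * m[-1]
    return CellState(counts=m + dm, time=state.time + params.dt)


def phase_oracle_cycle(
    state: CellState,
    weights: ScaledWeights,
    params: GradientParams,
    source_on: bool | None = None,
) -> tuple[CellState, CycleTrace]:
    """One 5-phase cycle of the net, as a direct integer recurrence.

    Mirrors the engine exactly, including a-priori testing (counters are
    filled from the *pre-cycle* marking, before the source token arrives)
    and the floor divisions enforced by token availability.  Non-monotone
    inputs (``m_i < m_{i+1}``) leave the surplus in the ``x''`` counter,
    which the net drains next cycle; the oracle clamps the corresponding
    ``alpha_i`` at zero and emits an :class:`AccuracyWarning`.
    """
    if source_on is None:
        source_on = params.source_on
    m = np.asarray(state.counts)
    if not np.issubdtype(m.dtype, np.integer):
        if not np.all(m == np.floor(m)):
            raise InputError("phase oracle requires integer counts")
        m = m.astype(np.int64)
    m = m.astype(np.int64, copy=True)
    pre = m.copy()
    # phase 1+2: counters filled with w_fill * pre-cycle counts, then
    # cancelled pairwise; source fires in phase 1
    diff = pre[:-1] - pre[1:]
    if np.any(diff < 0):
        warnings.warn(
            "non-monotone profile: m(x_i) < m(x_{i+1}); transport clamped at 0",
            AccuracyWarning,
            stacklevel=2,
        )
    alpha = weights.w_fill * np.maximum(diff, 0)
    source_in = weights.w_source if source_on else 0
    m[0] += source_in
    # phase 3: transport, floor division by the move cost, capped by the
    # tokens actually present in the donor cell
    beta = np.minimum(alpha // weights.w_move_cost, m[:-1])
    m[:-1] -= beta
    m[1:] += beta
    # phase 4+5: degradation counters from the post-transport marking,
    # then floor-division decay capped by availability
    rho = weights.w_deg_fill * m
    delta = np.minimum(rho // weights.w_deg_cost, m)
    m -= delta
    new = CellState(counts=m, time=state.time + params.dt)
    return new, CycleTrace(alpha=alpha, beta=beta, delta=delta, source_in=source_in)


def steady_state_infinite(r, params: GradientParams):
    """Closed-form steady state on an infinite domain:
    ``C*(r) = (J0 / sqrt(k*D)) * exp(-mu*r)`` with ``mu = sqrt(k/D)``."""
    if params.D <= 0 or params.k <= 0:
        raise ParameterError("closed-form steady state requires D > 0 and k > 0")
    mu = params.mu
    amp = params.J0 / math.sqrt(params.k * params.D)
    return amp * np.exp(-mu * np.asarray(r, dtype=float))


def steady_state_finite(r, params: GradientParams):
    """Closed-form steady state on [0, L] with zero flux at ``L = n*l``:
    the infinite-domain profile times ``(1 + exp(2*mu*(r-L))) / (1 - exp(-2*mu*L))``.

    Satisfies the influx condition ``-D C'(0) = J0`` and ``C'(L) = 0``
    exactly; converges to :func:`steady_state_infinite` as ``L -> inf``.
    """
    if params.D <= 0 or params.k <= 0:
        raise ParameterError("closed-form steady state requires D > 0 and k > 0")
    mu = params.mu
    L = params.length
    r = np.asarray(r, dtype=float)
    factor = (1.0 + np.exp(2.0 * mu * (r - L))) / (1.0 - math.exp(-2.0 * mu * L))
    return steady_state_infinite(r, params) * factor


def counts_from_density(field: DensityField, params: GradientParams) -> CellState:
    """Per-cell molecule numbers ``N_i = h * integral of C over cell i``,
    evaluated by the trapezoidal rule on the field's grid.

    Every cell edge ``0, l, 2l, ..., n*l`` must lie on the grid.  On a grid
    holding only the edges this is the basic per-cell trapezium
    ``N_i = h*l/2 * (C((i-1)l) + C(il))``; on a refined grid it is the
    composite rule, converging to the exact integral.
    """
    n, ell = params.n, params.ell
    grid, vals = field.grid, field.values
    if grid[0] > 1e-9 or grid[-1] < n * ell - 1e-9 * max(1.0, n * ell):
        raise InputError(
            f"field domain [{grid[0]:g}, {grid[-1]:g}] does not cover [0, {n * ell:g}]"
        )
    edges = np.arange(n + 1) * ell
    idx = np.searchsorted(grid, edges - 1e-9 * ell)
    if np.any(np.abs(grid[np.clip(idx, 0, grid.size - 1)] - edges) > 1e-6 * ell):
        raise InputError("cell edges must lie on the field grid")
    counts = np.empty(n)
    for i in range(n):
        sl = slice(idx[i], idx[i + 1] + 1)
        counts[i] = params.h * np.trapezoid(vals[sl], grid[sl])
    return CellState(counts=counts, time=field.time)


def solve_transient(
    params: GradientParams,
    t_end: float,
    refine: int = 8,
    initial: Callable[[np.ndarray], np.ndarray] | None = None,
) -> DensityField:
    """Fine-grid transient solution of the reaction-diffusion equation.

    Explicit finite differences on a node grid of spacing ``l/refine``
    (nodes include every cell edge), with the influx boundary imposed
    through a second-order ghost node at ``r = 0`` and zero flux at
    ``r = L``.  The internal time step is chosen at one quarter of the
    diffusive stability limit, so both space and time are refined well past
    the net's own discretization; halving the grid spacing moves the
    per-cell counts by well under 0.05 % of the profile amplitude.
    """
    if refine < 1:
        raise ParameterError("refine must be >= 1")
    if t_end < 0:
        raise ParameterError("t_end must be >= 0")
    n_nodes = params.n * refine + 1
    dx = params.ell / refine
    grid = np.arange(n_nodes) * dx
    c = np.zeros(n_nodes) if initial is None else np.asarray(initial(grid), dtype=float)
    if np.any(c < 0):
        raise InputError("initial density must be non-negative")
    if t_end > 0:
        if params.D > 0:
            dt_stab = 0.25 * dx * dx / params.D
        else:
            dt_stab = 0.5 / params.k if params.k > 0 else t_end
        n_steps = max(1, math.ceil(t_end / dt_stab))
        dt = t_end / n_steps
        lam = params.D * dt / (dx * dx)
        if lam > 0.5 or params.k * dt >= 1.0:
            raise NumericError(
                f"internal step unstable (lam={lam:.3g}, k*dt={params.k * dt:.3g})"
            )
        influx = 2.0 * params.J0 * dt / dx if params.source_on else 0.0
        kd = params.k * dt
        for _ in range(n_steps):
            new = np.empty_like(c)
            new[1:-1] = c[1:-1] + lam * (c[:-2] - 2.0 * c[1:-1] + c[2:]) - kd * c[1:-1]
            new[0] = c[0] + 2.0 * lam * (c[1] - c[0]) + influx - kd * c[0]
            new[-1] = c[-1] + 2.0 * lam * (c[-2] - c[-1]) - kd * c[-1]
            c = new
        if np.any(~np.isfinite(c)):
            raise NumericError("transient solve diverged; check stability inputs")
    return DensityField(grid=grid, values=c, time=float(t_end))
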