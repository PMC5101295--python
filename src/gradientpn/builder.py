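"""Construction of the gradient-formation PTA-net.

The net discretizes the 1-D reaction-diffusion equation

    dC/dt = D d2C/dr2 - k C

on a row of ``n`` cells of length ``l`` and height ``h``, with constant
influx areal density ``J0`` at the left boundary and zero flux at the right.
Cell places ``x1..xn`` hold token counts ``m_i ~ h * integral of C`` over
cell ``i``.  Production, transport and degradation happen in a 5-phase
cycle, scheduled by a ring of control places ``w1..w5`` (one token cycling)
and activator arcs:

1. counters ``x'_i`` / ``x''_i`` are filled with ``round(p*D*dt) * m(x_i)``
   tokens by auto-concurrent transitions ``c_i`` (weight-1 self-loop on
   ``x_i`` caps the auto-concurrency at ``m(x_i)``); residual counter tokens
   from the previous cycle are drained by ``e'_i`` / ``e''_i``; if the
   source toggle ``f`` is marked, ``s`` emits ``round(J0*h*dt)`` tokens
   into ``x1``;
2. ``d_i`` cancels counter tokens pairwise, leaving the scaled difference
   ``alpha_i = round(p*D*dt) * (m(x_i) - m(x_{i+1}))`` in ``x'_i``;
3. ``t'_i`` moves one token from ``x_i`` to ``x_{i+1}`` per ``round(p*l^2)``
   tokens in ``x'_i`` — i.e. ``floor(alpha_i / (p*l^2))`` tokens, the
   discrete diffusion flux ``(D*dt/l^2)(m_i - m_{i+1})``;
4. ``g_i`` fills ``r_i`` with ``round(b*k*dt) * m(x_i)`` tokens (``q_i``
   drains residuals);
5. ``g'_i`` removes one token from ``x_i`` per ``b`` tokens in ``r_i`` —
   the degradation loss ``floor(k*dt * m_i)``.

The scalers ``p`` and ``b`` control rounding accuracy: arc weights must be
natural numbers, and ``p*D*dt``, ``b*k*dt`` are rounded once, at the weight
level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import AccuracyWarning, InputError, ParameterError
from .pta import Marking, PTANet

__all__ = [
    "GradientParams",
    "ScaledWeights",
    "GradientNet",
    "scaled_weights",
    "build_gradient_net",
    "initial_marking",
]

STEPS_PER_CYCLE = 5


@dataclass(frozen=True)
class GradientParams:
    """Physical and numerical parameters of the gradient model.

    Attributes
    ----------
    n : int
        Number of cells (places ``x1..xn``); at least 2.
    D : float
        Effective diffusion coefficient, µm²/s (passive diffusion plus
        endocytosis-mediated transport, lumped).
    k : float
        First-order degradation rate, 1/s.
    J0 : float
        Influx areal density at the source boundary, molecules/(µm·s);
        ``J0*h*dt`` tokens enter cell 1 per cycle.
    ell, h : float
        Cell length and height, µm.
    dt : float
        Time step per 5-phase cycle, s.
    p, b : int
        Accuracy scalers for the transport and degradation weights.
    source_on : bool
        Whether the source toggle place ``f`` is initially marked.
    """

    n: int
    D: float
    k: float
    J0: float
    ell: float
    h: float
    dt: float
    p: int = 100
    b: int = 100_000
    source_on: bool = True
    steps_per_cycle: int = field(default=STEPS_PER_CYCLE, repr=False)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError(f"need at least two cells, got n={self.n}")
        if self.D < 0 or self.k < 0 or self.J0 < 0:
            raise ParameterError("D, k and J0 must be non-negative")
        if self.ell <= 0 or self.h <= 0 or self.dt <= 0:
            raise ParameterError("ell, h and dt must be positive")
        if self.p < 1 or self.b < 1:
            raise ParameterError("accuracy scalers p and b must be >= 1")
        if self.steps_per_cycle != STEPS_PER_CYCLE:
            raise ParameterError("the gradient cycle has exactly 5 phases")
        self.check_stability()

    # -- derived quantities ----------------------------------------------------
    @property
    def area(self) -> float:
        """Cell area A = l*h in the plane of observation, µm²."""
        return self.ell * self.h

    @property
    def length(self) -> float:
        """Tissue length L = n*l, µm."""
        return self.n * self.ell

    @property
    def mu(self) -> float:
        """Inverse decay length sqrt(k/D), 1/µm."""
        if self.D <= 0:
            raise ParameterError("mu undefined for D <= 0")
        return math.sqrt(self.k / self.D)

    def check_stability(self) -> None:
        """Explicit-scheme stability: D*dt/l^2 < 1 and k*dt < 1."""
        ratio = self.D * self.dt / self.ell**2
        if ratio >= 1.0:
            raise ParameterError(
                f"stability violated: D*dt/l^2 = {ratio:.3g} >= 1 (reduce dt)"
            )
        if self.k * self.dt >= 1.0:
            raise ParameterError(
                f"stability violated: k*dt = {self.k * self.dt:.3g} >= 1 (reduce dt)"
            )
        if ratio > 0.5:
            warnings.warn(
                f"D*dt/l^2 = {ratio:.3g} > 1/2: the explicit update can "
                "oscillate; accuracy is degraded",
                AccuracyWarning,
                stacklevel=2,
            )

    def with_(self, **kwargs) -> "GradientParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ScaledWeights:
    """Integer arc weights derived from :class:`GradientParams`.

    ``w_fill = round(p*D*dt)`` tokens per counter-fill firing,
    ``w_move_cost = round(p*l^2)`` counter tokens per transported token,
    ``w_deg_fill = round(b*k*dt)`` tokens per degradation-counter firing,
    ``w_deg_cost = b`` counter tokens per degraded token,
    ``w_source = round(J0*h*dt)`` tokens emitted by the source per cycle.
    """

    w_fill: int
    w_move_cost: int
    w_deg_fill: int
    w_deg_cost: int
    w_source: int

    def __post_init__(self) -> None:
        for name in ("w_fill", "w_move_cost", "w_deg_fill", "w_deg_cost", "w_source"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be a natural number")
        if self.w_move_cost < 1 or self.w_deg_cost < 1:
            raise ParameterError("w_move_cost and w_deg_cost must be >= 1")


def scaled_weights(params: GradientParams) -> ScaledWeights:
    """Derive the five integer arc weights from the PDE-level constants.

    Emits an :class:`AccuracyWarning` when rounding annihilates a positive
    rate (``round(p*D*dt) == 0`` with ``D > 0``, or ``round(b*k*dt) == 0``
    with ``k > 0``): increase the corresponding scaler.
    """
    params.check_stability()
    w_fill = round(params.p * params.D * params.dt)
    w_move_cost = round(params.p * params.ell**2)
    w_deg_fill = round(params.b * params.k * params.dt)
    w_source = round(params.J0 * params.h * params.dt)
    if params.D > 0 and w_fill == 0:
        warnings.warn(
            "round(p*D*dt) = 0 although D > 0: transport is lost to rounding; "
            "increase p",
            AccuracyWarning,
            stacklevel=2,
        )
    if params.k > 0 and w_deg_fill == 0:
        warnings.warn(
            "round(b*k*dt) = 0 although k > 0: degradation is lost to rounding; "
            "increase b",
            AccuracyWarning,
            stacklevel=2,
        )
    return ScaledWeights(
        w_fill=w_fill,
        w_move_cost=w_move_cost,
        w_deg_fill=w_deg_fill,
        w_deg_cost=params.b,
        w_source=w_source,
    )


@dataclass(frozen=True)
class GradientNet:
    """The constructed gradient net plus its bookkeeping identifiers."""

    net: PTANet
    cell_places: tuple[str, ...]
    phase_places: tuple[str, ...]
    source_place: str
    counter_places: tuple[str, ...]
    weights: ScaledWeights
    params: GradientParams

    @property
    def transport_transitions(self) -> tuple[str, ...]:
        return tuple(f"tp{i}" for i in range(1, self.params.n))

    @property
    def degradation_transitions(self) -> tuple[str, ...]:
        return tuple(f"gp{i}" for i in range(1, self.params.n + 1))


def cell_place(i: int) -> str:
    return f"x{i}"


def build_gradient_net(
    params: GradientParams,
    profile: Callable[[float], float] | Sequence[int] | None = None,
) -> GradientNet:
    """Build the complete conflict-free gradient net.

    For ``n`` cells the net has ``4n + 4`` places (``n`` cells, ``n-1``
    each of ``x'``/``x''`` counters, ``n`` degradation counters ``r``, five
    phase places, the source toggle ``f``) and ``8n + 2`` transitions.

    ``profile`` seeds the initial cell contents (see :func:`initial_marking`);
    by default all cells start empty.
    """
    w = scaled_weights(params)
    n = params.n
    weight: dict[tuple[str, str], int] = {}
    activators: set[tuple[str, str]] = set()
    places: set[str] = {"f"}
    transitions: set[str] = set()

    def arc(src: str, dst: str, wt: int) -> None:
        if wt:
            weight[(src, dst)] = wt

    # control ring: one token hops w1 -> w2 -> ... -> w5 -> w1
    for j in range(1, 6):
        places.add(f"w{j}")
        tick = f"u{j}"
        transitions.add(tick)
        arc(f"w{j}", tick, 1)
        arc(tick, f"w{j % 5 + 1}", 1)

    for i in range(1, n + 1):
        places.add(cell_place(i))
        places.add(f"r{i}")
    for i in range(1, n):
        places.add(f"xp{i}")      # x'_i,  i = 1..n-1
        places.add(f"xpp{i+1}")   # x''_i, i = 2..n

    # phase 1: counter fill (c_i), residual drains (e'_i, e''_i), source (s)
    for i in range(1, n + 1):
        c = f"c{i}"
        transitions.add(c)
        arc(cell_place(i), c, 1)
        arc(c, cell_place(i), 1)          # self-loop caps auto-concurrency at m(x_i)
        if i < n:
            arc(c, f"xp{i}", w.w_fill)
        if i > 1:
            arc(c, f"xpp{i}", w.w_fill)
        activators.add(("w1", c))
    for i in range(1, n):
        ep = f"ep{i}"
        transitions.add(ep)
        arc(f"xp{i}", ep, 1)
        activators.add(("w1", ep))
    for i in range(2, n + 1):
        epp = f"epp{i}"
        transitions.add(epp)
        arc(f"xpp{i}", epp, 1)
        activators.add(("w1", epp))
    transitions.add("s")
    arc("f", "s", 1)
    arc("s", "f", 1)                      # self-loop: s fires exactly once
    arc("s", cell_place(1), w.w_source)
    activators.add(("w1", "s"))

    # phase 2: pairwise cancellation d_i
    for i in range(1, n):
        d = f"d{i}"
        transitions.add(d)
        arc(f"xp{i}", d, 1)
        arc(f"xpp{i+1}", d, 1)
        activators.add(("w2", d))

    # phase 3: transport t'_i
    for i in range(1, n):
        tp = f"tp{i}"
        transitions.add(tp)
        arc(f"xp{i}", tp, w.w_move_cost)
        arc(cell_place(i), tp, 1)
        arc(tp, cell_place(i + 1), 1)
        activators.add(("w3", tp))

    # phase 4: degradation-counter fill g_i, residual drain q_i
    for i in range(1, n + 1):
        g = f"g{i}"
        transitions.add(g)
        arc(cell_place(i), g, 1)
        arc(g, cell_place(i), 1)
        arc(g, f"r{i}", w.w_deg_fill)
        activators.add(("w4", g))
        q = f"q{i}"
        transitions.add(q)
        arc(f"r{i}", q, 1)
        activators.add(("w4", q))

    # phase 5: degradation g'_i
    for i in range(1, n + 1):
        gp = f"gp{i}"
        transitions.add(gp)
        arc(f"r{i}", gp, w.w_deg_cost)
        arc(cell_place(i), gp, 1)
        activators.add(("w5", gp))

    m0 = initial_marking(params, profile)
    net = PTANet(
        places=frozenset(places),
        transitions=frozenset(transitions),
        weight=weight,
        activators=frozenset(activators),
        initial_marking=m0,
    )
    counter = tuple(
        [f"xp{i}" for i in range(1, n)]
        + [f"xpp{i}" for i in range(2, n + 1)]
        + [f"r{i}" for i in range(1, n + 1)]
    )
    return GradientNet(
        net=net,
        cell_places=tuple(cell_place(i) for i in range(1, n + 1)),
        phase_places=tuple(f"w{j}" for j in range(1, 6)),
        source_place="f",
        counter_places=counter,
        weights=w,
        params=params,
    )


def initial_marking(
    params: GradientParams,
    profile: Callable[[float], float] | Sequence[int] | None = None,
) -> Marking:
    """Initial marking: control token on ``w1``, source toggle per
    ``params.source_on``, counters empty, cells per ``profile``.

    ``profile`` may be a density ``C(r, 0)`` on ``[0, n*l]`` (cell ``i``
    then receives ``round(l*h * (C((i-1)l) + C(il)) / 2)`` tokens, the
    trapezium count), an explicit sequence of ``n`` non-negative integers,
    or ``None`` (empty cells).
    """
    counts: dict[str, int] = {"w1": 1}
    if params.source_on:
        counts["f"] = 1
    if profile is None:
        cells = [0] * params.n
    elif callable(profile):
        cells = []
        for i in range(1, params.n + 1):
            lo = profile((i - 1) * params.ell)
            hi = profile(i * params.ell)
            if lo < 0 or hi < 0:
                raise InputError(f"initial density is negative near cell {i}")
            cells.append(round(params.area * 0.5 * (lo + hi)))
    else:
        cells = [int(v) for v in profile]
        if len(cells) != params.n:
            raise InputError(f"expected {params.n} cell counts, got {len(cells)}")
        if any(v < 0 for v in cells):
            raise InputError("initial cell counts must be non-negative")
        if any(v != float(orig) for v, orig in zip(cells, profile)):
            raise InputError("explicit cell counts must be integers")
    for i, c in enumerate(cells, start=1):
        if c:
            counts[cell_place(i)] = c
    return Marking(counts)


def cell_counts(marking: Marking, n: int) -> np.ndarray:
    """Cell-place token counts as an integer vector."""
    return np.array([marking[cell_place(i)] for i in range(1, n + 1)], dtype=np.int64)
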