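"""Place/Transition nets with activator arcs (PTA-nets) under maximally
concurrent step semantics.

A PTA-net is a tuple ``(P, T, W, Act, m0)``: finite disjoint sets of places
and transitions, a natural-number weight function on ``(P x T) u (T x P)``,
a set of activator arcs ``Act`` in ``P x T``, and an initial marking.  A
*step* is a multiset of transitions.  A step ``U`` is enabled at marking
``m`` iff for every place ``p``

    m(p) >= sum_t U(t) * W(p, t)

and ``m(p) >= 1`` for every place tested through an activator arc by a
transition occurring in ``U``.  Activator arcs test *a priori*: enabledness
is judged entirely on the pre-step marking, so tokens produced within the
same step never help (nor hurt) enabling.  Executing ``U`` yields

    m'(p) = m(p) + sum_t U(t) * (W(t, p) - W(p, t)).

A step is *max-enabled* when no further transition occurrence can be added
without losing enabledness.  The engine is fully deterministic: on
conflict-free markings the maximal step is unique; otherwise a greedy policy
(transitions in sorted identifier order, each taken at its maximal
admissible multiplicity) is applied and a :class:`ConflictWarning` is
emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import ConflictWarning, EnablingError, StructuralError

__all__ = [
    "Marking",
    "Step",
    "PTANet",
    "CompiledNet",
    "is_enabled",
    "execute_step",
    "maximal_step",
    "run_steps",
]


class _NatMap(Mapping[str, int]):
    """Sparse mapping identifier -> natural number; absent means 0."""

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        data = dict(counts)
        for key, val in data.items():
            if not isinstance(val, (int, np.integer)) or val < 0:
                raise ValueError(f"count for {key!r} must be a natural number, got {val!r}")
        # drop explicit zeros to keep the sparse invariant
        self._counts: dict[str, int] = {k: int(v) for k, v in data.items() if v}

    def __getitem__(self, key: str) -> int:
        return self._counts.get(key, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, _NatMap):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}: {v}" for k, v in sorted(self._counts.items()))
        return f"{type(self).__name__}({{{inner}}})"

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self._counts)

    def total(self) -> int:
        return sum(self._counts.values())


class Marking(_NatMap):
    """Global state: tokens per place (sparse, absent place = 0 tokens)."""


class Step(_NatMap):
    """Multiset of transitions occurring simultaneously.

    ``step[t]`` is the multiplicity of ``t`` (auto-concurrency when > 1).
    """

    def is_empty(self) -> bool:
        return not self._counts


@dataclass(frozen=True)
class PTANet:
    """A PTA-net ``(P, T, W, Act, m0)``.

    Parameters
    ----------
    places, transitions
        Finite, disjoint identifier sets.
    weight
        Map from ``(source, target)`` pairs to positive integer weights;
        absent pairs have weight 0.  Each pair must connect a place and a
        transition (either direction).
    activators
        Set of ``(place, transition)`` activator arcs.
    initial_marking
        The initial marking ``m0``.
    """

    places: frozenset[str]
    transitions: frozenset[str]
    weight: Mapping[tuple[str, str], int]
    activators: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    initial_marking: Marking = field(default_factory=Marking)

    def __post_init__(self) -> None:
        object.__setattr__(self, "places", frozenset(self.places))
        object.__setattr__(self, "transitions", frozenset(self.transitions))
        object.__setattr__(self, "activators", frozenset(self.activators))
        if not isinstance(self.initial_marking, Marking):
            object.__setattr__(self, "initial_marking", Marking(self.initial_marking))
        if self.places & self.transitions:
            raise StructuralError(
                f"places and transitions overlap: {sorted(self.places & self.transitions)}"
            )
        weight = {pair: int(w) for pair, w in dict(self.weight).items() if w}
        object.__setattr__(self, "weight", weight)
        has_input: set[str] = set()
        for (src, dst), w in weight.items():
            if w < 0:
                raise StructuralError(f"negative weight on arc {src!r}->{dst!r}")
            if src in self.places and dst in self.transitions:
                has_input.add(dst)
            elif src in self.transitions and dst in self.places:
                pass
            else:
                raise StructuralError(f"arc {src!r}->{dst!r} does not connect a place and a transition")
        for place, trans in self.activators:
            if place not in self.places or trans not in self.transitions:
                raise StructuralError(f"activator arc ({place!r},{trans!r}) uses unknown identifiers")
        missing = self.transitions - has_input
        if missing:
            raise StructuralError(
                f"every transition needs at least one input place; missing for {sorted(missing)}"
            )
        unknown = self.initial_marking.support - self.places
        if unknown:
            raise StructuralError(f"initial marking mentions unknown places {sorted(unknown)}")

    # -- convenience accessors -------------------------------------------------
    def w(self, src: str, dst: str) -> int:
        return self.weight.get((src, dst), 0)

    def pre_places(self, t: str) -> dict[str, int]:
        """Input places of ``t`` with their consumption weights."""
        return {p: w for (p, tt), w in self.weight.items() if tt == t and p in self.places}

    def post_places(self, t: str) -> dict[str, int]:
        return {p: w for (tt, p), w in self.weight.items() if tt == t and p in self.places}


def _check_ids(net: PTANet, m: Marking, u: Step | None = None) -> None:
    unknown_p = m.support - net.places
    if unknown_p:
        raise StructuralError(f"marking mentions unknown places {sorted(unknown_p)}")
    if u is not None:
        unknown_t = u.support - net.transitions
        if unknown_t:
            raise StructuralError(f"step mentions unknown transitions {sorted(unknown_t)}")


def is_enabled(net: PTANet, m: Marking, u: Step) -> bool:
    """Whether step ``u`` is enabled at marking ``m`` (a-priori semantics)."""
    _check_ids(net, m, u)
    demand: dict[str, int] = {}
    for t, mult in u.items():
        for p, w in net.pre_places(t).items():
            demand[p] = demand.get(p, 0) + mult * w
    for p, need in demand.items():
        if m[p] < need:
            return False
    for place, trans in net.activators:
        if u[trans] >= 1 and m[place] < 1:
            return False
    return True


def execute_step(net: PTANet, m: Marking, u: Step) -> Marking:
    """Execute an enabled step, returning the successor marking.

    Raises
    ------
    EnablingError
        If ``u`` is not enabled at ``m``.
    """
    if not is_enabled(net, m, u):
        raise EnablingError(f"step {dict(u)!r} is not enabled at the given marking")
    delta: dict[str, int] = {}
    for t, mult in u.items():
        for p, w in net.pre_places(t).items():
            delta[p] = delta.get(p, 0) - mult * w
        for p, w in net.post_places(t).items():
            delta[p] = delta.get(p, 0) + mult * w
    new = dict(m)
    for p, d in delta.items():
        new[p] = new.get(p, 0) + d
    return Marking(new)


def _solo_max(net: PTANet, m: Marking, t: str) -> int:
    """Maximal multiplicity of ``t`` alone at ``m`` (0 if activator-blocked)."""
    for place, trans in net.activators:
        if trans == t and m[place] < 1:
            return 0
    best: int | None = None
    for p, w in net.pre_places(t).items():
        cap = m[p] // w
        best = cap if best is None else min(best, cap)
    return 0 if best is None else best


def maximal_step(net: PTANet, m: Marking) -> Step:
    """A max-enabled step at ``m``.

    Each transition is first assigned its maximal admissible multiplicity as
    if it fired alone; if the joint token demand fits the marking (always the
    case on conflict-free markings) that assignment *is* a maximal step, and
    it coincides with the greedy result.  Otherwise the step is rebuilt
    greedily in sorted transition order and a :class:`ConflictWarning` is
    emitted, because a different order could have produced a different
    (equally maximal) step.
    """
    _check_ids(net, m)
    solo = {t: _solo_max(net, m, t) for t in net.transitions}
    demand: dict[str, int] = {}
    for t, mult in solo.items():
        if mult:
            for p, w in net.pre_places(t).items():
                demand[p] = demand.get(p, 0) + mult * w
    if all(m[p] >= need for p, need in demand.items()):
        return Step({t: k for t, k in solo.items() if k})
    # conflict: greedy in fixed identifier order.  Token consumption is
    # tracked against the shrinking remainder, but activator arcs keep
    # testing the *pre-step* marking (a-priori semantics).
    warnings.warn(
        "transitions compete for tokens; greedy policy in sorted order applied",
        ConflictWarning,
        stacklevel=2,
    )
    remaining = dict(m)
    step: dict[str, int] = {}
    for t in sorted(net.transitions):
        if any(trans == t and m[place] < 1 for place, trans in net.activators):
            continue
        caps = [remaining.get(p, 0) // w for p, w in net.pre_places(t).items()]
        mult = min(caps) if caps else 0
        if mult > 0:
            step[t] = mult
            for p, w in net.pre_places(t).items():
                remaining[p] = remaining.get(p, 0) - mult * w
    return Step(step)


def run_steps(net: PTANet, m: Marking, n_steps: int) -> list[tuple[Step, Marking]]:
    """Iterate max-enabled steps from ``m``.

    Returns the trace ``[(U1, m1), ..., (Uk, mk)]`` with ``k <= n_steps``;
    the trace ends early when only the empty step is enabled (the formal
    step-sequence definition admits only non-empty steps).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    trace: list[tuple[Step, Marking]] = []
    current = m
    for _ in range(n_steps):
        u = maximal_step(net, current)
        if u.is_empty():
            break
        current = execute_step(net, current, u)
        trace.append((u, current))
    return trace


class CompiledNet:
    """Array-compiled form of a :class:`PTANet` for long runs.

    Semantics are identical to the mapping-based operations; only the data
    layout changes (flat arc arrays, integer marking vector).  Used by the
    gradient simulator, where a run is ~10^5 maximal steps on a net with a
    few hundred arcs.
    """

    _BIG = np.int64(2**62)

    def __init__(self, net: PTANet):
        self.net = net
        self.place_ids = sorted(net.places)
        self.trans_ids = sorted(net.transitions)
        self.p_index = {p: i for i, p in enumerate(self.place_ids)}
        self.t_index = {t: i for i, t in enumerate(self.trans_ids)}
        in_p, in_t, in_w, out_p, out_t, out_w = [], [], [], [], [], []
        for (src, dst), w in net.weight.items():
            if src in net.places:
                in_p.append(self.p_index[src])
                in_t.append(self.t_index[dst])
                in_w.append(w)
            else:
                out_t.append(self.t_index[src])
                out_p.append(self.p_index[dst])
                out_w.append(w)
        self.in_p = np.asarray(in_p, dtype=np.int64)
        self.in_t = np.asarray(in_t, dtype=np.int64)
        self.in_w = np.asarray(in_w, dtype=np.int64)
        self.out_p = np.asarray(out_p, dtype=np.int64)
        self.out_t = np.asarray(out_t, dtype=np.int64)
        self.out_w = np.asarray(out_w, dtype=np.int64)
        act_p = [self.p_index[p] for p, _ in net.activators]
        act_t = [self.t_index[t] for _, t in net.activators]
        self.act_p = np.asarray(act_p, dtype=np.int64)
        self.act_t = np.asarray(act_t, dtype=np.int64)
        self.n_places = len(self.place_ids)
        self.n_trans = len(self.trans_ids)

    def marking_vector(self, m: Marking) -> np.ndarray:
        vec = np.zeros(self.n_places, dtype=np.int64)
        for p, c in m.items():
            vec[self.p_index[p]] = c
        return vec

    def marking_from_vector(self, vec: np.ndarray) -> Marking:
        return Marking({p: int(vec[i]) for p, i in self.p_index.items() if vec[i]})

    def maximal_step_vector(self, m_vec: np.ndarray) -> tuple[np.ndarray, bool]:
        """Maximal-step multiplicities and a conflict flag."""
        mult = np.full(self.n_trans, self._BIG, dtype=np.int64)
        np.minimum.at(mult, self.in_t, m_vec[self.in_p] // self.in_w)
        if self.act_t.size:
            np.minimum.at(
                mult, self.act_t, np.where(m_vec[self.act_p] >= 1, self._BIG, 0)
            )
        mult[mult == self._BIG] = 0  # unreachable: every transition has inputs
        demand = np.zeros(self.n_places, dtype=np.int64)
        np.add.at(demand, self.in_p, mult[self.in_t] * self.in_w)
        conflict = bool(np.any(demand > m_vec))
        if conflict:
            # greedy fallback in sorted identifier order (rare; the gradient
            # net never reaches this branch)
            step = maximal_step(self.net, self.marking_from_vector(m_vec))
            mult = np.zeros(self.n_trans, dtype=np.int64)
            for t, k in step.items():
                mult[self.t_index[t]] = k
        return mult, conflict

    def apply_step_vector(self, m_vec: np.ndarray, mult: np.ndarray) -> np.ndarray:
        new = m_vec.copy()
        np.subtract.at(new, self.in_p, mult[self.in_t] * self.in_w)
        np.add.at(new, self.out_p, mult[self.out_t] * self.out_w)
        return new

    def step(self, m_vec: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
        """One maximal step: returns (multiplicities, new marking, conflict)."""
        mult, conflict = self.maximal_step_vector(m_vec)
        return mult, self.apply_step_vector(m_vec, mult), conflict
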