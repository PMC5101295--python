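"""Gradient-net simulation, steady-state detection, and validation against
the reaction-diffusion references (Dpp case study).

A *cycle* is five maximal steps of the net (one pass through the phase
ring).  Cell-place counts are recorded at every cycle boundary; the marking
at cycle ``j`` corresponds to time ``t_j = j * dt``.

The case study reproduces gradient formation of Decapentaplegic (Dpp) in
the *Drosophila* wing disc, in two FRAP-derived parameter regimes:

* ``Dpp``         — control at 32 °C: D = 0.10 µm²/s, k = 2.52e-4 1/s
* ``Dpp-rescue``  — *shibire* endocytosis mutant with rescued source:
                    D = 0.06 µm²/s, k = 1.53e-4 1/s

with n = 30 cells, l = h = 2.6 µm, accuracy scalers p = 10² and b = 10⁵.
The influx scale J0 and the cycle step dt are free numerical choices,
documented in docs/methods.md: J0 = 10⁴ molecules/(µm·s) makes single-token
quantization negligible, and dt (5 s for Dpp, 20 s for Dpp-rescue) balances
the scheme's two discretization biases.  Deviation statistics are relative,
hence insensitive to the J0 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .builder import (
    GradientNet,
    GradientParams,
    build_gradient_net,
    cell_counts,
)
from .errors import GradientPNError, InputError, SteadyStateTimeout
from .pta import CompiledNet
from .reference import (
    CellState,
    CycleTrace,
    DensityField,
    counts_from_density,
    solve_transient,
    steady_state_finite,
)

__all__ = [
    "Trajectory",
    "DeviationReport",
    "CASE_STUDIES",
    "simulate_gradient",
    "detect_steady_state",
    "deviation_metrics",
    "run_case_study",
]

#: Case-study parameter sets.  D and k are the FRAP estimates; dt and J0 are
#: this package's numerical defaults (see docs/methods.md).
CASE_STUDIES: dict[str, GradientParams] = {
    "Dpp": GradientParams(
        n=30, D=0.10, k=2.52e-4, J0=1e4, ell=2.6, h=2.6, dt=5.0, p=100, b=100_000
    ),
    "Dpp-rescue": GradientParams(
        n=30, D=0.06, k=1.53e-4, J0=1e4, ell=2.6, h=2.6, dt=20.0, p=100, b=100_000
    ),
}

#: Comparison times for the transient validation, seconds.
TRANSIENT_TIMES = (600.0, 2400.0)

#: Paper-reported deviation bounds used by the CLI ``validate`` exit status.
VALIDATION_BOUNDS = {
    "Dpp": {"steady_max": 0.2, "transient_max": 0.46},
    "Dpp-rescue": {"steady_max": 1.4, "transient_max": 0.2},
}


@dataclass
class Trajectory:
    """Cycle-boundary cell counts of a gradient-net run."""

    params: GradientParams
    counts: np.ndarray          # shape (n_cycles + 1, n); row 0 = initial
    traces: list[CycleTrace] | None = None
    conflict: bool = False

    @property
    def n_cycles(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.counts.shape[0]) * self.params.dt

    def at_time(self, t: float) -> np.ndarray:
        """Cell counts at time ``t`` (must be a recorded cycle boundary)."""
        j = t / self.params.dt
        if abs(j - round(j)) > 1e-9:
            raise InputError(f"t={t} is not a multiple of dt={self.params.dt}")
        j = round(j)
        if j >= self.counts.shape[0]:
            raise InputError(f"trajectory has {self.n_cycles} cycles, t={t} needs {j}")
        return self.counts[j]


@dataclass
class DeviationReport:
    """Relative deviations between net counts and a reference, in percent.

    ``denominator`` is either ``"local"`` (each cell's own reference count)
    or ``"amplitude"`` (the maximum reference count, i.e. the gradient
    amplitude).  ``per_cell`` rows are indexed like ``times``.
    """

    reference: str
    denominator: str
    times: tuple[float, ...]
    per_cell: np.ndarray        # shape (len(times), n), NaN where undefined
    max_dev: float
    mean_dev: float
    per_time_max: tuple[float, ...] = ()
    per_time_mean: tuple[float, ...] = ()


def simulate_gradient(
    params: GradientParams,
    n_cycles: int,
    record_traces: bool = False,
    stop_when_fixed: bool = False,
    gnet: GradientNet | None = None,
) -> Trajectory:
    """Run the gradient net for ``n_cycles`` 5-step cycles.

    The run is fully deterministic.  ``stop_when_fixed`` ends the run early
    at the first cycle whose boundary marking of the cell places equals the
    previous one exactly (the steady-state criterion).

    Raises
    ------
    GradientPNError
        If the engine flags a token conflict — the gradient net is
        conflict-free by construction, so this indicates an internal error.
    """
    if n_cycles < 0:
        raise InputError("n_cycles must be >= 0")
    if gnet is None:
        gnet = build_gradient_net(params)
    compiled = CompiledNet(gnet.net)
    m = compiled.marking_vector(gnet.net.initial_marking)
    cell_idx = np.array([compiled.p_index[p] for p in gnet.cell_places])
    tp_idx = np.array(
        [compiled.t_index[t] for t in gnet.transport_transitions], dtype=np.int64
    )
    gp_idx = np.array(
        [compiled.t_index[t] for t in gnet.degradation_transitions], dtype=np.int64
    )
    xp_idx = np.array(
        [compiled.p_index[f"xp{i}"] for i in range(1, params.n)], dtype=np.int64
    )
    rows = [m[cell_idx].copy()]
    traces: list[CycleTrace] | None = [] if record_traces else None
    for _ in range(n_cycles):
        alpha = beta = delta = None
        source_in = 0
        for phase in range(1, 6):
            mult, m_new, conflict = compiled.step(m)
            if conflict:
                raise GradientPNError(
                    "token conflict inside the gradient net; construction broken"
                )
            if record_traces:
                if phase == 1:
                    source_in = int(mult[compiled.t_index["s"]]) * gnet.weights.w_source
                elif phase == 2:
                    alpha = m_new[xp_idx].copy()
                elif phase == 3:
                    beta = mult[tp_idx].copy()
                elif phase == 5:
                    delta = mult[gp_idx].copy()
            m = m_new
        rows.append(m[cell_idx].copy())
        if record_traces:
            traces.append(
                CycleTrace(alpha=alpha, beta=beta, delta=delta, source_in=source_in)
            )
        if stop_when_fixed and np.array_equal(rows[-1], rows[-2]):
            break
    return Trajectory(params=params, counts=np.array(rows), traces=traces)


def detect_steady_state(traj: Trajectory, tol: int = 0) -> int | None:
    """First cycle index ``j >= 1`` whose counts match cycle ``j - 1``.

    With ``tol = 0`` (the default) matching means exact integer equality of
    every cell place, the criterion for a deterministic net.  ``tol >= 1``
    tolerates a small flicker: integer rounding can lock the net into a
    period-2 oscillation in which single tokens shuttle between neighbor
    cells forever.  To avoid firing during slow monotone relaxation (where
    per-cycle changes also pass through ±1), the tolerant mode additionally
    requires the period-2 condition ``counts[j] == counts[j-2]`` exactly.
    Returns ``None`` when no such cycle exists.
    """
    if traj.counts.shape[0] < 2:
        raise InputError("trajectory must contain at least one executed cycle")
    counts = traj.counts.astype(np.int64)
    diffs = np.abs(np.diff(counts, axis=0)).max(axis=1)
    if tol == 0:
        hits = np.nonzero(diffs == 0)[0]
        return int(hits[0]) + 1 if hits.size else None
    for j in range(2, counts.shape[0]):
        if diffs[j - 1] <= tol and np.array_equal(counts[j], counts[j - 2]):
            return j
    return None


def deviation_metrics(
    petri: CellState | np.ndarray,
    reference: CellState | np.ndarray,
    denominator: str = "local",
    reference_name: str = "reference",
    time: float = 0.0,
) -> DeviationReport:
    """Relative deviations (percent) between net counts and a reference.

    ``denominator="local"`` divides each cell's absolute deviation by that
    cell's reference count; cells whose reference is exactly zero are
    excluded (NaN) with a warning when the net count is nonzero there.
    ``denominator="amplitude"`` divides by the maximum reference count,
    which stays meaningful for cells holding fewer tokens than one molecule
    of reference mass (e.g. ahead of a spreading front).
    """
    pet = petri.counts if isinstance(petri, CellState) else np.asarray(petri)
    ref = reference.counts if isinstance(reference, CellState) else np.asarray(reference)
    if pet.shape != ref.shape:
        raise InputError("petri and reference vectors differ in length")
    pet = pet.astype(float)
    ref = ref.astype(float)
    abs_dev = np.abs(pet - ref)
    if denominator == "local":
        with np.errstate(divide="ignore", invalid="ignore"):
            per_cell = np.where(ref > 0, abs_dev / ref * 100.0, np.nan)
        excluded = (ref == 0) & (pet != 0)
        if np.any(excluded):
            warnings.warn(
                f"{int(excluded.sum())} cell(s) excluded: reference is zero but "
                "the net holds tokens there (deviation undefined)",
                UserWarning,
                stacklevel=2,
            )
    elif denominator == "amplitude":
        amp = ref.max()
        if amp <= 0:
            raise InputError("reference amplitude is zero; deviations undefined")
        per_cell = abs_dev / amp * 100.0
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    finite = per_cell[np.isfinite(per_cell)]
    max_dev = float(finite.max()) if finite.size else 0.0
    mean_dev = float(finite.mean()) if finite.size else 0.0
    return DeviationReport(
        reference=reference_name,
        denominator=denominator,
        times=(time,),
        per_cell=per_cell[None, :],
        max_dev=max_dev,
        mean_dev=mean_dev,
        per_time_max=(max_dev,),
        per_time_mean=(mean_dev,),
    )


def _aggregate(reports: Sequence[DeviationReport]) -> DeviationReport:
    """Pool single-time reports into one multi-time report."""
    if not reports:
        raise InputError("nothing to aggregate")
    per_cell = np.vstack([r.per_cell for r in reports])
    finite = per_cell[np.isfinite(per_cell)]
    return DeviationReport(
        reference=reports[0].reference,
        denominator=reports[0].denominator,
        times=tuple(t for r in reports for t in r.times),
        per_cell=per_cell,
        max_dev=float(finite.max()),
        mean_dev=float(finite.mean()),
        per_time_max=tuple(r.max_dev for r in reports),
        per_time_mean=tuple(r.mean_dev for r in reports),
    )


@dataclass
class CaseStudyResult:
    """Everything :func:`run_case_study` measures for one condition."""

    condition: str
    params: GradientParams
    trajectory: Trajectory
    steady_cycle: int
    steady_exact: bool
    steady_counts: np.ndarray
    steady_local: DeviationReport
    steady_amplitude: DeviationReport
    transient_amplitude: DeviationReport
    transient_local: DeviationReport

    def summary(self) -> dict:
        """Plain-data report (JSON-serializable)."""
        return {
            "condition": self.condition,
            "params": {
                "n": self.params.n,
                "D": self.params.D,
                "k": self.params.k,
                "J0": self.params.J0,
                "ell": self.params.ell,
                "h": self.params.h,
                "dt": self.params.dt,
                "p": self.params.p,
                "b": self.params.b,
            },
            "steady_state_cycle": self.steady_cycle,
            "steady_state_time_s": self.steady_cycle * self.params.dt,
            "steady_state_exact": self.steady_exact,
            "deviations": {
                "steady": {
                    "reference": "closed-form finite-domain steady state",
                    "local": {
                        "max": self.steady_local.max_dev,
                        "mean": self.steady_local.mean_dev,
                        "per_cell": self.steady_local.per_cell[0].tolist(),
                    },
                    "amplitude": {
                        "max": self.steady_amplitude.max_dev,
                        "mean": self.steady_amplitude.mean_dev,
                    },
                },
                "transient": {
                    "reference": "refined finite-difference transient solution",
                    "times_s": list(self.transient_amplitude.times),
                    "amplitude": {
                        "max": self.transient_amplitude.max_dev,
                        "mean": self.transient_amplitude.mean_dev,
                        "per_time_max": list(self.transient_amplitude.per_time_max),
                        "per_time_mean": list(self.transient_amplitude.per_time_mean),
                    },
                    "local_resolved": {
                        "max": self.transient_local.max_dev,
                        "mean": self.transient_local.mean_dev,
                    },
                },
            },
        }


def run_case_study(
    condition: str,
    overrides: Mapping[str, object] | None = None,
    max_cycles: int = 12_000,
    transient_times: Sequence[float] = TRANSIENT_TIMES,
    refine: int = 8,
) -> CaseStudyResult:
    """Simulate a case-study condition to steady state and compare it with
    the continuum references.

    The net starts empty with the source on, runs until the steady-state
    criterion fires (exact marking equality; if the run exhausts
    ``max_cycles`` without an exact fixed point, the ±1-token tolerance is
    applied to the recorded trajectory — see :func:`detect_steady_state`),
    and is compared:

    * at steady state, against the closed-form finite-domain profile
      converted to counts on a ``refine``-times finer grid (per-cell
      relative deviations: every cell is well resolved there);
    * at each transient time, against the refined transient solution
      (amplitude-relative deviations; per-cell deviations are additionally
      reported over the cells holding at least one reference molecule).
    """
    if condition not in CASE_STUDIES:
        raise InputError(
            f"unknown condition {condition!r}; choose from {sorted(CASE_STUDIES)}"
        )
    params = CASE_STUDIES[condition]
    if overrides:
        params = params.with_(**dict(overrides))
    for t in transient_times:
        if abs(t / params.dt - round(t / params.dt)) > 1e-9:
            raise InputError(f"comparison time {t} s is not a multiple of dt")

    traj = simulate_gradient(params, max_cycles, stop_when_fixed=True)
    steady_exact = True
    steady = detect_steady_state(traj, tol=0)
    if steady is None:
        steady_exact = False
        steady = detect_steady_state(traj, tol=1)
    if steady is None:
        raise SteadyStateTimeout(
            f"no steady state within {max_cycles} cycles "
            f"(last per-cycle change {np.abs(np.diff(traj.counts[-2:], axis=0)).max()} tokens)"
        )
    m_steady = traj.counts[steady]

    # steady-state reference: closed form on a refined grid
    grid = np.arange(params.n * refine + 1) * (params.ell / refine)
    ss_field = DensityField(grid=grid, values=steady_state_finite(grid, params))
    ss_ref = counts_from_density(ss_field, params)
    steady_local = deviation_metrics(
        m_steady, ss_ref, "local", "closed-form steady state", steady * params.dt
    )
    steady_amp = deviation_metrics(
        m_steady, ss_ref, "amplitude", "closed-form steady state", steady * params.dt
    )

    # transient references: refined FTCS solve at each comparison time
    amp_reports, local_reports = [], []
    for t in transient_times:
        dens = solve_transient(params, t, refine=refine)
        ref = counts_from_density(dens, params)
        pet = traj.at_time(t)
        amp_reports.append(
            deviation_metrics(pet, ref, "amplitude", "transient reference", t)
        )
        resolved = ref.counts >= 1.0
        local_reports.append(
            deviation_metrics(
                np.where(resolved, pet, 0.0),
                np.where(resolved, ref.counts, 0.0),
                "local",
                "transient reference (cells with >= 1 reference molecule)",
                t,
            )
        )
    return CaseStudyResult(
        condition=condition,
        params=params,
        trajectory=traj,
        steady_cycle=steady,
        steady_exact=steady_exact,
        steady_counts=m_steady,
        steady_local=steady_local,
        steady_amplitude=steady_amp,
        transient_amplitude=_aggregate(amp_reports),
        transient_local=_aggregate(local_reports),
    )
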