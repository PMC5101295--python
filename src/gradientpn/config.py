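"""Run configuration: YAML loading/saving, trajectory CSV I/O.

A configuration file is a flat YAML mapping.  ``condition`` selects a
case-study parameter set ("Dpp" or "Dpp-rescue") whose values serve as
defaults; any explicit key overrides it.  Keys: n, D, k, J0, ell, h, dt, p,
b, source_on, initial_profile (list of per-cell counts or null), max_cycles,
transient_times, steady_tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .builder import GradientParams
from .errors import ConfigError, InputError, ParameterError
from .simulate import CASE_STUDIES, TRANSIENT_TIMES, Trajectory

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "write_step_trace",
]

_PARAM_KEYS = ("n", "D", "k", "J0", "ell", "h", "dt", "p", "b", "source_on")


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    params: GradientParams
    condition: str | None = None
    initial_profile: list[int] | None = None
    max_cycles: int = 12_000
    transient_times: tuple[float, ...] = TRANSIENT_TIMES
    steady_tolerance: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        for t in self.transient_times:
            ratio = t / self.params.dt
            if abs(ratio - round(ratio)) > 1e-9:
                raise ConfigError(
                    f"comparison time {t} s is not a multiple of dt = {self.params.dt} s"
                )
        if self.max_cycles < 1:
            raise ConfigError("max_cycles must be >= 1")

    def to_dict(self) -> dict:
        out: dict = {k: getattr(self.params, k) for k in _PARAM_KEYS}
        out["condition"] = self.condition
        out["initial_profile"] = self.initial_profile
        out["max_cycles"] = self.max_cycles
        out["transient_times"] = list(self.transient_times)
        out["steady_tolerance"] = self.steady_tolerance
        return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration file.

    Unknown keys, wrong types and physically inadmissible values raise
    :class:`ConfigError` naming the offending key; stability violations
    (``D*dt/l^2 >= 1`` or ``k*dt >= 1``) surface here as well.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    condition = raw.pop("condition", None)
    if condition is not None and condition not in CASE_STUDIES:
        raise ConfigError(
            f"unknown condition {condition!r}; choose from {sorted(CASE_STUDIES)}"
        )
    base = CASE_STUDIES[condition] if condition else CASE_STUDIES["Dpp"]
    values = {k: getattr(base, k) for k in _PARAM_KEYS}
    for key in _PARAM_KEYS:
        if key in raw:
            values[key] = raw.pop(key)
    profile = raw.pop("initial_profile", None)
    max_cycles = raw.pop("max_cycles", 12_000)
    times = raw.pop("transient_times", list(TRANSIENT_TIMES))
    tol = raw.pop("steady_tolerance", 0)
    if raw:
        raise ConfigError(f"unknown configuration key(s): {sorted(raw)}")
    try:
        params = GradientParams(**values)
    except (ParameterError, TypeError) as exc:
        raise ConfigError(f"invalid parameters: {exc}") from exc
    if profile is not None:
        if not isinstance(profile, (list, tuple)):
            raise ConfigError("initial_profile must be a list of per-cell counts")
        profile = [int(v) for v in profile]
    return RunConfig(
        params=params,
        condition=condition,
        initial_profile=profile,
        max_cycles=int(max_cycles),
        transient_times=tuple(float(t) for t in times),
        steady_tolerance=int(tol),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips with load_config)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write cycle-boundary counts as CSV: cycle, time_s, cell_1..cell_n."""
    if traj.counts.shape[0] < 1:
        raise InputError("trajectory is empty")
    n = traj.counts.shape[1]
    frame = pd.DataFrame(
        traj.counts, columns=[f"cell_{i}" for i in range(1, n + 1)]
    )
    frame.insert(0, "time_s", traj.times)
    frame.insert(0, "cycle", np.arange(traj.counts.shape[0]))
    frame.to_csv(path, index=False)


def write_step_trace(
    trace: list,
    steps_path: str | Path,
    markings_path: str | Path,
    places: list[str] | None = None,
) -> None:
    """Write a :func:`gradientpn.run_steps` trace as two CSV files.

    ``steps_path`` gets one row per transition occurrence (step_index,
    transition, multiplicity); ``markings_path`` gets one row per step with
    a column per place.
    """
    rows = []
    place_set: set[str] = set(places or ())
    for idx, (step, marking) in enumerate(trace, start=1):
        for t in sorted(step):
            rows.append({"step_index": idx, "transition": t, "multiplicity": step[t]})
        if places is None:
            place_set.update(marking)
    pd.DataFrame(rows, columns=["step_index", "transition", "multiplicity"]).to_csv(
        steps_path, index=False
    )
    cols = list(places) if places is not None else sorted(place_set)
    mrows = [
        {"step_index": idx, **{p: marking[p] for p in cols}}
        for idx, (_, marking) in enumerate(trace, start=1)
    ]
    pd.DataFrame(mrows, columns=["step_index", *cols]).to_csv(markings_path, index=False)


def read_trajectory(path: str | Path, params: GradientParams) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    frame = pd.read_csv(path)
    cell_cols = [c for c in frame.columns if c.startswith("cell_")]
    if not cell_cols:
        raise InputError(f"{path} has no cell_* columns")
    cell_cols.sort(key=lambda c: int(c.split("_")[1]))
    counts = frame[cell_cols].to_numpy(dtype=np.int64)
    return Trajectory(params=params, counts=counts)
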