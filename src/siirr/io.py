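"""Run configuration parsing and trajectory serialization.

Config files are YAML with a versioned top-level key::

    siirr_config: 1
    scenario: fig1_base        # registry name, or an inline mapping with
                               # tau1, tau2, rho1, rho2, S0, I1_0, I2_0
                               # (optionally R1_0, R2_0, label)
    rel_tol: 1.0e-8            # optional, integrator relative tolerance
    abs_tol: 1.0e-6            # optional, integrator absolute tolerance
    t_end: 30000.0             # optional horizon override (default: auto)
    n_out: 4001                # optional output grid size
    out: trajectory.csv        # optional output path
    verbosity: 1               # optional, 0..2

Unknown keys are rejected by name.  Trajectories are stored as CSV with
header ``t,S,I1,I2,R1,R2``, one row per grid point, at %.17g precision
(lossless float round trip).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

from .effects import scenario_registry
from .errors import ConfigError, SiirrError, TrajectoryError
from .model import Scenario, Trajectory
from .simulate import DEFAULT_ABS_TOL, DEFAULT_REL_TOL

__all__ = [
    "RunConfig",
    "parse_config",
    "serialize_config",
    "write_trajectory",
    "read_trajectory",
    "TRAJECTORY_HEADER",
]

CONFIG_VERSION_KEY = "siirr_config"
CONFIG_VERSION = 1
TRAJECTORY_HEADER = "t,S,I1,I2,R1,R2"

_TOP_KEYS = {
    CONFIG_VERSION_KEY, "scenario", "rel_tol", "abs_tol",
    "t_end", "n_out", "out", "verbosity",
}
_SCENARIO_KEYS = {
    "tau1", "tau2", "rho1", "rho2", "S0", "I1_0", "I2_0", "R1_0", "R2_0",
    "label",
}
_REQUIRED_SCENARIO_KEYS = {"tau1", "tau2", "rho1", "rho2", "S0", "I1_0", "I2_0"}


@dataclass(frozen=True)
class RunConfig:
    scenario: Scenario
    scenario_name: str | None = None
    rel_tol: float = DEFAULT_REL_TOL
    abs_tol: float = DEFAULT_ABS_TOL
    out: str | None = None
    verbosity: int = 1


def _build_inline_scenario(mapping: dict, t_end, n_out) -> Scenario:
    unknown = set(mapping) - _SCENARIO_KEYS
    if unknown:
        raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
    missing = _REQUIRED_SCENARIO_KEYS - set(mapping)
    if missing:
        raise ConfigError(f"missing scenario keys: {sorted(missing)}")
    for rate in ("tau1", "tau2", "rho1", "rho2"):
        v = mapping[rate]
        if not isinstance(v, (int, float)) or v < 0:
            raise ConfigError(f"field {rate!r} must be a non-negative number")
    kw = {k: (v if k == "label" else float(v)) for k, v in mapping.items()}
    try:
        return Scenario.from_counts(
            t_end=t_end, **({"n_out": n_out} if n_out else {}), **kw
        )
    except SiirrError as exc:
        raise ConfigError(str(exc)) from exc


def parse_config(text: str) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if data.get(CONFIG_VERSION_KEY) != CONFIG_VERSION:
        raise ConfigError(
            f"config must declare {CONFIG_VERSION_KEY}: {CONFIG_VERSION}"
        )
    if "scenario" not in data:
        raise ConfigError("missing required field 'scenario'")

    for key in ("rel_tol", "abs_tol"):
        if key in data and not (
            isinstance(data[key], (int, float)) and data[key] > 0
        ):
            raise ConfigError(f"field {key!r} must be a positive number")
    t_end = data.get("t_end")
    if t_end is not None:
        t_end = float(t_end)
    n_out = data.get("n_out")

    ref = data["scenario"]
    if isinstance(ref, str):
        registry = scenario_registry()
        if ref not in registry:
            raise ConfigError(f"unknown scenario name {ref!r}")
        scenario = registry[ref]
        if t_end is not None or n_out is not None:
            scenario = dataclasses.replace(
                scenario,
                t_end=t_end if t_end is not None else scenario.t_end,
                n_out=int(n_out) if n_out is not None else scenario.n_out,
            )
        name = ref
    elif isinstance(ref, dict):
        scenario = _build_inline_scenario(ref, t_end, n_out)
        name = None
    else:
        raise ConfigError("'scenario' must be a registry name or a mapping")

    return RunConfig(
        scenario=scenario,
        scenario_name=name,
        rel_tol=float(data.get("rel_tol", DEFAULT_REL_TOL)),
        abs_tol=float(data.get("abs_tol", DEFAULT_ABS_TOL)),
        out=data.get("out"),
        verbosity=int(data.get("verbosity", 1)),
    )


def serialize_config(cfg: RunConfig) -> str:
    """YAML text that parses back to an equal RunConfig."""
    data: dict = {CONFIG_VERSION_KEY: CONFIG_VERSION}
    if cfg.scenario_name is not None:
        data["scenario"] = cfg.scenario_name
    else:
        ini, p = cfg.scenario.initial, cfg.scenario.params
        data["scenario"] = {
            "tau1": p.tau1, "tau2": p.tau2, "rho1": p.rho1, "rho2": p.rho2,
            "S0": ini.S, "I1_0": ini.I1, "I2_0": ini.I2,
            "R1_0": ini.R1, "R2_0": ini.R2,
            "label": cfg.scenario.label,
        }
    if cfg.scenario.t_end is not None:
        data["t_end"] = cfg.scenario.t_end
    data["n_out"] = cfg.scenario.n_out
    data["rel_tol"] = cfg.rel_tol
    data["abs_tol"] = cfg.abs_tol
    if cfg.out is not None:
        data["out"] = cfg.out
    data["verbosity"] = cfg.verbosity
    return yaml.safe_dump(data, sort_keys=False)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV (header t,S,I1,I2,R1,R2, full precision)."""
    table = np.column_stack([traj.times, traj.states])
    np.savetxt(path, table, delimiter=",", header=TRAJECTORY_HEADER,
               comments="", fmt="%.17g")


def read_trajectory(path, scenario: Scenario | None = None) -> Trajectory:
    """Read a trajectory CSV and re-validate every trajectory invariant."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise TrajectoryError(f"empty trajectory file: {path}")
    if lines[0] != TRAJECTORY_HEADER:
        raise TrajectoryError(
            f"bad header {lines[0]!r}; expected {TRAJECTORY_HEADER!r}"
        )
    if len(lines) < 3:
        raise TrajectoryError("trajectory must contain at least two rows")
    rows = []
    for k, ln in enumerate(lines[1:], start=2):
        parts = ln.split(",")
        if len(parts) != 6:
            raise TrajectoryError(f"malformed row {k}: {ln!r}")
        try:
            rows.append([float(x) for x in parts])
        except ValueError as exc:
            raise TrajectoryError(f"malformed row {k}: {ln!r}") from exc
    table = np.array(rows)
    times = table[:, 0]
    if np.any(np.diff(times) <= 0):
        raise TrajectoryError("time column is not strictly increasing")
    traj = Trajectory(times=times, states=table[:, 1:], scenario=scenario)
    traj.validate()
    return traj
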