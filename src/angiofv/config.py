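"""Configuration: benchmark defaults, flat dotted-key overrides, validation.

The configuration surface is a flat mapping of dotted keys to values,
diffable and trivially serialized::

    params.chi: 0.5
    grid.n: 100
    time.t_end: 2.0

Unset keys take the benchmark values, so an empty configuration is
exactly the benchmark run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .grid import EDGES, Edge
from .model import ModelParams, TimeConfig

__all__ = ["SimulationConfig", "load_config", "ConfigError", "KNOWN_KEYS"]


class ConfigError(ValueError):
    """A configuration key is unknown, malformed, or violates an invariant."""


PARAM_KEYS = {f"params.{name}": name for name in ("Du", "Dv", "chi", "alpha", "gamma", "mu")}

KNOWN_KEYS = frozenset(PARAM_KEYS) | {
    "grid.n",
    "geometry.tumor_edge",
    "time.t_end",
    "time.dt",
    "time.snapshots",
    "time.diag_stride",
    "bc.u_leak",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Fully resolved run configuration (benchmark defaults unless overridden)."""

    params: ModelParams = field(default_factory=ModelParams)
    n: int = 100
    tumor_edge: Edge = "top"
    time: TimeConfig = field(default_factory=TimeConfig)
    u_leak: bool = False

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ConfigError(f"grid.n: resolution n={self.n} too coarse; need n >= 4")
        if self.tumor_edge not in EDGES:
            raise ConfigError(
                f"geometry.tumor_edge: unknown edge {self.tumor_edge!r}; expected one of {EDGES}"
            )

    def with_overrides(self, **flat: Any) -> "SimulationConfig":
        """Return a copy with flat dotted-key overrides applied."""
        return _apply_overrides(self, flat)

    def as_flat_dict(self) -> dict[str, Any]:
        """The effective configuration as a flat dotted-key mapping."""
        out: dict[str, Any] = {key: getattr(self.params, name) for key, name in PARAM_KEYS.items()}
        out.update(
            {
                "grid.n": self.n,
                "geometry.tumor_edge": self.tumor_edge,
                "time.t_end": self.time.t_end,
                "time.dt": "auto" if self.time.dt is None else self.time.dt,
                "time.snapshots": list(self.time.snapshot_times),
                "time.diag_stride": self.time.diag_stride,
                "bc.u_leak": self.u_leak,
            }
        )
        return out


def _as_float(key: str, value: Any) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{key}: expected a number, got {value!r}")
    return float(value)


def _apply_overrides(base: SimulationConfig, flat: Mapping[str, Any]) -> SimulationConfig:
    unknown = set(flat) - KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")

    params = base.params
    param_changes = {
        PARAM_KEYS[k]: _as_float(k, v) for k, v in flat.items() if k in PARAM_KEYS
    }
    if param_changes:
        try:
            params = params.replace(**param_changes)
        except ValueError as err:
            raise ConfigError(f"params: {err}") from None

    n = base.n
    if "grid.n" in flat:
        v = flat["grid.n"]
        if isinstance(v, bool) or not isinstance(v, int):
            raise ConfigError(f"grid.n: expected an integer, got {v!r}")
        n = v

    tumor_edge = flat.get("geometry.tumor_edge", base.tumor_edge)

    time_changes: dict[str, Any] = {}
    if "time.t_end" in flat:
        time_changes["t_end"] = _as_float("time.t_end", flat["time.t_end"])
    if "time.dt" in flat:
        v = flat["time.dt"]
        if v in ("auto", None):
            time_changes["dt"] = None
        else:
            time_changes["dt"] = _as_float("time.dt", v)
    if "time.snapshots" in flat:
        v = flat["time.snapshots"]
        if not isinstance(v, (list, tuple)):
            raise ConfigError(f"time.snapshots: expected a list of times, got {v!r}")
        time_changes["snapshot_times"] = tuple(_as_float("time.snapshots", t) for t in v)
    if "time.diag_stride" in flat:
        v = flat["time.diag_stride"]
        if isinstance(v, bool) or not isinstance(v, int):
            raise ConfigError(f"time.diag_stride: expected an integer, got {v!r}")
        time_changes["diag_stride"] = v
    time_cfg = base.time
    if time_changes:
        # Clip default snapshots to a shortened time window unless given explicitly.
        if "t_end" in time_changes and "snapshot_times" not in time_changes:
            t_end = time_changes["t_end"]
            snaps = tuple(t for t in base.time.snapshot_times if t <= t_end)
            time_changes["snapshot_times"] = snaps if snaps else (t_end,)
        try:
            time_cfg = replace(base.time, **time_changes)
        except ValueError as err:
            raise ConfigError(f"time: {err}") from None

    u_leak = base.u_leak
    if "bc.u_leak" in flat:
        v = flat["bc.u_leak"]
        if not isinstance(v, bool):
            raise ConfigError(f"bc.u_leak: expected a boolean, got {v!r}")
        u_leak = v

    try:
        return SimulationConfig(
            params=params, n=n, tumor_edge=tumor_edge, time=time_cfg, u_leak=u_leak
        )
    except ValueError as err:
        raise ConfigError(str(err)) from None


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
    base: SimulationConfig | None = None,
) -> SimulationConfig:
    """Build a validated configuration from a file and/or override mapping.

    ``path`` points to a flat YAML file of dotted keys; ``overrides``
    (applied after the file) is the same mapping in memory; ``base`` is
    the starting configuration (benchmark defaults if omitted).  With no
    arguments, the benchmark configuration is returned.
    """
    cfg = base if base is not None else SimulationConfig()
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected flat key: value mappings")
        cfg = _apply_overrides(cfg, data)
    if overrides:
        cfg = _apply_overrides(cfg, dict(overrides))
    return cfg
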