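"""YAML configuration loading.

A config file may override any model parameter (including the lookup tables,
given as ordered ``[x, y]`` knot lists) and set the run options.  Omitted
keys fall back to the reference-rat defaults; unknown keys and malformed
values raise :class:`~hydrorat.params.ConfigError` naming the offending key.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .params import (CircadianAvpParams, ConfigError, DrinkingParams,
                     FurosemideParams, GutParams, ModelParams, PiecewiseTable)

__all__ = ["RunConfig", "load_config", "params_from_dict", "params_to_dict"]

_NESTED = {
    "circadian_avp": CircadianAvpParams,
    "drinking": DrinkingParams,
    "gut": GutParams,
    "furosemide": FurosemideParams,
}
_RUN_KEYS = {"protocol", "days", "seed", "out", "summary", "log_level"}


@dataclass
class RunConfig:
    params: ModelParams
    protocol: str = "control"
    days: int = 20
    seed: int = 0
    out: str | None = None
    summary: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ConfigError("days must be >= 1")


def _build(cls, data: dict[str, Any], context: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown key {context}{key!r}")
        ftype = fields[key].type
        if key in _NESTED:
            if not isinstance(value, dict):
                raise ConfigError(f"{context}{key} must be a mapping")
            kwargs[key] = _build(_NESTED[key], value, f"{context}{key}.")
        elif "PiecewiseTable" in str(ftype):
            try:
                kwargs[key] = PiecewiseTable.from_pairs(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad table knots for {context}{key}: {exc}") from exc
        elif isinstance(value, bool) or value is None:
            kwargs[key] = value
        elif isinstance(value, (int, float)):
            kwargs[key] = value
        else:
            raise ConfigError(f"non-numeric value for {context}{key}: {value!r}")
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid configuration under {context or 'top level'}: {exc}") from exc


def params_from_dict(data: dict[str, Any] | None) -> ModelParams:
    """Build a :class:`ModelParams` from a (possibly partial) mapping."""
    return _build(ModelParams, data or {}, "")


def params_to_dict(params: ModelParams) -> dict[str, Any]:
    """Serialize parameters to plain data (tables as knot lists)."""

    def conv(obj: Any) -> Any:
        if isinstance(obj, PiecewiseTable):
            return [list(k) for k in obj.knots]
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        return obj

    return conv(params)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config file into a fully-resolved :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping at the top level")
    run_opts = {k: raw.pop(k) for k in list(raw) if k in _RUN_KEYS}
    params_block = raw.pop("params", {}) or {}
    if not isinstance(params_block, dict):
        raise ConfigError("'params' must be a mapping")
    # remaining top-level keys are treated as parameter overrides too
    params = params_from_dict({**params_block, **raw})
    return RunConfig(params=params, **run_opts)
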