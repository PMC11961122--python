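"""Configuration plumbing: dotted-key overrides, INI-style config files, and
config echoing.

A configuration is the nested frozen-dataclass tree rooted at
:class:`psmclock.engine.SimConfig`. Overrides address leaves with dotted keys
(``clock.kappa=0.1``, ``geometry.Xc=240``); top-level run keys have no prefix
(``dt=0.02``). The virtual key ``geometry.L`` sets the AP length by moving
``Xc`` (L = rT + R + Xc - xa). Enum fields accept their string values.
"""

from __future__ import annotations

import configparser
import dataclasses
import enum
import json
from pathlib import Path
from typing import Any, Mapping

from .engine import SimConfig

__all__ = ["apply_overrides", "load_config", "config_to_dict", "save_sidecar"]

_GROUPS = ("geometry", "motion", "clock", "lifecycle", "shrinkage")


def _coerce(current: Any, raw: Any) -> Any:
    if isinstance(current, enum.Enum):
        return type(current)(raw) if not isinstance(raw, enum.Enum) else raw
    if isinstance(current, bool):
        if isinstance(raw, str):
            return raw.strip().lower() in ("1", "true", "yes", "on")
        return bool(raw)
    if isinstance(current, int) and not isinstance(current, bool):
        return int(raw)
    if isinstance(current, float) or current is None:
        return float(raw) if raw is not None else None
    return raw


def apply_overrides(cfg: SimConfig, overrides: Mapping[str, Any]) -> SimConfig:
    """Return a copy of ``cfg`` with dotted-key overrides applied."""
    groups: dict[str, dict[str, Any]] = {g: {} for g in _GROUPS}
    top: dict[str, Any] = {}
    for key, raw in overrides.items():
        if "." in key:
            group, field_name = key.split(".", 1)
            if group not in groups:
                raise KeyError(f"unknown parameter group '{group}'")
            groups[group][field_name] = raw
        else:
            top[key] = raw

    # virtual key geometry.L -> Xc
    geo_over = groups["geometry"]
    if "L" in geo_over:
        L = float(geo_over.pop("L"))
        geom = cfg.geometry
        rT = float(geo_over.get("rT", geom.rT))
        R = float(geo_over.get("R", geom.R))
        xa = float(geo_over.get("xa", geom.xa))
        geo_over["Xc"] = L - rT - R + xa

    new_groups = {}
    for g in _GROUPS:
        sub = getattr(cfg, g)
        if groups[g]:
            changes = {}
            for name, raw in groups[g].items():
                if not hasattr(sub, name):
                    raise KeyError(f"unknown parameter '{g}.{name}'")
                changes[name] = _coerce(getattr(sub, name), raw)
            if g == "geometry" and ("rT" in changes or "R" in changes) and "Yc" not in changes:
                rT = changes.get("rT", sub.rT)
                R = changes.get("R", sub.R)
                changes["Yc"] = rT + R
            sub = dataclasses.replace(sub, **changes)
        new_groups[g] = sub

    top_changes = {}
    for name, raw in top.items():
        if not hasattr(cfg, name):
            raise KeyError(f"unknown run parameter '{name}'")
        top_changes[name] = _coerce(getattr(cfg, name), raw)
    return dataclasses.replace(cfg, **new_groups, **top_changes)


def load_config(path: str | Path, base: SimConfig | None = None) -> SimConfig:
    """Read an INI-style file with sections geometry/motion/clock/lifecycle/
    shrinkage/run and apply it on top of ``base`` (default configuration if
    omitted)."""
    parser = configparser.ConfigParser()
    parser.optionxform = str  # parameter symbols are case-sensitive (Xc vs xc)
    with open(path) as fh:
        parser.read_file(fh)
    overrides: dict[str, Any] = {}
    for section in parser.sections():
        for key, value in parser.items(section):
            overrides[key if section == "run" else f"{section}.{key}"] = value
    return apply_overrides(base or SimConfig(), overrides)


def config_to_dict(cfg: SimConfig) -> dict:
    def conv(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, enum.Enum):
            return obj.value
        if isinstance(obj, tuple):
            return [conv(v) for v in obj]
        return obj

    d = conv(cfg)
    d.pop("initial_cells", None)
    return d


def save_sidecar(cfg: SimConfig, seed: int, path: str | Path) -> None:
    """Echo the full configuration and seed next to a run's outputs."""
    payload = {"seed": seed, "config": config_to_dict(cfg)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
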