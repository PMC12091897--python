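"""Flat key=value configuration files and result writers.

A config file is a plain-text list of ``key = value`` lines (``#`` starts a
comment).  Keys are the parameter-table symbols (``p``, ``Cm``, ``gc``,
``gL``, ``gNa``, ``gKDR``, ``gCa``, ``gKAHP``, ``gKC``, ``VNa``, ``VCa``,
``VK``, ``VL``, ``Vsyn``, ``Is``, ``Id``), the field amplitude ``Ve``, the
integration keys ``dt``, ``duration``, ``record_stride`` and the classifier
keys (``spike_threshold``, ``transient_discard``, ``intra_burst_isi_max``,
``resting_std_max``, ``block_voltage_min``, ``block_dwell_min``).  Every
key is optional; an empty file resolves to the full default configuration.
Unknown keys are rejected by name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

from .analysis import ClassifierCriteria
from .integrate import SimulationConfig
from .model import FieldConfig, ModelParams

__all__ = ["RunConfig", "ConfigError", "load_config", "config_template"]

log = logging.getLogger("prfield")


class ConfigError(ValueError):
    pass


_PARAM_KEYS = {f.name for f in dc_fields(ModelParams)}
_SIM_KEYS = {"dt", "duration", "record_stride"}
_CRIT_KEYS = {f.name for f in dc_fields(ClassifierCriteria)}
_FIELD_KEYS = {"Ve"}


@dataclass
class RunConfig:
    """Fully-resolved bundle of model, field, integration and classifier."""

    params: ModelParams
    field: FieldConfig
    sim: SimulationConfig
    criteria: ClassifierCriteria


def _parse_scalar(key: str, text: str):
    try:
        if key == "record_stride":
            return int(text)
        return float(text)
    except ValueError as exc:
        raise ConfigError(f"config key {key!r}: cannot parse {text!r} as a number") from exc


def parse_items(items: dict[str, str]) -> RunConfig:
    params_kw, sim_kw, crit_kw, field_kw = {}, {}, {}, {}
    for key, raw in items.items():
        if key in _PARAM_KEYS:
            params_kw[key] = _parse_scalar(key, raw)
        elif key in _SIM_KEYS:
            sim_kw[key] = _parse_scalar(key, raw)
        elif key in _CRIT_KEYS:
            crit_kw[key] = _parse_scalar(key, raw)
        elif key in _FIELD_KEYS:
            field_kw[key] = _parse_scalar(key, raw)
        else:
            raise ConfigError(f"unknown config key {key!r}")
    try:
        cfg = RunConfig(
            params=ModelParams(**params_kw),
            field=FieldConfig(**field_kw),
            sim=SimulationConfig(**sim_kw),
            criteria=ClassifierCriteria(**crit_kw),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    log.info("resolved configuration: params=%s field=%s sim=(dt=%g, duration=%g)",
             cfg.params, cfg.field, cfg.sim.dt, cfg.sim.duration)
    return cfg


def load_config(path: str | Path | None) -> RunConfig:
    """Read a flat key=value file; ``None`` resolves to all defaults."""
    items: dict[str, str] = {}
    if path is not None:
        try:
            text = Path(path).read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            items[key.strip()] = value.strip()
    return parse_items(items)


def config_template() -> str:
    """A commented template listing every accepted key with its default."""
    p, s, c = ModelParams(), SimulationConfig(), ClassifierCriteria()
    lines = ["# prfield configuration (flat key = value; all keys optional)",
             "# --- model parameters ---"]
    for f in dc_fields(ModelParams):
        lines.append(f"# {f.name} = {getattr(p, f.name)}")
    lines += ["# --- DC field ---", "# Ve = 0.0",
              "# --- integration ---",
              f"# dt = {s.dt}", f"# duration = {s.duration}",
              f"# record_stride = {s.record_stride}",
              "# --- classifier ---"]
    for f in dc_fields(ClassifierCriteria):
        lines.append(f"# {f.name} = {getattr(c, f.name)}")
    return "\n".join(lines) + "\n"
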