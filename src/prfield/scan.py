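"""Parameter sweeps: F-I and F-Ve curves, 2D regime maps, sensitivity ranges.

Every grid point is an independent simulation from the same printed initial
state (no warm-starting), so results are pure per-point functions of the
parameters and independent of evaluation order.  Sensitivity scans use the
weak-DC baseline Is = 0, Id = 1 uA/cm^2 — the stimulus that keeps the
neuron at a low baseline rate so field effects are visible.

A grid point whose simulation diverges before the analysis window opens is
recorded with F = 0 and the regime marker ``"divergent"`` (it contributes
no countable spikes and is never *sensitive*).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import (ClassifierCriteria, Regime, classify_regime,
                       detect_spikes, is_sensitive, mean_firing_rate)
from .integrate import SimulationConfig, Trace, simulate
from .model import FieldConfig, ModelParams

__all__ = [
    "ScanResult",
    "SensitivityInterval",
    "SCAN_AXES",
    "sweep_field",
    "sweep_current",
    "grid_2d",
    "sensitivity_interval",
    "evaluate_point",
]

DIVERGENT = "divergent"

#: Scannable axes and how each maps onto the model.
SCAN_AXES = ("gc", "Vk", "Ve", "Id")


def _apply_axis(params: ModelParams, ve: float, name: str, value: float):
    if name == "gc":
        return params.replace(gc=float(value)), ve
    if name == "Vk":
        return params.replace(VK=float(value)), ve
    if name == "Id":
        return params.replace(Id=float(value)), ve
    if name == "Ve":
        return params, float(value)
    raise ValueError(f"unknown scan axis {name!r}; expected one of {SCAN_AXES}")


def evaluate_point(params: ModelParams, ve: float,
                   config: SimulationConfig | None = None,
                   criteria: ClassifierCriteria | None = None) -> tuple[float, str]:
    """Simulate one configuration and return ``(F_hz, regime)``."""
    config = config or SimulationConfig()
    criteria = criteria or ClassifierCriteria()
    trace = simulate(params, FieldConfig(Ve=ve), config, on_divergence="truncate")
    if trace.diverged_at is not None and trace.duration < criteria.transient_discard + 1000.0:
        return 0.0, DIVERGENT
    train = detect_spikes(trace, criteria)
    regime = classify_regime(trace, train, criteria)
    return mean_firing_rate(train), regime.value


@dataclass
class SensitivityInterval:
    """Contiguous Ve range (mV) with sustained firing; grid endpoints."""

    lower: float | None
    upper: float | None

    @property
    def empty(self) -> bool:
        return self.lower is None

    def __iter__(self):
        yield self.lower
        yield self.upper


@dataclass
class ScanResult:
    """Grid of (F, regime) values with full provenance."""

    axes: list[tuple[str, np.ndarray]]
    table: pd.DataFrame
    provenance: dict

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")

    def write_provenance(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.provenance, indent=2, default=str))


def _provenance(params: ModelParams, config: SimulationConfig,
                criteria: ClassifierCriteria, axes) -> dict:
    return {
        "params": asdict(params),
        "config": {"dt": config.dt, "duration": config.duration,
                   "record_stride": config.record_stride,
                   "initial_state": asdict(config.initial_state)},
        "criteria": asdict(criteria),
        "axes": {name: list(map(float, grid)) for name, grid in axes},
    }


def _run_1d(params: ModelParams, axis: str, grid: Sequence[float], ve0: float,
            config: SimulationConfig, criteria: ClassifierCriteria) -> ScanResult:
    if len(grid) == 0:
        raise ValueError("scan grid must be nonempty")
    grid = np.asarray(grid, dtype=float)
    rows = []
    for value in grid:
        p, ve = _apply_axis(params, ve0, axis, value)
        f, regime = evaluate_point(p, ve, config, criteria)
        rows.append((value, f, regime))
    table = pd.DataFrame(rows, columns=[axis, "F_hz", "regime"])
    return ScanResult(axes=[(axis, grid)], table=table,
                      provenance=_provenance(params, config or SimulationConfig(),
                                             criteria or ClassifierCriteria(),
                                             [(axis, grid)]))


def sweep_field(params: ModelParams | None = None,
                ve_grid: Sequence[float] = tuple(range(-50, 51)),
                config: SimulationConfig | None = None,
                criteria: ClassifierCriteria | None = None) -> ScanResult:
    """F and regime versus DC field amplitude Ve under the weak-DC baseline.

    ``Is`` and ``Id`` are forced to the weak-DC stimulus (0 and 1 uA/cm^2):
    sensitivity scans are defined relative to that baseline drive.
    """
    params = (params or ModelParams()).replace(Is=0.0, Id=1.0)
    config = config or SimulationConfig()
    criteria = criteria or ClassifierCriteria()
    return _run_1d(params, "Ve", ve_grid, 0.0, config, criteria)


def sweep_current(params: ModelParams | None = None,
                  i_grid: Sequence[float] = tuple(range(0, 11)),
                  config: SimulationConfig | None = None,
                  criteria: ClassifierCriteria | None = None,
                  ve: float = 0.0) -> ScanResult:
    """F-I curve: firing rate versus dendritic drive Id (Is = 0)."""
    params = (params or ModelParams()).replace(Is=0.0)
    config = config or SimulationConfig()
    criteria = criteria or ClassifierCriteria()
    return _run_1d(params, "Id", i_grid, ve, config, criteria)


def grid_2d(params: ModelParams | None = None,
            axis1: tuple[str, Sequence[float]] = ("gc", (1.0, 2.1)),
            axis2: tuple[str, Sequence[float]] = ("Ve", (0.0,)),
            config: SimulationConfig | None = None,
            criteria: ClassifierCriteria | None = None) -> ScanResult:
    """Cartesian-product scan over two axes from {gc, Vk, Ve, Id}.

    Rows iterate axis1 in the given order, columns axis2; each point is an
    independent simulation, so any row or column equals the corresponding
    1D sweep point for point.
    """
    params = params or ModelParams()
    config = config or SimulationConfig()
    criteria = criteria or ClassifierCriteria()
    name1, grid1 = axis1
    name2, grid2 = axis2
    if len(grid1) == 0 or len(grid2) == 0:
        raise ValueError("scan grids must be nonempty")
    for name in (name1, name2):
        if name not in SCAN_AXES:
            raise ValueError(f"unknown scan axis {name!r}; expected one of {SCAN_AXES}")
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    rows = []
    for v1 in grid1:
        p1, ve1 = _apply_axis(params, 0.0, name1, v1)
        for v2 in grid2:
            p2, ve2 = _apply_axis(p1, ve1, name2, v2)
            f, regime = evaluate_point(p2, ve2, config, criteria)
            rows.append((v1, v2, f, regime))
    table = pd.DataFrame(rows, columns=[name1, name2, "F_hz", "regime"])
    axes = [(name1, grid1), (name2, grid2)]
    return ScanResult(axes=axes, table=table,
                      provenance=_provenance(params, config, criteria, axes))


def sensitivity_interval(scan: ScanResult) -> SensitivityInterval:
    """Maximal contiguous run of field amplitudes with sustained firing.

    The scan must be one-dimensional over Ve.  Sensitive means the regime is
    any spiking label (equivalently F > 0, excluding depolarization block,
    subthreshold/biphasic oscillation, resting and divergent points).  Ties
    on run length resolve to the run with the smallest lower endpoint.
    """
    if len(scan.axes) != 1 or scan.axes[0][0] != "Ve":
        raise ValueError("sensitivity_interval needs a 1D scan over the Ve axis")
    ve = scan.table["Ve"].to_numpy(float)
    sens = scan.table["regime"].map(is_sensitive).to_numpy(bool)
    best_len, best = 0, None
    cur_start = None
    for i, flag in enumerate(sens):
        if flag and cur_start is None:
            cur_start = i
        if cur_start is not None and (not flag or i == len(sens) - 1):
            end = i if flag else i - 1
            length = end - cur_start + 1
            if length > best_len:
                best_len, best = length, (ve[cur_start], ve[end])
            cur_start = None
    if best is None:
        return SensitivityInterval(None, None)
    return SensitivityInterval(float(best[0]), float(best[1]))
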