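"""Fixed-step classical RK4 integration with full-trace recording.

The scheme is the textbook tableau

    k1 = dt f(x),  k2 = dt f(x + k1/2),  k3 = dt f(x + k2/2),
    k4 = dt f(x + k3),  x' = x + k1/6 + k2/3 + k3/3 + k4/6

applied to the autonomous 8-dimensional model.  Defaults: dt = 0.1 ms over
T = 7000 ms (70 000 steps) starting from the printed initial state.  The
integration is fully deterministic; identical inputs give bit-identical
traces.

A run whose state becomes non-finite (which genuinely happens for very
strong coupling, gc >~ 20 mS/cm^2, at the default step) either raises
:class:`DivergenceError` naming the failure time (default) or returns the
valid prefix with ``Trace.diverged_at`` set (``on_divergence="truncate"``,
used by parameter scans so one runaway grid point cannot abort a sweep).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ._kernel import rk4_run
from .model import INITIAL_STATE, FieldConfig, ModelParams, NeuronState

__all__ = [
    "SimulationConfig",
    "Trace",
    "DivergenceError",
    "rk4_step",
    "simulate",
    "read_trace",
]

TRACE_COLUMNS = ["time_ms", "Vs", "Vd", "h", "n", "s", "c", "q", "Ca"]


class DivergenceError(RuntimeError):
    """The integrator produced a non-finite state."""

    def __init__(self, time_ms: float):
        self.time_ms = time_ms
        super().__init__(f"simulation diverged (non-finite state) at t = {time_ms:g} ms")


@dataclass(frozen=True)
class SimulationConfig:
    """Integration setup: step (ms), horizon (ms), recording stride, start."""

    dt: float = 0.1
    duration: float = 7000.0
    record_stride: int = 1
    initial_state: NeuronState = INITIAL_STATE

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one step")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class Trace:
    """Uniformly sampled record of one simulation."""

    time: np.ndarray
    Vs: np.ndarray
    Vd: np.ndarray
    h: np.ndarray
    n: np.ndarray
    s: np.ndarray
    c: np.ndarray
    q: np.ndarray
    Ca: np.ndarray
    dt: float
    diverged_at: float | None = None

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Time span actually covered (ms)."""
        return float(self.time[-1]) if len(self.time) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.time, "Vs": self.Vs, "Vd": self.Vd, "h": self.h,
            "n": self.n, "s": self.s, "c": self.c, "q": self.q, "Ca": self.Ca,
        })

    def to_csv(self, path: str | Path) -> None:
        # repr-precision floats so a round-trip is exact to the double
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trace(path: str | Path) -> Trace:
    """Read a trace CSV written by :meth:`Trace.to_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} lacks columns {missing}")
    t = df["time_ms"].to_numpy(float)
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.1
    return Trace(
        time=t, Vs=df["Vs"].to_numpy(float), Vd=df["Vd"].to_numpy(float),
        h=df["h"].to_numpy(float), n=df["n"].to_numpy(float),
        s=df["s"].to_numpy(float), c=df["c"].to_numpy(float),
        q=df["q"].to_numpy(float), Ca=df["Ca"].to_numpy(float), dt=dt,
    )


def rk4_step(y: np.ndarray, dt: float, f: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """One classical RK4 step of an autonomous system (generic, pure NumPy).

    Kept independent of the compiled sweep so the two can be checked against
    each other.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    y = np.asarray(y, dtype=float)
    k1 = dt * np.asarray(f(y), dtype=float)
    k2 = dt * np.asarray(f(y + k1 / 2.0), dtype=float)
    k3 = dt * np.asarray(f(y + k2 / 2.0), dtype=float)
    k4 = dt * np.asarray(f(y + k3), dtype=float)
    out = y + k1 / 6.0 + k2 / 3.0 + k3 / 3.0 + k4 / 6.0
    if not np.all(np.isfinite(out)):
        raise DivergenceError(float("nan"))
    return out


def simulate(params: ModelParams | None = None,
             fieldcfg: FieldConfig | None = None,
             config: SimulationConfig | None = None,
             on_divergence: str = "raise") -> Trace:
    """Integrate the field-modified model and record the trajectory.

    Parameters default to the published table (with the weak dendritic
    drive Id = 0.7), a zero field and the standard dt = 0.1 ms / 7 s run.
    """
    if on_divergence not in ("raise", "truncate"):
        raise ValueError("on_divergence must be 'raise' or 'truncate'")
    params = params or ModelParams()
    fieldcfg = fieldcfg or FieldConfig()
    config = config or SimulationConfig()

    prm = np.append(params.to_array(), fieldcfg.Ve)
    y0 = config.initial_state.to_array()
    states, n_rec, diverged_step = rk4_run(y0, prm, config.dt, config.n_steps,
                                           config.record_stride)
    diverged_at = None
    if diverged_step >= 0:
        diverged_at = diverged_step * config.dt
        if on_divergence == "raise":
            raise DivergenceError(diverged_at)
    states = states[:n_rec]
    t = np.arange(n_rec) * (config.dt * config.record_stride)
    return Trace(
        time=t, Vs=states[:, 0], Vd=states[:, 1], h=states[:, 2],
        n=states[:, 3], s=states[:, 4], c=states[:, 5], q=states[:, 6],
        Ca=states[:, 7], dt=config.dt * config.record_stride,
        diverged_at=diverged_at,
    )
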