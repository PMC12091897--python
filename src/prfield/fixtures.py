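"""Synthetic voltage traces realizing each firing regime by construction.

These are deterministic piecewise templates (spike triangles, burst
packets, sinusoidal plateaus) — not simulations — built so the classifier
can be unit-tested without integrating the model.  Baselines, amplitudes
and timings mirror what the real model produces in each regime: spikes
overshoot to ~+75 mV from a ~-5 mV baseline, bursts carry ~6 ms intra-burst
intervals, inter-burst intervals run 60-400 ms.
"""

from __future__ import annotations

import numpy as np

from .analysis import Regime
from .integrate import Trace

__all__ = ["make_fixture_traces", "synthetic_trace"]

_BASELINE = -5.0
_SPIKE_PEAK = 75.0


def synthetic_trace(vs: np.ndarray, dt: float = 0.1) -> Trace:
    """Wrap a somatic-voltage array into a Trace (other channels inert)."""
    n = len(vs)
    zeros = np.zeros(n)
    return Trace(
        time=np.arange(n) * dt, Vs=vs.astype(float), Vd=vs.astype(float).copy(),
        h=zeros.copy(), n=zeros.copy(), s=zeros.copy(), c=zeros.copy(),
        q=zeros.copy(), Ca=zeros.copy(), dt=dt,
    )


def _add_spike(vs: np.ndarray, t_ms: float, dt: float,
               peak: float = _SPIKE_PEAK, rise_ms: float = 1.0,
               fall_ms: float = 2.0) -> None:
    i0 = int(round(t_ms / dt))
    n_rise = max(1, int(round(rise_ms / dt)))
    n_fall = max(1, int(round(fall_ms / dt)))
    for k in range(n_rise + 1):
        i = i0 + k
        if 0 <= i < len(vs):
            vs[i] = max(vs[i], _BASELINE + (peak - _BASELINE) * k / n_rise)
    for k in range(1, n_fall + 1):
        i = i0 + n_rise + k
        if 0 <= i < len(vs):
            vs[i] = max(vs[i], peak + (_BASELINE - peak) * k / n_fall)


def _add_burst(vs: np.ndarray, t_ms: float, dt: float, n_spikes: int,
               intra_isi: float = 6.0) -> None:
    for k in range(n_spikes):
        _add_spike(vs, t_ms + k * intra_isi, dt)


def _subosc(vs: np.ndarray, t0: float, t1: float, dt: float,
            amplitude: float = 6.0, period_ms: float = 30.0,
            level: float = _BASELINE) -> None:
    i0, i1 = int(t0 / dt), int(t1 / dt)
    tt = np.arange(i0, min(i1, len(vs))) * dt
    vs[i0:min(i1, len(vs))] = level + amplitude * np.sin(2 * np.pi * (tt - t0) / period_ms)


def make_fixture_traces(dt: float = 0.1, duration: float = 7000.0) -> dict[str, Trace]:
    """One synthetic trace per regime label, keyed by the label value."""
    n = int(round(duration / dt)) + 1
    out: dict[str, Trace] = {}

    def blank() -> np.ndarray:
        return np.full(n, _BASELINE)

    # -- no-spike regimes -------------------------------------------------
    out[Regime.RESTING.value] = synthetic_trace(blank(), dt)

    vs = blank()
    _subosc(vs, 0.0, duration, dt, amplitude=4.0, period_ms=40.0, level=8.0)
    out[Regime.SUBTHRESHOLD_OSCILLATION.value] = synthetic_trace(vs, dt)

    out[Regime.DEPOLARIZATION_BLOCK.value] = synthetic_trace(np.full(n, 31.0), dt)

    vs = blank()
    _subosc(vs, 0.0, duration, dt, amplitude=18.0, period_ms=400.0, level=0.0)
    out[Regime.BIPHASIC_OSCILLATION.value] = synthetic_trace(vs, dt)

    # -- spiking regimes --------------------------------------------------
    vs = blank()
    for t in np.arange(100.0, duration - 20.0, 40.0):
        _add_spike(vs, t, dt)
    out[Regime.PERIODIC_SPIKING.value] = synthetic_trace(vs, dt)

    vs = blank()
    for t in np.arange(100.0, duration - 50.0, 300.0):
        _add_burst(vs, t, dt, 3)
    out[Regime.PERIODIC_BURSTING.value] = synthetic_trace(vs, dt)

    vs = blank()
    t, short = 100.0, True
    while t < duration - 50.0:
        _add_burst(vs, t, dt, 3)
        t += 220.0 if short else 380.0
        short = not short
    out[Regime.PERIOD2_BURSTING.value] = synthetic_trace(vs, dt)

    vs = blank()
    t, burst = 100.0, True
    while t < duration - 50.0:
        if burst:
            _add_burst(vs, t, dt, 3)
        else:
            _add_spike(vs, t, dt)
        t += 180.0
        burst = not burst
    out[Regime.BURST_SPIKE_ALTERNATING.value] = synthetic_trace(vs, dt)

    vs = blank()
    for t in np.arange(100.0, duration - 160.0, 160.0):
        _add_spike(vs, t, dt)
        _subosc(vs, t + 40.0, t + 130.0, dt, amplitude=6.0, period_ms=30.0)
    out[Regime.MIXED_MODE_OSCILLATION.value] = synthetic_trace(vs, dt)

    vs = blank()
    for t in np.arange(100.0, duration - 30.0, 60.0):
        _add_burst(vs, t, dt, 2)
    out[Regime.FAST_BURSTING.value] = synthetic_trace(vs, dt)

    vs = blank()
    t, short = 100.0, True
    while t < duration - 400.0:
        _add_burst(vs, t, dt, 3)
        gap = 250.0 if short else 420.0
        _subosc(vs, t + 60.0, t + gap - 40.0, dt, amplitude=6.0, period_ms=40.0)
        t += gap
        short = not short
    out[Regime.TWO_CYCLE_BURST_SUBTHRESHOLD.value] = synthetic_trace(vs, dt)

    return out
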