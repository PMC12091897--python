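"""Spike detection, firing rate and firing-regime classification.

The source material quantifies firing by a mean rate F without stating a
detection convention, so the conventions here are explicit and configurable
(:class:`ClassifierCriteria`): a spike is an upward crossing of the somatic
voltage through ``spike_threshold`` (default 20 mV — in the shifted-voltage
convention subthreshold activity stays below ~15 mV and spikes overshoot
far above), counted after an initial ``transient_discard`` window; spikes
closer than ``intra_burst_isi_max`` belong to one burst.

Eleven regimes are distinguished.  Without spikes: a persistently
oscillating trace is a subthreshold oscillation (two-sided swings between
depolarized and hyperpolarized plateaus make it biphasic); a quiescent
trace is depolarization block if it sits above ``block_voltage_min`` for at
least ``block_dwell_min``, otherwise resting.  With spikes, bursts are
grouped and the pattern of group sizes and inter-burst intervals decides
between tonic spiking, periodic / period-2 / fast bursting, burst-spike
alternation, mixed-mode oscillation and period-2 bursting with subthreshold
interludes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .integrate import Trace

__all__ = [
    "Regime",
    "SpikeTrain",
    "ClassifierCriteria",
    "detect_spikes",
    "mean_firing_rate",
    "classify_regime",
    "is_sensitive",
    "SPIKING_REGIMES",
]


class Regime(str, enum.Enum):
    RESTING = "resting"
    SUBTHRESHOLD_OSCILLATION = "subthreshold_oscillation"
    PERIODIC_SPIKING = "periodic_spiking"
    PERIODIC_BURSTING = "periodic_bursting"
    PERIOD2_BURSTING = "period2_bursting"
    BURST_SPIKE_ALTERNATING = "burst_spike_alternating"
    MIXED_MODE_OSCILLATION = "mixed_mode_oscillation"
    FAST_BURSTING = "fast_bursting"
    TWO_CYCLE_BURST_SUBTHRESHOLD = "two_cycle_burst_subthreshold"
    BIPHASIC_OSCILLATION = "biphasic_oscillation"
    DEPOLARIZATION_BLOCK = "depolarization_block"


#: Regimes with somatic spikes; a neuron in any of these counts as
#: *sensitive* to the applied field (equivalently F > 0).
SPIKING_REGIMES = frozenset({
    Regime.PERIODIC_SPIKING,
    Regime.PERIODIC_BURSTING,
    Regime.PERIOD2_BURSTING,
    Regime.BURST_SPIKE_ALTERNATING,
    Regime.MIXED_MODE_OSCILLATION,
    Regime.FAST_BURSTING,
    Regime.TWO_CYCLE_BURST_SUBTHRESHOLD,
})


def is_sensitive(regime: Regime | str) -> bool:
    try:
        return Regime(regime) in SPIKING_REGIMES
    except ValueError:
        return False  # e.g. the scan-level "divergent" marker


@dataclass(frozen=True)
class SpikeTrain:
    """Somatic spike times (ms) within an analysis window."""

    spike_times: np.ndarray
    window: tuple[float, float]

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class ClassifierCriteria:
    """Detection and classification conventions (all times ms, voltages mV)."""

    spike_threshold: float = 20.0
    transient_discard: float = 2000.0
    intra_burst_isi_max: float = 25.0
    resting_std_max: float = 0.5
    block_voltage_min: float = 25.0
    block_dwell_min: float = 1000.0
    ibi_cv_tol: float = 0.2          # regularity tolerance on inter-burst intervals
    fast_ibi_max: float = 100.0      # bursting faster than this is "fast bursting"
    period2_rel_gap: float = 0.1     # odd/even IBI means must differ by this fraction
    tail_window: float = 2000.0      # window for judging sustained oscillation
    subosc_prominence: float = 0.5   # peak prominence marking a subthreshold cycle
    alternation_min: float = 0.75    # fraction of type changes for alternation
    mmo_peaks_per_gap: float = 0.5   # mean subthreshold peaks/gap for mixed mode


def detect_spikes(trace: Trace, criteria: ClassifierCriteria | None = None) -> SpikeTrain:
    """Spike times as interpolated upward threshold crossings of Vs.

    One spike per crossing; times are linearly interpolated between the
    samples bracketing the crossing.  The trace must extend at least 1 s
    past the discarded transient.
    """
    criteria = criteria or ClassifierCriteria()
    t0 = criteria.transient_discard
    if trace.duration < t0 + 1000.0:
        raise ValueError(
            f"trace covers {trace.duration:g} ms; need at least "
            f"{t0 + 1000.0:g} ms for spike analysis")
    mask = trace.time >= t0
    t = trace.time[mask]
    v = trace.Vs[mask]
    th = criteria.spike_threshold
    idx = np.nonzero((v[:-1] < th) & (v[1:] >= th))[0]
    frac = (th - v[idx]) / (v[idx + 1] - v[idx])
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    return SpikeTrain(spike_times=times, window=(t0, float(trace.time[-1])))


def mean_firing_rate(train: SpikeTrain) -> float:
    """Spike count over window length, in Hz."""
    lo, hi = train.window
    if hi <= lo:
        raise ValueError("zero-length analysis window")
    return len(train) / ((hi - lo) / 1000.0)


def _burst_groups(times: np.ndarray, isi_max: float) -> list[np.ndarray]:
    if len(times) == 0:
        return []
    breaks = np.nonzero(np.diff(times) > isi_max)[0] + 1
    return np.split(times, breaks)


def _dwell_above(t: np.ndarray, v: np.ndarray, level: float) -> float:
    """Longest contiguous time (ms) the trace spends above ``level``."""
    above = v > level
    if not above.any():
        return 0.0
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(v) - 1)
    return max(float(t[e] - t[s]) for s, e in zip(starts, ends))


def _subthreshold_peaks_per_gap(t: np.ndarray, v: np.ndarray,
                                groups: Sequence[np.ndarray],
                                criteria: ClassifierCriteria,
                                margin: float = 8.0) -> float:
    """Mean number of prominent sub-threshold peaks between spike groups."""
    if len(groups) < 2:
        return 0.0
    counts = []
    for a, b in zip(groups[:-1], groups[1:]):
        lo, hi = a[-1] + margin, b[0] - margin
        if hi - lo < 2.0:
            counts.append(0)
            continue
        seg = v[(t >= lo) & (t <= hi)]
        if len(seg) < 3:
            counts.append(0)
            continue
        pk, _ = find_peaks(seg, prominence=max(criteria.subosc_prominence, 1.0))
        counts.append(int((seg[pk] < criteria.spike_threshold).sum()))
    return float(np.mean(counts))


def _alternation_fraction(multi: np.ndarray) -> float:
    if len(multi) < 2:
        return 0.0
    return float(np.mean(multi[:-1] != multi[1:]))


def _is_period2(ibi: np.ndarray, criteria: ClassifierCriteria) -> bool:
    """Inter-burst intervals alternating between two distinct values."""
    if len(ibi) < 4:
        return False
    even, odd = ibi[::2], ibi[1::2]
    gap = abs(even.mean() - odd.mean())
    if gap < criteria.period2_rel_gap * ibi.mean():
        return False
    spread = max(even.std(), odd.std())
    return spread < 0.5 * gap


def classify_regime(trace: Trace, train: SpikeTrain | None = None,
                    criteria: ClassifierCriteria | None = None) -> Regime:
    """Assign exactly one firing-regime label to a finite trace."""
    criteria = criteria or ClassifierCriteria()
    if train is None:
        train = detect_spikes(trace, criteria)

    mask = trace.time >= criteria.transient_discard
    t = trace.time[mask]
    v = trace.Vs[mask]

    if len(train) == 0:
        # judge persistence of oscillation on the tail, so a decaying
        # transient does not masquerade as sustained oscillation
        tail = v[t >= t[-1] - criteria.tail_window]
        oscillating = False
        if len(tail) > 2:
            pk, _ = find_peaks(tail, prominence=criteria.subosc_prominence)
            oscillating = len(pk) >= 3 or tail.std() >= criteria.resting_std_max
        if oscillating:
            half = criteria.block_voltage_min / 2.0
            if tail.min() < -half and tail.max() > half:
                return Regime.BIPHASIC_OSCILLATION
            return Regime.SUBTHRESHOLD_OSCILLATION
        if _dwell_above(t, v, criteria.block_voltage_min) >= criteria.block_dwell_min:
            return Regime.DEPOLARIZATION_BLOCK
        if tail.std() < criteria.resting_std_max:
            return Regime.RESTING
        return Regime.SUBTHRESHOLD_OSCILLATION

    groups = _burst_groups(train.spike_times, criteria.intra_burst_isi_max)
    sizes = np.array([len(g) for g in groups])
    multi = sizes >= 2
    starts = np.array([g[0] for g in groups])
    ibi = np.diff(starts)
    sub_per_gap = _subthreshold_peaks_per_gap(t, v, groups, criteria)
    mmo = sub_per_gap >= criteria.mmo_peaks_per_gap

    if not multi.any():
        if mmo:
            return Regime.MIXED_MODE_OSCILLATION
        return Regime.PERIODIC_SPIKING

    if multi.all():
        if _is_period2(ibi, criteria):
            if mmo:
                return Regime.TWO_CYCLE_BURST_SUBTHRESHOLD
            return Regime.PERIOD2_BURSTING
        if len(ibi) and ibi.mean() < criteria.fast_ibi_max:
            return Regime.FAST_BURSTING
        return Regime.PERIODIC_BURSTING

    # mixture of isolated spikes and multi-spike bursts
    if _alternation_fraction(multi) >= criteria.alternation_min:
        return Regime.BURST_SPIKE_ALTERNATING
    if mmo and (~multi).mean() > 0.5:
        return Regime.MIXED_MODE_OSCILLATION
    if multi.mean() >= 0.5:
        return Regime.PERIODIC_BURSTING
    return Regime.PERIODIC_SPIKING
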