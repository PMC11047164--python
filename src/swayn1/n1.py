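"""N1 trough detection on the cleaned EEG independent-component trace, and
extraction of labeled multichannel epochs.

The IC trace is baseline-corrected by subtracting its pre-task mean (−5..0 s).
For every detected instability event, the N1 is the most negative local
minimum lying at least two baseline SDs below zero within a −250..−100 ms
window before the event's COPv zero-crossing; events with no qualifying
trough are discarded.  All other sufficiently deep troughs, thinned and kept
clear of N1s, form the control set.  Epochs of −300..+100 ms around each
center carry every channel at its native rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .biomech import BiomechDerived, InstabilityEvent
from .synthetic import SubjectRecording
from .timeseries import TimeSeries

__all__ = [
    "BaselineStats",
    "N1Event",
    "LabeledEpoch",
    "baseline_correct",
    "detect_n1",
    "detect_control_troughs",
    "extract_epochs",
]

logger = logging.getLogger(__name__)

DEFAULT_BASELINE_WINDOW = (-5.0, 0.0)
DEFAULT_SEARCH_WINDOW_MS = (-250.0, -100.0)
DEFAULT_EXCLUSION_MS = 300.0   # control troughs this close to an N1 are dropped
DEFAULT_MIN_SEP_MS = 400.0     # minimum spacing between retained control troughs
EPOCH_WINDOW_S = (-0.3, 0.1)


@dataclass(frozen=True)
class BaselineStats:
    """Mean and SD of the IC trace over the pre-task baseline window."""

    mean: float
    sd: float
    window: tuple = DEFAULT_BASELINE_WINDOW

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("baseline SD must be positive")


@dataclass(frozen=True)
class N1Event:
    """An N1 trough time-locked before an event's corrective zero-crossing."""

    time_s: float
    amplitude: float       # baseline-corrected IC units, negative
    latency_ms: float      # zero_crossing_time - time_s
    event_ref: InstabilityEvent

    def __post_init__(self) -> None:
        if not (100.0 - 1e-6 <= self.latency_ms <= 250.0 + 1e-6):
            raise ValueError(f"latency {self.latency_ms} ms outside 100-250 ms")


@dataclass(frozen=True)
class LabeledEpoch:
    """A −300..+100 ms multichannel window around an N1 (label 1, Instability)
    or a control trough (label 0, Control).

    ``traces`` maps channel name → (relative_times_s, values); channels keep
    their native sampling rates.
    """

    subject_id: str
    center_time_s: float
    label: int
    traces: dict
    window_s: tuple = EPOCH_WINDOW_S


def baseline_correct(ic: TimeSeries, window: tuple = DEFAULT_BASELINE_WINDOW):
    """Subtract the pre-task mean from the whole trace; returns the corrected
    trace and the (mean, SD) of the baseline window."""
    seg = ic.slice(*window)
    if len(seg) == 0:
        raise ValueError("baseline window contains no samples")
    mean = float(seg.data.mean())
    sd = float(seg.data.std(ddof=1)) if len(seg) > 1 else 0.0
    corrected = TimeSeries(ic.data - mean, ic.fs, ic.t0, ic.units)
    return corrected, BaselineStats(mean=mean, sd=sd, window=tuple(window))


def _local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local minima; a plateau yields its first sample."""
    return np.flatnonzero((x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])) + 1


def detect_n1(ic_corrected: TimeSeries, stats: BaselineStats, events: list,
              search_window_ms: tuple = DEFAULT_SEARCH_WINDOW_MS,
              depth_k: float = 2.0) -> list:
    """Per event, the deepest qualifying trough before the zero-crossing.

    Qualifying troughs are local minima with amplitude at or below
    ``-depth_k * stats.sd`` inside ``search_window_ms`` (relative to the
    event's zero-crossing; default −250..−100 ms).  Ties go to the earliest
    trough.  Events with no qualifying trough produce no N1Event.
    """
    lo_ms, hi_ms = search_window_ms
    floor = -depth_k * stats.sd
    out = []
    for ev in events:
        zc = ev.zero_crossing_time_s
        t_lo, t_hi = zc + lo_ms / 1000.0, zc + hi_ms / 1000.0
        if not ic_corrected.covers(t_lo, t_hi):
            logger.warning("N1 search window [%.3f, %.3f] outside recording; "
                           "event skipped", t_lo, t_hi)
            continue
        seg = ic_corrected.slice(t_lo, t_hi)
        mins = _local_minima(seg.data)
        mins = mins[seg.data[mins] <= floor]
        if mins.size == 0:
            continue
        best = mins[np.argmin(seg.data[mins])]  # argmin returns the earliest tie
        t_n1 = seg.t0 + best / seg.fs
        out.append(N1Event(
            time_s=t_n1,
            amplitude=float(seg.data[best]),
            latency_ms=(zc - t_n1) * 1000.0,
            event_ref=ev,
        ))
    return out


def detect_control_troughs(ic_corrected: TimeSeries, stats: BaselineStats,
                           n1s: list,
                           min_sep_ms: float = DEFAULT_MIN_SEP_MS,
                           exclusion_ms: float = DEFAULT_EXCLUSION_MS,
                           task_window: tuple | None = None,
                           events: list | None = None,
                           event_exclusion_s: tuple = (2.45, 1.35)) -> np.ndarray:
    """All other sufficiently deep troughs: local minima at or below
    −2 SD, outside ``exclusion_ms`` of any N1, thinned so retained troughs are
    at least ``min_sep_ms`` apart (deeper troughs win), and far enough from
    the recording edges that a −300..+100 ms epoch fits.

    When ``events`` is given, troughs within ``event_exclusion_s`` (before,
    after) of any event's zero-crossing are also excluded, so epochs drawn
    from the instability excursion or its corrective response cannot enter
    the control class."""
    floor = -2.0 * stats.sd
    x = ic_corrected.data
    idx = _local_minima(x)
    idx = idx[x[idx] <= floor]
    times = ic_corrected.t0 + idx / ic_corrected.fs
    depths = x[idx]

    if task_window is None:
        task_window = (0.0, ic_corrected.t_end)
    lo = max(task_window[0], ic_corrected.t0) - EPOCH_WINDOW_S[0]
    hi = min(task_window[1], ic_corrected.t_end) - EPOCH_WINDOW_S[1]
    keep = (times >= lo) & (times <= hi)
    times, depths = times[keep], depths[keep]

    n1_times = np.asarray([n.time_s for n in n1s])
    if n1_times.size:
        d = np.abs(times[:, None] - n1_times[None, :]).min(axis=1)
        keep = d > exclusion_ms / 1000.0
        times, depths = times[keep], depths[keep]

    if events:
        zcs = np.asarray([ev.zero_crossing_time_s for ev in events])
        before, after = event_exclusion_s
        inside = ((times[:, None] >= zcs[None, :] - before)
                  & (times[:, None] <= zcs[None, :] + after)).any(axis=1)
        times, depths = times[~inside], depths[~inside]

    # greedy thinning, deepest first
    order = np.argsort(depths)  # most negative first
    accepted: list = []
    min_sep = min_sep_ms / 1000.0
    for k in order:
        if all(abs(times[k] - a) >= min_sep for a in accepted):
            accepted.append(times[k])
    return np.sort(np.asarray(accepted))


def extract_epochs(recording: SubjectRecording, derived: BiomechDerived,
                   centers: list) -> list:
    """Clip every channel to −300..+100 ms around each (time, label) center.

    Channels retain native rates: 100 Hz channels contribute 41 samples, 10 Hz
    channels the 4–5 samples whose timestamps fall in the closed window.
    Centers whose window crosses any channel's bounds are dropped.
    """
    channels = {
        "copv": derived.copv,
        "shear": recording.shear_ap,
        "head_acc": recording.head_acc_ap,
        "ttb": derived.ttb,
        "ic": recording.ic_trace,
    }
    w0, w1 = EPOCH_WINDOW_S
    epochs = []
    for center, label in centers:
        if not all(ch.covers(center + w0, center + w1) for ch in channels.values()):
            continue
        traces = {}
        for name, ch in channels.items():
            seg = ch.slice(center + w0, center + w1)
            traces[name] = (seg.times - center, seg.data)
        epochs.append(LabeledEpoch(
            subject_id=recording.subject_id,
            center_time_s=float(center),
            label=int(label),
            traces=traces,
        ))
    return epochs
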