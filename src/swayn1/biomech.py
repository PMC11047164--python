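"""Center-of-pressure biomechanics: COP velocity, distance/time to the
stability boundary, and instability-event detection.

The AP COP velocity (COPv) is estimated with a three-point central difference
(no time delay).  Anterior and posterior foot limits define a per-subject
rectangular stability zone; the distance to boundary (DTB) is measured toward
the boundary the COP is currently moving at, and the time to boundary (TTB)
is DTB divided by the COPv magnitude.  Instability events are supra-threshold
COPv extrema — the threshold being three standard deviations of COPv over the
first quiet-stance trial — each paired with the first subsequent zero-crossing
of COPv, the early biomechanical sign of the corrective balance response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "StabilityZone",
    "InstabilityEvent",
    "BiomechDerived",
    "compute_copv",
    "estimate_copv_threshold",
    "compute_dtb",
    "compute_ttb",
    "detect_instability_events",
    "derive",
]

logger = logging.getLogger(__name__)

DEFAULT_TTB_CAP_S = 10.0
DEFAULT_TTB_VELOCITY_FLOOR = 0.6  # cm/s, posturographic noise floor
DEFAULT_REFRACTORY_S = 0.5
DEFAULT_QUIET_WINDOW = (0.0, 20.0)


@dataclass(frozen=True)
class StabilityZone:
    """Rectangular AP stability zone (anterior positive, origin at the COP
    reference)."""

    anterior_limit_cm: float
    posterior_limit_cm: float

    def __post_init__(self) -> None:
        if not (self.anterior_limit_cm > 0 > self.posterior_limit_cm):
            raise ValueError("require anterior limit > 0 > posterior limit")


@dataclass(frozen=True)
class InstabilityEvent:
    """A supra-threshold COPv extremum and its subsequent zero-crossing."""

    peak_time_s: float
    peak_copv_cm_s: float
    zero_crossing_time_s: float

    def __post_init__(self) -> None:
        if not self.zero_crossing_time_s > self.peak_time_s:
            raise ValueError("zero-crossing must follow the peak")


@dataclass(frozen=True)
class BiomechDerived:
    """Derived series for one subject, sample-aligned with the COP channel."""

    copv: TimeSeries
    dtb: TimeSeries
    ttb: TimeSeries
    copv_threshold_cm_s: float


def compute_copv(cop: TimeSeries) -> TimeSeries:
    """COP velocity by three-point central difference.

    Interior sample ``i`` gets ``(x[i+1] - x[i-1]) * fs / 2``; the endpoints
    get one-sided first differences, so the output has the same length and
    timestamps as the input (no delay).  Exact for linear and quadratic
    trajectories on the interior.
    """
    if len(cop) < 3:
        raise ValueError("need at least 3 samples for a central difference")
    v = np.gradient(cop.data, 1.0 / cop.fs)
    return TimeSeries(v, cop.fs, cop.t0, units="cm/s")


def estimate_copv_threshold(copv: TimeSeries, quiet_window: tuple = DEFAULT_QUIET_WINDOW,
                            k: float = 3.0) -> float:
    """``k`` (default 3) times the sample SD of COPv over the quiet-stance
    window (default: the first 20-s gain-0 trial)."""
    seg = copv.slice(*quiet_window)
    if len(seg) == 0:
        raise ValueError("quiet window contains no samples")
    sd = float(np.std(seg.data, ddof=1)) if len(seg) > 1 else 0.0
    if sd == 0.0:
        logger.warning("degenerate quiet window: COPv SD is zero")
    return k * sd


def compute_dtb(cop: TimeSeries, copv: TimeSeries, zone: StabilityZone) -> TimeSeries:
    """Distance to the boundary in the direction of COP motion.

    Moving anteriorly (COPv > 0): distance to the anterior limit; moving
    posteriorly: distance to the posterior limit; at exactly zero velocity the
    nearer boundary is used.  Samples where the COP lies outside the zone are
    clamped to zero with a warning.
    """
    if len(cop) != len(copv):
        raise ValueError("cop and copv must be sample-aligned")
    x, v = cop.data, copv.data
    d_ant = zone.anterior_limit_cm - x
    d_post = x - zone.posterior_limit_cm
    dtb = np.where(v > 0, d_ant, np.where(v < 0, d_post, np.minimum(d_ant, d_post)))
    n_out = int(np.sum(dtb < 0))
    if n_out:
        logger.warning("COP outside stability zone at %d samples; DTB clamped to 0",
                       n_out)
        dtb = np.maximum(dtb, 0.0)
    return TimeSeries(dtb, cop.fs, cop.t0, units="cm")


def compute_ttb(dtb: TimeSeries, copv: TimeSeries, cap_s: float = DEFAULT_TTB_CAP_S,
                velocity_floor: float = DEFAULT_TTB_VELOCITY_FLOOR) -> TimeSeries:
    """Time to boundary: DTB divided by |COPv|, with a velocity floor
    ``velocity_floor`` (cm/s) guarding the division and a cap ``cap_s``
    bounding near-zero-velocity samples."""
    if cap_s <= 0:
        raise ValueError("cap_s must be positive")
    if np.any(dtb.data < 0):
        raise ValueError("DTB must be non-negative")
    speed = np.maximum(np.abs(copv.data), velocity_floor)
    ttb = np.minimum(dtb.data / speed, cap_s)
    return TimeSeries(ttb, dtb.fs, dtb.t0, units="s")


def detect_instability_events(copv: TimeSeries, threshold: float,
                              refractory_s: float = DEFAULT_REFRACTORY_S) -> list:
    """Supra-threshold COPv extrema paired with their subsequent zero-crossing.

    A candidate peak is a sample whose |COPv| exceeds ``threshold`` and is
    strictly greater than the previous sample's and not less than the next
    sample's magnitude (so a plateau yields its first sample).  Peaks of
    either sign are accepted.  Peaks within ``refractory_s`` of a previously
    accepted peak are dropped, as are peaks with no subsequent sign change of
    COPv before the end of the recording.  The zero-crossing is located at the
    first sample of opposite (or zero) sign, without sub-sample interpolation.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = copv.data
    a = np.abs(v)
    cand = np.flatnonzero(
        (a[1:-1] > threshold) & (a[1:-1] > a[:-2]) & (a[1:-1] >= a[2:])
    ) + 1
    events = []
    last_peak_t = -np.inf
    for i in cand:
        t_peak = copv.t0 + i / copv.fs
        if t_peak - last_peak_t < refractory_s:
            continue
        s = np.sign(v[i])
        rest = v[i + 1:]
        opp = np.flatnonzero(rest * s <= 0)
        if opp.size == 0:
            continue  # no corrective reversal before the recording ends
        j = i + 1 + opp[0]
        events.append(InstabilityEvent(
            peak_time_s=t_peak,
            peak_copv_cm_s=float(v[i]),
            zero_crossing_time_s=copv.t0 + j / copv.fs,
        ))
        last_peak_t = t_peak
    return events


def derive(cop: TimeSeries, zone: StabilityZone,
           quiet_window: tuple = DEFAULT_QUIET_WINDOW,
           ttb_cap_s: float = DEFAULT_TTB_CAP_S,
           velocity_floor: float = DEFAULT_TTB_VELOCITY_FLOOR,
           threshold_override: float | None = None) -> BiomechDerived:
    """Convenience: COPv, DTB, TTB and the per-subject COPv threshold.

    ``threshold_override`` replaces the 3-SD quiet-stance rule when a study
    adjusts the threshold per subject by some other criterion.
    """
    copv = compute_copv(cop)
    thr = (threshold_override if threshold_override is not None
           else estimate_copv_threshold(copv, quiet_window))
    dtb = compute_dtb(cop, copv, zone)
    ttb = compute_ttb(dtb, copv, ttb_cap_s, velocity_floor)
    return BiomechDerived(copv=copv, dtb=dtb, ttb=ttb, copv_threshold_cm_s=thr)
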