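"""Uniformly sampled scalar time series.

All channels in a recording (center of pressure, shear force, head
acceleration, the cleaned EEG independent-component trace) are represented as
:class:`TimeSeries`: a 1-D value array with a sampling rate, a start time on a
shared wall clock, and a unit string.  Timestamps are never stored; sample
``i`` lives at ``t0 + i / fs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = ["TimeSeries", "downsample_signal"]

# slack used when mapping wall-clock intervals to sample indices, so that a
# window boundary landing exactly on a sample is included despite float error
_TIME_TOL = 1e-9


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    data : ndarray, shape (n,)
        Sample values.
    fs : float
        Sampling rate in Hz; must be positive.
    t0 : float
        Wall-clock time of the first sample in seconds.
    units : str
        Physical units of the samples (e.g. ``"cm"``, ``"cm/s"``).
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 1:
            raise ValueError("TimeSeries data must be 1-D")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "data", arr)

    def __len__(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        """Span in seconds from the first sample to one step past the last."""
        return len(self) / self.fs

    @property
    def t_end(self) -> float:
        """Wall-clock time of the last sample."""
        return self.t0 + (len(self) - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to wall-clock time ``t``."""
        return int(round((t - self.t0) * self.fs))

    def slice(self, t_lo: float, t_hi: float) -> "TimeSeries":
        """Samples whose timestamps lie in the closed interval [t_lo, t_hi]."""
        if t_hi < t_lo:
            raise ValueError("empty interval: t_hi < t_lo")
        i0 = int(np.ceil((t_lo - self.t0) * self.fs - _TIME_TOL))
        i1 = int(np.floor((t_hi - self.t0) * self.fs + _TIME_TOL))
        i0 = max(i0, 0)
        i1 = min(i1, len(self) - 1)
        if i1 < i0:
            return replace(self, data=self.data[:0], t0=t_lo)
        return replace(self, data=self.data[i0 : i1 + 1], t0=self.t0 + i0 / self.fs)

    def covers(self, t_lo: float, t_hi: float) -> bool:
        """Whether the closed interval [t_lo, t_hi] lies inside the recording."""
        return (t_lo >= self.t0 - _TIME_TOL) and (t_hi <= self.t_end + _TIME_TOL)


def downsample_signal(x: TimeSeries, target_hz: float) -> TimeSeries:
    """Anti-aliased decimation to a lower, integer-divisor sampling rate.

    A zero-phase FIR low-pass filter (cutoff at the new Nyquist frequency) is
    applied before keeping every ``fs / target_hz``-th sample, so timestamps
    remain on a uniform grid starting at the original start time and no delay
    is introduced.

    Raises
    ------
    ValueError
        If ``target_hz`` exceeds the source rate or the ratio is not an
        integer.
    """
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if target_hz > x.fs:
        raise ValueError(f"cannot upsample: target {target_hz} Hz > source {x.fs} Hz")
    ratio = x.fs / target_hz
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(f"non-integer decimation ratio {ratio} not supported")
    if q == 1:
        return replace(x)
    if len(x) < 3 * q:
        raise ValueError("series too short to decimate with anti-alias filtering")
    data = signal.decimate(x.data, q, ftype="fir", zero_phase=True)
    return TimeSeries(data=data, fs=target_hz, t0=x.t0, units=x.units)
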