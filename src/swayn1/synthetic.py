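"""Synthetic standing-balance cohort generator.

Emulates a sway-referenced standing balance protocol: each subject stands for
nine consecutive 20-s trials (180 s total) on a support surface whose tilt
gain follows a fixed schedule, with a 5-s pre-task baseline recorded for the
EEG independent-component (IC) trace.  The generator produces, per subject:

* anterior–posterior (AP) center of pressure (COP, cm, 100 Hz) — a
  mean-reverting stochastic sway process whose velocity variance scales with
  the magnitude of the surface gain, plus sporadic instability events;
* AP shear force (N, 10 Hz) and AP head acceleration (m/s², generated at
  80 Hz and decimated to 10 Hz) — noisy linear functions of COP velocity;
* one cleaned fronto-central EEG IC trace (unit-SD arbitrary scale, 100 Hz,
  starting 5 s before the task) — band-limited 1/f background noise with an
  N1 trough injected 100–250 ms before each instability's corrective
  zero-crossing, and distractor troughs of comparable depth elsewhere.

Each instability event is a stereotyped COP-velocity excursion: a smooth
sub-threshold approach carrying the COP toward one stability boundary (scaled
so the excursion apex comes within ~2 cm of it), a slow drift holding the COP
slipping toward that boundary, a sharp supra-threshold velocity spike, and a
corrective reversal that forces a zero-crossing of the COP velocity (the
early biomechanical sign of the balance correction) and returns the COP
toward its reference.  Ground-truth event, N1 and distractor times are
recorded so detection stages can be scored.

Everything is a pure function of (CohortParams, subject index): per-subject
random streams are spawned deterministically from the cohort seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .timeseries import TimeSeries, downsample_signal

__all__ = [
    "GainSchedule",
    "SwayParams",
    "EventPulse",
    "N1Params",
    "ChannelCoupling",
    "CohortParams",
    "GroundTruth",
    "SubjectRecording",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

#: Surface-gain order used by the protocol: three quiet-stance trials (gain 0)
#: interleaved with amplifying (positive) and damping (negative) gains.
DEFAULT_GAINS = (0.0, 0.4, 2.0, 0.0, 0.6, -0.4, 0.0, 1.0, -1.0)

COP_FS = 100.0  #: Hz, COP / IC sampling rate
HA_RAW_FS = 80.0  #: Hz, head-accelerometer native rate before decimation
LOW_FS = 10.0  #: Hz, analysis rate for shear and head acceleration
PRETASK_S = 5.0  #: seconds of pre-task baseline carried by the IC trace


@dataclass(frozen=True)
class GainSchedule:
    """Sequence of surface sway-referencing gains, one per fixed-length trial."""

    gains: tuple = DEFAULT_GAINS
    trial_duration_s: float = 20.0

    def __post_init__(self) -> None:
        if len(self.gains) == 0:
            raise ValueError("gain schedule must contain at least one trial")
        if self.trial_duration_s <= 0:
            raise ValueError("trial duration must be positive")

    @property
    def total_duration_s(self) -> float:
        return len(self.gains) * self.trial_duration_s

    def gain_at(self, t: np.ndarray) -> np.ndarray:
        """Gain in effect at task time(s) ``t`` (seconds, 0 = task onset)."""
        t = np.asarray(t, dtype=float)
        idx = np.clip(
            (t / self.trial_duration_s).astype(int), 0, len(self.gains) - 1
        )
        return np.asarray(self.gains, dtype=float)[idx]


@dataclass(frozen=True)
class SwayParams:
    """Background sway model: velocity is an Ornstein–Uhlenbeck process that a
    leaky integrator turns into a bounded COP position.

    ``quiet_copv_sd_cm_s`` sets the stationary COP-velocity SD during gain-0
    trials; trials with gain ``g`` scale it by ``1 + gain_sd_slope * |g|``.
    """

    relaxation_s: float = 0.04         # velocity OU correlation time
    position_relaxation_s: float = 80.0  # leak keeping the COP near its reference
    quiet_copv_sd_cm_s: float = 0.5
    gain_sd_slope: float = 0.1
    # slow postural lean: a <0.03 Hz positional drift (cm) saturating at
    # lean_sat_cm, anchored at zero at task onset; its velocity is negligible
    # against the sway velocity but it carries the COP toward one boundary
    lean_sd_cm: float = 0.6
    lean_sat_cm: float = 1.5
    lean_cutoff_hz: float = 0.015


@dataclass(frozen=True)
class EventPulse:
    """Kinematics of one injected instability event, relative to its
    corrective zero-crossing at time 0.

    The velocity waveform has four phases.  An *approach* — a smooth
    sub-threshold velocity bump (``approach_amplitude_cm_s``,
    ``approach_duration_ms``) — carries the COP toward one stability
    boundary.  A *drift* — a ramp to ``drift_amplitude_cm_s`` followed by a
    plateau (``drift_duration_ms``, ending when the spike begins) — holds the
    COP slipping toward that boundary; this is the phase the pre-response
    feature window observes.  A half-sine velocity *spike* of height
    ``peak_copv_cm_s`` and width ``duration_ms`` is the supra-threshold peak
    the event detector keys on.  A *corrective* reversal
    (``corrective_duration_ms``; fast attack, slow release) forces the
    zero-crossing of COP velocity at time 0 and returns the COP, cancelling
    the accumulated displacement.
    """

    peak_copv_cm_s: float = 10.0
    duration_ms: float = 120.0
    drift_amplitude_cm_s: float = 0.65
    drift_duration_ms: float = 1000.0
    drift_ramp_ms: float = 200.0
    approach_amplitude_cm_s: float = 3.2
    approach_duration_ms: float = 1000.0
    corrective_duration_ms: float = 1200.0

    @property
    def span_s(self) -> tuple:
        """(start, end) of the waveform relative to the zero-crossing."""
        return (-(self.drift_duration_ms + self.duration_ms
                  + self.approach_duration_ms) / 1000.0,
                self.corrective_duration_ms / 1000.0)


#: IC background amplitude during the task relative to the pre-task baseline
#: (task-related desynchronization of the resting background); reached via a
#: 1-s ramp after task onset.
TASK_IC_SCALE = 0.7


@dataclass(frozen=True)
class N1Params:
    """Injected N1 trough: an inverted Gaussian on the IC trace whose center
    precedes the event's corrective zero-crossing by ``latency_mean_ms`` on
    average.  Amplitude is in units of the IC baseline SD."""

    amplitude_sd: float = 3.0
    latency_mean_ms: float = 165.0
    latency_sd_ms: float = 10.0
    width_fwhm_ms: float = 80.0


@dataclass(frozen=True)
class ChannelCoupling:
    """Linear coupling of shear force and head acceleration to COP velocity,
    with additive white noise at the native sampling rate.

    Both channels are driven by a low-pass-filtered COPv rather than the
    instantaneous value: shear tracks whole-body (COM) inertia and head
    acceleration the even slower head kinematics, so each reflects the slow
    component of the COP velocity plus its own noise.  This keeps the
    channels moderately — not collinearly — correlated with COPv.
    """

    shear_gain_n_per_cm_s: float = 1.2
    shear_noise_sd_n: float = 0.4
    shear_cutoff_hz: float = 0.5
    head_gain_ms2_per_cm_s: float = 0.15
    head_noise_sd_ms2: float = 0.4
    head_cutoff_hz: float = 0.6


@dataclass(frozen=True)
class CohortParams:
    """Free parameters of the synthetic cohort.

    ``event_rate_hz`` is the mean rate of instability events per second of
    task (events are a renewal process with a 3.5-s dead time so excursions
    never overlap).  ``distractor_rate_hz`` is the rate at which control
    troughs are injected into the IC trace away from events; its default is
    set so that detected control epochs outnumber instability epochs roughly
    two to one.
    """

    n_subjects: int = 10
    event_rate_hz: float = 0.19
    event_pulse: EventPulse = field(default_factory=EventPulse)
    n1_params: N1Params = field(default_factory=N1Params)
    distractor_rate_hz: float = 2.2
    channel_coupling: ChannelCoupling = field(default_factory=ChannelCoupling)
    sway_params: SwayParams = field(default_factory=SwayParams)
    stability_limits_cm: tuple = (6.0, -5.0)
    limit_jitter_cm: float = 0.5  # per-subject uniform jitter of each limit
    gain_schedule: GainSchedule = field(default_factory=GainSchedule)
    seed: int = 0

    def validate(self) -> None:
        if self.event_rate_hz < 0 or self.distractor_rate_hz < 0:
            raise ValueError("rates must be non-negative")
        lat = self.n1_params.latency_mean_ms
        if not (100.0 <= lat <= 250.0):
            raise ValueError(
                f"N1 latency mean {lat} ms outside the 100-250 ms window")
        if not (0.0 < lat < 300.0):  # pragma: no cover - subsumed above
            raise ValueError("latency window outside (0, 300) ms")
        ant, post = self.stability_limits_cm
        if not (ant > 0 > post):
            raise ValueError("anterior limit must be > 0 > posterior limit")
        if self.sway_params.relaxation_s <= 0 or self.sway_params.position_relaxation_s <= 0:
            raise ValueError("sway relaxation times must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Simulator oracle: true event, N1 and distractor times (seconds)."""

    event_zero_crossings: np.ndarray
    n1_times: np.ndarray
    control_trough_times: np.ndarray

    def __post_init__(self) -> None:
        for name in ("event_zero_crossings", "n1_times", "control_trough_times"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"{name} must be sorted ascending")
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class SubjectRecording:
    """All channels and metadata for one subject.

    ``cop_ap`` (cm, 100 Hz), ``shear_ap`` (N, 10 Hz) and ``head_acc_ap``
    (m/s², 10 Hz) span the task period; ``ic_trace`` (unit-SD scale, 100 Hz)
    additionally carries the 5-s pre-task baseline.  Anterior is positive.
    """

    subject_id: str
    cop_ap: TimeSeries
    shear_ap: TimeSeries
    head_acc_ap: TimeSeries
    ic_trace: TimeSeries
    stability_limits_cm: tuple
    gain_schedule: GainSchedule
    truth: GroundTruth | None = None


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited 1/f noise, band-passed 1–20 Hz (mimicking the high-pass
    applied to EEG before component extraction and the low-pass smoothness of
    a cleaned event-related component), normalized to unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    sos = _sig.butter(2, [1.0, 20.0], btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, x)
    return x / x.std()


def _event_velocity_waveform(pulse: EventPulse, fs: float,
                             approach_disp_cm: float | None = None) -> np.ndarray:
    """Velocity waveform (cm/s) of one event, sampled at ``fs``; index 0 is
    the waveform start (``pulse.span_s[0]`` relative to the crossing).

    ``approach_disp_cm`` overrides the approach bump's displacement (its
    amplitude is scaled accordingly); the default uses
    ``approach_amplitude_cm_s``."""
    start, end = pulse.span_s
    t = np.arange(int(round((end - start) * fs)) + 1) / fs + start
    v = np.zeros_like(t)
    ramp = pulse.drift_ramp_ms / 1000.0
    spike_d = pulse.duration_ms / 1000.0
    app_d = pulse.approach_duration_ms / 1000.0
    drift_start = start + app_d
    spike_start = -spike_d
    a_d = pulse.drift_amplitude_cm_s

    # approach: smooth sin^2 bump carrying the COP toward the boundary
    a_app = pulse.approach_amplitude_cm_s
    if approach_disp_cm is not None:
        a_app = 2.0 * approach_disp_cm / app_d  # sin^2 bump area = A*D/2
    m = (t >= start) & (t < drift_start)
    v[m] += a_app * np.sin(np.pi * (t[m] - start) / app_d) ** 2

    m = (t >= drift_start) & (t < drift_start + ramp)
    v[m] = a_d * (t[m] - drift_start) / ramp
    m = (t >= drift_start + ramp) & (t < spike_start)
    v[m] = a_d
    # spike region: drift decays linearly to zero while the half-sine spike
    # rides on top, so total injected velocity reaches 0 exactly at t = 0
    m = (t >= spike_start) & (t < 0)
    v[m] = a_d * (-t[m] / spike_d) + pulse.peak_copv_cm_s * np.sin(
        np.pi * (t[m] - spike_start) / spike_d
    )
    # corrective reversal: a fast quarter-sine attack (so the zero-crossing
    # slope stays steep against background sway) followed by a slow release,
    # with amplitude chosen so its area cancels the displacement accrued
    disp = np.sum(v[t < 0]) / fs
    corr_d = pulse.corrective_duration_ms / 1000.0
    attack = min(0.08, corr_d / 2)
    tc = np.clip(t, 0.0, corr_d)
    shape = np.where(
        tc < attack,
        np.sin(np.pi * tc / (2 * attack)),
        np.cos(np.pi * (tc - attack) / (2 * (corr_d - attack))),
    )
    shape[t < 0] = 0.0
    shape[t > corr_d] = 0.0
    a_c = disp / (np.sum(shape) / fs)
    v[t >= 0] = (-a_c * shape)[t >= 0]
    return v


def _draw_event_times(rng: np.random.Generator, rate_hz: float,
                      duration_s: float, pulse: EventPulse,
                      weight_fn=None) -> np.ndarray:
    """Renewal process with mean rate ``rate_hz`` and a dead time long enough
    that successive event waveforms never overlap.

    ``weight_fn(t) -> p in [0, 1]`` optionally modulates where events may
    start (rejected candidates are re-proposed shortly after), so event
    timing can depend on the slow postural state."""
    if rate_hz <= 0:
        return np.empty(0)
    dead = 3.5  # > event span so successive excursions cannot overlap
    mean_gap = 1.0 / rate_hz
    if mean_gap <= dead:
        raise ValueError("event_rate_hz too high for non-overlapping events")
    lo = -pulse.span_s[0] + 0.5  # full drift history inside the task
    hi = duration_s - pulse.span_s[1] - 0.4
    times = []
    t = lo + rng.exponential(mean_gap - dead)
    while t < hi:
        if weight_fn is None or rng.uniform() < weight_fn(t):
            times.append(t)
            t += dead + rng.exponential(mean_gap - dead)
        else:
            t += 0.3 + rng.exponential(0.5)  # retry shortly after
    return np.asarray(times)


def generate_subject(params: CohortParams, subject_index: int) -> SubjectRecording:
    """Generate one subject's recording; deterministic given
    ``(params.seed, subject_index)``.
    """
    params.validate()
    if not (0 <= subject_index < params.n_subjects):
        raise ValueError("subject_index out of range")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(subject_index,))
    )
    sched = params.gain_schedule
    dur = sched.total_duration_s
    fs = COP_FS
    n = int(round(dur * fs))
    t = np.arange(n) / fs

    # per-subject stability limits, jittered around the cohort values
    ant0, post0 = params.stability_limits_cm
    j = params.limit_jitter_cm
    ant = ant0 + rng.uniform(-j, j)
    post = post0 + rng.uniform(-j, j)

    # --- background sway: OU velocity integrated with a positional leak ---
    sp = params.sway_params
    sd_v = sp.quiet_copv_sd_cm_s * (1.0 + sp.gain_sd_slope * np.abs(sched.gain_at(t)))
    dt = 1.0 / fs
    sigma_w = sd_v * np.sqrt(2.0 / sp.relaxation_s)
    noise = rng.standard_normal(n) * sigma_w * np.sqrt(dt)
    v_bg = np.empty(n)
    x_bg = np.empty(n)
    v = 0.0
    x = 0.0
    a_v = dt / sp.relaxation_s
    a_x = dt / sp.position_relaxation_s
    for i in range(n):
        v_bg[i] = v
        x_bg[i] = x
        v += -v * a_v + noise[i]
        x += v * dt - x * a_x

    # slow postural lean superposed on the fast sway
    lean = np.zeros(n)
    if sp.lean_sd_cm > 0:
        raw = rng.standard_normal(n)
        sos_lean = _sig.butter(2, sp.lean_cutoff_hz, btype="lowpass", fs=fs,
                               output="sos")
        lean = _sig.sosfiltfilt(sos_lean, raw)
        lean *= sp.lean_sd_cm / max(lean.std(), 1e-12)
        lean = sp.lean_sat_cm * np.tanh((lean - lean[0]) / sp.lean_sat_cm)
        x_bg += lean

    # --- instability event times -------------------------------------------
    zc_times = _draw_event_times(rng, params.event_rate_hz, dur,
                                 params.event_pulse)
    zc_times = np.round(zc_times * fs) / fs  # snap to the 100 Hz grid

    # --- instability events -------------------------------------------------
    # the approach bump is scaled per event so the excursion's deepest point
    # comes within ~boundary_gap_cm of the boundary it heads for, wherever
    # the COP happens to be standing
    ep = params.event_pulse
    boundary_gap = 2.1  # cm left between the excursion apex and the boundary
    base_wave = _event_velocity_waveform(ep, fs, approach_disp_cm=0.0)
    base_disp = float((np.cumsum(base_wave) * dt).max())  # drift + spike only
    max_app = 2.0  # cm, cap keeping the approach bump sub-threshold
    x_ev = np.zeros(n)
    for k, zc in enumerate(zc_times):
        i0 = int(round((zc + ep.span_s[0]) * fs))
        x_here = x_bg[min(i0, n - 1)] + x_ev[min(i0, n - 1)]
        # instabilities develop toward the boundary the subject is already
        # leaning to; direction is random when the COP sits near its reference
        if abs(x_here) < 0.5:
            sign = rng.choice((-1.0, 1.0))
        else:
            sign = float(np.sign(x_here))
        headroom = (ant - x_here) if sign > 0 else (x_here - post)
        if headroom < base_disp + 0.2:  # about to hit the wall: correct away
            sign = -sign
            headroom = (ant - x_here) if sign > 0 else (x_here - post)
        app_disp = float(np.clip(headroom - boundary_gap - base_disp, 0.0, max_app))
        wave = _event_velocity_waveform(ep, fs, approach_disp_cm=app_disp)
        wave_disp = np.cumsum(wave) * dt
        seg = slice(i0, min(i0 + len(wave_disp), n))
        x_ev[seg] += sign * wave_disp[: seg.stop - seg.start]

    cop = x_bg + x_ev
    # hard safety clamp: the COP never exits the stability zone (no falls)
    np.clip(cop, post * 0.99, ant * 0.99, out=cop)

    # --- coupled channels ---------------------------------------------------
    copv = np.gradient(cop, dt)
    cc = params.channel_coupling

    def _slow(x, fc, rate):
        sos = _sig.butter(2, fc, btype="lowpass", fs=rate, output="sos")
        return _sig.sosfiltfilt(sos, x)

    sh100 = (cc.shear_gain_n_per_cm_s * _slow(copv, cc.shear_cutoff_hz, fs)
             + rng.standard_normal(n) * cc.shear_noise_sd_n)
    shear = downsample_signal(TimeSeries(sh100, fs, 0.0, "N"), LOW_FS)

    n80 = int(round(dur * HA_RAW_FS))
    t80 = np.arange(n80) / HA_RAW_FS
    copv80 = np.interp(t80, t, copv)
    ha80 = (cc.head_gain_ms2_per_cm_s * _slow(copv80, cc.head_cutoff_hz, HA_RAW_FS)
            + rng.standard_normal(n80) * cc.head_noise_sd_ms2)
    head_acc = downsample_signal(TimeSeries(ha80, HA_RAW_FS, 0.0, "m/s^2"), LOW_FS)

    # --- IC trace: pink-noise background + N1 and distractor troughs --------
    n_ic = int(round((PRETASK_S + dur) * fs))
    t_ic = -PRETASK_S + np.arange(n_ic) / fs
    ic = _pink_noise(n_ic, fs, rng)
    # background desynchronizes (shrinks) once the balance task starts
    scale = 1.0 - (1.0 - TASK_IC_SCALE) * np.clip(t_ic, 0.0, 1.0)
    ic *= scale
    baseline_sd = ic[t_ic < 0].std()

    n1p = params.n1_params
    lat = rng.normal(n1p.latency_mean_ms, n1p.latency_sd_ms, size=len(zc_times)) / 1000.0
    np.clip(lat, 0.105, 0.245, out=lat)
    n1_times = np.round((zc_times - lat) * fs) / fs
    sigma_t = n1p.width_fwhm_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def _add_trough(center: float, depth_sd: float) -> None:
        m = np.abs(t_ic - center) < 5 * sigma_t
        ic[m] -= depth_sd * baseline_sd * np.exp(
            -((t_ic[m] - center) ** 2) / (2 * sigma_t**2)
        )

    for c in n1_times:
        _add_trough(c, n1p.amplitude_sd)

    # distractor troughs: Poisson times kept away from event footprints
    span = params.event_pulse.span_s
    n_distr = rng.poisson(params.distractor_rate_hz * dur)
    cand = np.sort(rng.uniform(0.5, dur - 0.3, size=n_distr))
    cand = np.round(cand * fs) / fs
    distractors = []
    for c in cand:
        if len(zc_times):
            near = (zc_times + span[0] - 0.15 <= c) & (c <= zc_times + span[1] + 0.15)
            if np.any(near):
                continue
        if distractors and c - distractors[-1] < 0.5:
            continue
        distractors.append(c)
    distractors = np.asarray(distractors)
    depths = np.maximum(rng.normal(3.0, 0.3, size=len(distractors)), 2.4)
    for c, d in zip(distractors, depths):
        _add_trough(c, d)

    truth = GroundTruth(
        event_zero_crossings=zc_times,
        n1_times=np.sort(n1_times),
        control_trough_times=distractors,
    )
    return SubjectRecording(
        subject_id=f"S{subject_index:02d}",
        cop_ap=TimeSeries(cop, fs, 0.0, "cm"),
        shear_ap=shear,
        head_acc_ap=head_acc,
        ic_trace=TimeSeries(ic, fs, -PRETASK_S, "a.u."),
        stability_limits_cm=(float(ant), float(post)),
        gain_schedule=sched,
        truth=truth,
    )


def generate_cohort(params: CohortParams) -> list:
    """Generate all subjects; rejects cohorts of fewer than two subjects
    (leave-one-subject-out evaluation needs at least two)."""
    params.validate()
    if params.n_subjects < 2:
        raise ValueError("need at least 2 subjects for leave-one-subject-out")
    return [generate_subject(params, i) for i in range(params.n_subjects)]


# ---------------------------------------------------------------------------
# cohort disk layout


def _write_channel(path: Path, ts: TimeSeries) -> None:
    arr = np.column_stack([ts.times, ts.data])
    np.savetxt(path, arr, delimiter=",", header="time_s,value", comments="",
               fmt="%.6f")


def _read_channel(path: Path, fs: float, units: str) -> TimeSeries:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return TimeSeries(arr[:, 1], fs, float(arr[0, 0]), units)


def write_cohort(recordings: list, out_dir, params: CohortParams | None = None) -> Path:
    """Write one directory per subject (`cop.csv`, `shear.csv`, `headacc.csv`,
    `ic.csv`, `meta.json`, optional `truth.json`) plus a cohort
    `manifest.json`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subj_dirs = []
    for rec in recordings:
        d = out / rec.subject_id
        d.mkdir(exist_ok=True)
        _write_channel(d / "cop.csv", rec.cop_ap)
        _write_channel(d / "shear.csv", rec.shear_ap)
        _write_channel(d / "headacc.csv", rec.head_acc_ap)
        _write_channel(d / "ic.csv", rec.ic_trace)
        meta = {
            "subject_id": rec.subject_id,
            "rates_hz": {"cop": rec.cop_ap.fs, "shear": rec.shear_ap.fs,
                         "headacc": rec.head_acc_ap.fs, "ic": rec.ic_trace.fs},
            "units": {"cop": rec.cop_ap.units, "shear": rec.shear_ap.units,
                      "headacc": rec.head_acc_ap.units, "ic": rec.ic_trace.units},
            "stability_limits_cm": list(rec.stability_limits_cm),
            "gain_schedule": {"gains": list(rec.gain_schedule.gains),
                              "trial_duration_s": rec.gain_schedule.trial_duration_s},
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))
        if rec.truth is not None:
            truth = {
                "event_zero_crossings": rec.truth.event_zero_crossings.tolist(),
                "n1_times": rec.truth.n1_times.tolist(),
                "control_trough_times": rec.truth.control_trough_times.tolist(),
            }
            (d / "truth.json").write_text(json.dumps(truth, indent=1))
        subj_dirs.append(rec.subject_id)
    manifest = {"subjects": subj_dirs}
    if params is not None:
        manifest["params"] = json.loads(json.dumps(
            dataclasses.asdict(params), default=lambda o: list(o)))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_cohort(cohort_dir) -> list:
    """Read a cohort previously written by :func:`write_cohort`."""
    root = Path(cohort_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    recs = []
    for sid in manifest["subjects"]:
        d = root / sid
        meta = json.loads((d / "meta.json").read_text())
        rates, units = meta["rates_hz"], meta["units"]
        truth = None
        if (d / "truth.json").exists():
            tr = json.loads((d / "truth.json").read_text())
            truth = GroundTruth(
                event_zero_crossings=np.asarray(tr["event_zero_crossings"]),
                n1_times=np.asarray(tr["n1_times"]),
                control_trough_times=np.asarray(tr["control_trough_times"]),
            )
        recs.append(SubjectRecording(
            subject_id=meta["subject_id"],
            cop_ap=_read_channel(d / "cop.csv", rates["cop"], units["cop"]),
            shear_ap=_read_channel(d / "shear.csv", rates["shear"], units["shear"]),
            head_acc_ap=_read_channel(d / "headacc.csv", rates["headacc"], units["headacc"]),
            ic_trace=_read_channel(d / "ic.csv", rates["ic"], units["ic"]),
            stability_limits_cm=tuple(meta["stability_limits_cm"]),
            gain_schedule=GainSchedule(tuple(meta["gain_schedule"]["gains"]),
                                       meta["gain_schedule"]["trial_duration_s"]),
            truth=truth,
        ))
    return recs
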