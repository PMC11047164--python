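import numpy as np
import pytest

from swayn1 import n1 as n1m
from swayn1.biomech import InstabilityEvent
from swayn1.timeseries import TimeSeries

FS = 100.0


def _ic(data, t0=-5.0):
    return TimeSeries(np.asarray(data, dtype=float), FS, t0)


def _noise_ic(seed=0, dur=30.0, sd=1.0):
    rng = np.random.default_rng(seed)
    n = int((5.0 + dur) * FS)
    return _ic(rng.normal(0, sd, n))


def _event(zc):
    return InstabilityEvent(peak_time_s=zc - 0.07, peak_copv_cm_s=8.0,
                            zero_crossing_time_s=zc)


class TestBaseline:
    def test_constant_trace(self):
        ic = _ic(np.full(1000, 1.7))
        corrected, stats = n1m.baseline_correct(ic)
        assert np.allclose(corrected.data, 0.0)
        assert stats.mean == pytest.approx(1.7)

    def test_stats_match_direct_recomputation(self):
        ic = _noise_ic(seed=1)
        corrected, stats = n1m.baseline_correct(ic)
        pre = ic.slice(-5.0, 0.0).data
        assert stats.mean == pytest.approx(pre.mean())
        assert stats.sd == pytest.approx(pre.std(ddof=1))
        assert corrected.slice(-5.0, 0.0).data.mean() == pytest.approx(0.0, abs=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            n1m.baseline_correct(_ic(np.ones(100), t0=0.0), window=(-5.0, -1.0))


class TestDetectN1:
    def test_flat_trace_yields_nothing(self):
        ic = _ic(np.zeros(3000))
        _, stats = n1m.baseline_correct(_noise_ic(seed=2))
        assert n1m.detect_n1(ic, stats, [_event(10.0)]) == []

    def test_injected_trough_recovered_with_small_latency_error(self):
        ic = _noise_ic(seed=3, sd=0.2)
        corrected, stats_full = n1m.baseline_correct(ic)
        # inject a -3 SD Gaussian trough 160 ms before the crossing
        zc, depth = 12.0, 3.0 * stats_full.sd
        t = corrected.times
        sigma = 0.080 / 2.355
        data = corrected.data - depth * np.exp(-((t - (zc - 0.160)) ** 2)
                                               / (2 * sigma**2))
        n1s = n1m.detect_n1(_ic(data), stats_full, [_event(zc)])
        assert len(n1s) == 1
        assert n1s[0].latency_ms == pytest.approx(160.0, abs=10.0)
        assert n1s[0].amplitude <= -2.0 * stats_full.sd

    def test_trough_outside_window_not_selected(self):
        ic = _noise_ic(seed=4, sd=0.2)
        corrected, stats = n1m.baseline_correct(ic)
        zc = 12.0
        t = corrected.times
        sigma = 0.080 / 2.355
        # 60 ms before the crossing: later than the -100 ms window edge
        data = corrected.data - 3.0 * stats.sd * np.exp(
            -((t - (zc - 0.060)) ** 2) / (2 * sigma**2))
        assert n1m.detect_n1(_ic(data), stats, [_event(zc)]) == []

    def test_window_outside_recording_skips_event(self):
        ic = _noise_ic(seed=5, dur=10.0)
        corrected, stats = n1m.baseline_correct(ic)
        out = n1m.detect_n1(corrected, stats, [_event(10.2)])
        assert out == []

    def test_latency_invariant_enforced(self):
        with pytest.raises(ValueError):
            n1m.N1Event(time_s=1.0, amplitude=-3.0, latency_ms=50.0,
                        event_ref=_event(1.05))


class TestControlTroughs:
    def test_shallow_trace_yields_nothing(self):
        rng = np.random.default_rng(6)
        data = rng.uniform(-0.1, 0.1, 3500)
        corrected, stats = n1m.baseline_correct(_noise_ic(seed=7))
        out = n1m.detect_control_troughs(_ic(data), stats, [])
        assert out.size == 0

    def test_thinning_keeps_deeper_of_close_pair(self):
        ic = _noise_ic(seed=8, sd=0.05, dur=20.0)
        corrected, stats = n1m.baseline_correct(ic)
        t = corrected.times
        sigma = 0.030
        data = corrected.data.copy()
        data -= 2.0 * np.exp(-((t - 10.0) ** 2) / (2 * sigma**2))   # shallower
        data -= 3.0 * np.exp(-((t - 10.1) ** 2) / (2 * sigma**2))   # deeper
        out = n1m.detect_control_troughs(_ic(data), stats, [],
                                         min_sep_ms=400.0)
        near = out[(out > 9.5) & (out < 10.5)]
        assert len(near) == 1
        assert near[0] == pytest.approx(10.1, abs=0.02)

    def test_exclusion_radius_around_n1(self):
        ic = _noise_ic(seed=9, sd=0.05, dur=20.0)
        corrected, stats = n1m.baseline_correct(ic)
        t = corrected.times
        data = corrected.data - 3.0 * np.exp(-((t - 10.0) ** 2) / (2 * 0.03**2))
        fake_n1 = n1m.N1Event(time_s=9.85, amplitude=-1.0, latency_ms=150.0,
                              event_ref=_event(10.0))
        out = n1m.detect_control_troughs(_ic(data), stats, [fake_n1],
                                         exclusion_ms=300.0)
        assert not np.any(np.abs(out - 10.0) < 0.05)


class TestEpochs:
    def test_epoch_window_counts_and_truth_alignment(self, default_cohort,
                                                     cohort_detection):
        detail, epochs = cohort_detection
        assert len(epochs) > 0
        for e in epochs[:50]:
            t_ic, x_ic = e.traces["ic"]
            assert len(x_ic) == 41  # 400 ms at 100 Hz, closed interval
            assert len(e.traces["copv"][1]) == 41
            assert 2 <= len(e.traces["shear"][1]) <= 5
        # instability epoch centers track the injected N1 times: mostly to
        # sample precision, always within the injected trough's half-width
        truth = {rec.subject_id: rec.truth for rec in default_cohort}
        errs = np.array([
            np.abs(truth[e.subject_id].n1_times - e.center_time_s).min()
            for e in epochs if e.label == 1])
        assert np.mean(errs <= 0.0105) >= 0.7
        assert np.max(errs) <= 0.050

    def test_center_near_recording_start_dropped(self, subject0,
                                                 cohort_detection):
        detail, _ = cohort_detection
        derived = detail[subject0.subject_id]["derived"]
        out = n1m.extract_epochs(subject0, derived, [(0.1, 0)])
        assert out == []

    def test_classes_have_disjoint_centers(self, cohort_detection):
        _, epochs = cohort_detection
        ones = {(e.subject_id, round(e.center_time_s, 4))
                for e in epochs if e.label == 1}
        zeros = {(e.subject_id, round(e.center_time_s, 4))
                 for e in epochs if e.label == 0}
        assert ones.isdisjoint(zeros)
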