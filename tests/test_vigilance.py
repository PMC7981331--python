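import numpy as np
import pytest

from eegarousal import (
    CapabilityError,
    ClassifierConfig,
    SegmentFeatures,
    ValidationError,
    band_powers,
    classify_recording,
    classify_segment,
    detect_graphoelements,
    detect_sem,
    spectral_features,
)
from eegarousal.pipeline import process_recording
from eegarousal.preprocess import PreprocessConfig
from eegarousal.synth import MINIMAL_CHANNELS, make_stage_script, synthesize_recording
from eegarousal.vigilance import SCORE_STAGES, STAGE_SCORES

SFREQ = 256.0


def _sine(freq, duration=1.0, amp=10.0, sfreq=SFREQ, phase=0.0):
    t = np.arange(int(sfreq * duration)) / sfreq
    return amp * np.sin(2 * np.pi * freq * t + phase)


def _features(rel_alpha, slow, roi="occipital", sem=False, spindle=False, kc=False):
    return SegmentFeatures(
        band_power={},
        roi_alpha={"occipital": 1.0, "parietal": 0.5, "frontal": 0.25},
        max_roi=roi,
        relative_alpha=rel_alpha,
        slowwave_relative=slow,
        sem_present=sem,
        spindle_present=spindle,
        kcomplex_present=kc,
    )


class TestStageScoreMapping:
    def test_bijection_matches_ordering(self):
        assert STAGE_SCORES == {
            "0": 7, "A1": 6, "A2": 5, "A3": 4, "B1": 3, "B2/3": 2, "C": 1,
        }
        for name, score in STAGE_SCORES.items():
            assert SCORE_STAGES[score] == name


class TestBandPowers:
    def test_pure_alpha_dominates(self):
        bp = band_powers(_sine(10.0, amp=30.0), SFREQ)
        total = sum(float(v.sum()) for v in bp.values())
        assert bp["alpha"].sum() / total > 0.95

    def test_zero_signal_zero_power(self):
        bp = band_powers(np.zeros(int(SFREQ)), SFREQ)
        assert all(float(v.sum()) == 0.0 for v in bp.values())

    def test_white_noise_power_proportional_to_bandwidth(self):
        rng = np.random.default_rng(0)
        acc = {b: 0.0 for b in ("delta", "theta", "alpha", "beta")}
        for _ in range(300):
            bp = band_powers(rng.standard_normal(int(SFREQ)), SFREQ)
            for b in acc:
                acc[b] += float(bp[b].sum())
        # bandwidths 2 : 3 : 4 : 13 Hz
        widths = {"delta": 2, "theta": 3, "alpha": 4, "beta": 13}
        per_hz = {b: acc[b] / widths[b] for b in acc}
        vals = np.array(list(per_hz.values()))
        assert vals.max() / vals.min() < 1.15

    def test_wrong_segment_length_rejected(self):
        with pytest.raises(ValidationError):
            band_powers(np.zeros(100), SFREQ)


class TestSemDetection:
    def test_flat_eog_negative(self):
        assert not detect_sem(np.zeros(int(3 * SFREQ)), SFREQ)

    def test_slow_large_deflection_positive(self):
        assert detect_sem(_sine(0.3, duration=3.0, amp=50.0), SFREQ)

    def test_fast_blink_surrogate_negative(self):
        # 5 Hz, 200 µV burst is outside the 0.1-1 Hz SEM band
        assert not detect_sem(_sine(5.0, duration=3.0, amp=200.0), SFREQ)

    def test_missing_eog_raises_capability_error(self):
        with pytest.raises(CapabilityError):
            detect_sem(None, SFREQ)


class TestGraphoelements:
    def _background(self, duration=7.0, seed=0):
        rng = np.random.default_rng(seed)
        return _sine(3.0, duration, amp=15.0) + rng.normal(0, 2.0, int(duration * SFREQ))

    def test_spindle_burst_detected(self):
        x = self._background()
        i0 = int(3.1 * SFREQ)
        i1 = i0 + int(0.8 * SFREQ)
        from scipy.signal import windows

        burst = 25.0 * windows.tukey(i1 - i0, 0.3) * np.sin(
            2 * np.pi * 13.0 * np.arange(i1 - i0) / SFREQ
        )
        x[i0:i1] += burst
        spindle, _ = detect_graphoelements(x, SFREQ, segment_window=(3.0, 4.0))
        assert spindle

    def test_kcomplex_detected(self):
        x = self._background()
        i0 = int(3.0 * SFREQ)
        tau = np.arange(int(SFREQ)) / SFREQ
        x[i0 : i0 + int(SFREQ)] += 75.0 * np.sin(2 * np.pi * 1.0 * tau)
        _, kc = detect_graphoelements(x, SFREQ, segment_window=(3.0, 4.0))
        assert kc

    def test_plain_alpha_negative(self):
        x = _sine(10.0, duration=5.0, amp=30.0)
        spindle, kc = detect_graphoelements(x, SFREQ, segment_window=(2.0, 3.0))
        assert not spindle and not kc


class TestClassifySegment:
    @pytest.mark.parametrize(
        "features,expected",
        [
            # occipitally dominant alpha -> A1 (stage score 6)
            (_features(0.7, 0.2, roi="occipital"), "A1"),
            # low-amplitude beta profile with SEM -> B1 (score 3)
            (_features(0.1, 0.2, sem=True), "B1"),
            # spindle forces C regardless of the spectrum (score 1)
            (_features(0.7, 0.2, spindle=True), "C"),
            # slow-wave dominant without alpha -> B2/3 (score 2)
            (_features(0.05, 0.8), "B2/3"),
            # nothing distinctive -> 0 (score 7)
            (_features(0.1, 0.2), "0"),
            # parietal / frontal alpha -> A2 / A3
            (_features(0.6, 0.2, roi="parietal"), "A2"),
            (_features(0.6, 0.2, roi="frontal"), "A3"),
        ],
    )
    def test_decision_cascade(self, features, expected):
        assert classify_segment(features) == expected

    def test_deterministic(self):
        f = _features(0.5, 0.3)
        assert classify_segment(f) == classify_segment(f)


class TestScaleInvariance:
    def test_amplitude_scaling_keeps_spectral_stage(self):
        rng = np.random.default_rng(3)
        labels = list(MINIMAL_CHANNELS)
        seg = rng.normal(0, 3, (len(labels), int(SFREQ)))
        seg[labels.index("O1")] += _sine(10.0, amp=30.0)
        seg[labels.index("O2")] += _sine(10.0, amp=30.0, phase=1.0)
        for scale in (0.1, 1.0, 25.0):
            f = spectral_features(seg * scale, SFREQ, labels)
            assert classify_segment(f) == "A1"


class TestClassifyRecording:
    def test_stable_alpha_script_recovered(self):
        script = make_stage_script("custom", seed=0, stages=["A1"] * 120)
        rec = synthesize_recording(script, seed=0, channels=MINIMAL_CHANNELS)
        seq, _ = process_recording(rec, PreprocessConfig(), ClassifierConfig())
        assert np.mean([s == "A1" for s in seq.stages]) >= 0.90

    def test_declining_trajectory_monotone_after_smoothing(self):
        stages = ["A1"] * 120 + ["B1"] * 120 + ["B2/3"] * 120 + ["C"] * 60
        script = make_stage_script("custom", seed=1, stages=stages)
        rec = synthesize_recording(script, seed=1, channels=MINIMAL_CHANNELS)
        seq, _ = process_recording(rec, PreprocessConfig(), ClassifierConfig())
        scores = np.array([STAGE_SCORES[s] for s in seq.stages], float)
        smoothed = np.array(
            [np.median(scores[max(0, i - 15) : i + 15]) for i in range(scores.size)]
        )
        assert np.all(np.diff(smoothed) <= 1e-9)

    def test_artifact_mask_carried_through(self):
        script = make_stage_script("custom", seed=2, stages=["A1"] * 60)
        rec = synthesize_recording(script, seed=2, channels=MINIMAL_CHANNELS)
        mask = np.ones(60, bool)
        seq = classify_recording(rec, mask)
        assert seq.artifact_mask.all() and len(seq) == 60
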