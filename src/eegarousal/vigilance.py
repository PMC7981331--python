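"""Per-second EEG vigilance staging.

Each artifact-free 1-s segment of a resting eyes-closed recording is assigned
one of seven vigilance stages ordered from alert wakefulness to sleep onset:

====== =========== ==============================================
stage  stage score EEG characteristic
====== =========== ==============================================
0      7           low-amplitude desynchronized (beta) EEG, no SEM
A1     6           alpha (8-12 Hz) dominant occipitally
A2     5           alpha dominant parietally
A3     4           alpha dominant frontally
B1     3           low-amplitude EEG with horizontal slow eye movements
B2/3   2           predominantly delta (2-4 Hz) / theta (4-7 Hz) EEG
C      1           sleep-onset graphoelements (spindles / K-complexes)
====== =========== ==============================================

The decision cascade: graphoelements force C; slow-wave dominance without
alpha forces B2/3; alpha dominance selects an A-substage by the scalp region
(ROI) where alpha power is maximal; otherwise the presence of slow eye
movements (SEM) in the horizontal EOG separates B1 from 0.

All numeric thresholds are this package's own calibration (relative-power
thresholds, absolute SEM/spindle/K-complex amplitudes); they are exposed in
:class:`ClassifierConfig` and chosen so that the bundled synthetic generator
round-trips at >= 90% per-segment agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import CapabilityError, ValidationError
from .io import ROLE_EEG, Recording, StageSequenceRecord
from .preprocess import segment_bounds

logger = logging.getLogger("eegarousal")

# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

#: stage name -> stage score; higher scores mean higher arousal.
STAGE_SCORES: dict[str, int] = {
    "0": 7, "A1": 6, "A2": 5, "A3": 4, "B1": 3, "B2/3": 2, "C": 1,
}
SCORE_STAGES: dict[int, str] = {v: k for k, v in STAGE_SCORES.items()}

BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 25.0),
}


@dataclass
class ClassifierConfig:
    roi: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "occipital": ("O1", "O2"),
            "parietal": ("P3", "P4", "Pz"),
            "frontal": ("F3", "F4", "Fz"),
        }
    )
    frontocentral: tuple[str, ...] = ("Fz", "Cz", "F3", "F4", "FC1", "FC2", "C3", "C4")
    alpha_rel_min: float = 0.40
    slowwave_rel_min: float = 0.55
    sem_amp_uv: float = 25.0
    sem_band_hz: tuple[float, float] = (0.1, 1.0)
    sem_min_duration_s: float = 0.5
    spindle_band_hz: tuple[float, float] = (11.0, 16.0)
    spindle_env_factor: float = 3.0       # x subject median 11-16 Hz envelope
    spindle_min_amp_uv: float = 10.0      # absolute envelope floor
    spindle_min_duration_s: float = 0.5
    kcomplex_p2p_uv: float = 100.0
    kcomplex_window_s: tuple[float, float] = (0.5, 1.5)


@dataclass
class SegmentFeatures:
    """Spectral and event features of one 1-s segment."""

    band_power: dict[str, np.ndarray]   # band -> per-EEG-channel power (µV²)
    roi_alpha: dict[str, float]         # ROI -> mean alpha power
    max_roi: str                        # ROI with maximal alpha power
    relative_alpha: float               # alpha / (d+t+a+b) within max_roi
    slowwave_relative: float            # (delta+theta) / total, all EEG channels
    sem_present: bool = False
    spindle_present: bool = False
    kcomplex_present: bool = False


# ---------------------------------------------------------------------------
# spectral features
# ---------------------------------------------------------------------------


def band_powers(segment: np.ndarray, sfreq: float) -> dict[str, np.ndarray]:
    """Per-channel band power (µV²) of a 1-s segment at 1 Hz resolution.

    Hann-tapered periodogram; a band's power is the sum over frequency bins
    whose center lies in ``[lo, hi)``.
    """
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    if sfreq < 64:
        raise ValidationError("band powers need sfreq >= 64 Hz")
    if seg.shape[-1] != int(round(sfreq)):
        raise ValidationError(
            f"segment has {seg.shape[-1]} samples; expected a 1-s segment "
            f"({int(round(sfreq))} samples at {sfreq:g} Hz)"
        )
    freqs, pxx = sps.periodogram(seg, fs=sfreq, window="hann", axis=-1)
    return {
        name: pxx[..., (freqs >= lo) & (freqs < hi)].sum(axis=-1)
        for name, (lo, hi) in BANDS.items()
    }


def _roi_indices(labels: list[str], roi_channels: tuple[str, ...]) -> list[int]:
    return [i for i, lab in enumerate(labels) if lab in roi_channels]


def spectral_features(
    segment: np.ndarray,
    sfreq: float,
    eeg_labels: list[str],
    cfg: ClassifierConfig | None = None,
) -> SegmentFeatures:
    """Build the spectral part of :class:`SegmentFeatures` for one segment."""
    cfg = cfg or ClassifierConfig()
    bp = band_powers(segment, sfreq)
    roi_alpha: dict[str, float] = {}
    roi_rel: dict[str, float] = {}
    for roi_name in ("occipital", "parietal", "frontal"):
        chans = cfg.roi.get(roi_name, ())
        idx = _roi_indices(eeg_labels, chans)
        if not idx:
            from .exceptions import ConfigError

            raise ConfigError(f"no channels available for ROI {roi_name!r}")
        roi_alpha[roi_name] = float(bp["alpha"][idx].mean())
        total = sum(float(bp[b][idx].mean()) for b in BANDS)
        roi_rel[roi_name] = roi_alpha[roi_name] / total if total > 0 else 0.0
    # ties broken occipital > parietal > frontal (dict order is that order)
    max_roi = max(roi_alpha, key=lambda r: roi_alpha[r])
    total_all = sum(float(bp[b].mean()) for b in BANDS)
    slow = float(bp["delta"].mean() + bp["theta"].mean())
    return SegmentFeatures(
        band_power=bp,
        roi_alpha=roi_alpha,
        max_roi=max_roi,
        relative_alpha=roi_rel[max_roi],
        slowwave_relative=slow / total_all if total_all > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# event detectors (SEM, spindles, K-complexes)
# ---------------------------------------------------------------------------


def _bandpass(x: np.ndarray, lo: float, hi: float, sfreq: float, order: int = 2) -> np.ndarray:
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    return sps.sosfiltfilt(sos, x)


def _sem_filter(x: np.ndarray, sfreq: float) -> np.ndarray:
    """Isolate the slow-eye-movement band (~0.1-1 Hz) from an EOG trace.

    Moving-average cascade (0.25 s and 0.35 s windows) suppresses blinks,
    saccades and EMG above ~1 Hz; subtracting a 4-s moving average (or the
    snippet mean when shorter) removes baseline drift.  Unlike a narrow IIR
    band-pass this settles immediately, so it behaves on short snippets.
    """
    from scipy.ndimage import uniform_filter1d

    y = uniform_filter1d(x, max(1, int(0.25 * sfreq)), mode="reflect")
    y = uniform_filter1d(y, max(1, int(0.35 * sfreq)), mode="reflect")
    if x.size >= int(4 * sfreq):
        y = y - uniform_filter1d(y, int(4 * sfreq), mode="reflect")
    else:
        y = y - y.mean()
    return y


def _extrema(x: np.ndarray, prominence: float) -> np.ndarray:
    """Sorted sample indices of local maxima and minima (with endpoints)."""
    up, _ = sps.find_peaks(x, prominence=prominence)
    dn, _ = sps.find_peaks(-x, prominence=prominence)
    idx = np.sort(np.concatenate([[0], up, dn, [x.size - 1]]))
    return np.unique(idx)


def _monotone_deflections(
    x: np.ndarray, sfreq: float, amp_uv: float, min_dur_s: float
) -> list[tuple[int, int]]:
    """Sample spans of monotone deflections >= amp_uv lasting >= min_dur_s.

    A deflection is the stretch between two consecutive local extrema of the
    (already band-limited) signal.
    """
    ext = _extrema(x, prominence=amp_uv / 4)
    spans = []
    for a, b in zip(ext[:-1], ext[1:]):
        if abs(x[b] - x[a]) >= amp_uv and (b - a) / sfreq >= min_dur_s:
            spans.append((int(a), int(b)))
    return spans


def detect_sem(
    heog_context: np.ndarray,
    sfreq: float,
    cfg: ClassifierConfig | None = None,
    segment_window: tuple[float, float] | None = None,
) -> bool:
    """Slow-eye-movement presence in a horizontal-EOG snippet.

    ``heog_context`` is the segment plus surrounding context (default: the
    central second of a 3-s snippet is the segment of interest).  True iff
    the 0.1-1 Hz band-passed trace contains a monotone deflection exceeding
    ``sem_amp_uv`` lasting >= ``sem_min_duration_s`` that overlaps the
    segment window.
    """
    cfg = cfg or ClassifierConfig()
    if heog_context is None:
        raise CapabilityError(
            "no horizontal EOG derivation: slow-eye-movement detection "
            "(stage 0 vs B1) is impossible"
        )
    x = np.asarray(heog_context, dtype=float)
    dur = x.size / sfreq
    if segment_window is None:
        segment_window = ((dur - 1.0) / 2.0, (dur + 1.0) / 2.0) if dur > 1.0 else (0.0, dur)
    xf = _sem_filter(x, sfreq)
    lo = segment_window[0] * sfreq
    hi = segment_window[1] * sfreq
    for a, b in _monotone_deflections(xf, sfreq, cfg.sem_amp_uv, cfg.sem_min_duration_s):
        if a < hi and b > lo:
            return True
    return False


def _envelope(x: np.ndarray, band: tuple[float, float], sfreq: float) -> np.ndarray:
    return np.abs(sps.hilbert(_bandpass(x, *band, sfreq, order=4)))


def _kcomplex_spans(
    x: np.ndarray, sfreq: float, cfg: ClassifierConfig
) -> list[tuple[int, int]]:
    """Sample spans of biphasic deflections with peak-to-peak >= threshold
    completed within the configured window."""
    xf = _bandpass(x, 0.5, 6.0, sfreq, order=2)
    ext = _extrema(xf, prominence=cfg.kcomplex_p2p_uv / 4)
    lo_dt = cfg.kcomplex_window_s[0] / 2.0  # half-wave of the shortest complex
    hi_dt = cfg.kcomplex_window_s[1]
    spans = []
    for a, b in zip(ext[:-1], ext[1:]):
        dt = (b - a) / sfreq
        if abs(xf[b] - xf[a]) >= cfg.kcomplex_p2p_uv and lo_dt <= dt <= hi_dt:
            spans.append((int(a), int(b)))
    return spans


def _spindle_spans(
    env: np.ndarray, sfreq: float, threshold: float, min_dur_s: float
) -> list[tuple[int, int]]:
    above = env > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    starts += list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[-1]:
        stops.append(above.size)
    return [
        (int(a), int(b))
        for a, b in zip(starts, stops)
        if (b - a) / sfreq >= min_dur_s
    ]


def detect_graphoelements(
    context: np.ndarray,
    sfreq: float,
    cfg: ClassifierConfig | None = None,
    baseline_env: float | None = None,
    segment_window: tuple[float, float] | None = None,
) -> tuple[bool, bool]:
    """(spindle_present, kcomplex_present) for a fronto-central snippet.

    ``context`` is a 1-D fronto-central trace (or channels x samples, which
    is averaged).  A spindle is a stretch where the 11-16 Hz amplitude
    envelope exceeds ``spindle_env_factor`` times the subject's median
    envelope (``baseline_env``; computed from the snippet itself when not
    supplied) for >= ``spindle_min_duration_s``.  A K-complex is a biphasic
    deflection with peak-to-peak >= ``kcomplex_p2p_uv`` completed within
    ``kcomplex_window_s``.
    """
    cfg = cfg or ClassifierConfig()
    x = np.asarray(context, dtype=float)
    if x.ndim == 2:
        x = x.mean(axis=0)
    dur = x.size / sfreq
    if segment_window is None:
        segment_window = ((dur - 1.0) / 2.0, (dur + 1.0) / 2.0) if dur > 1.0 else (0.0, dur)
    lo = segment_window[0] * sfreq
    hi = segment_window[1] * sfreq
    env = _envelope(x, cfg.spindle_band_hz, sfreq)
    base = float(np.median(env)) if baseline_env is None else baseline_env
    threshold = max(cfg.spindle_env_factor * base, cfg.spindle_min_amp_uv)
    spindle = any(
        a < hi and b > lo
        for a, b in _spindle_spans(env, sfreq, threshold, cfg.spindle_min_duration_s)
    )
    kcomplex = any(
        a < hi and b > lo for a, b in _kcomplex_spans(x, sfreq, cfg)
    )
    return spindle, kcomplex


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_segment(features: SegmentFeatures, cfg: ClassifierConfig | None = None) -> str:
    """Stage decision for one segment.

    Cascade: graphoelements -> C; slow-wave dominant without alpha -> B2/3;
    alpha dominant -> A1/A2/A3 by the ROI with maximal alpha; else SEM -> B1;
    else 0.
    """
    cfg = cfg or ClassifierConfig()
    if features.spindle_present or features.kcomplex_present:
        return "C"
    if (
        features.slowwave_relative >= cfg.slowwave_rel_min
        and features.relative_alpha < cfg.alpha_rel_min
    ):
        return "B2/3"
    if features.relative_alpha >= cfg.alpha_rel_min:
        return {"occipital": "A1", "parietal": "A2", "frontal": "A3"}[features.max_roi]
    if features.sem_present:
        return "B1"
    return "0"


def _per_second_event_masks(
    rec: Recording, n_seg: int, cfg: ClassifierConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-second SEM, spindle and K-complex masks for a whole recording."""
    sfreq = rec.sfreq
    sem = np.zeros(n_seg, dtype=bool)
    heog = rec.horizontal_eog()
    if heog is None:
        logger.warning(
            "%s: no horizontal EOG derivation; SEM detection disabled and "
            "stage B1 collapses into stage 0", rec.subject_id,
        )
    else:
        xf = _sem_filter(heog, sfreq)
        for a, b in _monotone_deflections(xf, sfreq, cfg.sem_amp_uv, cfg.sem_min_duration_s):
            sem[int(a // sfreq): int(np.ceil(b / sfreq))] = True
    eeg_labels = [rec.channel_labels[i] for i in rec.picks(ROLE_EEG)]
    fc_idx = [rec.picks(ROLE_EEG)[i] for i, lab in enumerate(eeg_labels)
              if lab in cfg.frontocentral]
    if not fc_idx:  # fall back to all EEG channels
        fc_idx = list(rec.picks(ROLE_EEG))
    fc = rec.data[fc_idx].mean(axis=0)
    env = _envelope(fc, cfg.spindle_band_hz, sfreq)
    base = float(np.median(env))
    spindle = np.zeros(n_seg, dtype=bool)
    threshold = max(cfg.spindle_env_factor * base, cfg.spindle_min_amp_uv)
    for a, b in _spindle_spans(env, sfreq, threshold, cfg.spindle_min_duration_s):
        spindle[int(a // sfreq): int(np.ceil(b / sfreq))] = True
    kcomplex = np.zeros(n_seg, dtype=bool)
    for a, b in _kcomplex_spans(fc, sfreq, cfg):
        kcomplex[int(a // sfreq): int(np.ceil(b / sfreq))] = True
    return sem[:n_seg], spindle[:n_seg], kcomplex[:n_seg]


def extract_features(
    rec: Recording, cfg: ClassifierConfig | None = None
) -> list[SegmentFeatures]:
    """Per-second features for a preprocessed recording."""
    cfg = cfg or ClassifierConfig()
    bounds = segment_bounds(rec.n_samples, rec.sfreq)
    n_seg = bounds.shape[0]
    eeg = rec.picks(ROLE_EEG)
    eeg_labels = [rec.channel_labels[i] for i in eeg]
    sem, spindle, kcomplex = _per_second_event_masks(rec, n_seg, cfg)
    feats = []
    for i, (a, b) in enumerate(bounds):
        f = spectral_features(rec.data[eeg, a:b], rec.sfreq, eeg_labels, cfg)
        feats.append(
            replace(
                f,
                sem_present=bool(sem[i]),
                spindle_present=bool(spindle[i]),
                kcomplex_present=bool(kcomplex[i]),
            )
        )
    return feats


def classify_recording(
    rec: Recording,
    mask: np.ndarray | None = None,
    cfg: ClassifierConfig | None = None,
) -> StageSequenceRecord:
    """Stage every 1-s segment of a preprocessed recording.

    ``mask`` is the artifact mask; flagged segments keep their (meaningless)
    classified stage but carry the mask bit, and downstream scoring ignores
    them.
    """
    cfg = cfg or ClassifierConfig()
    feats = extract_features(rec, cfg)
    stages = [classify_segment(f, cfg) for f in feats]
    if mask is None:
        mask = np.zeros(len(stages), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.size != len(stages):
        raise ValidationError(
            f"artifact mask has {mask.size} entries for {len(stages)} segments"
        )
    return StageSequenceRecord(
        subject_id=rec.subject_id, stages=stages, artifact_mask=mask
    )


def features_frame(rec: Recording, cfg: ClassifierConfig | None = None) -> pd.DataFrame:
    """Diagnostic per-segment feature table (one row per second)."""
    feats = extract_features(rec, cfg)
    rows = []
    for i, f in enumerate(feats):
        row = {
            "segment_index": i,
            "relative_alpha": f.relative_alpha,
            "slowwave_relative": f.slowwave_relative,
            "max_roi": f.max_roi,
            "sem": f.sem_present,
            "spindle": f.spindle_present,
            "kcomplex": f.kcomplex_present,
        }
        row.update({f"alpha_{k}": v for k, v in f.roi_alpha.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def stage_timecourse_plot(seq: StageSequenceRecord, path) -> None:
    """Export a stage-score time-course (step plot over 1-s segments)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.array([STAGE_SCORES[s] for s in seq.stages], dtype=float)
    scores[seq.artifact_mask] = np.nan
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.step(np.arange(scores.size), scores, where="post", lw=0.8)
    ax.set_ylim(0.5, 7.5)
    ax.set_yticks(sorted(SCORE_STAGES))
    ax.set_yticklabels([SCORE_STAGES[s] for s in sorted(SCORE_STAGES)])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("vigilance stage")
    ax.set_title(seq.subject_id)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
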