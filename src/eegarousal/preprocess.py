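"""Filtering, re-referencing, artifact masking and 1-s segmentation.

The study pipeline band-limits the EEG to 0.5-70 Hz with a 50 Hz notch
(half-width 2 Hz), re-references to a common average, and scores 1-s
segments.  Ocular/muscle artifact removal by ICA plus visual inspection is
replaced here by a deterministic per-segment peak-amplitude mask; recordings
whose flagged fraction exceeds 15% are unusable.  EOG channels receive a
lower high-pass (0.1 Hz) than EEG so slow eye movements survive filtering.
All filters are zero-phase (forward-backward) to avoid phase shifts at
segment boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .exceptions import ConfigError, ValidationError
from .io import ROLE_EEG, Recording

logger = logging.getLogger("eegarousal")


@dataclass
class PreprocessConfig:
    highpass_hz: float = 0.5
    lowpass_hz: float = 70.0
    notch_hz: float = 50.0
    notch_halfwidth_hz: float = 2.0
    eog_highpass_hz: float = 0.1
    artifact_amp_uv: float = 100.0   # per-segment peak-amplitude threshold
    max_artifact_fraction: float = 0.15
    segment_len_s: float = 1.0

    def validate(self, sfreq: float) -> None:
        if not (0 < self.highpass_hz < self.lowpass_hz):
            raise ConfigError("need 0 < highpass_hz < lowpass_hz")
        if self.lowpass_hz >= sfreq / 2:
            raise ConfigError(
                f"lowpass {self.lowpass_hz} Hz needs sfreq > "
                f"{2 * self.lowpass_hz} Hz (got {sfreq})"
            )
        if not (0 < self.max_artifact_fraction < 1):
            raise ConfigError("max_artifact_fraction must lie in (0, 1)")


def _bandpass_sos(lo: float, hi: float, sfreq: float, order: int = 4):
    return signal.butter(order, [lo, hi], btype="bandpass", fs=sfreq, output="sos")


def filter_recording(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Zero-phase band-pass + notch.  EEG: highpass_hz; EOG: eog_highpass_hz."""
    cfg = cfg or PreprocessConfig()
    cfg.validate(rec.sfreq)
    out = rec.data.copy()
    sos_eeg = _bandpass_sos(cfg.highpass_hz, cfg.lowpass_hz, rec.sfreq)
    sos_eog = _bandpass_sos(cfg.eog_highpass_hz, cfg.lowpass_hz, rec.sfreq)
    bw = 2.0 * cfg.notch_halfwidth_hz
    b_notch, a_notch = signal.iirnotch(cfg.notch_hz, cfg.notch_hz / bw, fs=rec.sfreq)
    for i, role in enumerate(rec.channel_roles):
        sos = sos_eeg if role == ROLE_EEG else sos_eog
        x = signal.sosfiltfilt(sos, out[i])
        out[i] = signal.filtfilt(b_notch, a_notch, x)
    return rec.copy_with(out)


def common_average(rec: Recording) -> Recording:
    """Re-reference EEG channels to their per-sample mean; EOG untouched."""
    eeg = rec.picks(ROLE_EEG)
    if eeg.size < 2:
        raise ConfigError("common-average reference needs at least 2 EEG channels")
    out = rec.data.copy()
    out[eeg] -= out[eeg].mean(axis=0, keepdims=True)
    return rec.copy_with(out)


def segment_bounds(n_samples: int, sfreq: float, segment_len_s: float = 1.0) -> np.ndarray:
    """(n_segments, 2) start/stop sample indices of half-open 1-s windows."""
    spseg = int(round(sfreq * segment_len_s))
    n_seg = n_samples // spseg
    if n_seg == 0:
        raise ValidationError("recording shorter than one segment")
    starts = np.arange(n_seg) * spseg
    return np.stack([starts, starts + spseg], axis=1)


def segment(rec: Recording, cfg: PreprocessConfig | None = None) -> list[np.ndarray]:
    """Non-overlapping 1-s views (channels x samples); trailing partial second dropped."""
    cfg = cfg or PreprocessConfig()
    bounds = segment_bounds(rec.n_samples, rec.sfreq, cfg.segment_len_s)
    return [rec.data[:, a:b] for a, b in bounds]


def artifact_mask(rec: Recording, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Boolean per-segment mask: True where any EEG channel's peak |amplitude|
    within the segment exceeds ``artifact_amp_uv``."""
    cfg = cfg or PreprocessConfig()
    bounds = segment_bounds(rec.n_samples, rec.sfreq, cfg.segment_len_s)
    eeg = rec.picks(ROLE_EEG)
    spseg = bounds[0, 1] - bounds[0, 0]
    n_seg = bounds.shape[0]
    seg_data = rec.data[eeg][:, : n_seg * spseg].reshape(eeg.size, n_seg, spseg)
    peak = np.abs(seg_data).max(axis=(0, 2))
    mask = peak > cfg.artifact_amp_uv
    if mask.any():
        logger.info(
            "artifact mask: %d/%d segments flagged (peak > %g µV)",
            int(mask.sum()), n_seg, cfg.artifact_amp_uv,
        )
    return mask


def check_usable(mask: np.ndarray, max_artifact_fraction: float = 0.15) -> bool:
    """False iff the flagged fraction is strictly greater than the limit.

    The boundary is exact: 135 flagged of 900 (15.0%) is still usable.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValidationError("empty artifact mask")
    frac = Fraction(int(mask.sum()), int(mask.size))
    return not frac > Fraction(str(max_artifact_fraction))
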