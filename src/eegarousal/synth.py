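"""Synthetic study data: scripted EEG recordings and questionnaire cohorts.

The EEG generator emits multichannel eyes-closed recordings whose 1-s
segments follow a scripted vigilance trajectory, with stage-specific
spectral content (occipital/parietal/frontal alpha gradients, slow-wave
dominance, desynchronized beta, slow eye movements on the EOG, and sleep
spindles / K-complexes for sleep-onset seconds) over a pink-noise floor.
The cohort generator draws per-group questionnaire scale totals from
truncated normal distributions with the fatigued-MDD study-group means and
SDs (hypoaroused n = 24 vs non-hypoaroused n = 78 by default) and back-fills
item responses consistent with each total.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from scipy.signal import windows

from .exceptions import ConfigError
from .io import (
    ROLE_EEG,
    ROLE_EOG_H,
    ROLE_EOG_V,
    Recording,
    StageSequenceRecord,
)
from .questionnaires import MFI_DIMENSIONS, MFI_REVERSED
from .stability import stability_score

# ---------------------------------------------------------------------------
# stage scripts
# ---------------------------------------------------------------------------

PROFILES = ("stable_high", "declining", "fluctuating", "custom")


@dataclass
class StageScript:
    """Ground-truth per-second stage trajectory with its true stability score."""

    stages: list[str]
    profile: str
    seed: int | None
    true_score: int = 0

    def __post_init__(self) -> None:
        if not self.true_score:
            seq = StageSequenceRecord(
                subject_id="script",
                stages=self.stages,
                artifact_mask=np.zeros(len(self.stages), bool),
            )
            self.true_score = stability_score(seq).score

    @property
    def duration_s(self) -> int:
        return len(self.stages)


def make_stage_script(
    profile: str,
    duration_s: int = 900,
    seed: int | None = None,
    stages: list[str] | None = None,
    c_onset_s: int | None = None,
) -> StageScript:
    """Build a scripted vigilance trajectory.

    ``stable_high`` walks among the wake stages only (0/A1 dominated, so the
    score is 10 or 11 by construction); ``declining`` descends
    A1->A2->A3->B1->B2/3 with stochastic dwell times and then mixes B2/3
    with sleep-onset C seconds (``c_onset_s`` forces the first C second);
    ``fluctuating`` alternates wake and drowsiness runs without C;
    ``custom`` takes an explicit stage list.
    """
    if duration_s < 60:
        raise ConfigError("scripts must cover at least 60 s")
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}; choose from {PROFILES}")
    rng = np.random.default_rng(seed)
    if profile == "custom":
        if stages is None:
            raise ConfigError("custom profile needs an explicit stage list")
        return StageScript(list(stages), profile, seed)
    out: list[str] = []
    if profile == "stable_high":
        pool = ["A1", "0", "A2", "A3"]
        probs = [0.62, 0.20, 0.12, 0.06]
        while len(out) < duration_s:
            stage = rng.choice(pool, p=probs)
            out.extend([stage] * int(rng.integers(5, 25)))
        out = out[:duration_s]
    elif profile == "fluctuating":
        pool = ["A1", "A2", "0", "B1", "B2/3"]
        probs = [0.34, 0.16, 0.10, 0.20, 0.20]
        while len(out) < duration_s:
            stage = rng.choice(pool, p=probs)
            out.extend([stage] * int(rng.integers(10, 40)))
        out = out[:duration_s]
    else:  # declining
        dwell_means = {"A1": 150.0, "A2": 80.0, "A3": 60.0, "B1": 90.0, "B2/3": 100.0}
        dwells = {
            s: max(10, int(rng.gamma(4.0, m / 4.0))) for s, m in dwell_means.items()
        }
        if c_onset_s is not None:
            total = sum(dwells.values())
            scale = max(1, c_onset_s) / total
            dwells = {s: max(1, int(d * scale)) for s, d in dwells.items()}
        for s in ("A1", "A2", "A3", "B1", "B2/3"):
            out.extend([s] * dwells[s])
        if c_onset_s is not None:
            out = out[:c_onset_s]
        if len(out) < duration_s:
            out.append("C")  # sleep onset
        while len(out) < duration_s:
            out.append("C" if rng.random() < 0.35 else "B2/3")
        out = out[:duration_s]
    return StageScript(out, profile, seed)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

#: 31-channel extended 10-20 montage emulating the study's electrode set.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT9", "FC5", "FC1", "FC2",
    "FC6", "FT10", "T7", "C3", "Cz", "C4", "T8", "CP5", "CP1", "CP2", "CP6",
    "TP9", "P7", "P3", "Pz", "P4", "P8", "TP10", "O1", "O2",
)

#: minimal EEG montage covering all classifier ROIs (fast test runs)
MINIMAL_CHANNELS: tuple[str, ...] = (
    "F3", "Fz", "F4", "Cz", "P3", "Pz", "P4", "O1", "O2",
)

EOG_CHANNELS: tuple[str, ...] = ("EOGL", "EOGR", "EOGU", "EOGD")

_ROI_SETS = {
    "occipital": ("O1", "O2"),
    "parietal": ("P3", "P4", "Pz"),
    "frontal": ("F3", "F4", "Fz"),
}
_FRONTOCENTRAL = ("Fz", "Cz", "F3", "F4", "FC1", "FC2", "C3", "C4")

_ALPHA_ROI_OF_STAGE = {"A1": "occipital", "A2": "parietal", "A3": "frontal"}


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], rms: float) -> np.ndarray:
    """1/f-shaped noise, per-row RMS ``rms``."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:] / freqs[1])
    spec *= scale
    x = np.fft.irfft(spec, n=n, axis=1)
    x *= rms / x.std(axis=1, keepdims=True)
    return x


def _runs(stages: list[str]) -> list[tuple[int, int, str]]:
    """(start_s, stop_s, stage) runs of consecutive identical stages."""
    runs = []
    start = 0
    for i in range(1, len(stages) + 1):
        if i == len(stages) or stages[i] != stages[start]:
            runs.append((start, i, stages[start]))
            start = i
    return runs


def synthesize_recording(
    script: StageScript,
    sfreq: float = 256.0,
    channels: tuple[str, ...] | None = None,
    seed: int | None = None,
    noise_uv: float = 3.0,
    subject_id: str = "synthetic",
) -> Recording:
    """Emit a stage-consistent multichannel EEG+EOG recording in µV.

    Per second: wake stage 0 and B1 get low-amplitude broadband beta
    (12-25 Hz, ~8 µV RMS); A stages a 10 Hz oscillation with a 2:1 amplitude
    gradient favouring the stage's ROI; B1 additionally slow eye movements
    (0.25 Hz, 60 µV derivation amplitude) on the horizontal EOG; B2/3 a
    delta/theta-dominated pattern; C seconds the B2/3 background plus an
    alternating 13 Hz 0.8-s spindle or a biphasic K-complex (~150 µV
    peak-to-peak, attenuated background) over fronto-central channels.
    Oscillation phase is continuous across seconds within a stage run.
    """
    channels = tuple(channels or DEFAULT_CHANNELS)
    for roi, members in _ROI_SETS.items():
        if not set(members) & set(channels):
            raise ConfigError(f"channel set lacks every {roi} ROI channel")
    rng = np.random.default_rng(seed)
    labels = list(channels) + list(EOG_CHANNELS)
    roles = [ROLE_EEG] * len(channels) + [ROLE_EOG_H, ROLE_EOG_H, ROLE_EOG_V, ROLE_EOG_V]
    n_eeg = len(channels)
    sps_i = int(round(sfreq))
    n = script.duration_s * sps_i
    t = np.arange(n) / sfreq

    data = np.zeros((len(labels), n))
    if noise_uv > 0:
        data[:n_eeg] += _pink_noise(rng, (n_eeg, n), noise_uv)
        data[n_eeg:] += _pink_noise(rng, (4, n), noise_uv)

    ch_gain = rng.uniform(0.85, 1.15, size=n_eeg)
    in_roi = {
        roi: np.array([c in members for c in channels])
        for roi, members in _ROI_SETS.items()
    }
    fc_mask = np.array([c in _FRONTOCENTRAL for c in channels])
    if not fc_mask.any():
        fc_mask = in_roi["frontal"]
    # dipolar fronto-central topography for sleep-onset transients; zero-mean
    # across the montage so common-average re-referencing leaves it intact
    fc_topo = np.where(fc_mask, 1.0, -fc_mask.sum() / max(1, (~fc_mask).sum()))

    beta_freqs = np.array([16.5, 18.5, 20.5, 22.5, 24.5])
    beta_amp = 8.0 / np.sqrt(beta_freqs.size / 2.0)

    def _osc(freq: float, amp, tt: np.ndarray) -> np.ndarray:
        """Spatially incoherent oscillation: independent phase per channel."""
        ph = rng.uniform(0, 2 * np.pi, size=n_eeg)
        return np.asarray(amp)[..., None] * np.sin(
            2 * np.pi * freq * tt[None, :] + ph[:, None]
        )

    for s0, s1, stage in _runs(script.stages):
        a, b = s0 * sps_i, s1 * sps_i
        tt = t[a:b]
        if stage in ("0", "B1"):
            for f in beta_freqs:
                data[:n_eeg, a:b] += _osc(f, ch_gain * beta_amp, tt)
            if stage == "B1":
                ph = rng.uniform(0, 2 * np.pi)
                sem = 30.0 * np.sin(2 * np.pi * 0.25 * tt + ph)
                data[n_eeg + 0, a:b] += sem      # EOGL
                data[n_eeg + 1, a:b] -= sem      # EOGR (opposite polarity)
        elif stage in ("A1", "A2", "A3"):
            roi = _ALPHA_ROI_OF_STAGE[stage]
            gain = np.where(in_roi[roi], 1.0, 0.5)
            gain = np.where(
                in_roi["occipital"] | in_roi["parietal"] | in_roi["frontal"],
                gain,
                0.35,
            )
            data[:n_eeg, a:b] += _osc(10.0, 30.0 * ch_gain * gain, tt)
        elif stage in ("B2/3", "C"):
            bg = _osc(3.0, 28.0 * ch_gain, tt) + _osc(5.5, 20.0 * ch_gain, tt)
            if stage == "B2/3":
                data[:n_eeg, a:b] += bg
            else:
                # alternate spindle / K-complex seconds within the C run
                for k, sec in enumerate(range(s0, s1)):
                    sa, sb = sec * sps_i, (sec + 1) * sps_i
                    tau = (np.arange(sps_i) + 0.5) / sfreq
                    if k % 2 == 0:  # spindle second: full background + burst
                        data[:n_eeg, sa:sb] += bg[:, sa - a : sb - a]
                        win = np.zeros(sps_i)
                        i0 = int(0.1 * sps_i)
                        i1 = i0 + int(0.8 * sps_i)
                        win[i0:i1] = windows.tukey(i1 - i0, alpha=0.4)
                        burst = 25.0 * win * np.sin(2 * np.pi * 13.0 * tau)
                        data[:n_eeg, sa:sb] += fc_topo[:, None] * burst
                    else:  # K-complex second: attenuated background + wave
                        data[:n_eeg, sa:sb] += 0.25 * bg[:, sa - a : sb - a]
                        kc = 70.0 * np.sin(2 * np.pi * 1.0 * tau)
                        data[:n_eeg, sa:sb] += fc_topo[:, None] * kc
        else:  # pragma: no cover
            raise ConfigError(f"script contains unknown stage {stage!r}")
    return Recording(
        subject_id=subject_id,
        sfreq=float(sfreq),
        data=data,
        channel_labels=labels,
        channel_roles=roles,
    )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

#: per-variable (mean, sd) for (non-hypoaroused, hypoaroused) with scale
#: bounds, taken from the study's group tables.
DEFAULT_EFFECTS: dict[str, dict] = {
    "ess_total": {"non": (8.3, 4.0), "hypo": (10.4, 4.0), "range": (0, 24)},
    "sss": {"non": (3.4, 1.2), "hypo": (4.1, 1.2), "range": (1, 7)},
    "bdi_total": {"non": (29.2, 8.8), "hypo": (30.3, 7.9), "range": (0, 63)},
    "general_fatigue": {"non": (14.9, 2.4), "hypo": (15.4, 2.5), "range": (4, 20)},
    "mental_fatigue": {"non": (14.4, 3.3), "hypo": (15.9, 2.3), "range": (4, 20)},
    "physical_fatigue": {"non": (13.7, 3.3), "hypo": (14.8, 2.7), "range": (4, 20)},
    "reduced_activity": {"non": (15.3, 2.8), "hypo": (16.2, 3.1), "range": (4, 20)},
    "reduced_motivation": {"non": (13.5, 3.1), "hypo": (13.7, 3.5), "range": (4, 20)},
    "sfar_quality": {"non": (2.7, 1.03), "hypo": (2.6, 0.7), "range": (1, 5)},
    "time_in_bed_h": {"non": (7.15, 1.73), "hypo": (7.4, 1.32), "range": (1.0, 11.5)},
    "age": {"non": (38.4, 12.2), "hypo": (35.3, 13.5), "range": (18, 75)},
}

#: probability of the first-listed level per group, from the study's margins
DEFAULT_CATEGORICALS: dict[str, dict] = {
    "sex": {"levels": ("F", "M"), "non": 45 / 78, "hypo": 16 / 24},
    "med_status": {"levels": ("yes", "no"), "non": 37 / 78, "hypo": 7 / 24},
    "suicide_history": {"levels": ("yes", "no"), "non": 7 / 74, "hypo": 4 / 24},
    "icd10": {"levels": ("F32", "F33"), "non": 44 / 78, "hypo": 17 / 24},
    "family_history": {"levels": ("yes", "no"), "non": 11 / 50, "hypo": 5 / 19},
}


@dataclass
class CohortConfig:
    n_non_hypo: int = 78
    n_hypo: int = 24
    effects: dict = field(default_factory=lambda: DEFAULT_EFFECTS)
    categoricals: dict = field(default_factory=lambda: DEFAULT_CATEGORICALS)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_non_hypo < 2 or self.n_hypo < 2:
            raise ConfigError("each group needs n >= 2")
        for var, spec in self.effects.items():
            lo, hi = spec["range"]
            for grp in ("non", "hypo"):
                m, sd = spec[grp]
                if not lo <= m <= hi:
                    raise ConfigError(
                        f"{var}: group {grp} mean {m} outside scale range [{lo}, {hi}]"
                    )
                if sd <= 0:
                    raise ConfigError(f"{var}: group {grp} SD must be positive")


def _trunc_draw(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Truncated-normal draws whose *truncated* mean equals ``mean``.

    The location parameter is moment-matched (truncation at the scale
    bounds would otherwise bias the realized mean away from the configured
    group mean).
    """
    from scipy.optimize import brentq

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return sst.truncnorm.mean(a, b, loc=loc, scale=sd)

    span = hi - lo
    try:
        loc = brentq(
            lambda m: trunc_mean(m) - mean,
            max(lo - span, mean - 3 * sd),
            min(hi + span, mean + 3 * sd),
            xtol=1e-6,
        )
    except ValueError:  # target at a scale edge: fall back to direct loc
        loc = mean
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return sst.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _spread_total(total: int, n_items: int, lo: int, hi: int) -> list[int]:
    """n_items integer item values in [lo, hi] summing to ``total``."""
    total = int(np.clip(total, n_items * lo, n_items * hi))
    base, extra = divmod(total, n_items)
    vals = [base + 1] * extra + [base] * (n_items - extra)
    return [int(np.clip(v, lo, hi)) for v in vals]


def _fmt_clock(hours: float) -> str:
    hours = hours % 24.0
    h = int(hours)
    m = int(round((hours - h) * 60)) % 60
    return f"{h:02d}:{m:02d}"


def generate_cohort(cfg: CohortConfig | None = None) -> pd.DataFrame:
    """Per-subject questionnaire item table with group structure.

    Scale totals are truncated-normal around each group's configured
    mean/SD, rounded and clipped to the instrument range; item values are
    back-filled to match each total (including the MFI reverse-coding, so
    scoring recovers the target totals).  Deterministic under ``cfg.seed``.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    rows: list[dict] = []
    for grp_key, grp_label, n in (
        ("non", "non_hypoaroused", cfg.n_non_hypo),
        ("hypo", "hypoaroused", cfg.n_hypo),
    ):
        draws = {
            var: _trunc_draw(rng, *spec[grp_key], *spec["range"], n)
            for var, spec in cfg.effects.items()
        }
        cats = {
            var: np.where(
                rng.random(n) < spec[grp_key], spec["levels"][0], spec["levels"][1]
            )
            for var, spec in cfg.categoricals.items()
        }
        for i in range(n):
            row: dict = {
                "subject_id": f"{grp_key}_{i + 1:03d}",
                "group": grp_label,
                "age": float(np.round(draws["age"][i], 1)),
            }
            for var in cfg.categoricals:
                row[var] = cats[var][i]
            # MFI: back-fill each dimension, then undo the reverse-coding
            raw_items = [0] * 20
            for dim, item_nos in MFI_DIMENSIONS.items():
                tot = int(round(draws[dim][i]))
                for item_no, v in zip(item_nos, _spread_total(tot, 4, 1, 5)):
                    raw_items[item_no - 1] = 6 - v if item_no in MFI_REVERSED else v
            row.update({f"mfi_{j + 1:02d}": raw_items[j] for j in range(20)})
            bdi_items = _spread_total(int(round(draws["bdi_total"][i])), 21, 0, 3)
            row.update({f"bdi_{j + 1:02d}": bdi_items[j] for j in range(21)})
            ess_items = _spread_total(int(round(draws["ess_total"][i])), 8, 0, 3)
            row.update({f"ess_{j + 1:02d}": ess_items[j] for j in range(8)})
            row["sss"] = int(round(draws["sss"][i]))
            q_items = _spread_total(int(round(5 * draws["sfar_quality"][i])), 5, 1, 5)
            row.update({f"sfa_q{j + 1}": q_items[j] for j in range(5)})
            tib = round(draws["time_in_bed_h"][i] * 4) / 4.0  # quarter hours
            rise = 6.5 + float(rng.integers(0, 19)) / 12.0    # 06:30-08:00
            row["sfa_rise_time"] = _fmt_clock(rise)
            row["sfa_bed_time"] = _fmt_clock(rise - tib)
            rows.append(row)
    return pd.DataFrame(rows)
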