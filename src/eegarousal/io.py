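"""Readers and writers for EEG recordings and the pipeline's tabular artifacts.

EEG input goes through MNE (BrainVision header triplets and EDF/EDF+); signals
are held in a plain :class:`Recording` dataclass in microvolts.  Stage
sequences and cohort questionnaire tables are plain CSV handled with pandas.
Because no BrainVision/EDF *writer* library ships with the package's
dependency set, minimal writers for both formats are provided so synthetic
recordings can be round-tripped through the same readers real data would use.
"""

from __future__ import annotations

import datetime
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, UnsupportedDialectError, ValidationError

logger = logging.getLogger("eegarousal")

# ---------------------------------------------------------------------------
# channel roles
# ---------------------------------------------------------------------------

ROLE_EEG = "eeg"
ROLE_EOG_H = "eog_horizontal"
ROLE_EOG_V = "eog_vertical"

#: Default label -> role patterns, checked in order, case-insensitive.
#: Labels containing "EOG" become EOG channels (horizontal for canthus
#: electrodes L/R, vertical for above/below-eye U/D); everything else is EEG.
DEFAULT_ROLE_MAP: tuple[tuple[str, str], ...] = (
    (r"EOG.*(L|R)|(H|h)EOG|EOG(h|H)", ROLE_EOG_H),
    (r"EOG.*(U|D)|(V|v)EOG|EOG(v|V)", ROLE_EOG_V),
    (r"EOG", ROLE_EOG_H),
)

#: Extended 10-20 labels recognized as EEG positions.
TEN_TWENTY_LABELS = frozenset(
    "Fp1 Fpz Fp2 AF7 AF3 AFz AF4 AF8 F9 F7 F5 F3 F1 Fz F2 F4 F6 F8 F10 "
    "FT9 FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 FT10 T9 T7 C5 C3 C1 Cz C2 C4 "
    "C6 T8 T10 TP9 TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 TP10 P9 P7 P5 P3 P1 "
    "Pz P2 P4 P6 P8 P10 PO7 PO3 POz PO4 PO8 O1 Oz O2 Iz A1 A2 M1 M2".split()
)


def infer_roles(
    labels: Sequence[str],
    role_map: Sequence[tuple[str, str]] | None = None,
) -> list[str]:
    """Assign a role to each channel label using the (configurable) map."""
    patterns = DEFAULT_ROLE_MAP if role_map is None else tuple(role_map)
    roles = []
    for lab in labels:
        for pat, role in patterns:
            if re.search(pat, lab):
                roles.append(role)
                break
        else:
            roles.append(ROLE_EEG)
    return roles


# ---------------------------------------------------------------------------
# Recording container
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """A multichannel eyes-closed resting recording in microvolts.

    ``data`` is channels x samples; channel order matches ``channel_labels``
    and ``channel_roles``.
    """

    subject_id: str
    sfreq: float
    data: np.ndarray
    channel_labels: list[str]
    channel_roles: list[str] = field(default_factory=list)
    start_time: datetime.datetime | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not self.channel_roles:
            self.channel_roles = infer_roles(self.channel_labels)
        if len(self.channel_roles) != len(self.channel_labels):
            raise ValidationError("channel_roles length mismatch")
        if not self.sfreq > 0:
            raise ValidationError("sfreq must be positive")
        for lab, role in zip(self.channel_labels, self.channel_roles):
            if role == ROLE_EEG and lab not in TEN_TWENTY_LABELS:
                raise ValidationError(
                    f"EEG channel {lab!r} is not a recognized 10-20 label"
                )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def picks(self, role: str) -> np.ndarray:
        """Indices of channels with the given role."""
        return np.array(
            [i for i, r in enumerate(self.channel_roles) if r == role], dtype=int
        )

    def horizontal_eog(self) -> np.ndarray | None:
        """Horizontal EOG derivation (left canthus minus right canthus).

        With two horizontal-EOG channels the derivation is first minus
        second (label order); with one, that channel is used as-is; with
        none, ``None`` (slow-eye-movement detection is then impossible).
        """
        idx = self.picks(ROLE_EOG_H)
        if idx.size == 0:
            return None
        if idx.size == 1:
            return self.data[idx[0]]
        return self.data[idx[0]] - self.data[idx[1]]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(
            subject_id=self.subject_id,
            sfreq=self.sfreq,
            data=data,
            channel_labels=list(self.channel_labels),
            channel_roles=list(self.channel_roles),
            start_time=self.start_time,
        )


# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------


def read_brainvision(
    path: str | Path,
    role_map: Sequence[tuple[str, str]] | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read a BrainVision .vhdr triplet into a :class:`Recording` (µV)."""
    import mne

    vhdr = Path(path)
    if not vhdr.exists():
        raise FormatError(f"header file not found: {vhdr}")
    header = vhdr.read_text(errors="replace")
    for key in ("DataFile", "MarkerFile"):
        m = re.search(rf"^{key}=(.+)$", header, flags=re.MULTILINE)
        if m:
            companion = vhdr.parent / m.group(1).strip()
            if not companion.exists():
                raise FormatError(
                    f"companion file referenced by {vhdr.name} is missing: "
                    f"{companion.name}"
                )
    try:
        raw = mne.io.read_raw_brainvision(vhdr, preload=True, verbose="error")
    except FileNotFoundError as exc:  # pragma: no cover - caught above normally
        raise FormatError(str(exc)) from exc
    except (ValueError, NotImplementedError) as exc:
        raise UnsupportedDialectError(f"cannot read {vhdr}: {exc}") from exc
    return _from_mne_raw(raw, subject_id or vhdr.stem, role_map)


def read_edf(
    path: str | Path,
    role_map: Sequence[tuple[str, str]] | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (µV)."""
    import mne

    p = Path(path)
    if not p.exists():
        raise FormatError(f"EDF file not found: {p}")
    try:
        raw = mne.io.read_raw_edf(p, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot read EDF file {p}: {exc}") from exc
    return _from_mne_raw(raw, subject_id or p.stem, role_map)


def _from_mne_raw(raw, subject_id, role_map) -> Recording:
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    labels = list(raw.ch_names)
    meas_date = raw.info.get("meas_date")
    rec = Recording(
        subject_id=subject_id,
        sfreq=float(raw.info["sfreq"]),
        data=data_uv,
        channel_labels=labels,
        channel_roles=infer_roles(labels, role_map),
        start_time=meas_date if isinstance(meas_date, datetime.datetime) else None,
    )
    logger.info(
        "read %s: %d channels, %.1f s at %g Hz",
        subject_id, len(labels), rec.duration_s, rec.sfreq,
    )
    return rec


def write_brainvision(rec: Recording, vhdr_path: str | Path) -> None:
    """Write a minimal BrainVision triplet (IEEE float32, multiplexed, µV)."""
    vhdr = Path(vhdr_path)
    stem = vhdr.stem
    eeg_name, vmrk_name = f"{stem}.eeg", f"{stem}.vmrk"
    n_ch = len(rec.channel_labels)
    interval_us = 1e6 / rec.sfreq
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        f"MarkerFile={vmrk_name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    (vhdr.parent / vmrk_name).write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg_name}\n\n[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0\n",
        encoding="utf-8",
    )
    (vhdr.parent / eeg_name).write_bytes(
        np.asarray(rec.data, dtype="<f4").T.tobytes()
    )


# ---------------------------------------------------------------------------
# EDF writer (16-bit, one 1-s data record per second)
# ---------------------------------------------------------------------------


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write an EDF file.  16-bit quantization over each channel's range."""
    p = Path(path)
    n_ch = len(rec.channel_labels)
    sfreq = rec.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValidationError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_rec * spr]
    phys_min = np.floor(np.minimum(data.min(axis=1), -1.0))
    phys_max = np.ceil(np.maximum(data.max(axis=1), 1.0))
    dig_min, dig_max = -32768, 32767

    def f(x, width):
        s = str(x)[:width]
        return s.ljust(width)

    start = rec.start_time or datetime.datetime(2000, 1, 1, 0, 0, 0)
    header = (
        f("0", 8)
        + f(f"X X X {rec.subject_id}"[:80], 80)
        + f("Startdate X X X X", 80)
        + f(start.strftime("%d.%m.%y"), 8)
        + f(start.strftime("%H.%M.%S"), 8)
        + f(str(256 * (1 + n_ch)), 8)
        + f("", 44)
        + f(str(n_rec), 8)
        + f("1", 8)
        + f(str(n_ch), 4)
    )
    header += "".join(f(lab, 16) for lab in rec.channel_labels)
    header += "".join(f("AgAgCl electrode", 80) for _ in range(n_ch))
    header += "".join(f("uV", 8) for _ in range(n_ch))
    header += "".join(f(f"{pm:g}", 8) for pm in phys_min)
    header += "".join(f(f"{pm:g}", 8) for pm in phys_max)
    header += "".join(f(str(dig_min), 8) for _ in range(n_ch))
    header += "".join(f(str(dig_max), 8) for _ in range(n_ch))
    header += "".join(f("", 80) for _ in range(n_ch))  # prefiltering
    header += "".join(f(str(spr), 8) for _ in range(n_ch))
    header += "".join(f("", 32) for _ in range(n_ch))
    assert len(header) == 256 * (1 + n_ch)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(p, "wb") as fh:
        fh.write(header.encode("ascii"))
        for r in range(n_rec):
            chunk = data[:, r * spr : (r + 1) * spr]
            dig = np.rint(
                (chunk - phys_min[:, None]) * scale[:, None] + dig_min
            ).astype("<i2")
            fh.write(dig.tobytes())


# ---------------------------------------------------------------------------
# stage-sequence CSV
# ---------------------------------------------------------------------------

STAGE_TOKENS = ("0", "A1", "A2", "A3", "B1", "B2/3", "C")


@dataclass
class StageSequenceRecord:
    """Per-second vigilance stages with an artifact mask.

    Segment ``i`` covers the half-open window ``[i, i+1)`` seconds.
    ``artifact_mask[i]`` is True when segment ``i`` was rejected.
    """

    subject_id: str
    stages: list[str]
    artifact_mask: np.ndarray

    def __post_init__(self) -> None:
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if len(self.stages) != self.artifact_mask.size:
            raise ValidationError("stages and artifact_mask length mismatch")
        for s in self.stages:
            if s not in STAGE_TOKENS:
                raise ValidationError(f"unknown vigilance stage {s!r}")

    def __len__(self) -> int:
        return len(self.stages)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StageSequenceRecord)
            and self.subject_id == other.subject_id
            and self.stages == other.stages
            and bool(np.array_equal(self.artifact_mask, other.artifact_mask))
        )


def write_stage_sequence(record: StageSequenceRecord, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "segment_index": np.arange(len(record.stages)),
            "stage": record.stages,
            "artifact": record.artifact_mask.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_stage_sequence(path: str | Path, subject_id: str | None = None) -> StageSequenceRecord:
    p = Path(path)
    df = pd.read_csv(p, dtype={"stage": str})
    for col in ("segment_index", "stage", "artifact"):
        if col not in df.columns:
            raise FormatError(f"stage CSV {p} lacks required column {col!r}")
    for row_idx, tok in enumerate(df["stage"]):
        if tok not in STAGE_TOKENS:
            # +2: header line plus 1-based numbering
            raise FormatError(
                f"unknown stage token {tok!r} at line {row_idx + 2} of {p}"
            )
    df = df.sort_values("segment_index")
    return StageSequenceRecord(
        subject_id=subject_id or p.stem,
        stages=list(df["stage"]),
        artifact_mask=df["artifact"].to_numpy().astype(bool),
    )


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

MFI_COLS = [f"mfi_{i:02d}" for i in range(1, 21)]
BDI_COLS = [f"bdi_{i:02d}" for i in range(1, 22)]
ESS_COLS = [f"ess_{i:02d}" for i in range(1, 9)]
SFA_QUALITY_COLS = [f"sfa_q{i}" for i in range(1, 6)]


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a per-subject questionnaire table; missing items stay as NaN.

    One row per subject; item columns follow the ``mfi_01..mfi_20``,
    ``bdi_01..bdi_21``, ``ess_01..ess_08``, ``sss``, ``sfa_*`` scheme.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise FormatError("cohort CSV lacks a subject_id column")
    dupes = df["subject_id"][df["subject_id"].duplicated()].unique()
    if dupes.size:
        raise ValidationError(f"duplicate subject_id values: {list(dupes)}")
    logger.info("read cohort of %d subjects from %s", len(df), path)
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
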