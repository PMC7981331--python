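"""Scoring of the self-report instruments and the computable inclusion rules.

Instruments: MFI-20 (five 4-item fatigue dimensions, each 4-20), BDI-II
(21 items, total 0-63; items 16 and 18 use seven response options collapsed
to 0-3), ESS (8 items, total 0-24, > 10 flags excessive daytime sleepiness),
SSS (single 1-7 state-sleepiness rating) and the SF-A/R sleep inventory
(mean 1-5 sleep-quality score and total time in bed from bed/rise clock
times).  A questionnaire with more than 2 missing items excludes the
subject; up to 2 missing items are imputed with the rounded person-mean of
the answered items of the same scale (same dimension for the MFI).

Study inclusion requires the MFI general-fatigue dimension to strictly
exceed the sex- and age-specific 75th-percentile norm.  The population norm
table is not shipped with real values: :func:`synthetic_norm_table` builds a
clearly-labelled synthetic placeholder and real norms must be supplied for
substantive use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError

# ---------------------------------------------------------------------------
# MFI-20 key (published instrument structure; config data, overridable)
# ---------------------------------------------------------------------------

MFI_DIMENSIONS: dict[str, tuple[int, ...]] = {
    "general_fatigue": (1, 5, 12, 16),
    "physical_fatigue": (2, 8, 14, 20),
    "reduced_activity": (3, 6, 10, 17),
    "reduced_motivation": (4, 9, 15, 18),
    "mental_fatigue": (7, 11, 13, 19),
}
#: positively-worded items ("I feel fit") recoded as 6 - value so that
#: higher always means more fatigue
MFI_REVERSED: frozenset[int] = frozenset({1, 3, 4, 6, 7, 8, 11, 12, 15, 20})

BDI_MULTIOPTION_ITEMS = (16, 18)
#: the seven response options of BDI-II items 16/18 and their numeric values
BDI_OPTION_MAP = {"0": 0, "1a": 1, "1b": 1, "2a": 2, "2b": 2, "3a": 3, "3b": 3}

MAX_MISSING = 2


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ScaleResult:
    scores: dict[str, float]
    n_missing: int
    excluded: bool = False
    exclusion_reason: str | None = None
    low_confidence: bool = False


def _check_missing(values: list[float | None], instrument: str) -> ScaleResult | None:
    n_missing = sum(v is None for v in values)
    if n_missing > MAX_MISSING:
        return ScaleResult(
            scores={},
            n_missing=n_missing,
            excluded=True,
            exclusion_reason=f"{instrument}: {n_missing} missing items (> {MAX_MISSING})",
        )
    return None


def _as_items(values, n: int, lo: int, hi: int, instrument: str) -> list[float | None]:
    out = []
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            out.append(None)
            continue
        v = float(v)
        if v != int(v) or not lo <= v <= hi:
            raise ValidationError(
                f"{instrument} item value {v} outside the {lo}-{hi} scale"
            )
        out.append(v)
    if len(out) != n:
        raise ValidationError(f"{instrument} expects {n} items, got {len(out)}")
    return out


# ---------------------------------------------------------------------------
# MFI-20
# ---------------------------------------------------------------------------


def mfi_recode(items: list[float | None]) -> list[float | None]:
    """Recode reversed items (6 - value); an involution on raw responses."""
    return [
        None if v is None else (6 - v if (i + 1) in MFI_REVERSED else v)
        for i, v in enumerate(items)
    ]


def score_mfi(values, key: dict[str, tuple[int, ...]] | None = None) -> ScaleResult:
    """Five dimension scores (each 4-20) from the 20 raw item responses."""
    key = key or MFI_DIMENSIONS
    items = _as_items(values, 20, 1, 5, "MFI-20")
    bad = _check_missing(items, "MFI-20")
    if bad:
        return bad
    recoded = mfi_recode(items)
    scores: dict[str, float] = {}
    low_conf = False
    for dim, item_nos in key.items():
        vals = [recoded[i - 1] for i in item_nos]
        answered = [v for v in vals if v is not None]
        if len(answered) < 2:
            low_conf = True
        if not answered:
            raise ValidationError(f"MFI-20 dimension {dim} has no answered items")
        imput = _round_half_up(float(np.mean(answered)))
        scores[dim] = float(sum(v if v is not None else imput for v in vals))
    return ScaleResult(
        scores=scores,
        n_missing=sum(v is None for v in items),
        low_confidence=low_conf,
    )


# ---------------------------------------------------------------------------
# BDI-II
# ---------------------------------------------------------------------------


def score_bdi(values) -> ScaleResult:
    """BDI-II total (0-63); items 16/18 accept the 7-option tokens."""
    if len(values) != 21:
        raise ValidationError(f"BDI-II expects 21 items, got {len(values)}")
    items: list[float | None] = []
    for i, v in enumerate(values, start=1):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            items.append(None)
        elif isinstance(v, str) and i in BDI_MULTIOPTION_ITEMS:
            tok = v.strip().lower()
            if tok not in BDI_OPTION_MAP:
                raise ValidationError(f"BDI-II item {i}: unknown option {v!r}")
            items.append(float(BDI_OPTION_MAP[tok]))
        else:
            fv = float(v)
            if fv != int(fv) or not 0 <= fv <= 3:
                raise ValidationError(f"BDI-II item {i} value {v!r} outside 0-3")
            items.append(fv)
    bad = _check_missing(items, "BDI-II")
    if bad:
        return bad
    answered = [v for v in items if v is not None]
    imput = _round_half_up(float(np.mean(answered)))
    total = float(sum(v if v is not None else imput for v in items))
    return ScaleResult(scores={"bdi_total": total}, n_missing=21 - len(answered))


# ---------------------------------------------------------------------------
# ESS / SSS
# ---------------------------------------------------------------------------


def score_ess(values) -> ScaleResult:
    """ESS total (0-24) and the > 10 excessive-daytime-sleepiness flag."""
    items = _as_items(values, 8, 0, 3, "ESS")
    bad = _check_missing(items, "ESS")
    if bad:
        return bad
    answered = [v for v in items if v is not None]
    imput = _round_half_up(float(np.mean(answered)))
    total = float(sum(v if v is not None else imput for v in items))
    return ScaleResult(
        scores={"ess_total": total, "ess_sleepy": float(total > 10)},
        n_missing=8 - len(answered),
    )


def score_sss(value) -> ScaleResult:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ScaleResult(
            scores={}, n_missing=1, excluded=True, exclusion_reason="SSS missing"
        )
    v = float(value)
    if v != int(v) or not 1 <= v <= 7:
        raise ValidationError(f"SSS rating {value!r} outside 1-7")
    return ScaleResult(scores={"sss": v}, n_missing=0)


# ---------------------------------------------------------------------------
# SF-A/R
# ---------------------------------------------------------------------------


def _parse_clock(t) -> float:
    """Clock time as fractional hours from 'HH:MM' or a number."""
    if isinstance(t, str):
        hh, mm = t.strip().split(":")
        h = int(hh) + int(mm) / 60.0
    else:
        h = float(t)
    if not 0 <= h < 24:
        raise ValidationError(f"clock time {t!r} outside [0, 24)")
    return h


def time_in_bed_hours(bed_time, rise_time) -> float:
    """Rise minus bed time in hours, wrapping over midnight."""
    bed = _parse_clock(bed_time)
    rise = _parse_clock(rise_time)
    dt = rise - bed
    if dt <= 0:
        dt += 24.0
    if dt > 24.0:
        raise ValidationError("time in bed exceeds 24 h")
    return dt


def score_sfar(quality_items, bed_time=None, rise_time=None) -> ScaleResult:
    """Sleep quality (mean of the recoded 1-5 items) and time in bed (h)."""
    quality_items = list(quality_items)
    items = _as_items(quality_items, len(quality_items), 1, 5, "SF-A/R")
    answered = [v for v in items if v is not None]
    bad = _check_missing(items, "SF-A/R")
    if bad:
        return bad
    if not answered:
        raise ValidationError("SF-A/R: no quality items answered")
    scores = {"sfar_quality": float(np.mean(answered))}
    if bed_time is not None and rise_time is not None:
        try:
            scores["sfar_time_in_bed"] = time_in_bed_hours(bed_time, rise_time)
        except ValidationError:
            raise
    return ScaleResult(scores=scores, n_missing=len(items) - len(answered))


# ---------------------------------------------------------------------------
# MFI norm table & inclusion
# ---------------------------------------------------------------------------

NORM_AGE_BANDS: tuple[tuple[int, int], ...] = ((18, 40), (40, 60), (60, 200))


@dataclass
class MfiNormTable:
    """75th-percentile thresholds by sex x age band x dimension."""

    table: pd.DataFrame  # columns: sex, age_lo, age_hi, dimension, p75

    def __post_init__(self) -> None:
        need = {"sex", "age_lo", "age_hi", "dimension", "p75"}
        if not need.issubset(self.table.columns):
            raise ConfigError(f"norm table needs columns {sorted(need)}")
        if ((self.table["p75"] < 4) | (self.table["p75"] > 20)).any():
            raise ConfigError("norm p75 thresholds must lie within [4, 20]")

    def threshold(self, sex: str, age: float, dimension: str) -> float:
        t = self.table
        hit = t[
            (t["sex"] == sex)
            & (t["age_lo"] <= age)
            & (age < t["age_hi"])
            & (t["dimension"] == dimension)
        ]
        if hit.empty:
            raise ConfigError(
                f"no norm threshold for sex={sex!r}, age={age}, dimension={dimension!r}"
            )
        return float(hit["p75"].iloc[0])

    @classmethod
    def from_csv(cls, path) -> "MfiNormTable":
        return cls(pd.read_csv(path))


def synthetic_norm_table(p75: float = 12.0) -> MfiNormTable:
    """SYNTHETIC placeholder norm table (constant p75 in every cell).

    The population norms are published reference data not reproduced here;
    this placeholder exists so the pipeline runs end-to-end on synthetic
    cohorts.  Supply real norms via :meth:`MfiNormTable.from_csv` for any
    substantive analysis.
    """
    rows = [
        {"sex": sex, "age_lo": lo, "age_hi": hi, "dimension": dim, "p75": p75}
        for sex in ("F", "M")
        for lo, hi in NORM_AGE_BANDS
        for dim in MFI_DIMENSIONS
    ]
    return MfiNormTable(pd.DataFrame(rows))


def apply_inclusion(
    general_fatigue: float, norms: MfiNormTable, age: float, sex: str
) -> bool:
    """Included iff general fatigue strictly exceeds the sex/age p75 norm."""
    return general_fatigue > norms.threshold(sex, age, "general_fatigue")


# ---------------------------------------------------------------------------
# whole-subject scoring
# ---------------------------------------------------------------------------


@dataclass
class ScoredSubject:
    subject_id: str
    scores: dict[str, float] = field(default_factory=dict)
    included: bool = True
    exclusion_reason: str | None = None
    low_confidence: bool = False


def score_subject_row(
    row: pd.Series, norms: MfiNormTable | None = None
) -> ScoredSubject:
    """Score one cohort-CSV row across all instruments; apply inclusion."""
    from .io import BDI_COLS, ESS_COLS, MFI_COLS, SFA_QUALITY_COLS

    out = ScoredSubject(subject_id=str(row["subject_id"]))
    reasons: list[str] = []

    mfi = score_mfi([row.get(c) for c in MFI_COLS])
    bdi = score_bdi([row.get(c) for c in BDI_COLS])
    ess = score_ess([row.get(c) for c in ESS_COLS])
    sss = score_sss(row.get("sss"))
    sfar = score_sfar(
        [row.get(c) for c in SFA_QUALITY_COLS],
        bed_time=row.get("sfa_bed_time"),
        rise_time=row.get("sfa_rise_time"),
    )
    for res in (mfi, bdi, ess, sss, sfar):
        if res.excluded:
            reasons.append(res.exclusion_reason or "missing items")
        else:
            out.scores.update(res.scores)
        out.low_confidence = out.low_confidence or res.low_confidence
    if norms is not None and not reasons:
        if not apply_inclusion(
            out.scores["general_fatigue"], norms, float(row["age"]), str(row["sex"])
        ):
            reasons.append("general fatigue at or below the 75th-percentile norm")
    if reasons:
        out.included = False
        out.exclusion_reason = "; ".join(reasons)
    return out


def score_cohort(
    cohort: pd.DataFrame, norms: MfiNormTable | None = None
) -> pd.DataFrame:
    """Score every subject; returns one row per subject with an inclusion flag."""
    rows = []
    for _, row in cohort.iterrows():
        s = score_subject_row(row, norms)
        rec = {"subject_id": s.subject_id, "included": s.included,
               "exclusion_reason": s.exclusion_reason}
        rec.update(s.scores)
        for extra in ("age", "sex", "group", "med_status", "suicide_history",
                      "icd10", "family_history"):
            if extra in row.index:
                rec[extra] = row[extra]
        rows.append(rec)
    return pd.DataFrame(rows)
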