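"""Arousal stability score and hypoaroused-fatigue stratification.

The score (integer 1-11) summarizes how far and how early vigilance declines
over a 15-min recording, from per-second stages grouped into three 5-min
blocks (minutes 1-5, 6-10, 11-15; segment indices [0,300), [300,600),
[600,900) by original timing).  Criteria, lowest score first:

====== ==================================================
score  criterion
====== ==================================================
1      >= 1 C-stage in minutes 1-5
2      >= 1 C-stage in minutes 6-10
3      >= 1 C-stage in minutes 11-15
4      >= 1/3 of minutes 1-5 segments are B2/3
5      >= 1/3 of minutes 6-10 segments are B2/3
6      >= 1/3 of minutes 11-15 segments are B2/3
7      >= 1/3 of minutes 1-5 segments are B1
8      >= 1/3 of minutes 6-10 segments are B1
9      >= 1/3 of minutes 11-15 segments are B1
11     >= 2/3 of all segments are 0 or A1
10     >= 2/3 of all segments are 0, A1, A2 or A3
====== ==================================================

The first criterion satisfied in this order fires (deep decline dominates);
if none fires the configurable fallback (default 10) is used and flagged.
Artifact-flagged segments are excluded from numerators and denominators;
fractions compare with exact rational arithmetic.  Subjects with score <= 6
form the hypoaroused-fatigue group, score >= 7 the non-hypoaroused group.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .exceptions import ValidationError
from .io import StageSequenceRecord

BLOCK_LEN_S = 300  # 5-min blocks
N_BLOCKS = 3

HYPOAROUSED = "hypoaroused"
NON_HYPOAROUSED = "non_hypoaroused"

_BLOCK_NAMES = ("minutes_1_5", "minutes_6_10", "minutes_11_15")


@dataclass
class StabilityResult:
    score: int
    matched_criterion: str
    group: str
    block_fractions: list[dict[str, float]]  # per block: frac_b1, frac_b23
    c_first_block: int | None                # 0-based block index, if any C
    fallback_used: bool = False


def stratify(score: int) -> str:
    """Group label from the stability score: <= 6 hypoaroused, >= 7 not."""
    if not 1 <= int(score) <= 11 or int(score) != score:
        raise ValidationError(f"stability score must be an integer in [1, 11], got {score}")
    return HYPOAROUSED if score <= 6 else NON_HYPOAROUSED


def stability_score(
    seq: StageSequenceRecord, fallback_score: int = 10
) -> StabilityResult:
    """Evaluate the stability criteria on a stage sequence.

    Recordings shorter than 15 min use the blocks they reach.  Raises if no
    artifact-free segment exists.
    """
    stages = np.asarray(seq.stages, dtype=object)
    keep = ~seq.artifact_mask
    if not keep.any():
        raise ValidationError("no artifact-free segments to score")

    # per-block counts over artifact-free segments, by original timing
    blocks: list[np.ndarray] = []
    for b in range(N_BLOCKS):
        sl = slice(b * BLOCK_LEN_S, (b + 1) * BLOCK_LEN_S)
        blocks.append(stages[sl][keep[sl]])

    third = Fraction(1, 3)
    two_thirds = Fraction(2, 3)

    def frac(block: np.ndarray, members: tuple[str, ...]) -> Fraction:
        if block.size == 0:
            return Fraction(0)
        return Fraction(int(np.isin(block, members).sum()), int(block.size))

    block_fractions = [
        {
            "frac_b1": float(frac(blk, ("B1",))),
            "frac_b23": float(frac(blk, ("B2/3",))),
        }
        for blk in blocks
    ]
    c_first = next(
        (b for b, blk in enumerate(blocks) if (blk == "C").any()), None
    )

    score: int | None = None
    criterion = ""
    if c_first is not None:
        score = 1 + c_first
        criterion = f"c_stage_in_{_BLOCK_NAMES[c_first]}"
    if score is None:
        for b, blk in enumerate(blocks):
            if frac(blk, ("B2/3",)) >= third:
                score, criterion = 4 + b, f"b23_ge_third_{_BLOCK_NAMES[b]}"
                break
    if score is None:
        for b, blk in enumerate(blocks):
            if frac(blk, ("B1",)) >= third:
                score, criterion = 7 + b, f"b1_ge_third_{_BLOCK_NAMES[b]}"
                break
    fallback = False
    if score is None:
        all_stages = stages[keep]
        if frac(all_stages, ("0", "A1")) >= two_thirds:
            score, criterion = 11, "two_thirds_0_or_A1"
        elif frac(all_stages, ("0", "A1", "A2", "A3")) >= two_thirds:
            score, criterion = 10, "two_thirds_A_stages"
        else:
            score, criterion, fallback = fallback_score, "fallback_no_criterion", True
    return StabilityResult(
        score=int(score),
        matched_criterion=criterion,
        group=stratify(int(score)),
        block_fractions=block_fractions,
        c_first_block=c_first,
        fallback_used=fallback,
    )
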