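"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results by the most literal route available —
direct transcription of the stability scoring table and full enumeration of
the Mann-Whitney permutation distribution — and share no code with the
implementations they check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np

# ---------------------------------------------------------------------------
# arousal stability score: literal row-by-row transcription
# ---------------------------------------------------------------------------


def brute_force_stability(stages: list[str], artifact: np.ndarray | None = None) -> int:
    """Literal evaluation of the scoring rows, lowest score first.

    Row semantics: a C stage in minutes 1-5 / 6-10 / 11-15 gives 1 / 2 / 3;
    at least one third B2/3 in those blocks gives 4 / 5 / 6; one third B1
    gives 7 / 8 / 9; two thirds of all segments in {0, A1} gives 11; two
    thirds in {0, A1, A2, A3} gives 10; otherwise 10 (fallback).
    """
    if artifact is None:
        artifact = np.zeros(len(stages), dtype=bool)
    kept = [(i, s) for i, (s, bad) in enumerate(zip(stages, artifact)) if not bad]
    assert kept, "need at least one artifact-free segment"

    def block(b):
        return [s for i, s in kept if b * 300 <= i < (b + 1) * 300]

    def frac_of(b, members):
        blk = block(b)
        if not blk:
            return Fraction(0)
        return Fraction(sum(s in members for s in blk), len(blk))

    if any(s == "C" for s in block(0)):
        return 1
    if any(s == "C" for s in block(1)):
        return 2
    if any(s == "C" for s in block(2)):
        return 3
    if frac_of(0, {"B2/3"}) >= Fraction(1, 3):
        return 4
    if frac_of(1, {"B2/3"}) >= Fraction(1, 3):
        return 5
    if frac_of(2, {"B2/3"}) >= Fraction(1, 3):
        return 6
    if frac_of(0, {"B1"}) >= Fraction(1, 3):
        return 7
    if frac_of(1, {"B1"}) >= Fraction(1, 3):
        return 8
    if frac_of(2, {"B1"}) >= Fraction(1, 3):
        return 9
    all_kept = [s for _, s in kept]
    if Fraction(sum(s in ("0", "A1") for s in all_kept), len(all_kept)) >= Fraction(2, 3):
        return 11
    if Fraction(
        sum(s in ("0", "A1", "A2", "A3") for s in all_kept), len(all_kept)
    ) >= Fraction(2, 3):
        return 10
    return 10  # fallback: no sustained-decline criterion fired


# ---------------------------------------------------------------------------
# Mann-Whitney U: exact permutation distribution by full enumeration
# ---------------------------------------------------------------------------


def mw_exact_distribution(n1: int, n2: int) -> dict[float, float]:
    """P(U1 = u) under the null, by enumerating all rank assignments."""
    n = n1 + n2
    counts: dict[float, int] = {}
    for idx in itertools.combinations(range(n), n1):
        u = sum(idx) + n1 - n1 * (n1 + 1) / 2.0
        counts[u] = counts.get(u, 0) + 1
    total = sum(counts.values())
    return {u: c / total for u, c in counts.items()}


def mw_exact_p(x, y, convention: str = "inclusive") -> float:
    """Exact two-sided p of the observed U (tie-free samples only).

    ``inclusive``: P(|U - mu| >= |u_obs - mu|).  ``mid``: the mid-p variant
    counting the observed deviation with weight one half — the quantity the
    (uncorrected) normal approximation estimates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = np.argsort(np.argsort(np.concatenate([x, y]))) + 1
    u_obs = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    dist = mw_exact_distribution(x.size, y.size)
    mu = x.size * y.size / 2.0
    dev = abs(u_obs - mu)
    if convention == "inclusive":
        return min(1.0, sum(p for u, p in dist.items() if abs(u - mu) >= dev - 1e-9))
    above = sum(p for u, p in dist.items() if abs(u - mu) > dev + 1e-9)
    at = sum(p for u, p in dist.items() if abs(abs(u - mu) - dev) <= 1e-9)
    return min(1.0, above + 0.5 * at) if dev > 1e-9 else 1.0


def spearman_direct(x, y) -> float:
    """Rank correlation straight from the definition (average ranks)."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(
        np.sum((rx - rx.mean()) * (ry - ry.mean()))
        / np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
    )
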