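"""The group-comparison statistical battery.

Continuous variables are compared between the hypoaroused and non-hypoaroused
groups with the Mann-Whitney U test reported as a tie-corrected asymptotic
Z (no continuity correction, as statistical packages print it) with the
effect size eta^2 = Z^2 / N and a percentile-bootstrap 90% confidence
interval (10,000 replications, groups resampled independently).  Categorical
variables use the Pearson chi-square without continuity correction.
Associations use the Spearman rank correlation; partial rank correlations
are realized as partial Pearson correlations on average ranks with
covariates removed by least-squares residualization.

Sign convention for Z: negative when the first-listed group has the lower
mean rank (the non-hypoaroused group is listed first in the group tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .exceptions import ValidationError

logger = logging.getLogger("eegarousal")


@dataclass
class TestResult:
    test_name: str
    statistic: float                 # U (min convention) or chi-square
    z_value: float | None = None
    p_two_sided: float = np.nan
    eta_squared: float | None = None
    eta_ci_90: tuple[float, float] | None = None
    n_per_group: tuple[int, int] | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def mann_whitney(x, y) -> TestResult:
    """Mann-Whitney U with tie-corrected asymptotic Z and two-sided p.

    Z = (U1 - n1*n2/2) / sd where U1 belongs to the first sample and sd
    carries the tie correction; no continuity correction.  The reported
    ``statistic`` is min(U1, U2) (the conventional U).  Degenerate input
    (all values identical across both samples) yields Z = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = sst.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        logger.info("mann_whitney: degenerate samples (all values tied)")
        z, p = 0.0, 1.0
    else:
        z = (u1 - mu) / np.sqrt(var)
        p = 2.0 * sst.norm.sf(abs(z))
    return TestResult(
        test_name="mann_whitney_u",
        statistic=float(min(u1, n1 * n2 - u1)),
        z_value=float(z),
        p_two_sided=float(min(p, 1.0)),
        eta_squared=eta_squared_mw(z, n),
        n_per_group=(n1, n2),
    )


def eta_squared_mw(z: float, n_total: int, divisor: str = "n") -> float:
    """Effect size eta^2 from the Mann-Whitney Z: Z^2 / N (or Z^2/(N-1))."""
    if n_total < 2:
        raise ValidationError("eta^2 needs a total sample size of at least 2")
    den = n_total if divisor == "n" else n_total - 1
    return float(z**2 / den)


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square (df = 1, no continuity correction) on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("chi_square_2x2 expects a 2x2 count table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("all row and column margins must be positive")
    chi2, p, _, _ = sst.chi2_contingency(t, correction=False)
    return TestResult(
        test_name="chi_square",
        statistic=float(chi2),
        p_two_sided=float(p),
        n_per_group=(int(t[0].sum()), int(t[1].sum())),
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _default_effect(x: np.ndarray, y: np.ndarray) -> float:
    return mann_whitney(x, y).eta_squared


def bootstrap_ci(
    x,
    y,
    statistic=None,
    reps: int = 10_000,
    level: float = 0.90,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a two-sample statistic.

    Groups are resampled independently with replacement, preserving group
    sizes; deterministic given ``seed``.  Default statistic: eta^2 of the
    Mann-Whitney comparison.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if reps < 100:
        raise ValidationError("bootstrap needs at least 100 replications")
    if x.size < 2 or y.size < 2:
        raise ValidationError("bootstrap needs at least 2 observations per group")
    stat = statistic or _default_effect
    rng = np.random.default_rng(seed)
    ix = rng.integers(0, x.size, size=(reps, x.size))
    iy = rng.integers(0, y.size, size=(reps, y.size))
    vals = np.empty(reps)
    for r in range(reps):
        vals[r] = stat(x[ix[r]], y[iy[r]])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("spearman needs paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("spearman is undefined for a constant input vector")
    rho, p = sst.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(x, y, covariates) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariate columns.

    All variables are rank-transformed (average ranks); x and y are then
    residualized on the covariates (with intercept) and the Pearson
    correlation of the residuals is returned, with p from a t distribution
    on n - 2 - k degrees of freedom.  An empty covariate set reduces to the
    plain Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.size == 0:
        return spearman(x, y)
    if cov.ndim == 1:
        cov = cov[:, None]
    n, k = cov.shape
    if x.size != n or y.size != n:
        raise ValidationError("x, y and covariates must have equal length")
    rx = sst.rankdata(x)
    ry = sst.rankdata(y)
    rc = np.column_stack([sst.rankdata(cov[:, j]) for j in range(k)])
    design = np.column_stack([np.ones(n), rc])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        for j in range(k):
            others = np.delete(design, 1 + j, axis=1)
            beta, *_ = np.linalg.lstsq(others, design[:, 1 + j], rcond=None)
            if np.allclose(others @ beta, design[:, 1 + j]):
                raise ValidationError(
                    f"covariate column {j} is collinear with the others"
                )
        raise ValidationError("collinear covariate matrix")
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    if np.allclose(ex, 0) or np.allclose(ey, 0):
        raise ValidationError(
            "partial correlation undefined: a variable is fully explained "
            "by the covariates"
        )
    rho = float(np.corrcoef(ex, ey)[0, 1])
    df = n - 2 - k
    if df <= 0:
        raise ValidationError("not enough observations for the covariate count")
    t = rho * np.sqrt(df / max(1e-12, 1.0 - rho**2))
    p = float(2.0 * sst.t.sf(abs(t), df))
    return rho, p


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def compare_groups(
    df,
    group_col: str,
    continuous: list[str],
    categorical: list[str] | None = None,
    group_order: tuple[str, str] | None = None,
    reps: int = 10_000,
    seed: int | None = None,
):
    """Mann-Whitney + eta^2 + bootstrap CI per continuous variable and
    chi-square per categorical variable, shaped like the study's group
    tables.  Returns a DataFrame (one row per variable)."""
    import pandas as pd

    groups = list(group_order) if group_order else sorted(df[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValidationError(f"group comparison needs exactly 2 groups, got {groups}")
    g1 = df[df[group_col] == groups[0]]
    g2 = df[df[group_col] == groups[1]]
    rows = []
    for var in continuous:
        x = g1[var].dropna().to_numpy(dtype=float)
        y = g2[var].dropna().to_numpy(dtype=float)
        row = {
            "variable": var, "type": "continuous",
            f"mean_{groups[0]}": x.mean() if x.size else np.nan,
            f"sd_{groups[0]}": x.std(ddof=1) if x.size > 1 else np.nan,
            f"n_{groups[0]}": x.size,
            f"mean_{groups[1]}": y.mean() if y.size else np.nan,
            f"sd_{groups[1]}": y.std(ddof=1) if y.size > 1 else np.nan,
            f"n_{groups[1]}": y.size,
        }
        if x.size >= 2 and y.size >= 2:
            res = mann_whitney(x, y)
            lo, hi = bootstrap_ci(x, y, reps=reps, seed=seed)
            row.update(
                statistic=res.statistic, z=res.z_value, p=res.p_two_sided,
                eta_squared=res.eta_squared, eta_ci_lo=lo, eta_ci_hi=hi,
                computable=True,
            )
        else:
            row.update(computable=False)
        rows.append(row)
    for var in categorical or []:
        counts1 = g1[var].value_counts()
        counts2 = g2[var].value_counts()
        levels = sorted(set(counts1.index) | set(counts2.index))
        row = {"variable": var, "type": "categorical",
               f"counts_{groups[0]}": "/".join(str(int(counts1.get(l, 0))) for l in levels),
               f"counts_{groups[1]}": "/".join(str(int(counts2.get(l, 0))) for l in levels)}
        table = np.array(
            [[counts1.get(l, 0) for l in levels], [counts2.get(l, 0) for l in levels]],
            dtype=float,
        )
        if len(levels) == 2 and (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            res = chi_square_2x2(table)
            row.update(statistic=res.statistic, p=res.p_two_sided, computable=True)
        else:
            row.update(computable=False)
        rows.append(row)
    return pd.DataFrame(rows)
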