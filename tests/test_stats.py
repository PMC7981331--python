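import itertools

import numpy as np
import pytest
from scipy import stats as sst

from eegarousal import (
    ValidationError,
    bootstrap_ci,
    chi_square_2x2,
    compare_groups,
    eta_squared_mw,
    mann_whitney,
    partial_spearman,
    spearman,
)

from .oracles import mw_exact_distribution, mw_exact_p, spearman_direct


class TestMannWhitney:
    def test_identical_samples_degenerate(self):
        res = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.z_value == 0.0 and res.p_two_sided == 1.0

    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        # enumeration of all 20 rank arrangements gives exact p = 0.1
        assert mw_exact_p([1, 2, 3], [4, 5, 6], "inclusive") == pytest.approx(0.1)

    def test_swapping_samples_flips_z(self):
        x, y = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 9.0, 11.0]
        a = mann_whitney(x, y)
        b = mann_whitney(y, x)
        assert a.z_value == pytest.approx(-b.z_value)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_sign_convention_lower_first_group_negative(self):
        res = mann_whitney([1, 2, 3, 4], [10, 11, 12, 13])
        assert res.z_value < 0

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 40)
        ours = mann_whitney(x, y)
        ref = sst.mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-10)

    def test_normal_approximation_tracks_exact_midp_for_moderate_n(self):
        """The uncorrected normal p estimates the exact mid-p; for group
        sizes of 4-8 (tie-free) the deviation stays below 0.03."""
        worst = 0.0
        for n1 in range(4, 9):
            for n2 in range(n1, 9):
                dist = mw_exact_distribution(n1, n2)
                mu = n1 * n2 / 2.0
                sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
                for u in dist:
                    p_norm = min(1.0, 2 * sst.norm.sf(abs(u - mu) / sd))
                    dev = abs(u - mu)
                    above = sum(p for v, p in dist.items() if abs(v - mu) > dev + 1e-9)
                    at = sum(
                        p for v, p in dist.items() if abs(abs(v - mu) - dev) <= 1e-9
                    )
                    p_mid = 1.0 if dev < 1e-9 else min(1.0, above + 0.5 * at)
                    worst = max(worst, abs(p_norm - p_mid))
        assert worst <= 0.03

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestChiSquare:
    def test_printed_contingency_tables(self):
        # suicide-attempt history: 7 yes / 67 no vs 4 yes / 20 no
        assert chi_square_2x2([[7, 67], [4, 20]]).statistic == pytest.approx(0.94, abs=0.005)
        # family history of affective disorders: 11/39 vs 5/14
        assert chi_square_2x2([[11, 39], [5, 14]]).statistic == pytest.approx(0.14, abs=0.005)

    def test_proportional_table_is_zero(self):
        assert chi_square_2x2([[10, 20], [5, 10]]).statistic == pytest.approx(0.0)

    def test_scaling_all_cells_scales_statistic(self):
        base = chi_square_2x2([[8, 12], [15, 5]]).statistic
        scaled = chi_square_2x2([[24, 36], [45, 15]]).statistic
        assert scaled == pytest.approx(3 * base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_2x2([[0, 0], [5, 10]])


class TestEtaSquared:
    def test_zero_z_gives_zero(self):
        assert eta_squared_mw(0.0, 50) == 0.0

    def test_closed_form(self):
        assert eta_squared_mw(2.0, 100) == pytest.approx(0.04)

    def test_even_in_z(self):
        assert eta_squared_mw(-1.7, 64) == eta_squared_mw(1.7, 64)

    def test_alternative_divisor(self):
        assert eta_squared_mw(2.0, 101, divisor="n-1") == pytest.approx(0.04)


class TestBootstrap:
    def test_same_seed_identical_interval(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 40), rng.normal(0.6, 1, 25)
        a = bootstrap_ci(x, y, reps=2000, seed=123)
        b = bootstrap_ci(x, y, reps=2000, seed=123)
        assert a == b

    def test_constant_data_degenerate_interval(self):
        lo, hi = bootstrap_ci([2.0] * 10, [2.0] * 10, reps=200, seed=0)
        assert lo == hi

    def test_interval_ordering(self):
        rng = np.random.default_rng(9)
        lo, hi = bootstrap_ci(rng.normal(size=30), rng.normal(size=30),
                              reps=500, seed=1)
        assert lo <= hi

    def test_nominal_coverage_for_mean_difference_under_null(self):
        """Percentile 90% CI of the mean difference covers the true value
        (zero) at close to nominal rate over simulated null datasets."""
        rng = np.random.default_rng(11)
        stat = lambda a, b: a.mean() - b.mean()  # noqa: E731
        n_datasets, covered = 500, 0
        for i in range(n_datasets):
            x = rng.standard_normal(50)
            y = rng.standard_normal(50)
            lo, hi = bootstrap_ci(x, y, statistic=stat, reps=1000, seed=i)
            covered += lo <= 0.0 <= hi
        assert abs(covered / n_datasets - 0.90) < 0.04

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_ci([1.0], [1.0, 2.0], reps=200, seed=0)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 5, 9], [10, 20, 21, 50, 100])
        assert rho == pytest.approx(1.0)

    def test_antithetic(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_matches_direct_rank_formula(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(spearman_direct(x, y))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestPartialSpearman:
    def test_empty_covariates_reduce_to_plain(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert partial_spearman(x, y, np.empty((30, 0))) == pytest.approx(
            spearman(x, y)
        )

    def test_covariate_identical_to_x_rejected(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        with pytest.raises(ValidationError):
            partial_spearman(x, y, x[:, None])

    def test_collinear_covariates_identified(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=25), rng.normal(size=25)
        c = rng.normal(size=25)
        with pytest.raises(ValidationError, match="collinear"):
            partial_spearman(x, y, np.column_stack([c, 2 * c]))

    def test_recovers_known_partial_structure(self):
        # y = x + c with x independent of c: controlling for c should
        # reveal a strong x-y partial association, while the confounded
        # marginal association with c is removed
        rng = np.random.default_rng(6)
        n = 400
        x = rng.normal(size=n)
        c = rng.normal(size=n)
        y = x + c
        rho_partial, p = partial_spearman(x, y, c[:, None])
        rho_plain, _ = spearman(x, y)
        assert rho_partial > 0.65
        assert rho_partial > rho_plain
        assert p < 1e-6
        # and the partial association of c with x given y is negative
        rho_cx, _ = partial_spearman(c, x, y[:, None])
        assert rho_cx < -0.3


class TestCompareGroups:
    def test_table_shape_and_direction(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "group": ["a"] * 40 + ["b"] * 40,
                "v": np.concatenate([rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)]),
                "cat": ["yes", "no"] * 40,
            }
        )
        out = compare_groups(df, "group", ["v"], ["cat"],
                             group_order=("a", "b"), reps=300, seed=0)
        row = out[out["variable"] == "v"].iloc[0]
        assert row["mean_a"] < row["mean_b"]
        assert row["z"] < 0  # first-listed group has the lower mean rank
        assert 0 <= row["eta_squared"] <= 1
        assert row["eta_ci_lo"] <= row["eta_ci_hi"]
        cat_row = out[out["variable"] == "cat"].iloc[0]
        assert cat_row["computable"]
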