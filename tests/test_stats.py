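"""Rank tests, correlations, LOESS and the cutoff detector."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from vrsquant import default_cohort_config, generate_cohort
from vrsquant.stats import (
    bonferroni_threshold,
    correlation_panel,
    detect_cutoff,
    format_p,
    loess_fit,
    mann_whitney_u,
    pairwise_group_comparisons,
    pearson_r,
    seizure_duration_cutoff,
    summarize_groups,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    the pooled (tie-free) values to the two groups."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle needs tie-free data"
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    le = ge = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        total += 1
        le += u <= u_obs
        ge += u >= u_obs
    return min(1.0, 2 * min(le, ge) / total)


class TestMannWhitney:
    def test_disjoint_samples_exact_p(self):
        u, p, method = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert method == "exact"
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        x = [1.0, 2.0, 2.0, 3.0]
        u, p, _ = mann_whitney_u(x, x)
        assert u == len(x) ** 2 / 2
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_exact_path_matches_enumeration_exhaustively(self, n):
        """Every tie-free rank configuration at n1 = n2 = n."""
        ranks = list(range(1, 2 * n + 1))
        for combo in itertools.combinations(ranks, n):
            x = [float(r) for r in combo]
            y = [float(r) for r in ranks if r not in combo]
            _, p, method = mann_whitney_u(x, y)
            assert method == "exact"
            assert p == pytest.approx(enumeration_p(x, y), abs=1e-12)

    def test_exact_path_matches_enumeration_unequal_sizes(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pooled = rng.permutation(np.arange(1.0, 11.0))
            x, y = pooled[:4], pooled[4:]
            _, p, _ = mann_whitney_u(x, y)
            assert p == pytest.approx(enumeration_p(x, y), abs=1e-12)

    def test_asymptotic_close_to_exact_at_n8(self):
        """The continuity-corrected normal approximation tracks the exact
        p closely at n1 = n2 = 8: the p-value depends on the data only
        through U, so all 65 possible U values are checked exhaustively.
        The true worst-case gap of this approximation is 0.0109 (at
        U = 24/40), so 0.011 is the tightest honest bound."""
        from scipy.stats import mannwhitneyu

        base = np.arange(1.0, 17.0)
        worst = 0.0
        for u in range(0, 65):
            # realise a tie-free configuration with this U: move the top
            # u pairwise wins into x one rank swap at a time
            x, y = self._samples_with_u(u)
            p_exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            p_asym = min(
                mannwhitneyu(
                    x, y, alternative="two-sided", method="asymptotic", use_continuity=True
                ).pvalue,
                1.0,
            )
            worst = max(worst, abs(p_asym - p_exact))
        assert worst <= 0.011

    @staticmethod
    def _samples_with_u(u):
        """A tie-free 8-vs-8 sample whose Mann-Whitney U equals ``u``."""
        # start with x holding the 8 smallest ranks (U = 0) and promote x
        # elements upward one rank step at a time; each swap adds 1 to U
        order = list(range(16))
        x_idx = list(range(8))
        steps = u
        for i in reversed(range(8)):
            while steps > 0 and x_idx[i] + 1 < 16 and (x_idx[i] + 1 not in x_idx):
                x_idx[i] += 1
                steps -= 1
        x = [float(order[i] + 1) for i in x_idx]
        y = [float(r + 1) for r in range(16) if r not in x_idx]
        return x, y

    def test_large_samples_take_asymptotic_path(self):
        rng = np.random.default_rng(0)
        _, _, method = mann_whitney_u(rng.normal(size=30), rng.normal(size=40))
        assert method == "asymptotic"


class TestBonferroni:
    def test_three_comparisons_render_017(self):
        adj = bonferroni_threshold(0.05, 3)
        assert f"{adj:.3f}".lstrip("0") == ".017"

    def test_single_comparison_unchanged(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_ten_comparisons(self):
        assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_p_rendering(self):
        assert format_p(0.0004) == "<.001"
        assert format_p(0.6234) == ".623"


class TestPairwiseComparisons:
    def test_published_significance_pattern_is_modal(self):
        """Counts and volume separate the long-seizure group from both
        others; for counts the short-seizure vs control pair is also
        reliably non-significant.  (The volume non-difference of that
        pair is not reproducible from the printed group parameters: the
        control volume SD of 111.50 is an order of magnitude below the
        other groups', which makes the 342 mm^3 mean gap detectable.)"""
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cohort = generate_cohort(default_cohort_config(seed=seed))
            ok = True
            for metric in ("vrs_count", "vrs_volume_mm3"):
                res = {
                    (c.group_a, c.group_b): c.significant
                    for c in pairwise_group_comparisons(cohort, metric)
                }
                ok &= res[("SFS>5M", "SFS<=5M")]
                ok &= res[("SFS>5M", "control")]
            res_counts = {
                (c.group_a, c.group_b): c.significant
                for c in pairwise_group_comparisons(cohort, "vrs_count")
            }
            ok &= not res_counts[("SFS<=5M", "control")]
            hits += ok
        assert hits / n_seeds > 0.5

    def test_identical_metric_never_flagged(self, default_cohort):
        cohort = default_cohort.copy()
        cohort["flat"] = 1.0
        res = pairwise_group_comparisons(cohort, "flat")
        assert not any(c.significant for c in res)

    def test_tiny_groups_match_enumeration_oracle(self):
        cohort = pd.DataFrame(
            {
                "group": ["SFS>5M"] * 3 + ["SFS<=5M"] * 3 + ["control"] * 3,
                "m": [9.0, 7.0, 8.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        for c in pairwise_group_comparisons(cohort, "m"):
            x = cohort.loc[cohort.group == c.group_a, "m"].tolist()
            y = cohort.loc[cohort.group == c.group_b, "m"].tolist()
            assert c.p_value == pytest.approx(enumeration_p(x, y), abs=1e-12)

    def test_missing_metric_column(self, default_cohort):
        with pytest.raises(KeyError):
            pairwise_group_comparisons(default_cohort, "nonexistent")

    def test_type_one_error_controlled_under_null(self):
        """All three groups from one distribution: the family-wise rate of
        any pairwise p < .017 stays near alpha."""
        rng = np.random.default_rng(2024)
        adj = bonferroni_threshold(0.05, 3)
        false_hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            a = rng.normal(size=30)
            b = rng.normal(size=40)
            c = rng.normal(size=35)
            ps = [
                mann_whitney_u(a, b)[1],
                mann_whitney_u(a, c)[1],
                mann_whitney_u(b, c)[1],
            ]
            false_hits += min(ps) < adj
        assert false_hits / n_rep <= 0.06


class TestPearson:
    def test_exact_linearity(self):
        r, p, n = pearson_r([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_half_correlation_closed_form(self):
        # cov = 0.5, sd_x = sd_y = 1 (population formulas cancel n):
        # r = 0.5 for y a single transposition of x
        r, _, _ = pearson_r([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_negation_flips_sign_exactly(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r1, _, _ = pearson_r(x, y)
        r2, _, _ = pearson_r(x, -y)
        assert r1 == pytest.approx(-r2, abs=1e-15)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r1, _, _ = pearson_r(x, y)
        r2, _, _ = pearson_r(3.2 * x + 7, 0.5 * y - 2)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestCorrelationPanel:
    def test_sign_pattern_on_long_seizure_group(self, large_cohort):
        res = correlation_panel(large_cohort, "SFS>5M")
        signs = {(r.var_x, r.var_y): np.sign(r.r) for r in res}
        assert signs[("duration_min", "vrs_count")] == 1
        assert signs[("duration_min", "vrs_volume_mm3")] == 1
        assert signs[("course_days", "vrs_count")] == -1
        assert signs[("course_days", "vrs_volume_mm3")] == -1

    def test_configured_correlation_recovered(self, large_cohort):
        res = correlation_panel(large_cohort, "SFS>5M")
        r = next(
            r.r for r in res if (r.var_x, r.var_y) == ("duration_min", "vrs_count")
        )
        assert r == pytest.approx(0.778, abs=0.05)

    def test_control_group_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="not applicable"):
            correlation_panel(default_cohort, "control")


class TestLoess:
    def test_constant_y_reproduced(self):
        x = np.linspace(0, 10, 40)
        fit = loess_fit(x, np.full(40, 3.5))
        assert np.allclose(fit.fitted, 3.5, atol=1e-12)

    @pytest.mark.parametrize("span", [0.2, 0.5, 1.0])
    def test_linear_y_reproduced_any_span(self, span):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 10, 50))
        y = 2.5 * x - 4
        fit = loess_fit(x, y, span=span)
        assert np.allclose(fit.fitted, 2.5 * fit.grid - 4, atol=1e-9)

    def test_single_grid_point_matches_direct_wls_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 60)
        y = np.sin(x) + rng.normal(0, 0.1, 60)
        fit = loess_fit(x, y, span=0.4)
        g = fit.grid[57]
        # independent tricube-weighted least squares at that point
        k = math.ceil(0.4 * 60)
        d = np.abs(x - g)
        idx = np.argsort(d)[:k]
        w = (1 - (d[idx] / d[idx].max()) ** 3) ** 3
        X = np.vstack([np.ones(k), x[idx]]).T
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[idx])
        assert fit.fitted[57] == pytest.approx(beta[0] + beta[1] * g, abs=1e-9)

    def test_matches_reference_lowess_implementation(self):
        sm = pytest.importorskip("statsmodels.nonparametric.smoothers_lowess")
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 70)
        y = x**2 / 10 + rng.normal(0, 0.5, 70)
        fit = loess_fit(x, y, span=0.5)
        ref = sm.lowess(y, x, frac=0.5, it=0, xvals=fit.grid)
        assert np.allclose(fit.fitted, ref, atol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_fit([1, 2, 3], [1, 2, 3])

    def test_span_too_small_rejected(self):
        with pytest.raises(ValueError, match="neighbours"):
            loess_fit(np.arange(10.0), np.arange(10.0), span=0.2)


class TestDetectCutoff:
    @pytest.mark.parametrize("breakpoint", [3, 5, 8])
    def test_slope_break_recovered(self, breakpoint):
        cuts = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.5, 10.5, 70)
            y = np.where(x > breakpoint, (x - breakpoint) * 60, 0.0) + 450
            y += rng.normal(0, 20, 70)
            cuts.append(detect_cutoff(loess_fit(x, y)).cutoff)
        assert abs(np.median(cuts) - breakpoint) <= 0.5

    def test_globally_linear_curve_has_no_cutoff(self):
        x = np.linspace(0, 10, 50)
        fit = loess_fit(x, 3 * x + 1)
        with pytest.raises(ValueError, match="no cutoff"):
            detect_cutoff(fit)

    def test_cutoff_inside_observed_range(self, default_cohort):
        cut = seizure_duration_cutoff(default_cohort)
        dur = default_cohort["duration_min"].dropna()
        assert dur.min() < cut.cutoff < dur.max()

    def test_unknown_criterion_rejected(self):
        x = np.linspace(0, 10, 50)
        fit = loess_fit(x, x**2)
        with pytest.raises(ValueError, match="criterion"):
            detect_cutoff(fit, criterion="steepest")


class TestSummaries:
    def test_single_subject_sd_zero_with_flag(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a"],
                "group": ["control"],
                "sex": ["M"],
                "vrs_count": [400.0],
            }
        )
        out = summarize_groups(df)
        row = out[(out.variable == "vrs_count")].iloc[0]
        assert row["sd"] == 0.0
        assert row["flag"] == "single-subject"

    def test_large_cohort_round_trip_recovers_configured_means(self, large_cohort):
        out = summarize_groups(large_cohort)
        got = out[
            (out.group == "SFS>5M") & (out.variable == "vrs_count")
        ].iloc[0]["mean"]
        assert got == pytest.approx(642.70, rel=0.01)

    def test_male_counts_reported(self, default_cohort):
        out = summarize_groups(default_cohort)
        male = out[(out.group == "SFS>5M") & (out.variable == "male")].iloc[0]
        assert 0 <= male["mean"] <= 30
        assert 0 <= male["sd"] <= 100  # percentage slot

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_groups(pd.DataFrame(columns=["group"]))
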