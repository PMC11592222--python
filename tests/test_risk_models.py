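"""Decile stratification, 2x2 odds ratios, Wald CIs and logistic fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import melprs as m
from melprs.risk_models import SeparationError

# Published decile layout of a 270-case / 296-control melanoma series,
# deciles of the control score distribution, reference = merged 5-6th.
MELANOMA_DECILE_COUNTS = {
    "1": (10, 30), "2": (14, 30), "3": (15, 29), "4": (21, 30),
    "5-6": (49, 58), "7": (17, 30), "8": (32, 30), "9": (42, 29), "10": (70, 30),
}
# MPM (n=177) vs SPM (n=93) by case-score decile, reference = 1st decile.
MPM_DECILE_COUNTS = {
    "1": (13, 14), "2": (18, 9), "3": (18, 9), "4": (14, 13), "5": (21, 6),
    "6": (17, 10), "7": (13, 14), "8": (21, 6), "9": (20, 7), "10": (22, 5),
}


class TestDecileCutpoints:
    def test_matches_interpolated_order_statistics(self):
        scores = np.arange(1.0, 101.0)
        cuts = m.decile_cutpoints(scores)
        # brute-force type-7 rule: q_p = x_(k) + g*(x_(k+1) - x_(k)), h=(n-1)p
        srt = np.sort(scores)
        for d, c in enumerate(cuts, start=1):
            h = (len(srt) - 1) * d / 10
            k, g = int(np.floor(h)), h - np.floor(h)
            expected = srt[k] + g * (srt[k + 1] - srt[k]) if g else srt[k]
            assert c == pytest.approx(expected, abs=1e-12)

    def test_too_few_scores_error(self):
        with pytest.raises(ValueError):
            m.decile_cutpoints(np.arange(9.0))

    def test_constant_vector_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            m.decile_cutpoints(np.ones(20))

    def test_reference_bins_itself_evenly(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=300)
        scheme = m.DecileScheme(m.decile_cutpoints(ref), {}, "1")
        labels = m.assign_deciles(ref, scheme)
        counts = pd.Series(labels).value_counts()
        assert all(abs(counts[str(d)] - 30) <= 1 for d in range(1, 11))


class TestAssignDeciles:
    scheme = m.DecileScheme(np.arange(1.0, 10.0), {}, "1")

    @pytest.mark.parametrize("score,expected", [
        (-5.0, "1"),    # below all cutpoints
        (5.0, "5"),     # exactly at a cutpoint -> lower decile (right-closed)
        (5.1, "6"),
        (99.0, "10"),   # above all cutpoints
    ])
    def test_boundaries_and_tie_rule(self, score, expected):
        assert m.assign_deciles(np.array([score]), self.scheme)[0] == expected

    def test_merged_groups_applied_after_assignment(self):
        scheme = m.DecileScheme(np.arange(1.0, 10.0), m.MERGE_5_6, "5-6")
        labels = m.assign_deciles(np.array([4.5, 5.5, 6.5]), scheme)
        assert labels.tolist() == ["5-6", "5-6", "7"]

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=120)
        scores = rng.normal(size=60)
        scheme = m.DecileScheme(m.decile_cutpoints(ref), {}, "1")
        t = np.exp  # strictly increasing
        scheme_t = m.DecileScheme(t(m.decile_cutpoints(ref)), {}, "1")
        assert np.array_equal(m.assign_deciles(scores, scheme),
                              m.assign_deciles(t(scores), scheme_t))


class TestOr2x2AndWaldCi:
    @pytest.mark.parametrize("table,expected", [
        ((70, 30, 49, 58), 2.76),   # top decile vs merged 5-6 reference
        ((22, 5, 13, 14), 4.74),    # top case-decile MPM vs decile 1
    ])
    def test_published_cross_products(self, table, expected):
        assert round(m.or_2x2(m.ContingencyTable2x2(*table)), 2) == expected

    def test_equal_odds_is_one(self):
        assert m.or_2x2(m.ContingencyTable2x2(12, 7, 12, 7)) == pytest.approx(1.0)

    def test_zero_cell_errors_unless_haldane(self):
        t = m.ContingencyTable2x2(5, 0, 3, 4)
        with pytest.raises(ValueError):
            m.or_2x2(t)
        assert m.or_2x2(t, haldane=True) == pytest.approx((5.5 * 4.5) / (0.5 * 3.5))

    def test_wald_ci_lower_bound_published(self):
        low, high = m.wald_ci(m.ContingencyTable2x2(70, 30, 49, 58))
        assert round(low, 2) == 1.56

    def test_level_zero_collapses_to_point(self):
        t = m.ContingencyTable2x2(8, 6, 5, 9)
        low, high = m.wald_ci(t, level=1e-12)
        assert low == pytest.approx(m.or_2x2(t), rel=1e-6)
        assert high == pytest.approx(m.or_2x2(t), rel=1e-6)

    def test_matches_log_scale_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 40, 4)
            t = m.ContingencyTable2x2(int(a), int(b), int(c), int(d))
            log_or = np.log(a) + np.log(d) - np.log(b) - np.log(c)
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            z = stats.norm.ppf(0.975)
            low, high = m.wald_ci(t)
            assert low == pytest.approx(np.exp(log_or - z * se), abs=1e-12)
            assert high == pytest.approx(np.exp(log_or + z * se), abs=1e-12)


class TestFitLogistic:
    def test_saturated_2x2_equals_cross_product(self):
        labels, y = m.expand_counts({"exp": (70, 30), "ref": (49, 58)})
        x = (labels == "exp").astype(float)
        design = np.column_stack([np.ones_like(x), x])
        fit = m.fit_logistic(design, y)
        t = m.ContingencyTable2x2(70, 30, 49, 58)
        assert np.exp(fit.coefficients[1]) == pytest.approx(m.or_2x2(t), abs=1e-8)
        rec = fit.wald("x1")
        low, high = m.wald_ci(t)
        assert rec.ci_low == pytest.approx(low, abs=1e-6)
        assert rec.ci_high == pytest.approx(high, abs=1e-6)

    def test_mle_beats_coefficient_grid(self):
        # tiny n: the IRLS optimum must dominate a brute-force 2-D grid search
        x = np.array([0.1, -0.3, 0.8, 1.2, -0.5, 0.4, -1.0, 0.9])
        y = np.array([0, 0, 1, 1, 1, 0, 0, 1], float)
        design = np.column_stack([np.ones(8), x])
        fit = m.fit_logistic(design, y)

        def ll(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))

        grid = [ll(b0, b1) for b0 in np.linspace(-5, 5, 81)
                for b1 in np.linspace(-8, 8, 81)]
        assert fit.log_likelihood >= max(grid) - 1e-9
        assert fit.converged

    def test_separation_raises(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            m.fit_logistic(np.column_stack([np.ones(6), x]), y)

    def test_singular_design_raises(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        design = np.column_stack([np.ones(4), x, 2 * x])
        with pytest.raises((ValueError, SeparationError)):
            m.fit_logistic(design, np.array([0, 1, 0, 1.0]))

    def test_one_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            m.fit_logistic(np.ones((5, 1)), np.zeros(5))


class TestDecileOrTable:
    def test_melanoma_table_crude_ors(self):
        labels, y = m.expand_counts(MELANOMA_DECILE_COUNTS)
        recs = {r.label: r for r in m.decile_or_table(labels, y, reference="5-6")}
        assert round(recs["10"].or_value, 2) == 2.76
        assert round(recs["9"].or_value, 2) == 1.71
        assert round(recs["8"].or_value, 2) == 1.26
        assert round(recs["1"].or_value, 2) == 0.39
        assert round(recs["10"].ci_low, 2) == 1.56

    def test_mpm_table_crude_ors(self):
        labels, y = m.expand_counts(MPM_DECILE_COUNTS)
        recs = {r.label: r for r in m.decile_or_table(labels, y, reference="1")}
        assert round(recs["10"].or_value, 2) == 4.74
        assert round(recs["5"].or_value, 2) == 3.77

    def test_logistic_route_agrees_with_cross_product(self):
        labels, y = m.expand_counts(MELANOMA_DECILE_COUNTS)
        recs = {r.label: r for r in m.decile_or_table(labels, y, reference="5-6")}
        c_ref, n_ref = MELANOMA_DECILE_COUNTS["5-6"]
        for g, (cases, ctrls) in MELANOMA_DECILE_COUNTS.items():
            if g == "5-6":
                continue
            t = m.ContingencyTable2x2(cases, ctrls, c_ref, n_ref)
            assert recs[g].or_value == pytest.approx(m.or_2x2(t), abs=1e-6)

    def test_empty_reference_errors(self):
        labels, y = m.expand_counts({"2": (5, 5), "3": (6, 4)})
        with pytest.raises(ValueError):
            m.decile_or_table(labels, y, reference="1")

    def test_null_simulation_ci_coverage(self):
        # outcome independent of group labels: 95% Wald CIs should cover 1
        rng = np.random.default_rng(42)
        covered = total = 0
        for _ in range(500):
            labels = rng.choice(["1", "2", "3", "4"], size=200)
            y = rng.random(200) < 0.5
            try:
                recs = m.decile_or_table(labels, y.astype(float), reference="1")
            except (SeparationError, ValueError):
                continue
            for r in recs:
                covered += r.ci_low <= 1.0 <= r.ci_high
                total += 1
        assert 0.92 <= covered / total <= 0.98


class TestPerSdOr:
    def test_rescaled_scores_give_same_or_after_restandardization(self):
        rng = np.random.default_rng(6)
        raw = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-0.5 * raw))).astype(float)
        ctrl = y == 0
        a = m.per_sd_or(m.standardize(raw, ctrl).std_score, y)
        b = m.per_sd_or(m.standardize(raw * 3.7, ctrl).std_score, y)
        assert a.or_value == pytest.approx(b.or_value, rel=1e-9)

    def test_null_ci_covers_one(self):
        rng = np.random.default_rng(13)
        covered = 0
        reps = 200
        for _ in range(reps):
            z = rng.normal(size=300)
            y = (rng.random(300) < 0.5).astype(float)
            rec = m.per_sd_or(z, y)
            covered += rec.ci_low <= 1.0 <= rec.ci_high
        assert covered / reps >= 0.90


class TestDecileReport:
    def test_report_mirrors_published_layout(self):
        labels, y = m.expand_counts(MELANOMA_DECILE_COUNTS)
        table = m.risk_models.decile_report(
            labels, y, reference="5-6",
            group_order=["1", "2", "3", "4", "5-6", "7", "8", "9", "10"],
        )
        assert list(table.columns) == ["group", "n_outcome", "n_reference",
                                       "or_ci", "p_value"]
        row10 = table[table["group"] == "10"].iloc[0]
        assert row10["n_outcome"] == "70 (25.9%)"
        assert row10["n_reference"] == "30 (10.1%)"
        assert row10["or_ci"].startswith("2.76 (1.56,")
        assert table[table["group"] == "5-6"].iloc[0]["or_ci"] == "ref."
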