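"""Titration fits, Poisson variance, ROC, agreement, budgets, and power."""

import math

import numpy as np
import pytest
from scipy import stats

from campseq.evaluate import (
    ROC_BINS,
    auc_rank,
    bland_altman,
    detection_power,
    expected_cv_poisson,
    expected_mixture,
    fit_titration,
    median_log10_se,
    platform_bias_correction,
    read_budget,
    roc_fold_change,
)


class TestFitTitration:
    def test_exact_hyperbola_has_slope_minus_one(self):
        points = [(sc, 1e7 / sc) for sc in (1e6, 1e5, 1e4, 1e3, 300)]
        fit = fit_titration(points)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(7.0)
        assert all(w == pytest.approx(0.0, abs=1e-9) for w in fit.pi95)

    def test_two_points_is_no_fit(self):
        assert fit_titration([(1e5, 10.0), (1e4, 100.0)]) is None

    def test_nonpositive_ratios_dropped_before_counting_points(self):
        points = [(1e5, 10.0), (1e4, 100.0), (1e3, 0.0), (300, float("nan"))]
        assert fit_titration(points) is None

    def test_prediction_interval_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        x = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        y = -x + 3 + rng.normal(0, 0.1, size=5)
        fit = fit_titration(list(zip(10**x, 10**y)))
        # independent recomputation of the PI at the first point
        res = stats.linregress(x, y)
        resid = y - (res.intercept + res.slope * x)
        s = math.sqrt(np.sum(resid**2) / 3)
        sxx = np.sum((x - x.mean()) ** 2)
        expect = stats.t.ppf(0.975, 3) * s * math.sqrt(1 + 1 / 5 + (x[0] - x.mean()) ** 2 / sxx)
        assert fit.pi95[0] == pytest.approx(expect, rel=1e-9)


@pytest.mark.parametrize("copies,cv", [(100, 0.10), (1e4, 0.01), (1, 1.0), (15, 1 / math.sqrt(15))])
def test_poisson_cv_law(copies, cv):
    assert expected_cv_poisson(copies) == pytest.approx(cv)


@pytest.mark.parametrize(
    "a,b,w,expected", [(1000, 200, 0.75, 800.0), (1000, 200, 0.25, 400.0), (7.0, 99.0, 1.0, 7.0)]
)
def test_mixture_expectation(a, b, w, expected):
    assert expected_mixture(a, b, w) == pytest.approx(expected)


class TestFoldChangeROC:
    def test_perfect_separation_gives_auc_one(self):
        assert auc_rank([2.0, 3.0, 4.0], [0.9, 1.0, 1.1]) == 1.0

    def test_same_distribution_gives_auc_near_half(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=500), rng.normal(size=500)
        assert auc_rank(a, b) == pytest.approx(0.5, abs=0.05)

    def test_auc_matches_sklearn_on_mixed_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        tests, controls = rng.normal(1.0, 1.0, 80), rng.normal(0.0, 1.0, 100)
        ours = auc_rank(tests, controls)
        ref = roc_auc_score([1] * 80 + [0] * 100, np.concatenate([tests, controls]))
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        tests, controls = rng.lognormal(0.5, 0.3, 50), rng.lognormal(0.0, 0.3, 60)
        assert auc_rank(np.log(tests), np.log(controls)) == pytest.approx(
            auc_rank(tests, controls), abs=1e-12
        )

    def test_expected_ratio_two_lands_in_printed_bin(self):
        lo, hi = ROC_BINS["2.0"]
        assert lo <= 2.0 < hi
        # the printed bin edges
        assert (lo, hi) == (1.75, 2.5)

    def test_binning_and_controls_from_sample_design(self):
        expected = {
            "A": {"g1": 100.0, "g2": 100.0},
            "B": {"g1": 200.0, "g2": 100.0},
        }
        measured = {
            "A": {"g1": 110.0, "g2": 95.0},
            "B": {"g1": 230.0, "g2": 101.0},
        }
        rocs = roc_fold_change(measured, expected)
        assert len(rocs["2.0"].test_scores) == 1
        assert rocs["2.0"].test_scores[0] == pytest.approx(230 / 110)
        assert rocs["2.0"].control_scores == [pytest.approx(95 / 101)]


class TestBlandAltman:
    def test_identical_measurements(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba == (0.0, 0.0, 0.0, 3)

    def test_constant_shift_is_the_mean_difference(self):
        x = [1.0, 2.0, 3.0, 4.0]
        ba = bland_altman(x, [v + 0.3 for v in x])
        assert ba.mean_difference == pytest.approx(0.3)
        assert ba.loa_low == pytest.approx(0.3) and ba.loa_high == pytest.approx(0.3)

    def test_limits_reflect_known_offset_spread(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(2, 6, 400)
        offsets = rng.normal(0.5, 0.2, 400)
        ba = bland_altman(x, x + offsets)
        assert ba.mean_difference == pytest.approx(0.5, abs=0.05)
        assert (ba.loa_high - ba.loa_low) / 2 == pytest.approx(1.96 * 0.2, rel=0.15)

    def test_fewer_than_two_pairs_raises(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])


class TestPlatformBiasCorrection:
    def test_per_gene_constant_bias_cancels_exactly(self):
        ref_ab = {"A": {"g1": 2.0, "g2": 4.0}, "B": {"g1": 3.0, "g2": 5.0}}
        bias = {"g1": 0.7, "g2": -1.2}
        other_ab = {s: {g: v + bias[g] for g, v in d.items()} for s, d in ref_ab.items()}
        ref_cd = {"C": {"g1": 2.5, "g2": 4.5}, "D": {"g1": 2.2, "g2": 4.9}}
        other_cd = {s: {g: v + bias[g] for g, v in d.items()} for s, d in ref_cd.items()}
        result = platform_bias_correction(ref_ab, other_ab, other_cd)
        for s in ref_cd:
            for g in ref_cd[s]:
                assert result.corrected[s][g] == pytest.approx(ref_cd[s][g])

    def test_zero_offsets_identity(self):
        ab = {"A": {"g1": 2.0}, "B": {"g1": 3.0}}
        cd = {"C": {"g1": 2.5}}
        result = platform_bias_correction(ab, ab, cd)
        assert result.corrected == cd and result.offsets["g1"] == 0.0

    def test_sample_specific_bias_leaves_residual(self):
        """Genes whose bias differs between A and B (different transcript
        isoforms seen by the platforms) stay off after correction."""
        rng = np.random.default_rng(5)
        genes = [f"g{k}" for k in range(50)]
        bad = set(genes[:5])
        ref_ab = {s: {g: rng.uniform(2, 6) for g in genes} for s in "AB"}
        other_ab = {
            s: {
                g: v + (0.4 if s == "A" and g in bad else -0.4 if s == "B" and g in bad else 0.1)
                for g, v in d.items()
            }
            for s, d in ref_ab.items()
        }
        ref_cd = {"C": {g: rng.uniform(2, 6) for g in genes}}
        other_cd = {"C": {g: v + (0.4 if g in bad else 0.1) for g, v in ref_cd["C"].items()}}
        result = platform_bias_correction(ref_ab, other_ab, other_cd)
        residual = {g: abs(result.corrected["C"][g] - ref_cd["C"][g]) for g in genes}
        assert all(residual[g] > 0.2 for g in bad)
        assert all(residual[g] < 1e-9 for g in genes if g not in bad)

    def test_gene_missing_in_reference_is_flagged_not_corrected(self):
        ref_ab = {"A": {"g1": 2.0}, "B": {"g1": 3.0}}
        other_ab = {"A": {"g1": 2.5}, "B": {"g1": 3.5}}
        other_cd = {"C": {"g1": 4.0, "g2": 1.0}}
        result = platform_bias_correction(ref_ab, other_ab, other_cd)
        assert result.uncorrected_genes == ["g2"]
        assert result.corrected["C"]["g2"] == 1.0


class TestReadBudget:
    def test_million_fold_two_target_example(self):
        budget = read_budget([1e6, 1.0], min_reads=15)
        assert budget.traditional_reads == 15_000_015

    def test_equimolar_targets_need_min_reads_each(self):
        budget = read_budget([500.0] * 8, min_reads=15)
        assert budget.traditional_reads == budget.competitive_reads == 15 * 8
        assert budget.fold_reduction == 1.0

    def test_fold_reduction_grows_with_dynamic_range(self):
        reductions = [
            read_budget([10.0**r, 1.0], min_reads=15).fold_reduction for r in (2, 4, 6)
        ]
        assert reductions == sorted(reductions)

    def test_observed_fractions_drive_competitive_budget(self):
        budget = read_budget([1e6, 1.0], min_reads=15, competitive_fractions=[0.5, 0.0005])
        assert budget.competitive_reads == math.ceil(15 / 0.0005)

    def test_empty_or_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            read_budget([])
        with pytest.raises(ValueError):
            read_budget([0.0, 10.0])


class TestDetectionPower:
    def test_fifteen_reads_meets_benchmark_error_rates(self):
        result = detection_power(15, 2.0, 0.05)
        assert result.type1 <= 0.05
        assert result.type2 <= 0.20

    def test_exact_tails_match_monte_carlo(self):
        """Independent check of the exact computation by simulation."""
        result = detection_power(15, 2.0, 0.05)
        rng = np.random.default_rng(6)
        null_draws = rng.poisson(15, 200_000)
        alt_draws = rng.poisson(30, 200_000)
        rej_null = np.mean((null_draws <= result.reject_below) | (null_draws >= result.reject_above))
        rej_alt = np.mean((alt_draws <= result.reject_below) | (alt_draws >= result.reject_above))
        assert result.type1 == pytest.approx(rej_null, abs=0.005)
        assert result.type2 == pytest.approx(1 - rej_alt, abs=0.005)

    def test_fold_one_means_type2_complements_type1(self):
        result = detection_power(15, 1.0, 0.05)
        assert result.type2 == pytest.approx(1 - result.type1, abs=1e-12)

    def test_deep_sequencing_makes_misses_negligible(self):
        assert detection_power(1500, 2.0, 0.05).type2 < 1e-6

    @pytest.mark.parametrize("lam", [2, 5, 15, 40, 200])
    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.1])
    def test_exact_test_is_conservative(self, lam, alpha):
        assert detection_power(lam, 2.0, alpha).type1 <= alpha

    def test_type2_decreases_with_depth_and_effect_size(self):
        by_depth = [detection_power(lam, 2.0, 0.05).type2 for lam in (5, 15, 60, 240)]
        assert by_depth == sorted(by_depth, reverse=True)
        by_fold = [detection_power(15, f, 0.05).type2 for f in (1.5, 2.0, 4.0)]
        assert by_fold == sorted(by_fold, reverse=True)


def test_median_se_shrinks_with_replicates_and_depth():
    shallow = median_log10_se([(20, 20)])
    deep = median_log10_se([(2000, 2000)])
    many = median_log10_se([(20, 20)] * 6)
    assert deep < shallow and many < shallow
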