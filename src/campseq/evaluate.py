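"""Statistical evaluation of competitive amplicon quantification.

Covers titration linearity (log-log regression of the NT:IS read ratio
on IS input, expected slope -1), the Poisson sampling-variance law
(CV = 1/sqrt(copies)), mixture-design expectations for blended
samples, fold-change detection graded by ROC AUC over binned expected
ratios, Bland-Altman agreement, cross-platform systematic-bias
correction, sequencing read-budget arithmetic, and the exact Poisson
power calculation behind the 15-read quantification benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

#: Fold-change ROC bins: label -> half-open [low, high) expected-ratio range.
ROC_BINS: dict[str, tuple[float, float]] = {
    "1.1": (1.05, 1.175),
    "1.25": (1.175, 1.375),
    "1.5": (1.375, 1.75),
    "2.0": (1.75, 2.5),
    ">=4.0": (2.5, 10.0 + 1e-9),
}


# ---------------------------------------------------------------------------
# Titration linearity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TitrationFit:
    """OLS fit of log10(NT:IS) on log10(IS input) for one assay."""

    slope: float
    intercept: float
    r2: float
    pi95: tuple[float, ...]
    n_points: int
    gene_id: str | None = None


def fit_titration(
    points: Sequence[tuple[float, float]], gene_id: str | None = None
) -> TitrationFit | None:
    """Fit the titration line; returns ``None`` below three usable points.

    ``points`` are (SC copies loaded, NT:IS read ratio) pairs; pairs
    with non-finite or non-positive entries are dropped first.  The
    95% prediction-interval half-width is reported at each retained
    point from the standard linear-regression formula.
    """
    clean = [
        (sc, ratio)
        for sc, ratio in points
        if math.isfinite(sc) and math.isfinite(ratio) and sc > 0 and ratio > 0
    ]
    if len(clean) < 3:
        return None
    x = np.log10([sc for sc, _ in clean])
    y = np.log10([r for _, r in clean])
    n = len(x)
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if n > 2 and sxx > 0:
        s_err = math.sqrt(float(np.sum(resid**2)) / (n - 2))
        tcrit = stats.t.ppf(0.975, n - 2)
        pi = tuple(
            float(tcrit * s_err * math.sqrt(1 + 1 / n + (xi - x.mean()) ** 2 / sxx)) for xi in x
        )
    else:
        pi = tuple(0.0 for _ in x)
    return TitrationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        pi95=pi,
        n_points=n,
        gene_id=gene_id,
    )


# ---------------------------------------------------------------------------
# Poisson variance and mixture design
# ---------------------------------------------------------------------------


def median_log10_se(count_pairs: Sequence[tuple[int, int]]) -> float:
    """Poisson-propagated standard error of log10(NC_median).

    Each replicate's log10(NT/IS) variance is (1/NT + 1/IS)/ln(10)^2;
    the median of k replicates carries ~pi/2 times the variance of
    their unweighted mean (the asymptotic normal-median factor).
    """
    k = len(count_pairs)
    if k == 0:
        raise ValueError("at least one replicate required")
    ln10_sq = math.log(10) ** 2
    var_mean = sum((1.0 / nt + 1.0 / is_) / ln10_sq for nt, is_ in count_pairs) / k**2
    return math.sqrt(math.pi / 2 * var_mean)


def expected_cv_poisson(copies: float) -> float:
    """Expected coefficient of variation from Poisson sampling: 1/sqrt(n)."""
    if copies <= 0:
        raise ValueError("copies must be positive")
    return 1.0 / math.sqrt(copies)


def expected_mixture(a: float, b: float, weight_a: float) -> float:
    """Expected copies in a blend of samples A and B (e.g. 0.75A + 0.25B)."""
    if not 0.0 <= weight_a <= 1.0:
        raise ValueError("weight_a must be in [0, 1]")
    return weight_a * a + (1.0 - weight_a) * b


# ---------------------------------------------------------------------------
# Fold-change ROC
# ---------------------------------------------------------------------------


@dataclass
class FoldChangeROC:
    bin_label: str
    ratio_range: tuple[float, float]
    control_scores: list[float] = field(default_factory=list)
    test_scores: list[float] = field(default_factory=list)
    auc: float = math.nan
    ci95: tuple[float, float] = (math.nan, math.nan)


def auc_rank(test_scores: Sequence[float], control_scores: Sequence[float]) -> float:
    """AUC as the Mann-Whitney rank statistic P(test > control)."""
    u = stats.mannwhitneyu(test_scores, control_scores, alternative="greater").statistic
    return float(u) / (len(test_scores) * len(control_scores))


def auc_ci_hanley_mcneil(auc: float, n_test: int, n_control: int) -> tuple[float, float]:
    """Normal-approximation 95% CI for an AUC (Hanley-McNeil variance)."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n_test - 1) * (q1 - auc**2) + (n_control - 1) * (q2 - auc**2)
    ) / (n_test * n_control)
    half = 1.96 * math.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_fold_change(
    measured: Mapping[str, Mapping[str, float]],
    expected: Mapping[str, Mapping[str, float]],
    control_tolerance: float = 1e-6,
) -> dict[str, FoldChangeROC]:
    """Grade fold-change detection across all sample pairs, per ratio bin.

    ``measured`` and ``expected`` map sample -> gene -> copies.  Every
    unordered sample pair and shared gene yields one comparison,
    oriented so the expected ratio is >= 1; its score is the measured
    ratio in that orientation.  Comparisons whose expected ratio is
    exactly 1 are the controls (shared across bins); comparisons whose
    expected ratio falls in a bin's range are that bin's tests.  AUC is
    the rank statistic with a Hanley-McNeil 95% CI; bins with an empty
    test or control set keep a NaN AUC.
    """
    samples = sorted(measured)
    controls: list[float] = []
    rocs = {label: FoldChangeROC(label, rng) for label, rng in ROC_BINS.items()}
    for i, s1 in enumerate(samples):
        for s2 in samples[i + 1 :]:
            genes = set(measured[s1]) & set(measured[s2]) & set(expected[s1]) & set(expected[s2])
            for gene in genes:
                e1, e2 = expected[s1][gene], expected[s2][gene]
                m1, m2 = measured[s1][gene], measured[s2][gene]
                if min(e1, e2, m1, m2) <= 0 or not all(
                    map(math.isfinite, (e1, e2, m1, m2))
                ):
                    continue
                if e2 > e1:  # orient so expected ratio >= 1
                    e1, e2, m1, m2 = e2, e1, m2, m1
                e_ratio = e1 / e2
                score = m1 / m2
                if abs(e_ratio - 1.0) <= control_tolerance:
                    controls.append(score)
                else:
                    for roc in rocs.values():
                        lo, hi = roc.ratio_range
                        if lo <= e_ratio < hi:
                            roc.test_scores.append(score)
                            break
    for roc in rocs.values():
        roc.control_scores = list(controls)
        if roc.test_scores and controls:
            roc.auc = auc_rank(roc.test_scores, controls)
            roc.ci95 = auc_ci_hanley_mcneil(roc.auc, len(roc.test_scores), len(controls))
    return rocs


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------


class BlandAltman(NamedTuple):
    mean_difference: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltman:
    """Bland-Altman summary of paired log10 measurements (y - x)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 2:
        raise ValueError("Bland-Altman requires at least 2 finite pairs")
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean, mean - 1.96 * sd, mean + 1.96 * sd, len(d))


@dataclass
class BiasCorrection:
    corrected: dict[str, dict[str, float]]
    offsets: dict[str, float]
    uncorrected_genes: list[str]


def platform_bias_correction(
    ref_ab: Mapping[str, Mapping[str, float]],
    other_ab: Mapping[str, Mapping[str, float]],
    other_cd: Mapping[str, Mapping[str, float]],
) -> BiasCorrection:
    """Remove per-gene systematic cross-platform offsets.

    All inputs map sample -> gene -> log10 value.  For each gene, the
    offset is the mean over the reference samples (A and B) of
    (other - ref); it is subtracted from the other platform's C/D
    values.  Genes lacking an A or B value on either platform are
    returned uncorrected and flagged.
    """
    ref_samples = sorted(ref_ab)
    offsets: dict[str, float] = {}
    flagged: list[str] = []
    genes = {g for sample in other_cd.values() for g in sample}
    for gene in sorted(genes):
        diffs = []
        for s in ref_samples:
            ref_v = ref_ab.get(s, {}).get(gene)
            other_v = other_ab.get(s, {}).get(gene)
            if ref_v is None or other_v is None:
                diffs = None
                break
            diffs.append(other_v - ref_v)
        if diffs:
            offsets[gene] = float(np.mean(diffs))
        else:
            flagged.append(gene)
    corrected = {
        sample: {
            gene: (value - offsets[gene]) if gene in offsets else value
            for gene, value in genes_map.items()
        }
        for sample, genes_map in other_cd.items()
    }
    return BiasCorrection(corrected=corrected, offsets=offsets, uncorrected_genes=flagged)


# ---------------------------------------------------------------------------
# Read budget
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadBudget:
    """Total reads so every target is observed >= min_reads times."""

    traditional_reads: int
    competitive_reads: int
    fold_reduction: float
    min_reads_per_target: int


def read_budget(
    copies: Sequence[float],
    min_reads: int = 15,
    competitive_fractions: Sequence[float] | None = None,
) -> ReadBudget:
    """Compare traditional and competitive sequencing read budgets.

    Traditional library preparation preserves the input proportions, so
    the budget is ``ceil(min_reads * sum(copies) / min(copies))`` — the
    least abundant target dictates total depth.  Competitive plateau
    normalisation compresses the per-target read share; given the
    observed post-normalisation read fractions, the budget is
    ``ceil(min_reads / min(fraction))``.  When no fractions are given,
    perfect normalisation (equal shares) is assumed.
    """
    copies = list(copies)
    if not copies:
        raise ValueError("empty copies list")
    if any(c <= 0 for c in copies):
        raise ValueError("all copies must be positive")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    traditional = math.ceil(min_reads * sum(copies) / min(copies))
    if competitive_fractions is None:
        competitive_fractions = [1.0 / len(copies)] * len(copies)
    fractions = list(competitive_fractions)
    if any(f <= 0 for f in fractions) or sum(fractions) > 1 + 1e-9:
        raise ValueError("fractions must be positive and sum to at most 1")
    competitive = math.ceil(min_reads / min(fractions))
    return ReadBudget(
        traditional_reads=traditional,
        competitive_reads=competitive,
        fold_reduction=traditional / competitive,
        min_reads_per_target=min_reads,
    )


# ---------------------------------------------------------------------------
# Detection power at a given read depth
# ---------------------------------------------------------------------------


class PowerResult(NamedTuple):
    type1: float
    type2: float
    reject_below: int  # reject when X <= reject_below (-1: no lower tail)
    reject_above: int  # reject when X >= reject_above


def detection_power(null_mean_reads: float, fold: float, alpha: float = 0.05) -> PowerResult:
    """Exact one-sample Poisson test errors at a given expected depth.

    The null is X ~ Poisson(null_mean_reads) — the IS-anchored expected
    read count for an unchanged target.  The two-sided rejection region
    allots alpha/2 to each exact tail: reject when X <= c_lo or
    X >= c_hi with the largest/smallest cutoffs whose exact tail
    probabilities do not exceed alpha/2.  Type I error is the exact null
    mass of the region (conservative, <= alpha); type II error is the
    non-rejection mass under Poisson(fold * null_mean_reads).  All
    probabilities are exact tail sums; nothing is simulated.
    """
    if null_mean_reads < 1:
        raise ValueError("null_mean_reads must be >= 1")
    if fold <= 0:
        raise ValueError("fold must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lam0 = float(null_mean_reads)
    half = alpha / 2

    c_lo = -1
    while stats.poisson.cdf(c_lo + 1, lam0) <= half:
        c_lo += 1
    c_hi = int(stats.poisson.ppf(1 - half, lam0))
    while stats.poisson.sf(c_hi - 1, lam0) > half:
        c_hi += 1

    type1 = float(stats.poisson.cdf(c_lo, lam0) + stats.poisson.sf(c_hi - 1, lam0))
    lam1 = fold * lam0
    power = float(stats.poisson.cdf(c_lo, lam1) + stats.poisson.sf(c_hi - 1, lam1))
    return PowerResult(type1=type1, type2=1.0 - power, reject_below=c_lo, reject_above=c_hi)
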