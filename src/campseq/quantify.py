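"""Absolute copy-number estimation from binned NT/IS counts.

For each library (sample x IS-dilution replicate *i*) and gene, the
native concentration is estimated from the read ratio and the known IS
input:

    NC_i = (NT_i / IS_i) * SC_i        [copies per library preparation]

Replicates are then corrected for pipetting offsets (a systematic
log-scale shift of a whole dilution replicate relative to the gene-wise
cross-replicate medians), QC-filtered (minimum counts on both NT and
IS, maximum dispersion of log10 NC across replicates), and summarised
per gene — by default the median of surviving replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from campseq.panel import CountTable, InternalStandardMix

LN10_SQ = math.log(10) ** 2

SUMMARIZERS = ("average", "median", "least_squares", "weighted_least_squares")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """One NC_i estimate with its validity flag.

    ``flag`` is ``ok``, ``undefined`` (IS count zero — the ratio does
    not exist), or ``below_detection`` (NT count zero — the target is
    below the detection bound of one NT read, ``sc / is_count``).
    """

    value: float
    flag: str
    detection_bound: float = math.nan


def estimate_concentration(nt_count: int, is_count: int, sc: float) -> ConcentrationEstimate:
    """NC_i = (NT_i / IS_i) * SC_i, with zero-count flags."""
    if sc <= 0:
        raise ValueError(f"SC must be positive, got {sc}")
    if nt_count < 0 or is_count < 0:
        raise ValueError("counts must be non-negative")
    if is_count == 0:
        return ConcentrationEstimate(math.nan, "undefined")
    if nt_count == 0:
        return ConcentrationEstimate(math.nan, "below_detection", detection_bound=sc / is_count)
    return ConcentrationEstimate(nt_count / is_count * sc, "ok")


@dataclass
class ReplicateEstimate:
    sample_id: str
    gene_id: str
    dilution_index: int
    nt_count: int
    is_count: int
    sc: float
    nc_raw: float = math.nan
    nc_corrected: float = math.nan
    flag: str = "ok"


@dataclass(frozen=True)
class GeneSummary:
    sample_id: str
    gene_id: str
    nc_median: float
    n_valid: int
    cv_log10: float
    reason: str = "ok"  # ok | high_cv | no_valid_replicates

    @property
    def valid(self) -> bool:
        return self.reason == "ok"


@dataclass(frozen=True)
class QCParams:
    """QC filter and summarisation settings.

    ``min_counts`` is required of both NT_i and IS_i; ``max_cv_log10``
    bounds the dispersion of log10(NC_i) across surviving replicates;
    ``summarizer`` picks the cross-replicate estimator.
    """

    min_counts: int = 15
    max_cv_log10: float = 1.00
    summarizer: str = "median"

    def __post_init__(self) -> None:
        if self.min_counts < 1:
            raise ValueError("min_counts must be >= 1")
        if not self.max_cv_log10 > 0:
            raise ValueError("max_cv_log10 must be positive")
        if self.summarizer not in SUMMARIZERS:
            raise ValueError(f"summarizer must be one of {SUMMARIZERS}")


def log_dispersion(values: Sequence[float], kind: str = "sd") -> float:
    """Dispersion of log10 values across replicates.

    ``kind='sd'`` (default) is the sample standard deviation of
    log10(values); ``kind='cv'`` is |SD/mean| of the logs, which is
    ill-behaved when the mean log is near zero and provided only for
    comparison.
    """
    logs = np.log10(np.asarray(values, dtype=float))
    if len(logs) < 2:
        return 0.0
    sd = float(np.std(logs, ddof=1))
    if kind == "sd":
        return sd
    if kind == "cv":
        mean = float(np.mean(logs))
        return math.inf if mean == 0 else abs(sd / mean)
    raise ValueError(f"unknown dispersion kind {kind!r}")


def replicate_estimates(
    counts: CountTable, mix: InternalStandardMix
) -> list[ReplicateEstimate]:
    """Raw NC_i for every (sample, dilution, gene) row of a count table."""
    out: list[ReplicateEstimate] = []
    for row in counts.df.itertuples():
        sc = mix.copies(row.gene, int(row.dilution_index))
        est = estimate_concentration(int(row.nt_count), int(row.is_count), sc)
        out.append(
            ReplicateEstimate(
                sample_id=row.sample,
                gene_id=row.gene,
                dilution_index=int(row.dilution_index),
                nt_count=int(row.nt_count),
                is_count=int(row.is_count),
                sc=sc,
                nc_raw=est.value,
                nc_corrected=est.value,
                flag=est.flag,
            )
        )
    return out


def correct_pipetting(
    estimates: Sequence[ReplicateEstimate], min_replicates: int = 3
) -> tuple[list[ReplicateEstimate], dict[int, float]]:
    """Remove per-dilution-replicate systematic offsets for one sample.

    For every gene with valid estimates in at least ``min_replicates``
    dilution replicates, the gene's cross-replicate median log10 NC is
    the expected level; the offset of replicate *i* is the median over
    such genes of (log10 NC_i - expected), and is subtracted on the log
    scale.  Returns the corrected estimates and the offsets applied.
    """
    samples = {e.sample_id for e in estimates}
    if len(samples) > 1:
        raise ValueError("correct_pipetting operates on one sample at a time")
    dilutions = sorted({e.dilution_index for e in estimates})
    if len(dilutions) < 2:
        warnings.warn("fewer than 2 dilution replicates; pipetting correction skipped")
        return list(estimates), {i: 0.0 for i in dilutions}

    by_gene: dict[str, list[ReplicateEstimate]] = {}
    for e in estimates:
        if e.flag == "ok" and e.nc_raw > 0:
            by_gene.setdefault(e.gene_id, []).append(e)
    anchors = {
        gene: float(np.median(np.log10([e.nc_raw for e in reps])))
        for gene, reps in by_gene.items()
        if len(reps) >= min_replicates
    }
    if not anchors:
        warnings.warn("no gene has enough replicates; pipetting correction skipped")
        return list(estimates), {i: 0.0 for i in dilutions}

    offsets: dict[int, float] = {}
    for i in dilutions:
        residuals = [
            math.log10(e.nc_raw) - anchors[e.gene_id]
            for gene, reps in by_gene.items()
            if gene in anchors
            for e in reps
            if e.dilution_index == i
        ]
        offsets[i] = float(np.median(residuals)) if residuals else 0.0

    corrected = [
        replace(
            e,
            nc_corrected=(
                10 ** (math.log10(e.nc_raw) - offsets.get(e.dilution_index, 0.0))
                if e.flag == "ok" and e.nc_raw > 0
                else e.nc_raw
            ),
        )
        for e in estimates
    ]
    return corrected, offsets


def _summarize_values(reps: Sequence[ReplicateEstimate], summarizer: str) -> float:
    values = np.array([e.nc_corrected for e in reps])
    if summarizer == "median":
        return float(np.median(values))
    if summarizer == "average":
        return float(np.mean(values))
    logs = np.log10(values)
    if summarizer == "least_squares":
        # log-linear titration fit with slope fixed to -1: the
        # intercept-implied NC is the plain mean of log10 NC_i.
        return float(10 ** np.mean(logs))
    # weighted by inverse Poisson-propagated variance of log10(NT/IS)
    var = np.array([(1.0 / e.nt_count + 1.0 / e.is_count) / LN10_SQ for e in reps])
    w = 1.0 / var
    return float(10 ** (np.sum(w * logs) / np.sum(w)))


def summarize_gene(
    estimates: Sequence[ReplicateEstimate], qc: QCParams = QCParams()
) -> GeneSummary:
    """QC-filter and summarise one (sample, gene)'s replicates."""
    keys = {(e.sample_id, e.gene_id) for e in estimates}
    if len(keys) != 1:
        raise ValueError("summarize_gene expects replicates of a single (sample, gene)")
    sample_id, gene_id = next(iter(keys))
    survivors = [
        e
        for e in estimates
        if e.flag == "ok"
        and e.nt_count >= qc.min_counts
        and e.is_count >= qc.min_counts
        and np.isfinite(e.nc_corrected)
        and e.nc_corrected > 0
    ]
    if not survivors:
        return GeneSummary(sample_id, gene_id, math.nan, 0, math.nan, "no_valid_replicates")
    cv = log_dispersion([e.nc_corrected for e in survivors])
    if cv >= qc.max_cv_log10:
        return GeneSummary(sample_id, gene_id, math.nan, len(survivors), cv, "high_cv")
    return GeneSummary(
        sample_id, gene_id, _summarize_values(survivors, qc.summarizer), len(survivors), cv
    )


def quantify(
    counts: CountTable,
    mix: InternalStandardMix,
    qc: QCParams = QCParams(),
    pipetting_correction: bool = True,
) -> tuple[list[ReplicateEstimate], list[GeneSummary]]:
    """Full count-table -> per-gene summary pipeline."""
    estimates = replicate_estimates(counts, mix)
    by_sample: dict[str, list[ReplicateEstimate]] = {}
    for e in estimates:
        by_sample.setdefault(e.sample_id, []).append(e)
    corrected: list[ReplicateEstimate] = []
    for sample_ests in by_sample.values():
        if pipetting_correction:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sample_ests, _ = correct_pipetting(sample_ests)
        corrected.extend(sample_ests)
    by_key: dict[tuple[str, str], list[ReplicateEstimate]] = {}
    for e in corrected:
        by_key.setdefault((e.sample_id, e.gene_id), []).append(e)
    summaries = [summarize_gene(reps, qc) for reps in by_key.values()]
    return corrected, summaries


def summaries_frame(summaries: Iterable[GeneSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": s.sample_id,
                "gene": s.gene_id,
                "nc_median": s.nc_median,
                "n_valid": s.n_valid,
                "cv_log10": s.cv_log10,
                "reason": s.reason,
            }
            for s in summaries
        ]
    )


def estimates_frame(estimates: Iterable[ReplicateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": e.sample_id,
                "gene": e.gene_id,
                "dilution_index": e.dilution_index,
                "nt_count": e.nt_count,
                "is_count": e.is_count,
                "sc": e.sc,
                "nc_raw": e.nc_raw,
                "nc_corrected": e.nc_corrected,
                "flag": e.flag,
            }
            for e in estimates
        ]
    )


@dataclass
class GridResult:
    best: QCParams
    table: pd.DataFrame = field(repr=False)


def optimize_summarization(
    counts: CountTable,
    mix: InternalStandardMix,
    expected: Mapping[tuple[str, str], float],
    summarizers: Sequence[str] = ("average", "median"),
    min_counts_grid: Sequence[int] = (5, 15),
    max_cv_grid: Sequence[float] = (0.5, 1.0),
    min_retained: int | None = None,
) -> GridResult:
    """Exhaustive grid search over summarisation method and QC filters.

    For each combination, genes surviving QC are compared with their
    expected copies; the objective is the squared Pearson correlation of
    log10(measured) vs log10(expected), reported jointly with the
    number of genes retained (a Pareto table — the trade-off between
    accuracy and census is not scalarised).  The returned ``best`` is
    the combination maximising R^2 subject to retaining at least
    ``min_retained`` gene-sample cells (default: half the maximum
    retention achieved anywhere on the grid).
    """
    combos = list(product(summarizers, min_counts_grid, max_cv_grid))
    if not combos:
        raise ValueError("empty grid")
    rows = []
    for summarizer, min_counts, max_cv in combos:
        qc = QCParams(min_counts=min_counts, max_cv_log10=max_cv, summarizer=summarizer)
        _, summaries = quantify(counts, mix, qc)
        pairs = [
            (math.log10(s.nc_median), math.log10(expected[(s.sample_id, s.gene_id)]))
            for s in summaries
            if s.valid and expected.get((s.sample_id, s.gene_id), 0) > 0
        ]
        n_retained = len(pairs)
        if n_retained >= 3:
            x, y = np.array(pairs).T
            r2 = float(np.corrcoef(x, y)[0, 1] ** 2) if np.std(x) > 0 and np.std(y) > 0 else 1.0
        else:
            r2 = math.nan
        rows.append(
            {
                "summarizer": summarizer,
                "min_counts": min_counts,
                "max_cv_log10": max_cv,
                "r2": r2,
                "n_retained": n_retained,
            }
        )
    table = pd.DataFrame(rows)
    floor = (
        min_retained
        if min_retained is not None
        else int(table["n_retained"].max()) // 2
    )
    eligible = table[(table["n_retained"] >= floor) & table["r2"].notna()]
    if eligible.empty:
        eligible = table[table["r2"].notna()]
    if eligible.empty:
        best_row = table.loc[table["n_retained"].idxmax()]
    else:
        # ties in R^2 (to 1e-9) break toward the larger census
        ranked = eligible.assign(_r2=eligible["r2"].round(9)).sort_values(
            ["_r2", "n_retained"]
        )
        best_row = ranked.iloc[-1]
    best = QCParams(
        min_counts=int(best_row["min_counts"]),
        max_cv_log10=float(best_row["max_cv_log10"]),
        summarizer=str(best_row["summarizer"]),
    )
    return GridResult(best=best, table=table)
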