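# Methods

## Measurement model

Each assay is a 101-nt amplicon amplified from two templates: the
native target (NT) present at unknown copy number, and a synthetic
competitive internal standard (IS) spiked at known copies `SC_i` for
dilution replicate *i*.  NT and IS share both priming sites and differ
at exactly six positions inside the central 60-nt window, so they
compete for one limiting primer pair and amplify with equal
efficiency.  The model's single load-bearing assumption is that the
NT:IS molar ratio is invariant through amplification and sequencing;
the estimator is then

    NC_i = (NT_i / IS_i) · SC_i   [copies per library preparation],

independent of amplification depth, plateau level, and sequencing
depth.  Multiplying `SC` by *k* scales every estimate by *k* (scale
equivariance); multiplying both read counts by any factor leaves the
estimate unchanged (read-depth invariance).  Both are enforced as
property tests.

Competitive multiplex PCR is deliberately driven to plateau with
limiting primers so each gene's amplicon pool converges to a common
endpoint (~10⁹ molecules).  This compresses the per-target read-count
range (a 10⁶-fold template range becomes ~10³-fold in reads) without
touching any within-gene ratio, which is what cuts the read budget.

## Read processing and binning

Reads longer than 150 nt are split into the first/last 14 nt (barcode
tags) and the interior.  The length rule is strict (`>150`).  Base
qualities are carried but unused: classification is purely by
alignment-free sequence comparison, which is justified because the
amplicons are fixed-length and indel-free by construction.  Gapped or
heuristic alignment of 60-nt windows against a few hundred references
adds no information at this scale, so the classifier is:

1. **Demultiplexing** — the forward 4-nt index (tag positions 10–14)
   and reverse index (positions 0–4 of the terminal tag) are each
   matched *exactly*; a read counts only when both map to the same
   (sample, dilution) library.  Reasons `fwd_unknown`, `rev_unknown`
   and `conflict` are tallied, never fractionally assigned.  Exact
   matching of 4-nt indices is a policy choice: with single-base
   tolerance, dual 4-mers would lose most of their false-indexing
   protection.
2. **Gene assignment** — minimal Hamming distance of the read's 60-nt
   window over all NT and IS reference windows; reads beyond
   `max_mismatch` (default 5) are `no_gene`.  Simulated panels enforce
   pairwise inter-gene window distances ≥15 > 2·max_mismatch, so gene
   assignment cannot flip between genes within the mismatch budget.
3. **Allele call** — decided at the six diagnostic positions only: a
   read must match ≥4 of one allele's diagnostic bases and strictly
   more than the other allele's to be called; everything else is
   `ambiguous` and excluded.  Exhaustive enumeration over all reads
   within Hamming distance 2 of either allele's window shows zero
   NT↔IS swaps under this rule (the boundary needs ≥3 diagnostic
   errors before a call can even become ambiguous).

An exact-match dictionary covers error-free reads; the vectorised
Hamming path handles the remainder in batches.

## Quantification pipeline

**Pipetting correction.**  A whole dilution replicate can be shifted by
a pipetting error of the sample or IS mix.  For each gene with valid
estimates in ≥3 replicates, its cross-replicate median log10 NC is the
expected level; the replicate's offset is the median over such genes
of (log10 NC_i − expected) and is subtracted on the log scale.  The
cross-replicate median (rather than neighbour interpolation along the
ladder) is order-free and robust with as few as three replicates.
With fewer than two replicates, or no multi-replicate gene, the
correction is skipped with a warning.

**QC filters and summarisation** (defaults): a replicate is valid when
both NT_i and IS_i have ≥15 reads (`min_counts`); a gene is reported
when the dispersion of log10 NC_i across surviving replicates is
<1.00 (`max_cv_log10`) — i.e. replicates must agree within about
10-fold; the summary is the median of surviving corrected NC_i.
"Dispersion on the base-10 logarithm scale" is implemented as the
sample SD of log10 NC_i: a mean-normalised CV of logs is ill-defined
when the mean log crosses zero, so the SD form is the default and the
CV-of-logs form is exposed as an alternative (`log_dispersion(...,
kind="cv")`).  Four summarisers are available: average, median, and
log-linear titration fits with slope fixed to −1 (unweighted, which
reduces to the geometric mean, and weighted by the inverse
Poisson-propagated variance (1/NT + 1/IS)/ln²10).  The grid search
over summariser × min-counts × CV threshold reports R² against
expected values jointly with the retained census as a Pareto table;
ties in R² (to 1e-9) break toward the larger census.  The trade-off is
deliberately not scalarised.

Zero counts are flags, not exceptions: IS = 0 leaves the ratio
undefined; NT = 0 is below-detection with bound `SC/IS` (the copy
level at which one NT read would have been expected), never reported
as zero.

## Evaluation layer

- **Titration linearity** — OLS of log10(NT:IS) on log10(SC); the
  competitive model predicts slope −1 exactly, and noise-free data
  recover it to machine precision.  Fits require ≥3 usable points;
  95% prediction intervals use the textbook single-regression
  formula, pooled across points.
- **Poisson law** — expected CV of a count with mean *n* is 1/√n; at
  the 15-read QC floor this is ≈0.258.
- **Fold-change ROC** — every unordered sample pair and shared gene
  yields a comparison oriented so the expected ratio is ≥1; its score
  is the measured ratio.  Expected-ratio-1 comparisons are controls,
  shared across bins; tests fall into the half-open bins
  [1.05–1.175), [1.175–1.375), [1.375–1.75), [1.75–2.5), [2.5–10.0].
  AUC is the Mann–Whitney rank statistic (cross-checked against
  scikit-learn in tests); the 95% CI uses the Hanley–McNeil normal
  approximation.
- **Cross-platform bias correction** — per-gene offset = mean over
  reference samples A and B of (other platform − reference) on the
  log10 scale, subtracted from the other platform's C/D values.
  Genes with sample-specific (A≠B) bias — e.g. platforms reading
  different transcript isoforms — retain a residual by construction;
  genes missing an A or B value are flagged, not corrected.
- **Read budget** — traditional: `ceil(min_reads · Σcopies /
  min(copies))`; competitive: `ceil(min_reads / min(read fraction))`
  from observed post-normalisation fractions (equal shares when none
  are supplied).
- **Detection power** — the 15-read benchmark is interpreted as a
  one-sample exact Poisson test of an observed count against the
  IS-anchored expected level: two-sided rejection region with α/2
  exact mass per tail, all error rates by exact tail summation.  At a
  null mean of 15 and α = 0.05 the region is X ≤ 7 or X ≥ 24, giving
  type I error 0.0375 and type II error 0.1146 for a 2-fold change.
  A one-sample construction is the only standard one under which 15
  reads achieves both stated error bounds for a 2-fold change;
  two-sample constructions at this depth have power near 0.6.

## Synthetic data generator

The generator emulates the evaluated study designs end to end:

- **Panels** — random 101-nt NT amplicons with pairwise central-window
  Hamming distance ≥15; IS differs at six random central positions;
  distinct forward/reverse 4-nt indices per library.
- **Sample designs** — sample A log-uniform over the configured
  abundance range; B = A × per-gene subgroup ratio (0.5/0.67/1.0/4.0,
  assigned round-robin) for the spike-in design, or a log-normal
  per-gene fold (σ = 1 log10) for the endogenous design;
  C = 0.75A + 0.25B and D = 0.25A + 0.75B.  Presets encode the three
  designs: spike-in (26 targets, 5-point IS ladder 10⁶…300),
  endogenous (100 targets over ~10⁷-fold, 12-point 3-fold ladder
  6×10⁷…3.4×10²), and genomic-DNA calibration (150 loci all at 10⁵
  copies, 10-point 3-fold ladder 2×10⁷…10³, one sample).
- **Competitive PCR** — every gene's endpoint pool is
  `plateau_copies` (default 10⁹) with log-normal jitter σ = 0.1 log10
  modelling unequal primer efficiency; the NT fraction is exactly
  nt/(nt+sc).  Jitter acts on totals only — the NT:IS ratio of a
  healthy assay is never perturbed, encoding the core assumption
  explicitly.
- **Assay defects** — the gDNA preset marks 26 assays as
  low-efficiency (endpoint pool ×10⁻⁴, so they fall below the 15-read
  floor) and 1 assay with log-normal inter-replicate scatter on its
  NT:IS odds (σ = 1.5 log10, failing the CV filter): the failure
  census observed for that design.  Tests verify the QC filters
  recover exactly this failed set (123 of 150 valid).
- **Reads** — one multinomial draw per library over (gene, allele)
  cells (Poisson marginals for rare cells); reads are 151 nt
  (14-nt tag + 11-nt pad + 101-nt amplicon + 11-nt pad + 14-nt tag)
  with uniform substitution errors at the configured rate (default
  0.2%; indels are not modelled since classification is
  Hamming-based and the orientation is fixed by directional
  adapters).  A manifest records every read's true origin.

Reads per library default to 10⁵ — enough that a mid-ladder replicate
of a typical target clears the 15-read floor while the rarest targets
remain Poisson-limited, which is the regime the QC rules are designed
for; the total number of reads per library is not dictated by the
measurement model itself.

What the generator does *not* emulate: per-assay systematic biases
(reverse-transcription efficiency differences, IS concentration
calibration error), platform-specific base-calling artefacts
(homopolymer indels), chimeras/heterodimers, and cross-platform
isoform differences.  Passing tests therefore demonstrate correctness
of the estimator, QC logic and statistics under the method's own
model — Poisson sampling around plateau-normalised competitive
ratios — not robustness to every wet-lab failure mode.  Consistent
with this, simulated accuracy statistics (blend-prediction R²,
known-input R², fold-change AUC) sit at or above the levels
achievable with real libraries, and are asserted as lower bounds.

## Numerical choices and degenerate inputs

- Coordinates are 0-based, half-open; the 60-nt window is centred in
  the amplicon (offset 20) as a convention.
- Too-short read interiors map to an unclassifiable marker, never an
  exception; malformed FASTQ records are skipped and counted.
- The dispersion of a single replicate is 0 (no evidence of
  disagreement); sample SD (ddof = 1) is used for ≥2 replicates.
- The Poisson-propagated interval for NC_median uses the asymptotic
  normal-median variance: var ≈ (π/2) · Σ(1/NT_j + 1/IS_j) /
  (k² ln²10) for k surviving replicates — conservative for
  heterogeneous replicate depths, where the median effectively
  downweights the noisiest replicates.
- Allele-call and demultiplexing tie-breaks are never random; every
  discard is reason-coded and conserved in the binning report
  (assigned + unknown + conflict + no-gene + ambiguous = accepted).
- All randomness flows from a single seed via spawned generator
  streams (panel, design, PCR jitter, read sampling), so reruns are
  byte-identical.

## Known limitations

- The classifier assumes substitution-only errors; platforms with
  frequent indels would need realignment before windowing.
- Exact index matching discards any read with an index sequencing
  error (visible in the worked example's `fwd_unknown` tally); this
  is a deliberate precision-over-yield trade.
- The pipetting correction assumes most genes in a replicate share
  the offset; it cannot separate a true global abundance shift from a
  pipetting error within a single sample.
- Cross-platform correction removes only per-gene constant offsets;
  sample-dependent biases (isoform effects) are detectable but not
  correctable by design.
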