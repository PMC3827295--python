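# campseq

Absolute transcript quantification from **competitive internal-standard
amplicon sequencing** — targeted RNA-seq in which every native target
(NT) is co-amplified with a synthetic competitive internal standard
(IS) spiked in at a known copy number.

## The problem and the method

Targeted amplicon RNA-seq panels suffer from two linked problems: PCR
enrichment distorts between-target proportions (different targets
plateau at different cycles), and quantifying a panel whose members
span a million-fold abundance range forces massive over-sequencing of
the abundant targets just to see the rare ones.

The competitive design solves both at once.  Each assay's IS is
identical to its NT at the priming sites but carries six diagnostic
substitutions inside the central 60 nt of the 101-nt amplicon, so the
pair competes for the same primers and amplifies with the same
efficiency.  The NT:IS read ratio at PCR plateau therefore equals the
pre-PCR copy ratio, and the absolute native copy number per library
preparation is

```
NC_i = (NT_i / IS_i) · SC_i
```

where `NT_i`, `IS_i` are binned read counts at IS dilution *i* and
`SC_i` the known IS copies loaded.  Driving every reaction to a common
plateau (~10⁹ amplicons per gene) *normalises* read counts across
targets — a 10⁶-fold template range collapses to ~10³-fold in reads —
without distorting any within-gene NT:IS ratio.  Fifteen reads per
target suffice to detect a 2-fold change (exact Poisson test: type I
error 0.037 < 0.05, type II error 0.115 < 0.20), so the read budget
drops by orders of magnitude relative to proportional sequencing.

`campseq` implements the full desk side of this method:

- **panel** — assay/panel/IS-mix domain types, validation (six central
  diagnostic substitutions, dual 4-nt barcode table), panel and count
  table CSV formats, reference FASTA export;
- **reads** — FASTQ parsing; reads >150 nt are split into 14-nt
  terminal barcode tags and the interior containing the 60-nt window;
- **binning** — dual-index demultiplexing (discordant pairs are
  discarded) and minimal-Hamming NT/IS allele calling on the
  diagnostic positions;
- **quantify** — NC_i estimation, pipetting-offset correction, QC
  filtering (≥15 reads on both alleles, log10 CV < 1.00), per-gene
  summarisation (median by default) and the summariser/QC grid search;
- **evaluate** — titration linearity fits, Poisson CV law, mixture
  expectations, fold-change ROC with the printed ratio bins,
  Bland–Altman agreement, cross-platform bias correction, read-budget
  arithmetic, exact Poisson detection power;
- **simulate** — a synthetic study generator (panels, ERCC-style
  subgroup designs, A–D sample blends, plateau-normalised competitive
  PCR, multinomial read sampling, FASTQ + ground-truth manifests) so
  the whole pipeline is testable without any external data.

## Worked example

Simulate a 5-target spike-in style study, emit reads, bin, and
quantify — all through the CLI:

```sh
campseq pipeline --seed 3 --n-genes 5 --reads-per-library 2000 --out-dir demo/
# pipeline complete: 39383 reads binned, 19 valid gene-sample cells
```

`demo/binning_report.json` accounts for every read (40,000 records: 39,383
assigned, 548 with an unrecognised index — the default 0.2% per-base
error rate corrupts some 4-nt indices — and 69 dual-index conflicts
discarded).  `demo/summaries.csv` holds the absolute estimates:

```
sample   gene    nc_median  n_valid  cv_log10 reason
     A ERCC-1 1.659278e+02        2  0.119498     ok
     A ERCC-2 2.200000e+05        3  0.011808     ok
     A ERCC-3 4.828571e+04        3  0.002130     ok
     A ERCC-4 1.007978e+07        1  0.000000     ok
```

`nc_median` is in copies per library preparation; `n_valid` is how many
IS dilution replicates survived the count filter; `cv_log10` is the
replicate dispersion on the log10 scale.  The exact-power benchmark is
one call:

```sh
campseq evaluate power --null-mean 15 --fold 2
# {"type1": 0.0375, "type2": 0.1146, "reject_below": 7, "reject_above": 24}
```

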