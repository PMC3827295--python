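"""Synthetic competitive amplicon library generator.

Emulates the full measurement chain: a panel of NT/IS amplicon pairs,
reference-sample designs (sample A with log-uniform abundances, sample
B related to A by ERCC-style subgroup ratios or by gene-specific fold
changes, and C/D as 3:1 and 1:3 blends of A and B), competitive
multiplex PCR driven to a common plateau (~1e9 amplicons per gene, so
the read-count dynamic range collapses while every NT:IS ratio is
preserved exactly — the core modelling assumption, applied here by
construction), multinomial read sampling (Poisson marginals for rare
cells), and FASTQ emission with a ground-truth manifest.

Deliberate assay-defect knobs (``low_efficiency_genes``,
``noisy_ratio_genes``) emulate failed assays: targets whose primers
amplify poorly yield too few reads, and a defective assay can show
inter-replicate NT:IS scatter.  These act on per-gene totals or as
assay-specific artifacts — never on the NT:IS ratio of a healthy assay.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from campseq.binning import PAD_LEN
from campseq.panel import (
    AMPLICON_LEN,
    AssayDefinition,
    AssayPanel,
    CountTable,
    DEFAULT_CENTRAL_OFFSET,
    InternalStandardMix,
    N_DIAGNOSTIC,
    WINDOW_LEN,
)

_BASES = np.array(list("ACGT"))

#: Fixed interior pads standing in for the universal primer tails,
#: sized to make every emitted read exactly 151 nt:
#: 14 + 11 + 101 + 11 + 14.
PAD_FWD = "ACGGTCATCGA"
PAD_REV = "TCAGGACGTTA"
assert len(PAD_FWD) == len(PAD_REV) == PAD_LEN

READ_LEN = 2 * 14 + 2 * PAD_LEN + AMPLICON_LEN  # 151

#: ERCC-style subgroup fold differences between mixes 1 and 2 (B vs A).
SUBGROUP_RATIOS = (0.5, 0.67, 1.0, 4.0)

#: 5-point IS input ladder used for the ERCC targets (copies loaded).
ERCC_LADDER = (1e6, 1e5, 1e4, 1e3, 300.0)


def threefold_ladder(top: float, n_points: int) -> tuple[float, ...]:
    """A strictly decreasing 3-fold serial dilution series."""
    return tuple(top / 3**k for k in range(n_points))


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one simulated study.

    Defaults describe an ERCC-style design: 26 targets over a ~1e6-fold
    abundance range split evenly among the four subgroup ratios, four
    samples A-D with C/D as 3:1 / 1:3 blends, a 5-point IS ladder, PCR
    plateau at 1e9 amplicons per gene with 0.1 log10 inter-gene jitter
    (unequal primer efficiency), 1e5 reads per library, and a 0.2%
    per-base substitution error rate.
    """

    n_genes: int = 26
    samples: tuple[str, ...] = ("A", "B", "C", "D")
    abundance_min_log10: float = 1.0
    abundance_log10_range: float = 6.0
    subgroup_ratios: tuple[float, ...] | None = SUBGROUP_RATIOS
    b_fold_sigma_log10: float = 1.0  # used when subgroup_ratios is None
    uniform_copies: float | None = None  # overrides abundances (gDNA-style)
    is_copies_ladder: tuple[float, ...] = ERCC_LADDER
    plateau_copies: float = 1e9
    plateau_jitter_log10: float = 0.1
    reads_per_library: int = 100_000
    error_rate: float = 0.002
    seed: int = 0
    gene_prefix: str = "G"
    low_efficiency_genes: tuple[int, ...] = ()
    efficiency_factor: float = 1e-4
    noisy_ratio_genes: tuple[int, ...] = ()
    ratio_noise_sigma_log10: float = 1.5

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        ladder = self.is_copies_ladder
        if any(b >= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("IS ladder must be strictly decreasing")
        if any(c <= 0 for c in ladder):
            raise ValueError("IS copies must be positive")
        if self.plateau_copies <= 0 or self.reads_per_library < 0:
            raise ValueError("plateau_copies and reads_per_library must be positive")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"{self.gene_prefix}{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def dilution_indices(self) -> list[int]:
        return list(range(1, len(self.is_copies_ladder) + 1))

    @property
    def ladder_by_index(self) -> dict[int, float]:
        return dict(zip(self.dilution_indices, self.is_copies_ladder))


@dataclass
class GroundTruth:
    """Per-cell truth recorded alongside the simulated counts."""

    copies: dict[tuple[str, str], float]  # (sample, gene) -> NT copies
    sc: dict[tuple[str, int, str], float]
    nt_fraction: dict[tuple[str, int, str], float]  # post-PCR NT/(NT+IS)
    expected_reads: dict[tuple[str, int, str, str], float]  # ... allele ->


@dataclass
class StudyData:
    config: SimulationConfig
    panel: AssayPanel
    mix: InternalStandardMix
    subgroup: dict[str, float]  # gene -> B:A fold
    truth: GroundTruth
    counts: CountTable


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def build_panel(
    n_genes: int,
    libraries: Iterable[tuple[str, int]],
    seed: int | np.random.Generator = 0,
    gene_ids: list[str] | None = None,
    min_window_distance: int = 15,
) -> AssayPanel:
    """Random panel: NT amplicons with well-separated central windows,
    IS = NT with six substitutions at random central positions, and a
    distinct forward/reverse 4-nt index per library."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if gene_ids is None:
        width = len(str(n_genes))
        gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    windows: list[np.ndarray] = []
    assays: dict[str, AssayDefinition] = {}
    lo = DEFAULT_CENTRAL_OFFSET
    for gene in gene_ids:
        for _ in range(1000):
            nt = _random_seq(rng, AMPLICON_LEN)
            window = np.frombuffer(
                nt[lo : lo + WINDOW_LEN].encode(), dtype=np.uint8
            )
            if all((window != w).sum() >= min_window_distance for w in windows):
                break
        else:  # pragma: no cover - unreachable below ~1e4 genes
            raise RuntimeError("could not satisfy the inter-gene window distance")
        windows.append(window)
        positions = np.sort(rng.choice(WINDOW_LEN, size=N_DIAGNOSTIC, replace=False)) + lo
        is_seq = list(nt)
        for p in positions:
            is_seq[p] = rng.choice([b for b in "ACGT" if b != nt[p]])
        assays[gene] = AssayDefinition(gene_id=gene, nt_sequence=nt, is_sequence="".join(is_seq))

    libraries = list(libraries)
    all_indices = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
    if 2 * len(libraries) > len(all_indices):
        raise ValueError("too many libraries for 4-nt dual indexing")
    chosen = rng.choice(len(all_indices), size=2 * len(libraries), replace=False)
    barcode_table = {
        (all_indices[chosen[2 * k]], all_indices[chosen[2 * k + 1]]): lib
        for k, lib in enumerate(libraries)
    }
    return AssayPanel(assays=assays, barcode_table=barcode_table)


# ---------------------------------------------------------------------------
# Sample design and competitive PCR
# ---------------------------------------------------------------------------


def design_samples(
    config: SimulationConfig, seed: int | np.random.Generator | None = None
) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """True per-sample NT copies and the per-gene B:A fold assignment.

    Sample A abundances are log-uniform over the configured range (or
    all equal to ``uniform_copies``); B is A scaled per gene by its
    subgroup ratio (assigned round-robin) or, with no subgroups, by a
    log-normal fold; C = 0.75A + 0.25B and D = 0.25A + 0.75B.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    genes = config.gene_ids
    if config.uniform_copies is not None:
        a = np.full(len(genes), float(config.uniform_copies))
    else:
        a = 10 ** (
            config.abundance_min_log10
            + rng.uniform(0, config.abundance_log10_range, size=len(genes))
        )
    if config.subgroup_ratios is not None:
        ratios = np.array(
            [config.subgroup_ratios[i % len(config.subgroup_ratios)] for i in range(len(genes))]
        )
    else:
        ratios = 10 ** rng.normal(0.0, config.b_fold_sigma_log10, size=len(genes))
    b = a * ratios
    copies: dict[str, dict[str, float]] = {}
    per_sample = {
        "A": a,
        "B": b,
        "C": 0.75 * a + 0.25 * b,
        "D": 0.25 * a + 0.75 * b,
    }
    for sample in config.samples:
        values = per_sample.get(sample, a)
        copies[sample] = dict(zip(genes, values))
    return copies, dict(zip(genes, ratios))


def simulate_competitive_pcr(
    nt_copies: float,
    sc_copies: float,
    plateau_copies: float = 1e9,
    jitter_log10: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Plateau-normalised endpoint of one competitive reaction.

    Returns (total amplicons, NT fraction).  Every gene's amplicon pool
    converges to ``plateau_copies`` (optionally log-normally jittered,
    modelling unequal primer efficiency); the NT fraction is exactly
    ``nt / (nt + sc)`` — competition never distorts the ratio.
    """
    if nt_copies <= 0 or sc_copies <= 0:
        raise ValueError("copies must be positive")
    total = plateau_copies
    if jitter_log10 > 0:
        if rng is None:
            rng = np.random.default_rng()
        total = plateau_copies * 10 ** rng.normal(0.0, jitter_log10)
    return total, nt_copies / (nt_copies + sc_copies)


def sample_reads(
    weights: Mapping[tuple[str, str], float],
    reads_per_library: int,
    seed: int | np.random.Generator = 0,
) -> dict[tuple[str, str], int]:
    """Multinomial read draw over (gene, allele) cells.

    Cell probabilities are the normalised weights; marginal counts of
    rare cells are Poisson to good approximation.
    """
    if reads_per_library <= 0:
        raise ValueError("reads_per_library must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = list(weights)
    p = np.array([weights[c] for c in cells], dtype=float)
    p = p / p.sum()
    draws = rng.multinomial(reads_per_library, p)
    return dict(zip(cells, (int(d) for d in draws)))


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate panel, IS mix, ground truth, and binned count tables."""
    ss = np.random.SeedSequence(config.seed)
    rng_panel, rng_design, rng_pcr, rng_reads = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    genes = config.gene_ids
    libraries = [(s, i) for s in config.samples for i in config.dilution_indices]
    panel = build_panel(config.n_genes, libraries, seed=rng_panel, gene_ids=genes)
    mix = InternalStandardMix.uniform(genes, config.ladder_by_index)
    copies, subgroup = design_samples(config, seed=rng_design)

    low_eff = {genes[i] for i in config.low_efficiency_genes}
    noisy = {genes[i] for i in config.noisy_ratio_genes}

    truth = GroundTruth(
        copies={(s, g): copies[s][g] for s in config.samples for g in genes},
        sc={},
        nt_fraction={},
        expected_reads={},
    )
    rows = []
    for sample, dil in libraries:
        sc = config.ladder_by_index[dil]
        weights: dict[tuple[str, str], float] = {}
        for gene in genes:
            nt = copies[sample][gene]
            total, frac = simulate_competitive_pcr(
                nt, sc, config.plateau_copies, config.plateau_jitter_log10, rng_pcr
            )
            if gene in low_eff:
                total *= config.efficiency_factor
            if gene in noisy:
                # assay defect: inter-replicate scatter of the NT:IS odds
                odds = frac / (1 - frac) * 10 ** rng_pcr.normal(
                    0.0, config.ratio_noise_sigma_log10
                )
                frac = odds / (1 + odds)
            truth.sc[(sample, dil, gene)] = sc
            truth.nt_fraction[(sample, dil, gene)] = frac
            weights[(gene, "NT")] = total * frac
            weights[(gene, "IS")] = total * (1 - frac)
        total_weight = sum(weights.values())
        for (gene, allele), w in weights.items():
            truth.expected_reads[(sample, dil, gene, allele)] = (
                w / total_weight * config.reads_per_library
            )
        drawn = sample_reads(weights, config.reads_per_library, seed=rng_reads)
        for gene in genes:
            rows.append(
                {
                    "sample": sample,
                    "dilution_index": dil,
                    "gene": gene,
                    "nt_count": drawn[(gene, "NT")],
                    "is_count": drawn[(gene, "IS")],
                }
            )
    counts = CountTable(
        pd.DataFrame(rows),
        library_totals={lib: config.reads_per_library for lib in libraries},
    )
    return StudyData(
        config=config,
        panel=panel,
        mix=mix,
        subgroup=subgroup,
        truth=truth,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for p in hits:
        arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
    return "".join(arr)


def emit_fastq(
    study: StudyData,
    fastq_path: str | Path,
    manifest_path: str | Path | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write the simulated reads as FASTQ plus a ground-truth manifest.

    Each read is ``fwd_tag(14) + pad(11) + amplicon(101) + pad(11) +
    rev_tag(14)`` = 151 nt, with substitution errors injected at the
    configured per-base rate.  The manifest records every read's true
    (sample, dilution, gene, allele).
    """
    config = study.config
    rng = np.random.default_rng(config.seed + 7919 if seed is None else seed)
    manifest_rows = []
    with open(fastq_path, "w") as fh:
        n = 0
        for row in study.counts.df.itertuples():
            assay = study.panel.assays[row.gene]
            fwd_tag = study.panel.fwd_tag(row.sample, int(row.dilution_index))
            rev_tag = study.panel.rev_tag(row.sample, int(row.dilution_index))
            for allele, count in (("NT", row.nt_count), ("IS", row.is_count)):
                amplicon = assay.nt_sequence if allele == "NT" else assay.is_sequence
                template = fwd_tag + PAD_FWD + amplicon + PAD_REV + rev_tag
                for _ in range(count):
                    n += 1
                    read_id = f"sim_{n:08d}"
                    seq = _mutate(template, config.error_rate, rng)
                    fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
                    manifest_rows.append(
                        {
                            "read_id": read_id,
                            "sample": row.sample,
                            "dilution_index": int(row.dilution_index),
                            "gene": row.gene,
                            "allele": allele,
                        }
                    )
    manifest = pd.DataFrame(
        manifest_rows, columns=["read_id", "sample", "dilution_index", "gene", "allele"]
    )
    if manifest_path is not None:
        manifest.to_csv(manifest_path, index=False)
    return manifest


# ---------------------------------------------------------------------------
# Study-design presets (the conditions of the evaluated designs)
# ---------------------------------------------------------------------------


def ercc_config(seed: int = 0, reads_per_library: int = 100_000, **overrides) -> SimulationConfig:
    """26 synthetic spike-in targets, 4 subgroups (0.5/0.67/1.0/4.0x),
    samples A-D, 5-point IS ladder 1e6..300 copies."""
    base = SimulationConfig(
        n_genes=26,
        gene_prefix="ERCC-",
        abundance_min_log10=1.5,
        abundance_log10_range=6.0,
        is_copies_ladder=ERCC_LADDER,
        reads_per_library=reads_per_library,
        seed=seed,
    )
    return replace(base, **overrides)


def endogenous_config(
    seed: int = 0, reads_per_library: int = 100_000, n_genes: int = 100, **overrides
) -> SimulationConfig:
    """Endogenous cDNA design: log-uniform abundances over ~1e7-fold,
    gene-specific A-vs-B folds, 12-point 3-fold IS ladder 6e7..3.4e2."""
    base = SimulationConfig(
        n_genes=n_genes,
        abundance_min_log10=1.0,
        abundance_log10_range=7.0,
        subgroup_ratios=None,
        is_copies_ladder=threefold_ladder(6e7, 12),
        reads_per_library=reads_per_library,
        seed=seed,
    )
    return replace(base, **overrides)


def gdna_config(
    seed: int = 0,
    reads_per_library: int = 100_000,
    n_genes: int = 150,
    n_low_efficiency: int = 26,
    n_noisy: int = 1,
    **overrides,
) -> SimulationConfig:
    """Genomic-DNA calibration design: one sample, every locus at 1e5
    copies, 10-point 3-fold IS ladder 2e7..1e3; a subset of assays fail
    (low primer efficiency or excessive inter-replicate scatter)."""
    rng = np.random.default_rng(seed + 104729)
    failed = rng.choice(n_genes, size=n_low_efficiency + n_noisy, replace=False)
    base = SimulationConfig(
        n_genes=n_genes,
        samples=("gDNA",),
        uniform_copies=1e5,
        subgroup_ratios=None,
        is_copies_ladder=threefold_ladder(2e7, 10),
        reads_per_library=reads_per_library,
        seed=seed,
        low_efficiency_genes=tuple(int(i) for i in failed[:n_low_efficiency]),
        noisy_ratio_genes=tuple(int(i) for i in failed[n_low_efficiency:]),
    )
    return replace(base, **overrides)
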