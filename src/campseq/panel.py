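"""Panel domain model and file formats.

An assay pairs a 101-nt native-target (NT) amplicon with its competitive
internal standard (IS): identical at the priming sites, differing at
exactly six diagnostic positions inside the central 60-nt window.  A
panel bundles the assays with the dual-barcode table that maps 4-nt
forward/reverse indices to (sample, IS-dilution) libraries.

Coordinates are 0-based with half-open windows throughout.  Diagnostic
positions are stored in amplicon coordinates (0..100) and must fall
inside ``[central_offset, central_offset + 60)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMPLICON_LEN = 101
WINDOW_LEN = 60
#: 60-nt window centered in the 101-nt amplicon.
DEFAULT_CENTRAL_OFFSET = (AMPLICON_LEN - WINDOW_LEN) // 2
N_DIAGNOSTIC = 6
TAG_LEN = 14
INDEX_LEN = 4

# Fixed adapter context surrounding the 4-nt sample index inside each
# 14-nt terminal tag.  The forward index occupies tag[10:14]; the
# reverse index occupies tag[0:4] (the read ends with the reverse tag).
FWD_TAG_ADAPTER = "TCAGCGGAAC"
REV_TAG_ADAPTER = "GTTCCGCTGA"

_VALID_BASES = frozenset("ACGT")


class PanelError(ValueError):
    """Raised for invalid panel definitions or files."""


def diagnostic_positions_from_sequences(nt: str, is_: str) -> tuple[int, ...]:
    """Positions (amplicon coordinates) where NT and IS differ."""
    if len(nt) != len(is_):
        raise PanelError("NT and IS sequences differ in length")
    return tuple(i for i, (a, b) in enumerate(zip(nt, is_)) if a != b)


@dataclass(frozen=True)
class AssayDefinition:
    """One gene's NT/IS amplicon pair.

    Parameters
    ----------
    gene_id : str
        Unique target identifier.
    nt_sequence, is_sequence : str
        101-nt amplicon sequences in sequencing orientation.
    fwd_primer_len, rev_primer_len : int
        Lengths of the target-specific priming sites at either end.
    central_offset : int
        0-based start of the 60-nt variant window within the amplicon.
    diagnostic_positions : tuple of int
        The six positions (amplicon coordinates) at which NT and IS
        differ; derived from the sequences when omitted.
    """

    gene_id: str
    nt_sequence: str
    is_sequence: str
    fwd_primer_len: int = 20
    rev_primer_len: int = 20
    central_offset: int = DEFAULT_CENTRAL_OFFSET
    diagnostic_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        nt, is_ = self.nt_sequence.upper(), self.is_sequence.upper()
        object.__setattr__(self, "nt_sequence", nt)
        object.__setattr__(self, "is_sequence", is_)
        for name, seq in (("nt_sequence", nt), ("is_sequence", is_)):
            if len(seq) != AMPLICON_LEN:
                raise PanelError(
                    f"{self.gene_id}: {name} is {len(seq)} nt, expected {AMPLICON_LEN}"
                )
            bad = set(seq) - _VALID_BASES
            if bad:
                raise PanelError(f"{self.gene_id}: non-ACGT characters {sorted(bad)} in {name}")
        if not 0 <= self.central_offset <= AMPLICON_LEN - WINDOW_LEN:
            raise PanelError(f"{self.gene_id}: central window exceeds amplicon bounds")
        derived = diagnostic_positions_from_sequences(nt, is_)
        if not derived:
            raise PanelError(f"{self.gene_id}: zero diagnostic positions (NT == IS)")
        if len(derived) != N_DIAGNOSTIC:
            raise PanelError(
                f"{self.gene_id}: NT/IS Hamming distance {len(derived)}, expected {N_DIAGNOSTIC}"
            )
        lo, hi = self.central_offset, self.central_offset + WINDOW_LEN
        outside = [p for p in derived if not lo <= p < hi]
        if outside:
            raise PanelError(
                f"{self.gene_id}: diagnostic positions {outside} outside the central window"
            )
        if self.diagnostic_positions:
            if tuple(self.diagnostic_positions) != derived:
                raise PanelError(
                    f"{self.gene_id}: stored diagnostic positions disagree with sequences"
                )
        else:
            object.__setattr__(self, "diagnostic_positions", derived)

    @property
    def nt_window(self) -> str:
        """Central 60-nt window of the NT amplicon."""
        return self.nt_sequence[self.central_offset : self.central_offset + WINDOW_LEN]

    @property
    def is_window(self) -> str:
        """Central 60-nt window of the IS amplicon."""
        return self.is_sequence[self.central_offset : self.central_offset + WINDOW_LEN]

    @property
    def window_diagnostic_positions(self) -> tuple[int, ...]:
        """Diagnostic positions in window-relative coordinates."""
        return tuple(p - self.central_offset for p in self.diagnostic_positions)


@dataclass
class AssayPanel:
    """A collection of assays plus the dual-barcode library map.

    ``barcode_table`` maps ``(fwd_index, rev_index)`` 4-nt pairs to
    ``(sample_id, dilution_index)``; each library has exactly one pair,
    and each index is unique on its own side so that a single-end match
    identifies a library unambiguously.
    """

    assays: dict[str, AssayDefinition] = field(default_factory=dict)
    barcode_table: dict[tuple[str, str], tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        libraries = list(self.barcode_table.values())
        if len(set(libraries)) != len(libraries):
            raise PanelError("duplicate (sample, dilution) in barcode table")
        fwd = [f for f, _ in self.barcode_table]
        rev = [r for _, r in self.barcode_table]
        if len(set(fwd)) != len(fwd) or len(set(rev)) != len(rev):
            raise PanelError("barcode indices must be unique per side")
        for f, r in self.barcode_table:
            if len(f) != INDEX_LEN or len(r) != INDEX_LEN:
                raise PanelError("barcode indices must be 4 nt")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.assays)

    @property
    def libraries(self) -> list[tuple[str, int]]:
        """All (sample_id, dilution_index) pairs, in table order."""
        return list(self.barcode_table.values())

    def fwd_index_map(self) -> dict[str, tuple[str, int]]:
        return {f: lib for (f, _), lib in self.barcode_table.items()}

    def rev_index_map(self) -> dict[str, tuple[str, int]]:
        return {r: lib for (_, r), lib in self.barcode_table.items()}

    def barcode_for(self, sample_id: str, dilution_index: int) -> tuple[str, str]:
        for pair, lib in self.barcode_table.items():
            if lib == (sample_id, dilution_index):
                return pair
        raise KeyError((sample_id, dilution_index))

    def fwd_tag(self, sample_id: str, dilution_index: int) -> str:
        f, _ = self.barcode_for(sample_id, dilution_index)
        return FWD_TAG_ADAPTER + f

    def rev_tag(self, sample_id: str, dilution_index: int) -> str:
        _, r = self.barcode_for(sample_id, dilution_index)
        return r + REV_TAG_ADAPTER


@dataclass
class InternalStandardMix:
    """Known IS copies per library preparation: (gene, dilution) -> SC_i."""

    sc: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.sc.items():
            if not value > 0:
                raise PanelError(f"SC must be positive, got {value} for {key}")

    def copies(self, gene_id: str, dilution_index: int) -> float:
        return self.sc[(gene_id, dilution_index)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "dilution_index": i, "sc_copies": v}
            for (g, i), v in sorted(self.sc.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "dilution_index", "sc_copies"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InternalStandardMix":
        return cls({(r.gene, int(r.dilution_index)): float(r.sc_copies) for r in df.itertuples()})

    @classmethod
    def uniform(
        cls, gene_ids: Iterable[str], ladder: Mapping[int, float]
    ) -> "InternalStandardMix":
        """Equimolar mix: every gene at the same SC within a dilution."""
        return cls({(g, i): float(c) for g in gene_ids for i, c in ladder.items()})


COUNT_COLUMNS = ["sample", "dilution_index", "gene", "nt_count", "is_count"]


@dataclass
class CountTable:
    """Binned NT/IS read counts per (sample, dilution replicate, gene).

    ``df`` has columns ``sample, dilution_index, gene, nt_count,
    is_count`` with one row per key; ``library_totals`` carries the
    unbinned per-library read tallies when known.
    """

    df: pd.DataFrame
    library_totals: dict[tuple[str, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise PanelError(f"count table missing columns {missing}")
        df = df[COUNT_COLUMNS].copy()
        for col in ("nt_count", "is_count"):
            values = df[col]
            if not (values == values.astype(int)).all():
                raise PanelError(f"{col} contains non-integer values")
            if (values < 0).any():
                raise PanelError(f"{col} contains negative values")
            df[col] = values.astype(int)
        df["dilution_index"] = df["dilution_index"].astype(int)
        keys = df[["sample", "dilution_index", "gene"]]
        if keys.duplicated().any():
            raise PanelError("duplicate (sample, dilution_index, gene) keys")
        self.df = df.reset_index(drop=True)

    def unknown_genes(self, panel: AssayPanel) -> list[str]:
        """Genes present in the table but absent from the panel."""
        return sorted(set(self.df["gene"]) - set(panel.assays))

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_ASSAY_COLUMNS = [
    "gene_id",
    "nt_sequence",
    "is_sequence",
    "fwd_primer_len",
    "rev_primer_len",
    "central_offset",
]
_BARCODE_COLUMNS = ["sample_id", "dilution_index", "fwd_index", "rev_index"]


def write_panel(panel: AssayPanel, path: str | Path) -> None:
    """Write a panel as a sectioned comma-delimited table.

    The file has an ``[assays]`` section followed by a ``[barcodes]``
    section, each a plain CSV with a header row.  Diagnostic positions
    are not stored: they are recovered from the sequence pair on load.
    """
    lines = ["[assays]", ",".join(_ASSAY_COLUMNS)]
    for a in panel.assays.values():
        lines.append(
            f"{a.gene_id},{a.nt_sequence},{a.is_sequence},"
            f"{a.fwd_primer_len},{a.rev_primer_len},{a.central_offset}"
        )
    lines.append("[barcodes]")
    lines.append(",".join(_BARCODE_COLUMNS))
    for (f, r), (sample, i) in panel.barcode_table.items():
        lines.append(f"{sample},{i},{f},{r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_panel(path: str | Path) -> AssayPanel:
    """Read a panel table written by :func:`write_panel`."""
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], [])
        elif current is not None:
            current.append(line)
        else:
            raise PanelError(f"content before first section header: {line!r}")
    for name in ("assays", "barcodes"):
        if name not in sections:
            raise PanelError(f"panel file missing [{name}] section")

    assays: dict[str, AssayDefinition] = {}
    adf = pd.read_csv(io.StringIO("\n".join(sections["assays"])))
    if list(adf.columns) != _ASSAY_COLUMNS:
        raise PanelError(f"[assays] columns must be {_ASSAY_COLUMNS}")
    for row in adf.itertuples():
        if row.gene_id in assays:
            raise PanelError(f"duplicate gene_id {row.gene_id}")
        assays[row.gene_id] = AssayDefinition(
            gene_id=row.gene_id,
            nt_sequence=row.nt_sequence,
            is_sequence=row.is_sequence,
            fwd_primer_len=int(row.fwd_primer_len),
            rev_primer_len=int(row.rev_primer_len),
            central_offset=int(row.central_offset),
        )
    bdf = pd.read_csv(io.StringIO("\n".join(sections["barcodes"])))
    if list(bdf.columns) != _BARCODE_COLUMNS:
        raise PanelError(f"[barcodes] columns must be {_BARCODE_COLUMNS}")
    barcode_table = {
        (row.fwd_index, row.rev_index): (row.sample_id, int(row.dilution_index))
        for row in bdf.itertuples()
    }
    return AssayPanel(assays=assays, barcode_table=barcode_table)


def export_reference_fasta(panel: AssayPanel, kind: str, path: str | Path) -> int:
    """Write a reference FASTA and return the number of records.

    ``kind='subject'``: two records per gene (``<gene>_NT`` and
    ``<gene>_IS``), each the central 60-nt window.  ``kind='barcode'``:
    one record per 14-nt terminal tag (forward and reverse per library).
    """
    if not panel.assays and kind == "subject":
        raise PanelError("empty panel")
    records: list[SeqRecord] = []
    if kind == "subject":
        for a in panel.assays.values():
            records.append(SeqRecord(Seq(a.nt_window), id=f"{a.gene_id}_NT", description=""))
            records.append(SeqRecord(Seq(a.is_window), id=f"{a.gene_id}_IS", description=""))
    elif kind == "barcode":
        if not panel.barcode_table:
            raise PanelError("empty barcode table")
        for sample, i in panel.libraries:
            records.append(
                SeqRecord(Seq(panel.fwd_tag(sample, i)), id=f"{sample}_{i}_fwd", description="")
            )
            records.append(
                SeqRecord(Seq(panel.rev_tag(sample, i)), id=f"{sample}_{i}_rev", description="")
            )
    else:
        raise PanelError(f"unknown reference kind {kind!r}")
    return SeqIO.write(records, str(path), "fasta")


def write_count_table(counts: CountTable, path: str | Path) -> None:
    counts.df.to_csv(path, index=False)


def read_count_table(path: str | Path, panel: AssayPanel | None = None) -> CountTable:
    """Read a comma-delimited count table; optionally flag unknown genes."""
    df = pd.read_csv(path)
    table = CountTable(df)
    if panel is not None:
        unknown = table.unknown_genes(panel)
        if unknown:
            raise PanelError(f"count table contains genes absent from panel: {unknown}")
    return table
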