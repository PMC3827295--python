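"""Dual-barcode demultiplexing and NT/IS allele calling.

Each parsed read is assigned to a (sample, IS-dilution) library only
when its forward and reverse 4-nt indices agree; discordant pairs are
discarded, which suppresses false indexing.  The central 60-nt window
is then matched against every assay's NT and IS windows by Hamming
distance (amplicons are fixed-length and indel-free by construction, so
gapped alignment adds nothing at this scale).  The NT-vs-IS call is
made from the six diagnostic positions alone: a read must match at
least four of the six bases of one allele, and more than it matches the
other, to be called; anything else is ambiguous and excluded from
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from campseq.panel import (
    AssayPanel,
    CountTable,
    DEFAULT_CENTRAL_OFFSET,
    INDEX_LEN,
    WINDOW_LEN,
)
from campseq.reads import ParseResult, ParsedRead, extract_central_window, parse_reads

DEFAULT_MAX_MISMATCH = 5
DEFAULT_MIN_DIAG_MATCH = 4

#: Interior pad between each 14-nt tag and the amplicon in the
#: simulator's 151-nt read layout; the variant window therefore starts
#: at interior offset ``PAD_LEN + DEFAULT_CENTRAL_OFFSET``.
PAD_LEN = 11
DEFAULT_WINDOW_OFFSET = PAD_LEN + DEFAULT_CENTRAL_OFFSET

#: Position of the 4-nt index inside each 14-nt tag: last four bases of
#: the forward tag, first four of the reverse tag.
FWD_INDEX_SLICE = slice(10, 14)
REV_INDEX_SLICE = slice(0, 4)

_ENC = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate("ACGT", start=1):
    _ENC[ord(_b)] = _i


def _encode(seqs: Sequence[str]) -> np.ndarray:
    flat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _ENC[flat].reshape(len(seqs), -1)


@dataclass(frozen=True)
class AlleleCall:
    gene_id: str | None
    allele: str  # NT | IS | ambiguous | no_gene
    mismatches: int

    def __post_init__(self) -> None:
        assert self.allele in {"NT", "IS", "ambiguous", "no_gene"}
        assert self.mismatches >= 0


@dataclass
class BinningReport:
    """Per-category read tallies from one binning run."""

    n_records: int = 0
    n_rejected_short: int = 0
    n_malformed: int = 0
    assigned: int = 0
    fwd_unknown: int = 0
    rev_unknown: int = 0
    barcode_conflict: int = 0
    no_gene: int = 0
    ambiguous: int = 0

    @property
    def n_accepted(self) -> int:
        return self.n_records - self.n_rejected_short - self.n_malformed

    def as_dict(self) -> dict[str, int]:
        return {
            "n_records": self.n_records,
            "n_rejected_short": self.n_rejected_short,
            "n_malformed": self.n_malformed,
            "n_accepted": self.n_accepted,
            "assigned": self.assigned,
            "fwd_unknown": self.fwd_unknown,
            "rev_unknown": self.rev_unknown,
            "barcode_conflict": self.barcode_conflict,
            "no_gene": self.no_gene,
            "ambiguous": self.ambiguous,
        }


def demultiplex(
    parsed: ParsedRead, panel: AssayPanel
) -> tuple[tuple[str, int] | None, str]:
    """Assign a read to its library by dual exact 4-nt index matching.

    Returns ``(library, 'ok')`` when both indices map to the same
    (sample, dilution); otherwise ``(None, reason)`` with reason in
    ``{fwd_unknown, rev_unknown, conflict}``.
    """
    fwd = parsed.fwd_tag[FWD_INDEX_SLICE]
    rev = parsed.rev_tag[REV_INDEX_SLICE]
    lib_f = panel.fwd_index_map().get(fwd)
    lib_r = panel.rev_index_map().get(rev)
    if lib_f is None:
        return None, "fwd_unknown"
    if lib_r is None:
        return None, "rev_unknown"
    if lib_f != lib_r:
        return None, "conflict"
    return lib_f, "ok"


class AlleleClassifier:
    """Vectorised minimal-Hamming NT/IS classifier over a panel."""

    def __init__(
        self,
        panel: AssayPanel,
        max_mismatch: int = DEFAULT_MAX_MISMATCH,
        min_diag_match: int = DEFAULT_MIN_DIAG_MATCH,
    ) -> None:
        self.panel = panel
        self.max_mismatch = int(max_mismatch)
        self.min_diag_match = int(min_diag_match)
        self._genes = list(panel.assays)
        windows: list[str] = []
        for a in panel.assays.values():
            windows.append(a.nt_window)
            windows.append(a.is_window)
        self._ref = _encode(windows) if windows else np.empty((0, WINDOW_LEN), np.uint8)
        self._exact = {w: i for i, w in enumerate(windows)}
        # window-relative diagnostic positions and the two allele bases
        self._diag_pos = [a.window_diagnostic_positions for a in panel.assays.values()]

    def call(self, window: str | None) -> AlleleCall:
        if window is None or len(window) != WINDOW_LEN or set(window) - set("ACGT"):
            return AlleleCall(None, "no_gene", 0)
        return self.call_many([window])[0]

    def call_many(self, windows: Sequence[str]) -> list[AlleleCall]:
        calls: list[AlleleCall] = [None] * len(windows)  # type: ignore[list-item]
        pending: list[int] = []
        for i, w in enumerate(windows):
            hit = self._exact.get(w)
            if hit is not None:
                gene = self._genes[hit // 2]
                calls[i] = AlleleCall(gene, "NT" if hit % 2 == 0 else "IS", 0)
            else:
                pending.append(i)
        if pending:
            enc = _encode([windows[i] for i in pending])
            for chunk in range(0, len(pending), 2048):
                idx = pending[chunk : chunk + 2048]
                sub = enc[chunk : chunk + 2048]
                # mismatches to every NT/IS reference window
                dists = (sub[:, None, :] != self._ref[None, :, :]).sum(axis=2)
                for row, i in enumerate(idx):
                    calls[i] = self._call_from_dists(windows[i], dists[row])
        return calls

    def _call_from_dists(self, window: str, dists: np.ndarray) -> AlleleCall:
        best = int(dists.argmin())
        gene_idx = best // 2
        d_pair = int(min(dists[2 * gene_idx], dists[2 * gene_idx + 1]))
        if d_pair > self.max_mismatch:
            return AlleleCall(None, "no_gene", d_pair)
        assay = self.panel.assays[self._genes[gene_idx]]
        nt_win, is_win = assay.nt_window, assay.is_window
        nt_diag = sum(window[p] == nt_win[p] for p in self._diag_pos[gene_idx])
        is_diag = sum(window[p] == is_win[p] for p in self._diag_pos[gene_idx])
        if nt_diag >= self.min_diag_match and nt_diag > is_diag:
            return AlleleCall(assay.gene_id, "NT", int(dists[2 * gene_idx]))
        if is_diag >= self.min_diag_match and is_diag > nt_diag:
            return AlleleCall(assay.gene_id, "IS", int(dists[2 * gene_idx + 1]))
        return AlleleCall(assay.gene_id, "ambiguous", d_pair)


def call_allele(
    window: str | None,
    panel: AssayPanel,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_diag_match: int = DEFAULT_MIN_DIAG_MATCH,
) -> AlleleCall:
    """Classify one 60-nt window against the panel (see module docs)."""
    return AlleleClassifier(panel, max_mismatch, min_diag_match).call(window)


def bin_reads(
    source: str | Path | ParseResult | Iterable[ParsedRead],
    panel: AssayPanel,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_diag_match: int = DEFAULT_MIN_DIAG_MATCH,
    window_offset: int = DEFAULT_WINDOW_OFFSET,
) -> tuple[CountTable, BinningReport]:
    """Demultiplex, call alleles, and aggregate a full count table.

    ``source`` may be a FASTQ path, a :class:`ParseResult`, or an
    iterable of already-parsed reads.  The returned table has one row
    for every (library, gene) combination, including zeros, so that
    downstream summaries see explicit absences.
    """
    if isinstance(source, (str, Path)):
        parsed = parse_reads(source)
    elif isinstance(source, ParseResult):
        parsed = source
    else:
        parsed = ParseResult(reads=list(source))

    report = BinningReport(
        n_records=parsed.n_records,
        n_rejected_short=parsed.n_rejected_short,
        n_malformed=parsed.n_malformed,
    )
    classifier = AlleleClassifier(panel, max_mismatch, min_diag_match)
    fwd_map = panel.fwd_index_map()
    rev_map = panel.rev_index_map()

    counts: dict[tuple[str, int, str], list[int]] = {
        (sample, i, gene): [0, 0] for sample, i in panel.libraries for gene in panel.assays
    }
    totals: dict[tuple[str, int], int] = {lib: 0 for lib in panel.libraries}

    assigned_lib: list[tuple[str, int]] = []
    assigned_windows: list[str | None] = []
    for read in parsed.reads:
        lib_f = fwd_map.get(read.fwd_tag[FWD_INDEX_SLICE])
        lib_r = rev_map.get(read.rev_tag[REV_INDEX_SLICE])
        if lib_f is None:
            report.fwd_unknown += 1
            continue
        if lib_r is None:
            report.rev_unknown += 1
            continue
        if lib_f != lib_r:
            report.barcode_conflict += 1
            continue
        totals[lib_f] += 1
        assigned_lib.append(lib_f)
        assigned_windows.append(extract_central_window(read, window_offset))

    classifiable = [i for i, w in enumerate(assigned_windows) if w is not None]
    report.no_gene += len(assigned_windows) - len(classifiable)
    calls = classifier.call_many([assigned_windows[i] for i in classifiable])
    for i, call in zip(classifiable, calls):
        sample, dil = assigned_lib[i]
        if call.allele == "NT":
            counts[(sample, dil, call.gene_id)][0] += 1
            report.assigned += 1
        elif call.allele == "IS":
            counts[(sample, dil, call.gene_id)][1] += 1
            report.assigned += 1
        elif call.allele == "ambiguous":
            report.ambiguous += 1
        else:
            report.no_gene += 1

    rows = [
        {"sample": s, "dilution_index": i, "gene": g, "nt_count": nt, "is_count": is_}
        for (s, i, g), (nt, is_) in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["sample", "dilution_index", "gene", "nt_count", "is_count"])
    return CountTable(df, library_totals=totals), report
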