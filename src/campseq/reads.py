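"""FASTQ ingestion and read splitting.

Reads longer than 150 nt are split into three regions: the first and
last 14 bases (forward and reverse barcode tags) and the interior
between them.  Reads of 150 nt or shorter are rejected; malformed
records (sequence/quality length mismatch, truncated record) are
skipped and tallied.  Base qualities are carried but play no role in
classification.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from campseq.panel import TAG_LEN, WINDOW_LEN

MIN_READ_LEN = 151  # strict "> 150 bases"


@dataclass(frozen=True)
class ParsedRead:
    read_id: str
    fwd_tag: str
    central: str
    rev_tag: str
    quality: str = ""

    @property
    def sequence(self) -> str:
        """The original read sequence (tag + central + tag)."""
        return self.fwd_tag + self.central + self.rev_tag


@dataclass
class ParseResult:
    reads: list[ParsedRead] = field(default_factory=list)
    n_rejected_short: int = 0
    n_malformed: int = 0

    @property
    def n_accepted(self) -> int:
        return len(self.reads)

    @property
    def n_records(self) -> int:
        return self.n_accepted + self.n_rejected_short + self.n_malformed


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(handle: Iterable[str]) -> Iterator[tuple[str, str, str] | None]:
    """Yield (id, seq, qual) per record, or None for a malformed one."""
    lines = iter(handle)
    while True:
        try:
            header = next(lines)
        except StopIteration:
            return
        header = header.rstrip("\n")
        if not header:
            continue
        try:
            seq = next(lines).rstrip("\n")
            plus = next(lines).rstrip("\n")
            qual = next(lines).rstrip("\n")
        except StopIteration:
            yield None
            return
        if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
            yield None
            continue
        yield header[1:].split()[0], seq, qual


def split_read(read_id: str, seq: str, qual: str = "") -> ParsedRead:
    """Split one accepted read into the 14/interior/14 regions."""
    return ParsedRead(
        read_id=read_id,
        fwd_tag=seq[:TAG_LEN],
        central=seq[TAG_LEN:-TAG_LEN],
        rev_tag=seq[-TAG_LEN:],
        quality=qual,
    )


def parse_reads(source: str | Path | Iterable[str]) -> ParseResult:
    """Parse a FASTQ file (optionally gzipped) or line iterable.

    Returns the accepted reads split into regions plus tallies of
    too-short and malformed records.
    """
    if isinstance(source, (str, Path)):
        with _open_text(source) as handle:
            return parse_reads(handle)
    result = ParseResult()
    for record in _iter_fastq(source):
        if record is None:
            result.n_malformed += 1
            continue
        read_id, seq, qual = record
        if len(seq) < MIN_READ_LEN:
            result.n_rejected_short += 1
            continue
        result.reads.append(split_read(read_id, seq, qual))
    return result


def extract_central_window(parsed: ParsedRead, expected_offset: int) -> str | None:
    """The 60-nt variant window at ``expected_offset`` in the interior.

    Returns ``None`` (unclassifiable) when the interior is too short to
    contain the window; never raises for degenerate inputs.
    """
    window = parsed.central[expected_offset : expected_offset + WINDOW_LEN]
    if expected_offset < 0 or len(window) < WINDOW_LEN:
        return None
    return window


def write_region_fastqs(reads: Iterable[ParsedRead], prefix: str | Path) -> dict[str, Path]:
    """Write the three per-region FASTQ files (barcode/revbarcode/subject)."""
    prefix = Path(prefix)
    paths = {
        "barcode": prefix.with_name(prefix.name + "-barcode.fastq"),
        "revbarcode": prefix.with_name(prefix.name + "-revbarcode.fastq"),
        "subject": prefix.with_name(prefix.name + "-subject.fastq"),
    }
    with open(paths["barcode"], "w") as fb, open(paths["revbarcode"], "w") as fr, open(
        paths["subject"], "w"
    ) as fs:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fb.write(f"@{r.read_id}\n{r.fwd_tag}\n+\n{qual[:TAG_LEN]}\n")
            fr.write(f"@{r.read_id}\n{r.rev_tag}\n+\n{qual[-TAG_LEN:]}\n")
            fs.write(f"@{r.read_id}\n{r.central}\n+\n{qual[TAG_LEN:-TAG_LEN]}\n")
    return paths
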