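"""Sliding-window base-quality trimming and paired-read length filtering.

The trimmer scans each read 5'->3' and stops at the first base whose own
quality drops below a floor, or where the mean quality of the window
starting at that base drops below a second floor; bases before the stop are
kept.  Pairs are discarded when either mate ends up at or below the minimum
length.  Summary statistics mirror the usual sequencing QC report (clean
read/base percentages, Q20/Q30, GC).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .report import percentage


@dataclass(frozen=True)
class TrimParams:
    window_size: int = 5
    base_qual_floor: int = 2
    window_mean_floor: float = 20.0
    min_read_length: int = 50      # pairs with either mate <= this are discarded

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.base_qual_floor < 0 or self.window_mean_floor < 0:
            raise ValueError("quality floors must be >= 0")


@dataclass
class FastqRead:
    """One read: identifier, bases, per-base Phred qualities."""

    id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError("sequence and quality lengths differ")

    def __len__(self) -> int:
        return len(self.seq)

    def prefix(self, n: int) -> "FastqRead":
        return FastqRead(self.id, self.seq[:n], self.quals[:n])


@dataclass
class QcSummary:
    raw_reads: int
    raw_bases: int
    clean_reads: int
    clean_bases: int
    clean_read_pct: float | None
    clean_base_pct: float | None
    gc_pct: float | None
    q20_pct: float | None
    q30_pct: float | None


def trim_read(read: FastqRead, params: TrimParams = TrimParams()) -> FastqRead:
    """Keep the longest 5' prefix before the sliding window stops.

    Scanning position i anchors a window of ``window_size`` bases starting at
    i (shorter at the 3' end, where the actual length is used for the mean);
    the scan stops where qual[i] < base_qual_floor or the window mean is
    below window_mean_floor, and bases [0, i) are returned.  A read with no
    stop point is returned unchanged; an empty read is returned empty.
    """
    q = read.quals
    w = params.window_size
    for i in range(len(q)):
        if q[i] < params.base_qual_floor:
            return read.prefix(i)
        window = q[i:i + w]
        if sum(window) / len(window) < params.window_mean_floor:
            return read.prefix(i)
    return read


def filter_pair(read1: FastqRead, read2: FastqRead, params: TrimParams = TrimParams()) -> bool:
    """True to keep the pair; discarded iff either mate is <= min_read_length."""
    return len(read1) > params.min_read_length and len(read2) > params.min_read_length


# ---------------------------------------------------------------------------
# FASTQ IO
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield FastqRead(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        for r in reads:
            qstr = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def summarize_fastq(raw: Iterable[FastqRead], clean: Iterable[FastqRead]) -> QcSummary:
    """QC report over a raw stream and its cleaned counterpart.

    Percentages are half-up rounded to two decimals; Q20/Q30/GC are computed
    over clean bases.  With zero raw reads all percentages are None.
    """
    raw_reads = raw_bases = 0
    for r in raw:
        raw_reads += 1
        raw_bases += len(r)
    clean_reads = clean_bases = gc = q20 = q30 = 0
    for r in clean:
        clean_reads += 1
        clean_bases += len(r)
        gc += sum(1 for b in r.seq if b in "GCgc")
        q20 += sum(1 for q in r.quals if q >= 20)
        q30 += sum(1 for q in r.quals if q >= 30)
    return QcSummary(
        raw_reads=raw_reads,
        raw_bases=raw_bases,
        clean_reads=clean_reads,
        clean_bases=clean_bases,
        clean_read_pct=percentage(clean_reads, raw_reads),
        clean_base_pct=percentage(clean_bases, raw_bases),
        gc_pct=percentage(gc, clean_bases),
        q20_pct=percentage(q20, clean_bases),
        q30_pct=percentage(q30, clean_bases),
    )


def process_pairs(
    in1: str | Path, in2: str | Path, out1: str | Path, out2: str | Path,
    params: TrimParams = TrimParams(),
) -> QcSummary:
    """Trim both mates, drop short pairs, write survivors; return the QC summary."""
    raw1 = list(read_fastq(in1))
    raw2 = list(read_fastq(in2))
    if len(raw1) != len(raw2):
        raise ValueError("mate files have different read counts")
    kept1: list[FastqRead] = []
    kept2: list[FastqRead] = []
    for r1, r2 in zip(raw1, raw2):
        t1, t2 = trim_read(r1, params), trim_read(r2, params)
        if filter_pair(t1, t2, params):
            kept1.append(t1)
            kept2.append(t2)
    write_fastq(kept1, out1)
    write_fastq(kept2, out2)
    return summarize_fastq(raw1 + raw2, kept1 + kept2)


def write_qc_report(summary: QcSummary, path: str | Path) -> None:
    cols = [f.name for f in summary.__dataclass_fields__.values()]  # type: ignore[attr-defined]
    vals = [getattr(summary, c) for c in cols]
    Path(path).write_text(
        "\t".join(cols) + "\n" + "\t".join("NA" if v is None else str(v) for v in vals) + "\n"
    )
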