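"""Short-read quality metrics and whole-read filtering.

Q20/Q30 are the percentage of called bases with Phred quality >= 20/30;
GC content is computed over unambiguous (A/C/G/T) bases only; the
duplication level is the percentage of reads whose full sequence was
already seen earlier in the stream.  Filtering removes reads containing
the library adapter, reads dominated by N calls, and reads of low mean
quality, tallied by the first failing rule in that order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .io import FastqRead, iter_fastq


@dataclass
class BaseTally:
    """Single-pass accumulator whose merge is the weighted union of streams."""

    n_reads: int = 0
    n_bases: int = 0
    n_q20: int = 0
    n_q30: int = 0
    n_gc: int = 0
    n_acgt: int = 0
    n_dup: int = 0

    def update(self, read: FastqRead, seen: set[str]) -> None:
        self.n_reads += 1
        self.n_bases += len(read.seq)
        self.n_q20 += sum(1 for q in read.quals if q >= 20)
        self.n_q30 += sum(1 for q in read.quals if q >= 30)
        self.n_gc += sum(1 for b in read.seq if b in "GC")
        self.n_acgt += sum(1 for b in read.seq if b in "ACGT")
        if read.seq in seen:
            self.n_dup += 1
        else:
            seen.add(read.seq)

    def merge(self, other: "BaseTally") -> "BaseTally":
        return BaseTally(*(getattr(self, f) + getattr(other, f) for f in (
            "n_reads", "n_bases", "n_q20", "n_q30", "n_gc", "n_acgt", "n_dup")))


@dataclass
class QCReport:
    n_reads: int
    q20_pct: float
    q30_pct: float
    gc_pct: float
    dup_pct: float

    @classmethod
    def from_tally(cls, t: BaseTally) -> "QCReport":
        if t.n_reads == 0:
            raise ValueError("empty FASTQ stream")
        return cls(
            n_reads=t.n_reads,
            q20_pct=100.0 * t.n_q20 / t.n_bases,
            q30_pct=100.0 * t.n_q30 / t.n_bases,
            gc_pct=100.0 * t.n_gc / t.n_acgt if t.n_acgt else 0.0,
            dup_pct=100.0 * t.n_dup / t.n_reads,
        )


def tally_reads(reads: Iterable[FastqRead]) -> BaseTally:
    tally = BaseTally()
    seen: set[str] = set()
    for read in reads:
        tally.update(read, seen)
    return tally


def compute_qc(reads: Iterable[FastqRead] | str | Path) -> QCReport:
    """Compute the QC metrics over a FASTQ stream (path or parsed reads)."""
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    return QCReport.from_tally(tally_reads(reads))


@dataclass
class FilterRules:
    adapter_seq: str
    max_n_frac: float = 0.1
    min_mean_q: float = 20.0

    def __post_init__(self) -> None:
        if not self.adapter_seq:
            raise ValueError("adapter sequence must be non-empty")


def filter_reads(
    reads: Iterable[FastqRead] | str | Path, rules: FilterRules
) -> tuple[list[FastqRead], Counter]:
    """Remove adapter-bearing, poly-N and low-mean-quality reads.

    Returns the retained reads in input order and a tally of rejections
    keyed by the first failing rule (``adapter``, ``polyN``, ``low_quality``).
    """
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    kept: list[FastqRead] = []
    tally: Counter = Counter()
    for read in reads:
        if rules.adapter_seq in read.seq:
            tally["adapter"] += 1
        elif read.seq.count("N") > rules.max_n_frac * len(read.seq):
            tally["polyN"] += 1
        elif read.quals and sum(read.quals) / len(read.quals) < rules.min_mean_q:
            tally["low_quality"] += 1
        else:
            kept.append(read)
    return kept, tally


def _qc_rows(report: QCReport) -> Iterator[tuple[str, float]]:
    yield ("n_reads", report.n_reads)
    yield ("q20_pct", report.q20_pct)
    yield ("q30_pct", report.q30_pct)
    yield ("gc_pct", report.gc_pct)
    yield ("dup_pct", report.dup_pct)


def write_qc_report(report: QCReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key, val in _qc_rows(report):
            fh.write(f"{key}\t{val:.4f}\n" if isinstance(val, float) else f"{key}\t{val}\n")
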