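"""FASTA/FASTQ and tabular I/O.

Sequence parsing goes through Biopython; writers emit deterministic plain
text so that fixed-seed pipeline runs are byte-identical.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO


@dataclass
class Transcript:
    """A sequence record — the universal currency of the pipeline."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FastqRead:
    id: str
    seq: str
    quals: list[int] = field(default_factory=list)  # Phred scores


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[Transcript]:
    with _open_text(path) as fh:
        return [Transcript(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[Transcript], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")
            n += 1
    return n


def iter_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream Phred+33 FASTQ records; malformed input raises a parse error
    naming the index of the offending record."""
    i = 0
    with _open_text(path) as fh:
        parser = SeqIO.parse(fh, "fastq")
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ at record {i}: {exc}") from exc
            yield FastqRead(rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"])
            i += 1


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")
            n += 1
    return n
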