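"""ORF scanning and hexamer log-likelihood coding classification.

Candidate ORFs are enumerated in all six frames.  Within each frame the
stop codons partition the codon stream into runs; a run bounded upstream
by a stop yields a candidate starting at its first ATG, while a run that
reaches the 5' transcript edge yields the longest candidate (from the
run start), since the true start may lie upstream of the fragment.
Completeness is classified mechanically: ``complete`` begins with ATG
and ends with a stop inside the transcript, ``5prime_partial`` lacks an
in-frame start before the 5' edge, ``3prime_partial`` lacks a stop
before the 3' edge, ``internal`` lacks both.

A candidate is retained when (i) its protein length reaches ``min_aa``;
(ii) its mean hexamer log-likelihood ratio — in-frame hexamer
frequencies of a coding training set over position-free background
frequencies — is positive; (iii) that score, computed on the candidate's
own span, strictly exceeds the score of the same span read in each of
the other five frames (ragged ends truncate to whole hexamers; ties
reject); and (iv) it is not fully contained in a longer retained ORF on
the same strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._util import revcomp
from .io import Transcript

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ORFRecord:
    transcript_id: str
    start: int  # 0-based half-open on the transcript (plus-strand coords)
    end: int
    strand: str  # '+' or '-'
    frame: int  # 0..2, offset on the reading-direction sequence
    completeness: str  # complete | 5prime_partial | 3prime_partial | internal
    protein_length: int  # aa, stop codon excluded
    coding_score: float = float("nan")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class HexamerModel:
    """log(f_coding / f_background) per hexamer, additive-pseudocount smoothed."""

    table: np.ndarray  # shape (4096,)
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.table.shape != (4096,) or not np.isfinite(self.table).all():
            raise ValueError("hexamer table must be 4096 finite entries")


def _hexamer_code(seq: str, i: int) -> int:
    code = 0
    for j in range(i, i + 6):
        b = _BASE_INDEX.get(seq[j])
        if b is None:
            return -1
        code = code * 4 + b
    return code


def _count_hexamers(seqs: Iterable[str], step: int) -> np.ndarray:
    counts = np.zeros(4096)
    for seq in seqs:
        seq = seq.upper()
        for i in range(0, len(seq) - 5, step):
            code = _hexamer_code(seq, i)
            if code >= 0:
                counts[code] += 1
    return counts


def train_coding_model(coding_seqs: Sequence[str], background_seqs: Sequence[str],
                       pseudocount: float = 1.0) -> HexamerModel:
    """In-frame (step 3) hexamer frequencies of the coding set against
    position-free (step 1) frequencies of the background set."""
    if not coding_seqs or not background_seqs:
        raise ValueError("both training sets must be non-empty")
    coding = _count_hexamers(coding_seqs, step=3) + pseudocount
    background = _count_hexamers(background_seqs, step=1) + pseudocount
    table = np.log(coding / coding.sum()) - np.log(background / background.sum())
    return HexamerModel(table, pseudocount)


def score_orf(orf_seq: str, model: HexamerModel) -> float:
    """Mean log-likelihood ratio over in-frame hexamers (step 3 from the
    first base); unknown bases contribute zero.  Length < 6 is an error."""
    if len(orf_seq) < 6:
        raise ValueError("sequence shorter than one hexamer")
    total = 0.0
    n = 0
    for i in range(0, len(orf_seq) - 5, 3):
        code = _hexamer_code(orf_seq, i)
        if code >= 0:
            total += model.table[code]
        n += 1
    return total / n


def scan_orfs(transcript: Transcript, min_aa: int = 100) -> list[ORFRecord]:
    """Enumerate candidate ORFs in all six frames.

    Protein length excludes the stop codon; candidates shorter than
    ``min_aa`` are dropped.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    out: list[ORFRecord] = []
    n = len(transcript.seq)
    for strand in "+-":
        seq = transcript.seq if strand == "+" else revcomp(transcript.seq)
        for frame in range(3):
            n_codons = (len(seq) - frame) // 3
            if n_codons == 0:
                continue
            codons = [seq[frame + 3 * c: frame + 3 * c + 3] for c in range(n_codons)]
            run_start = 0
            for c in range(n_codons + 1):
                at_end = c == n_codons
                if not at_end and codons[c] not in STOP_CODONS:
                    continue
                # codon run [run_start, c), bounded by a stop at c unless at_end
                upstream_bounded = run_start > 0
                if upstream_bounded:
                    starts = [i for i in range(run_start, c) if codons[i] == START_CODON]
                    cand = starts[0] if starts else None
                else:
                    cand = run_start if c > run_start else None
                if cand is not None:
                    span_lo = frame + 3 * cand
                    span_hi = frame + 3 * (c + (0 if at_end else 1))
                    rec = _make_record(transcript.id, seq, strand, frame,
                                       span_lo, span_hi, n)
                    if rec.protein_length >= min_aa:
                        out.append(rec)
                run_start = c + 1
    out.sort(key=lambda r: (r.start, r.end, r.strand, r.frame))
    return out


def _make_record(tid: str, oriented_seq: str, strand: str, frame: int,
                 lo: int, hi: int, transcript_len: int) -> ORFRecord:
    sub = oriented_seq[lo:hi]
    has_start = sub[:3] == START_CODON
    has_stop = sub[-3:] in STOP_CODONS
    if has_start and has_stop:
        completeness = "complete"
    elif has_stop:
        completeness = "5prime_partial"
    elif has_start:
        completeness = "3prime_partial"
    else:
        completeness = "internal"
    protein_len = (hi - lo) // 3 - (1 if has_stop else 0)
    if strand == "+":
        start, end = lo, hi
    else:
        start, end = transcript_len - hi, transcript_len - lo
    return ORFRecord(tid, start, end, strand, frame, completeness, protein_len)


def orf_sequence(transcript: Transcript, rec: ORFRecord) -> str:
    """The nucleotide sequence of an ORF in reading direction."""
    sub = transcript.seq[rec.start:rec.end]
    return revcomp(sub) if rec.strand == "-" else sub


def _frame_shift_scores(span_seq: str, model: HexamerModel) -> list[float]:
    """Scores of the same span read in the five alternative frames."""
    rc = revcomp(span_seq)
    scores = []
    for alt in (span_seq[1:], span_seq[2:], rc, rc[1:], rc[2:]):
        scores.append(score_orf(alt, model) if len(alt) >= 6 else -math.inf)
    return scores


def select_orfs(transcript: Transcript, candidates: Sequence[ORFRecord],
                model: HexamerModel) -> list[ORFRecord]:
    """Apply the coding-score, frame-maximality and nesting rules."""
    scored: list[ORFRecord] = []
    for rec in candidates:
        seq = orf_sequence(transcript, rec)
        if len(seq) < 6:
            continue
        rec.coding_score = score_orf(seq, model)
        if rec.coding_score <= 0:
            continue
        if any(rec.coding_score <= s for s in _frame_shift_scores(seq, model)):
            continue
        scored.append(rec)
    # drop ORFs fully contained in a longer retained ORF on the same strand
    scored.sort(key=lambda r: (-(r.span), r.start))
    kept: list[ORFRecord] = []
    for rec in scored:
        if any(k.strand == rec.strand and k.start <= rec.start and rec.end <= k.end
               and k.span > rec.span for k in kept):
            continue
        kept.append(rec)
    kept.sort(key=lambda r: (r.start, r.end, r.strand))
    return kept


def predict_orfs(transcripts: Iterable[Transcript], model: HexamerModel,
                 min_aa: int = 100) -> dict[str, list[ORFRecord]]:
    """scan + select for a transcript set; keyed by transcript id."""
    return {t.id: select_orfs(t, scan_orfs(t, min_aa), model) for t in transcripts}


def completeness_summary(records: Iterable[ORFRecord]) -> dict[str, int]:
    counts = {"complete": 0, "5prime_partial": 0, "3prime_partial": 0, "internal": 0}
    for rec in records:
        counts[rec.completeness] += 1
    return counts


def write_orf_gff3(orfs: dict[str, list[ORFRecord]], path) -> None:
    """GFF3 of ORF coordinates (protein length excludes the stop codon)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tid in sorted(orfs):
            for i, rec in enumerate(orfs[tid], 1):
                attrs = (f"ID={tid}.orf{i};completeness={rec.completeness};"
                         f"protein_length={rec.protein_length};"
                         f"coding_score={rec.coding_score:.4f}")
                fh.write(f"{tid}\tisocurl\tCDS\t{rec.start + 1}\t{rec.end}\t.\t"
                         f"{rec.strand}\t0\t{attrs}\n")
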