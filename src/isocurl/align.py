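"""Pairwise local alignment into high-scoring segment pairs (HSPs).

A built-in seed-and-extend aligner (exact k-mer seeds grouped by
diagonal, ungapped x-drop extension) produces the HSPs needed by the
alternative-splicing caller without an external BLAST binary.  Because
the pipeline's error model is substitution-only, every local alignment
lies on a single diagonal, which this aligner recovers exactly.
Precomputed alignments in 12-column BLAST tabular format (outfmt 6) are
accepted interchangeably.

Coordinates are 0-based half-open throughout; reverse-orientation HSPs
keep subject coordinates on the original (plus) strand with
``orientation == "reverse"``, mirroring the BLAST convention of a
descending sstart/send pair.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from ._util import revcomp

FORWARD = "forward"
REVERSE = "reverse"


@dataclass
class HSP:
    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    orientation: str = FORWARD
    identity_pct: float = 100.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.q_start >= self.q_end or self.s_start >= self.s_end:
            raise ValueError("HSP coordinates must satisfy start < end")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start


@dataclass
class AlignParams:
    k: int = 15                   # exact seed length
    max_seed_gap: int = 60        # max diagonal gap bridged between seeds
    xdrop: float = 12.0           # ungapped extension drop-off
    match: float = 1.0
    mismatch: float = -3.0
    min_hsp_len: int = 40
    min_identity_pct: float = 95.0


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i:i + k]].append(i)
    return index


def _extend(q: str, s: str, q_lo: int, q_hi: int, diag: int,
            params: AlignParams) -> tuple[int, int, float, float]:
    """Ungapped x-drop extension of the diagonal segment [q_lo, q_hi).

    Returns (q_start, q_end, identity_pct, score) of the trimmed maximal
    scoring extension.
    """
    def base_score(qi: int) -> float:
        return params.match if q[qi] == s[qi - diag] else params.mismatch

    # extend right
    best = run = 0.0
    best_end = q_hi
    i = q_hi
    while i < len(q) and i - diag < len(s):
        run += base_score(i)
        i += 1
        if run > best:
            best, best_end = run, i
        elif best - run > params.xdrop:
            break
    # extend left
    bestl = runl = 0.0
    best_start = q_lo
    i = q_lo - 1
    while i >= 0 and i - diag >= 0:
        runl += base_score(i)
        if runl > bestl:
            bestl, best_start = runl, i
        elif bestl - runl > params.xdrop:
            break
        i -= 1
    matches = sum(1 for j in range(best_start, best_end) if q[j] == s[j - diag])
    length = best_end - best_start
    score = matches * params.match + (length - matches) * params.mismatch
    return best_start, best_end, 100.0 * matches / length, score


def _diagonal_hsps(q: str, s: str, sindex: dict[str, list[int]],
                   params: AlignParams) -> list[tuple[int, int, int, float, float]]:
    """(q_start, q_end, diag, identity_pct, score) candidate segments."""
    by_diag: dict[int, list[int]] = defaultdict(list)
    k = params.k
    for i in range(len(q) - k + 1):
        for j in sindex.get(q[i:i + k], ()):
            by_diag[i - j].append(i)
    out = []
    for diag, positions in sorted(by_diag.items()):
        positions.sort()
        # merge seeds separated by at most max_seed_gap along the diagonal
        seg_lo = positions[0]
        seg_hi = positions[0] + k
        segments = []
        for p in positions[1:]:
            if p <= seg_hi + params.max_seed_gap:
                seg_hi = max(seg_hi, p + k)
            else:
                segments.append((seg_lo, seg_hi))
                seg_lo, seg_hi = p, p + k
        segments.append((seg_lo, seg_hi))
        covered_until = -1
        for lo, hi in segments:
            if hi <= covered_until:
                continue
            qs, qe, ident, score = _extend(q, s, lo, hi, diag, params)
            covered_until = max(covered_until, qe)
            if qe - qs >= params.min_hsp_len and ident >= params.min_identity_pct:
                out.append((qs, qe, diag, ident, score))
    return out


def align_pair(a_id: str, a_seq: str, b_id: str, b_seq: str,
               params: Optional[AlignParams] = None,
               b_index: Optional[dict] = None,
               b_rc_index: Optional[dict] = None) -> list[HSP]:
    """All HSPs between two sequences in both orientations, sorted by
    score descending.  Precomputed k-mer indexes of the subject (plus and
    minus strand) may be passed to amortize all-vs-all searches."""
    if not a_seq or not b_seq:
        raise ValueError("sequences must be non-empty")
    params = params or AlignParams()
    hsps: list[HSP] = []

    if b_index is None:
        b_index = _kmer_index(b_seq, params.k)
    for qs, qe, diag, ident, score in _diagonal_hsps(a_seq, b_seq, b_index, params):
        hsps.append(HSP(a_id, b_id, qs, qe, qs - diag, qe - diag,
                        FORWARD, ident, score))

    b_rc = revcomp(b_seq)
    if b_rc_index is None:
        b_rc_index = _kmer_index(b_rc, params.k)
    n = len(b_seq)
    for qs, qe, diag, ident, score in _diagonal_hsps(a_seq, b_rc, b_rc_index, params):
        # map [qs-diag, qe-diag) on the minus strand back to plus-strand coords
        hsps.append(HSP(a_id, b_id, qs, qe, n - (qe - diag), n - (qs - diag),
                        REVERSE, ident, score))
    hsps.sort(key=lambda h: (-h.score, h.q_start, h.s_start))
    return hsps


# ---------------------------------------------------------------------------
# BLAST outfmt-6 interchange (1-based inclusive coordinates in the file)

BLAST6_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                  "qstart", "qend", "sstart", "send", "evalue", "bitscore")


def read_blast6(path: str | Path) -> list[HSP]:
    hsps = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"line {line_no}: expected 12 tab-separated columns")
            (qid, sid, pident, _length, _mm, _go,
             qstart, qend, sstart, send, _evalue, bitscore) = fields[:12]
            qs, qe = int(qstart), int(qend)
            ss, se = int(sstart), int(send)
            orientation = FORWARD if ss <= se else REVERSE
            hsps.append(HSP(qid, sid,
                            min(qs, qe) - 1, max(qs, qe),
                            min(ss, se) - 1, max(ss, se),
                            orientation, float(pident), float(bitscore)))
    return hsps


def write_blast6(hsps: Iterable[HSP], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hsps:
            if h.orientation == FORWARD:
                ss, se = h.s_start + 1, h.s_end
            else:
                ss, se = h.s_end, h.s_start + 1
            mism = round(h.q_span * (1 - h.identity_pct / 100.0))
            fh.write("\t".join(map(str, (
                h.query_id, h.subject_id, f"{h.identity_pct:.2f}", h.q_span, mism, 0,
                h.q_start + 1, h.q_end, ss, se, "0.0", f"{h.score:.1f}"))) + "\n")
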