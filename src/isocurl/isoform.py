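"""Full-length read classification, trimming, and redundancy removal.

A long read is *full-length* (FL) when it carries the 5' cDNA primer near
its 5' end, a poly(A) tail, and the (reverse-complemented) 3' primer near
its 3' end; an extra interior primer copy marks a chimera.  FL bodies are
trimmed of primers and tail, then collapsed into a non-redundant set by
greedy longest-first clustering at a global-alignment identity threshold.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from ._util import revcomp, summarize_percentage  # noqa: F401  (re-exported)
from .io import Transcript

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


# ---------------------------------------------------------------------------
# full-length classification


@dataclass
class FLClassification:
    read_id: str
    status: str  # FL | missing_polyA | missing_primer | chimera
    trim_start: int = 0  # 0-based half-open body coordinates on the read
    trim_end: int = 0
    strand: str = "+"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _match_positions(seq: np.ndarray, primer: np.ndarray, max_mismatch: int,
                     lo: int, hi: int) -> list[tuple[int, int]]:
    """(start, mismatches) of primer occurrences with start in [lo, hi]."""
    m = len(primer)
    lo = max(lo, 0)
    hi = min(hi, len(seq) - m)
    if hi < lo:
        return []
    window = np.lib.stride_tricks.sliding_window_view(seq[lo:hi + m], m)
    mism = (window != primer).sum(axis=1)
    return [(lo + int(i), int(mism[i])) for i in np.flatnonzero(mism <= max_mismatch)]


def _best_match(seq, primer, max_mismatch, lo, hi) -> Optional[tuple[int, int]]:
    hits = _match_positions(seq, primer, max_mismatch, lo, hi)
    return min(hits, key=lambda t: (t[1], t[0])) if hits else None


def _polya_run(seq: str, end: int, max_interruptions: int = 1) -> int:
    """Length of the A-run ending at ``end`` (exclusive), tolerating up to
    ``max_interruptions`` single non-A bases inside the run.  Returns the
    start index of the run (== end if there is no run)."""
    i = end
    interruptions = 0
    start = end
    while i > 0:
        if seq[i - 1] == "A":
            i -= 1
            start = i
        elif interruptions < max_interruptions and i - 1 > 0 and seq[i - 2] == "A":
            interruptions += 1
            i -= 1
        else:
            break
    return start


def _classify_oriented(seq: str, primer5: str, primer3: str, min_polya: int,
                       max_mismatch_frac: float) -> Optional[FLClassification]:
    """Classify one orientation; returns None when neither primer is found."""
    p5 = _encode(primer5)
    p3rc = _encode(revcomp(primer3))
    arr = _encode(seq)
    k5 = math.ceil(max_mismatch_frac * len(p5))
    k3 = math.ceil(max_mismatch_frac * len(p3rc))
    slack = 10  # primers may sit a few bases in from the read ends

    hit5 = _best_match(arr, p5, k5, 0, slack)
    hit3 = _best_match(arr, p3rc, k3, len(arr) - len(p3rc) - slack, len(arr) - len(p3rc))
    if hit5 is None and hit3 is None:
        return None
    if hit5 is None or hit3 is None:
        return FLClassification("", "missing_primer")

    body_start = hit5[0] + len(p5)
    p3_start = hit3[0]
    # an interior copy of either primer marks a chimeric read
    interior_lo = body_start + 5
    interior_hi = p3_start - 5
    for primer in (p5, p3rc):
        if _match_positions(arr, primer, math.ceil(max_mismatch_frac * len(primer)),
                            interior_lo, interior_hi - len(primer)):
            return FLClassification("", "chimera")

    tail_start = _polya_run(seq, p3_start)
    n_a = sum(1 for b in seq[tail_start:p3_start] if b == "A")
    if n_a < min_polya:
        return FLClassification("", "missing_polyA")
    return FLClassification("", "FL", trim_start=body_start, trim_end=tail_start)


_STATUS_PRIORITY = {"FL": 0, "chimera": 1, "missing_polyA": 2, "missing_primer": 3}


def classify_full_length(read_id: str, seq: str, primer5: str, primer3: str,
                         min_polya: int = 20,
                         max_mismatch_frac: float = 0.1) -> FLClassification:
    """Classify a read as FL / missing_polyA / missing_primer / chimera.

    Both orientations are searched; trim coordinates are reported on the
    original read (for strand '-', the body is the reverse complement of
    ``seq[trim_start:trim_end]``).  Primer matching tolerates up to
    ``ceil(max_mismatch_frac * primer_len)`` substitutions; pass 0 for
    exact matching.
    """
    if not primer5 or not primer3:
        raise ValueError("primers must be non-empty")
    if len(seq) < len(primer5) + len(primer3):
        return FLClassification(read_id, "missing_primer")

    best: Optional[FLClassification] = None
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        res = _classify_oriented(oriented, primer5, primer3, min_polya, max_mismatch_frac)
        if res is None:
            continue
        res.read_id = read_id
        res.strand = strand
        if strand == "-" and res.status == "FL":
            res.trim_start, res.trim_end = len(seq) - res.trim_end, len(seq) - res.trim_start
        if best is None or _STATUS_PRIORITY[res.status] < _STATUS_PRIORITY[best.status]:
            best = res
        if best.status == "FL":
            break
    if best is None:
        best = FLClassification(read_id, "missing_primer")
    return best


def extract_body(seq: str, cls: FLClassification) -> str:
    """The trimmed, sense-strand body of an FL read."""
    if cls.status != "FL":
        raise ValueError("only FL reads have a trimmed body")
    body = seq[cls.trim_start:cls.trim_end]
    return revcomp(body) if cls.strand == "-" else body


# ---------------------------------------------------------------------------
# greedy identity clustering


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    identity_to_rep: dict[str, float] = field(default_factory=dict)


def global_identity(a: str, b: str) -> float:
    """Fraction of identical columns in a global (Needleman-Wunsch)
    alignment; the denominator includes gap columns."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    columns = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches / columns if columns else 0.0


def cluster_transcripts(transcripts: Sequence[Transcript],
                        threshold: float = 0.99) -> list[Cluster]:
    """Greedy longest-first clustering at a global-identity threshold.

    Sequences are visited longest first (ties by input order); each joins
    the first existing cluster whose *representative* it matches at
    identity >= threshold, else founds a new cluster.  Representatives
    form the non-redundant set.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(range(len(transcripts)), key=lambda i: (-len(transcripts[i].seq), i))
    clusters: list[Cluster] = []
    reps: list[Transcript] = []
    for i in order:
        t = transcripts[i]
        placed = False
        for cl, rep in zip(clusters, reps):
            # identity <= min_len / max_len: skip pairs that cannot reach threshold
            if len(t.seq) < threshold * len(rep.seq):
                continue
            ident = global_identity(t.seq, rep.seq)
            if ident >= threshold:
                cl.member_ids.append(t.id)
                cl.identity_to_rep[t.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(Cluster(t.id, [t.id], {t.id: 1.0}))
            reps.append(t)
    return clusters


# ---------------------------------------------------------------------------
# length-bin summaries

LENGTH_BIN_EDGES = (0, 1000, 2000, 3000, 4000)
LENGTH_BIN_LABELS = ("0-1kb", "1-2kb", "2-3kb", "3-4kb", ">=4kb")


@dataclass
class LengthBinSummary:
    counts: dict[str, int]
    mean_lengths: dict[str, Optional[float]]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def length_bin_summary(lengths: Iterable[int]) -> LengthBinSummary:
    """Half-open kilobase bins [0,1k), [1,2k), [2,3k), [3,4k), [4k, inf)."""
    sums = {lab: 0 for lab in LENGTH_BIN_LABELS}
    counts = {lab: 0 for lab in LENGTH_BIN_LABELS}
    for length in lengths:
        if length <= 0:
            raise ValueError("lengths must be positive")
        idx = min(length // 1000, 4)
        lab = LENGTH_BIN_LABELS[idx]
        counts[lab] += 1
        sums[lab] += length
    means = {lab: (sums[lab] / counts[lab] if counts[lab] else None)
             for lab in LENGTH_BIN_LABELS}
    return LengthBinSummary(counts, means)
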