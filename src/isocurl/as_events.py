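"""Candidate alternative-splicing events from two-HSP alignment geometry.

A transcript pair is a candidate AS product when its local alignment
contains two HSPs in the same orientation such that one sequence is
continuous across the HSP junction (inter-HSP distance smaller than 5 bp
in magnitude, i.e. a sub-5 bp overlap or gap) while the other shows a
distinct *AS gap*: an unaligned interval longer than 100 bp lying at
least 100 bp from both sequence ends.  The continuous sequence must in
addition align nearly fully (default >= 95% of its length covered by the
two HSPs).  In transcript space this signature corresponds to an exon
skip or intron retention difference between two isoforms of one gene,
without distinguishing the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

from .align import FORWARD, AlignParams, HSP, _kmer_index, align_pair
from ._util import revcomp
from .io import Transcript


@dataclass
class ASParams:
    max_overlap_bp: int = 5        # exclusive: |junction distance| < 5 is "continuous"
    min_gap_bp: int = 100          # exclusive: the AS gap must exceed 100 bp
    min_end_distance_bp: int = 100  # inclusive: gap at least 100 bp from either end
    min_continuous_coverage: float = 0.95
    # greedy extension lets both HSPs claim the same junction-adjacent bases
    # when gap-flanking sequence matches by chance; doubly-covered overlaps up
    # to this size are trimmed from the second HSP before the rule is applied,
    # larger overlaps disqualify the pair (real duplicated structure)
    hsp_overlap_trim_bp: int = 20

    def __post_init__(self) -> None:
        if min(self.max_overlap_bp, self.min_gap_bp, self.min_end_distance_bp) < 0:
            raise ValueError("AS thresholds must be non-negative")


@dataclass
class ASEvent:
    continuous_id: str
    gapped_id: str
    gap_start: int  # 0-based half-open, on the gapped sequence
    gap_end: int
    hsp_pair: tuple[HSP, HSP] = field(default=None, repr=False, compare=False)

    @property
    def gap_len(self) -> int:
        return self.gap_end - self.gap_start


def _span_union(a: tuple[int, int], b: tuple[int, int]) -> int:
    (a0, a1), (b0, b1) = sorted((a, b))
    if b0 >= a1:
        return (a1 - a0) + (b1 - b0)
    return max(a1, b1) - a0


def _reconcile_overlap(h1: HSP, h2: HSP, params: ASParams) -> Optional[HSP]:
    """Trim bases of h2 that h1 already covers on either sequence.

    Returns the (possibly trimmed) second HSP, or None when the overlap
    exceeds the trim budget or consumes h2 entirely.
    """
    overlap_q = h1.q_end - h2.q_start
    if h1.orientation == FORWARD:
        overlap_s = h1.s_end - h2.s_start
    else:
        overlap_s = h2.s_end - h1.s_start
    trim = max(overlap_q, overlap_s, 0)
    if trim == 0:
        return h2
    if trim > params.hsp_overlap_trim_bp or trim >= h2.q_span:
        return None
    if h2.orientation == FORWARD:
        return HSP(h2.query_id, h2.subject_id, h2.q_start + trim, h2.q_end,
                   h2.s_start + trim, h2.s_end, h2.orientation,
                   h2.identity_pct, h2.score)
    return HSP(h2.query_id, h2.subject_id, h2.q_start + trim, h2.q_end,
               h2.s_start, h2.s_end - trim, h2.orientation,
               h2.identity_pct, h2.score)


def _evaluate_pair(h1: HSP, h2: HSP, len_q: int, len_s: int,
                   params: ASParams) -> Optional[ASEvent]:
    """Evaluate an ordered (by query start) same-orientation HSP pair."""
    trimmed = _reconcile_overlap(h1, h2, params)
    if trimmed is None:
        return None
    h2 = trimmed
    dist_q = h2.q_start - h1.q_end
    if h1.orientation == FORWARD:
        dist_s = h2.s_start - h1.s_end
        s_gap = (h1.s_end, h2.s_start)
    else:  # query ascends while plus-strand subject coordinates descend
        dist_s = h1.s_start - h2.s_end
        s_gap = (h2.s_end, h1.s_start)
    q_gap = (h1.q_end, h2.q_start)

    def continuous(dist: int) -> bool:
        return -params.max_overlap_bp < dist < params.max_overlap_bp

    def distinct_gap(dist: int, gap: tuple[int, int], length: int) -> bool:
        return (dist > params.min_gap_bp
                and gap[0] >= params.min_end_distance_bp
                and length - gap[1] >= params.min_end_distance_bp)

    q_cov = _span_union((h1.q_start, h1.q_end), (h2.q_start, h2.q_end)) / len_q
    s_cov = _span_union((h1.s_start, h1.s_end), (h2.s_start, h2.s_end)) / len_s

    if (continuous(dist_q) and distinct_gap(dist_s, s_gap, len_s)
            and q_cov >= params.min_continuous_coverage):
        return ASEvent(h1.query_id, h1.subject_id, s_gap[0], s_gap[1], (h1, h2))
    if (continuous(dist_s) and distinct_gap(dist_q, q_gap, len_q)
            and s_cov >= params.min_continuous_coverage):
        return ASEvent(h1.subject_id, h1.query_id, q_gap[0], q_gap[1], (h1, h2))
    return None


def classify_as_event(hsps: Sequence[HSP], len_q: int, len_s: int,
                      params: Optional[ASParams] = None) -> Optional[ASEvent]:
    """Call at most one AS event from the HSPs of a single transcript pair.

    All ordered same-orientation HSP pairs are evaluated; the
    highest-scoring qualifying pair wins.  Fewer than two HSPs yield no
    event (not an error).
    """
    params = params or ASParams()
    best: Optional[tuple[float, ASEvent]] = None
    for a, b in combinations(hsps, 2):
        if a.orientation != b.orientation:
            continue
        h1, h2 = (a, b) if a.q_start <= b.q_start else (b, a)
        event = _evaluate_pair(h1, h2, len_q, len_s, params)
        if event is not None:
            score = h1.score + h2.score
            if best is None or score > best[0]:
                best = (score, event)
    return best[1] if best else None


def call_as_events(transcripts: Sequence[Transcript],
                   as_params: Optional[ASParams] = None,
                   align_params: Optional[AlignParams] = None) -> list[ASEvent]:
    """Align all unordered transcript pairs and call AS candidates.

    Each pair contributes at most one event; output is sorted by
    (continuous_id, gapped_id) for determinism.
    """
    if len(transcripts) < 2:
        return []
    as_params = as_params or ASParams()
    align_params = align_params or AlignParams()
    k = align_params.k
    fwd_index = {t.id: _kmer_index(t.seq, k) for t in transcripts}
    rc_index = {t.id: _kmer_index(revcomp(t.seq), k) for t in transcripts}
    events = []
    for a, b in combinations(transcripts, 2):
        hsps = align_pair(a.id, a.seq, b.id, b.seq, align_params,
                          b_index=fwd_index[b.id], b_rc_index=rc_index[b.id])
        if len(hsps) < 2:
            continue
        event = classify_as_event(hsps, len(a.seq), len(b.seq), as_params)
        if event is not None:
            events.append(event)
    events.sort(key=lambda e: (e.continuous_id, e.gapped_id))
    return events


def write_events_tsv(events: Sequence[ASEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("continuous_id\tgapped_id\tgap_start\tgap_end\tgap_len\n")
        for e in events:
            fh.write(f"{e.continuous_id}\t{e.gapped_id}\t{e.gap_start}\t{e.gap_end}\t{e.gap_len}\n")
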