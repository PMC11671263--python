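"""Perfect and compound microsatellite (SSR) detection.

Finds maximal perfect tandem repeats of 1-6 bp motifs meeting per-length
minimum repeat counts (defaults 10, 6, 5, 5, 5, 5 — the conventional
definition for transcriptome surveys), then merges neighbouring loci
separated by at most 100 bp of interruption into compound records:
category ``c`` when members are adjacent, ``c*`` when they overlap.
Only transcripts longer than 500 bp are scanned.  Motifs are reported as
the lexicographically smallest rotation of the repeat unit; transcripts
are stranded, so no reverse-complement folding is applied.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io import Transcript

DEFAULT_MIN_REPEATS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

PERFECT_CATEGORIES = ("p1", "p2", "p3", "p4", "p5", "p6")
ALL_CATEGORIES = PERFECT_CATEGORIES + ("c", "c*")


@dataclass
class SSRThresholds:
    min_repeats: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))
    max_interruption_bp: int = 100
    min_transcript_len: int = 500

    def __post_init__(self) -> None:
        if set(self.min_repeats) != set(range(1, 7)) or min(self.min_repeats.values()) < 1:
            raise ValueError("min_repeats must map motif lengths 1..6 to positive counts")


@dataclass
class SSRLocus:
    transcript_id: str
    start: int  # 0-based half-open
    end: int
    motif: str
    n_repeats: int
    category: str
    members: tuple = ()  # perfect member loci, for compound records


def canonical_motif(unit: str) -> str:
    """Lexicographically smallest rotation of the repeat unit."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    """True when the unit is not itself a repetition of a shorter unit."""
    n = len(unit)
    return not any(n % d == 0 and unit == unit[:d] * (n // d)
                   for d in range(1, n))


def find_perfect_ssrs(transcript: Transcript,
                      thresholds: Optional[SSRThresholds] = None) -> list[SSRLocus]:
    """All maximal perfect tandem repeats of unit length 1..6.

    A locus is reported at its smallest period (a periodic unit such as
    ``ATAT`` is never a motif) and at the leftmost phase of its run, so
    each run yields exactly one record.  Runs cover whole units only;
    trailing partial units are not counted.
    """
    thresholds = thresholds or SSRThresholds()
    seq = transcript.seq
    if any(b not in "ACGTN" for b in seq):
        raise ValueError(f"{transcript.id}: non-ACGTN alphabet")
    if len(seq) <= thresholds.min_transcript_len:
        return []
    loci: list[SSRLocus] = []
    n = len(seq)
    for m in range(1, 7):
        min_rep = thresholds.min_repeats[m]
        i = 0
        while i + m * min_rep <= n:
            # leftmost phase: position i must break the period with i-1
            if i > 0 and seq[i - 1] == seq[i - 1 + m]:
                i += 1
                continue
            unit = seq[i:i + m]
            if "N" in unit or not _is_primitive(unit):
                i += 1
                continue
            # count whole-unit tandem repeats starting at i
            j = i + m
            while j + m <= n and seq[j:j + m] == unit:
                j += m
            k = (j - i) // m
            if k >= min_rep:
                loci.append(SSRLocus(transcript.id, i, i + k * m,
                                     canonical_motif(unit), k, f"p{m}"))
                i = j  # a maximal run yields one record; resume past it
            else:
                i += 1
    loci.sort(key=lambda l: (l.start, l.end))
    return loci


def merge_compound(loci: Sequence[SSRLocus],
                   thresholds: Optional[SSRThresholds] = None) -> list[SSRLocus]:
    """Merge perfect loci separated by <= max_interruption_bp into
    compound records (``c``; ``c*`` when members overlap).  Member loci
    are consumed by the compound, so every repeat run is counted once."""
    thresholds = thresholds or SSRThresholds()
    ordered = sorted(loci, key=lambda l: (l.start, l.end))
    out: list[SSRLocus] = []
    i = 0
    while i < len(ordered):
        chain = [ordered[i]]
        chain_end = ordered[i].end
        overlapping = False
        j = i + 1
        while j < len(ordered):
            gap = ordered[j].start - chain_end
            if gap > thresholds.max_interruption_bp:
                break
            overlapping = overlapping or gap < 0
            chain.append(ordered[j])
            chain_end = max(chain_end, ordered[j].end)
            j += 1
        if len(chain) == 1:
            out.append(chain[0])
        else:
            out.append(SSRLocus(
                chain[0].transcript_id,
                chain[0].start, max(l.end for l in chain),
                "+".join(l.motif for l in chain),
                sum(l.n_repeats for l in chain),
                "c*" if overlapping else "c",
                members=tuple(chain)))
        i = j
    return out


def find_ssrs(transcripts: Iterable[Transcript],
              thresholds: Optional[SSRThresholds] = None,
              compound: bool = True) -> list[SSRLocus]:
    """Scan a transcript set; returns perfect and (optionally) compound loci."""
    thresholds = thresholds or SSRThresholds()
    out: list[SSRLocus] = []
    for t in transcripts:
        perfect = find_perfect_ssrs(t, thresholds)
        out.extend(merge_compound(perfect, thresholds) if compound else perfect)
    return out


def category_counts(loci: Iterable[SSRLocus]) -> Counter:
    return Counter(l.category for l in loci)


def category_total(counts: dict[str, int]) -> int:
    """Total SSR records across the eight categories (the categories
    partition the detected set, so the total is their plain sum)."""
    unknown = set(counts) - set(ALL_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown SSR categories: {sorted(unknown)}")
    return sum(counts.values())


def ssr_density(loci: Iterable[SSRLocus], total_scanned_bp: int) -> dict[str, float]:
    """Per-category density in sites per Mb of scanned sequence."""
    if total_scanned_bp <= 0:
        raise ValueError("total_scanned_bp must be positive")
    counts = category_counts(loci)
    return {cat: counts.get(cat, 0) / (total_scanned_bp / 1e6) for cat in ALL_CATEGORIES}


def write_ssr_tsv(loci: Sequence[SSRLocus], path) -> None:
    """TSV with 1-based inclusive coordinates (stated in the header)."""
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("transcript_id\tcategory\tmotif\tn_repeats\tstart\tend\n")
        for l in sorted(loci, key=lambda l: (l.transcript_id, l.start)):
            fh.write(f"{l.transcript_id}\t{l.category}\t{l.motif}\t{l.n_repeats}"
                     f"\t{l.start + 1}\t{l.end}\n")
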