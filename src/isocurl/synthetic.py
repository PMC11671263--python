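"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator works entirely in transcript space (no genome): gene
models are lists of exon lengths, isoforms are exon concatenations, and
alternative-splicing pairs differ by one contiguous internal segment.
Long reads carry the 5' cDNA primer, the transcript body, a poly(A)
tail, and the reverse-complemented 3' primer, with configurable
fractions of degenerate reads (missing tail, missing primer, chimeric
two-body reads with an interior primer copy) and substitution-only
noise, so that planted truth coordinates stay exact.  Count matrices
follow a negative-binomial model over the full 2 organs x 4 stages x 3
replicates design, with a planted excess of sepal-upregulated genes
mirroring the strong up-bias observed in curled-sepal contrasts.

Every output is a pure function of ``SimConfig.seed``; each stage draws
from its own named substream so outputs are byte-stable when unrelated
stages are reconfigured.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import mutate_substitutions, random_dna, revcomp, stream_rng
from .io import FastqRead, Transcript
from .ssr import SSRLocus, canonical_motif, _is_primitive

FL_STATUSES = ("FL", "missing_polyA", "missing_primer", "chimera")

_STREAM = {"genes": 1, "isoforms": 2, "reads": 3, "ssr": 4, "counts": 5,
           "coding": 6, "terms": 7, "morpho": 8}


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    The defaults describe the conditions the pipeline is validated
    under: ~24% of long reads degenerate (so the full-length yield
    matches the ~76% seen in real library classifications), a 0.5%
    substitution error rate typical of polished long reads, skipped
    segments straddling the 100 bp AS-gap threshold, and a differential
    signal where ~73% of planted DEGs are sepal-upregulated.
    """

    seed: int = 0
    n_genes: int = 60
    exon_count_range: tuple[int, int] = (2, 8)
    exon_len_range: tuple[int, int] = (150, 500)
    # alternative splicing
    frac_as_genes: float = 0.2
    skip_len_range: tuple[int, int] = (120, 300)
    min_flank: int = 150
    # full-length reads
    primer5: str = "AAGCAGTGGTATCAACGCAG"
    primer3: str = "GTACTCTGCGTTGATACCAC"
    polya_len: int = 30
    reads_per_transcript: int = 3
    frac_missing_polya: float = 0.08
    frac_missing_primer: float = 0.10
    frac_chimera: float = 0.06
    error_rate: float = 0.005
    # count matrix design: organs x stages x replicates
    n_stages: int = 4
    n_replicates: int = 3
    frac_up: float = 0.073
    frac_down: float = 0.027
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.1
    base_mean_log_mu: float = 4.0
    base_mean_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must not exceed 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not self.primer5 or not self.primer3 or self.primer5 == self.primer3:
            raise ValueError("primers must be non-empty and distinct")

    def rng(self, stream: str) -> np.random.Generator:
        return stream_rng(self.seed, _STREAM[stream])


@dataclass
class GeneModel:
    gene_id: str
    exon_lengths: list[int]

    @property
    def length(self) -> int:
        return sum(self.exon_lengths)


@dataclass
class TruthSet:
    """Planted ground truth for all generated artifacts."""

    as_events: list[dict] = field(default_factory=list)
    ssr_loci: list[SSRLocus] = field(default_factory=list)
    de_genes: list[dict] = field(default_factory=list)
    fl_status: dict[str, str] = field(default_factory=dict)
    read_source: dict[str, str] = field(default_factory=dict)


def generate_gene_models(cfg: SimConfig) -> list[GeneModel]:
    """Exon-length skeletons; >=2 exons each so every gene is AS-capable."""
    rng = cfg.rng("genes")
    lo, hi = cfg.exon_count_range
    models = []
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        n_exons = int(rng.integers(max(lo, 2), hi + 1))
        lengths = [int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
                   for _ in range(n_exons)]
        models.append(GeneModel(f"g{i:0{width}d}", lengths))
    return models


_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in {"TAA", "TAG", "TGA"}]
_CODON_WEIGHTS = np.array([1.0 + 2.0 * sum(x in "GC" for x in cod)
                           for cod in _SENSE_CODONS])
_CODON_WEIGHTS /= _CODON_WEIGHTS.sum()


def biased_codon_seq(rng: np.random.Generator, n_codons: int) -> str:
    """Stop-free codon sequence from a GC-skewed codon usage — the
    learnable signal behind the hexamer coding model."""
    return "".join(rng.choice(_SENSE_CODONS, size=n_codons, p=_CODON_WEIGHTS))


def _transcript_seq(rng: np.random.Generator, length: int,
                    forbidden: Sequence[str]) -> str:
    """mRNA-shaped sequence: random UTRs around a codon-biased ORF
    (ATG .. TAA) when the length allows one, screened against primer
    sequences."""
    while True:
        utr_len = max(30, int(0.15 * length))
        n_codons = (length - 2 * utr_len - 6) // 3
        if n_codons < 40:
            seq = random_dna(rng, length)
        else:
            cds = "ATG" + biased_codon_seq(rng, n_codons) + "TAA"
            utr3 = random_dna(rng, length - utr_len - len(cds))
            seq = random_dna(rng, utr_len) + cds + utr3
        if not any(f in seq for f in forbidden):
            return seq


def generate_isoform_pairs(models: Sequence[GeneModel], cfg: SimConfig,
                           truth: Optional[TruthSet] = None
                           ) -> tuple[list[Transcript], TruthSet]:
    """Transcript sequences; AS genes contribute an isoform pair that
    differs by one internal contiguous segment.

    Truth records the skipped segment's position on the containing
    isoform and a ``detectable`` flag (gap > 100 bp and both end
    distances >= 100 bp — the AS caller's thresholds reached by
    construction, not by tuning).
    """
    truth = truth or TruthSet()
    rng = cfg.rng("isoforms")
    forbidden = [cfg.primer5, revcomp(cfg.primer5),
                 cfg.primer3, revcomp(cfg.primer3)]
    n_as = round(cfg.frac_as_genes * len(models))
    skip_lo, skip_hi = cfg.skip_len_range
    eligible = [i for i, m in enumerate(models)
                if m.length >= skip_lo + 2 * cfg.min_flank]
    if n_as > len(eligible):
        raise ValueError(
            f"skip range incompatible with exon structure: only {len(eligible)} "
            f"of {len(models)} genes can host a >= {skip_lo} bp skip with "
            f"{cfg.min_flank} bp flanks, {n_as} AS genes requested")
    as_ids = (set(np.asarray(eligible)[rng.choice(len(eligible), size=n_as,
                                                  replace=False)])
              if n_as else set())
    transcripts: list[Transcript] = []
    for idx, model in enumerate(models):
        seq = _transcript_seq(rng, model.length, forbidden)
        full_id = f"{model.gene_id}.iso1"
        transcripts.append(Transcript(full_id, seq))
        if idx not in as_ids:
            continue
        max_skip = len(seq) - 2 * cfg.min_flank
        skip_len = int(rng.integers(skip_lo, min(skip_hi, max_skip) + 1))
        gap_start = int(rng.integers(cfg.min_flank, len(seq) - skip_len - cfg.min_flank + 1))
        alt_id = f"{model.gene_id}.iso2"
        alt_seq = seq[:gap_start] + seq[gap_start + skip_len:]
        transcripts.append(Transcript(alt_id, alt_seq))
        detectable = (skip_len > 100 and gap_start >= 100
                      and len(seq) - (gap_start + skip_len) >= 100)
        truth.as_events.append({
            "transcript_id_a": full_id, "transcript_id_b": alt_id,
            "gap_start": gap_start, "gap_len": skip_len,
            "detectable": detectable,
        })
    return transcripts, truth


@dataclass
class SSRInsert:
    transcript_id: str
    position: int
    motif: str
    n_repeats: int


def embed_ssrs(transcripts: Sequence[Transcript], inserts: Sequence[SSRInsert],
               truth: Optional[TruthSet] = None) -> tuple[list[Transcript], TruthSet]:
    """Overwrite transcript bases with perfect repeat runs at recorded
    positions.

    Insertion is by replacement, so all other planted coordinates on the
    transcript stay valid.  The flanking bases are adjusted to break the
    repeat period on both sides, making each planted locus maximal.
    """
    truth = truth or TruthSet()
    by_id = {t.id: list(t.seq) for t in transcripts}
    for ins in inserts:
        m = len(ins.motif)
        if not 1 <= m <= 6:
            raise ValueError(f"motif length {m} outside 1..6")
        if not _is_primitive(ins.motif):
            raise ValueError(f"motif {ins.motif!r} is itself periodic")
        seq = by_id[ins.transcript_id]
        run = ins.motif * ins.n_repeats
        lo, hi = ins.position, ins.position + len(run)
        if lo < 1 or hi + 1 > len(seq):
            raise ValueError(f"run [{lo},{hi}) leaves no flank inside "
                             f"{ins.transcript_id} of length {len(seq)}")
        seq[lo:hi] = run
        # break the period one base on each side so the truth locus is maximal
        seq[lo - 1] = _breaking_base(ins.motif[-1])
        seq[hi] = _breaking_base(ins.motif[0])
        truth.ssr_loci.append(SSRLocus(ins.transcript_id, lo, hi,
                                       canonical_motif(ins.motif), ins.n_repeats,
                                       f"p{m}"))
    return [Transcript(t.id, "".join(by_id[t.id])) for t in transcripts], truth


def _breaking_base(base: str) -> str:
    return "C" if base != "C" else "G"


def random_ssr_inserts(transcripts: Sequence[Transcript], n: int,
                       rng: np.random.Generator,
                       motifs: Sequence[str] = ("A", "AG", "AAG", "AGAT", "AACGT", "AACGTG"),
                       n_repeats_range: tuple[int, int] = (10, 16),
                       exclude_ids: Optional[set[str]] = None) -> list[SSRInsert]:
    """Random insert specs on distinct transcripts long enough to host
    them; transcripts in ``exclude_ids`` (e.g. members of planted AS
    pairs, whose sequences must stay aligned) are skipped."""
    inserts = []
    exclude = exclude_ids or set()
    eligible = [t for t in transcripts if len(t.seq) > 600 and t.id not in exclude]
    chosen = rng.choice(len(eligible), size=min(n, len(eligible)), replace=False)
    for idx in chosen:
        t = eligible[int(idx)]
        motif = motifs[int(rng.integers(0, len(motifs)))]
        reps = int(rng.integers(*n_repeats_range))
        span = len(motif) * reps
        pos = int(rng.integers(1, len(t.seq) - span - 1))
        inserts.append(SSRInsert(t.id, pos, motif, reps))
    return inserts


def generate_fl_reads(transcripts: Sequence[Transcript], cfg: SimConfig,
                      truth: Optional[TruthSet] = None
                      ) -> tuple[list[FastqRead], TruthSet]:
    """Long reads per transcript with planted FL-status truth labels.

    Proper FL reads are primer5 + body + poly(A) + revcomp(primer3);
    degenerate classes drop the tail, drop the 5' primer, or join two
    bodies around an interior primer copy.  Half the reads are emitted
    on the minus strand; substitution noise at ``error_rate``.
    """
    truth = truth or TruthSet()
    rng = cfg.rng("reads")
    p_fl = 1.0 - cfg.frac_missing_polya - cfg.frac_missing_primer - cfg.frac_chimera
    if p_fl < 0:
        raise ValueError("degenerate read fractions exceed 1")
    probs = [p_fl, cfg.frac_missing_polya, cfg.frac_missing_primer, cfg.frac_chimera]
    reads: list[FastqRead] = []
    counter = 0
    for t in transcripts:
        for _ in range(cfg.reads_per_transcript):
            status = FL_STATUSES[int(rng.choice(4, p=probs))]
            tail = "A" * cfg.polya_len
            p3rc = revcomp(cfg.primer3)
            if status == "FL":
                seq = cfg.primer5 + t.seq + tail + p3rc
            elif status == "missing_polyA":
                seq = cfg.primer5 + t.seq + p3rc
            elif status == "missing_primer":
                seq = t.seq + tail + p3rc
            else:  # chimera: two bodies joined by an interior 5' primer copy
                other = transcripts[int(rng.integers(0, len(transcripts)))]
                seq = cfg.primer5 + t.seq + cfg.primer5 + other.seq + tail + p3rc
            seq = mutate_substitutions(rng, seq, cfg.error_rate)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            read_id = f"read{counter:06d}"
            counter += 1
            quals = list(rng.integers(25, 41, size=len(seq)))
            reads.append(FastqRead(read_id, seq, [int(q) for q in quals]))
            truth.fl_status[read_id] = status
            truth.read_source[read_id] = t.id
    return reads, truth


def generate_count_matrix(cfg: SimConfig, truth: Optional[TruthSet] = None,
                          gene_ids: Optional[Sequence[str]] = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Negative-binomial counts over the organ x stage x replicate design.

    Planted up/down genes carry an organ effect of +/- ``lfc_magnitude``
    log2 units on the sepal mean; all other genes share means across
    organs.  Returns (counts, design, truth).
    """
    truth = truth or TruthSet()
    rng = cfg.rng("counts")
    genes = list(gene_ids) if gene_ids is not None else [
        f"g{i:0{len(str(cfg.n_genes))}d}" for i in range(cfg.n_genes)]
    n = len(genes)
    n_up = round(cfg.frac_up * n)
    n_down = round(cfg.frac_down * n)
    planted = rng.choice(n, size=n_up + n_down, replace=False)
    lfc = np.zeros(n)
    lfc[planted[:n_up]] = cfg.lfc_magnitude
    lfc[planted[n_up:]] = -cfg.lfc_magnitude

    base = rng.lognormal(cfg.base_mean_log_mu, cfg.base_mean_log_sd, size=n)
    organ_mean = {"sepal": base * 2.0 ** lfc, "petal": base}

    samples = []
    for organ in ("sepal", "petal"):
        for stage in range(1, cfg.n_stages + 1):
            for rep in range(1, cfg.n_replicates + 1):
                samples.append((f"{organ}_s{stage}_r{rep}", organ, stage, rep))
    design = pd.DataFrame(samples, columns=["sample", "organ", "stage", "replicate"]
                          ).set_index("sample")

    r = 1.0 / cfg.nb_dispersion  # NB size parameter; variance = mu + alpha mu^2
    cols = {}
    for sample, organ, _stage, _rep in samples:
        mu = organ_mean[organ]
        cols[sample] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(cols, index=genes)

    for idx in planted[:n_up]:
        truth.de_genes.append({"gene_id": genes[int(idx)], "direction": "up",
                               "log2fc": cfg.lfc_magnitude})
    for idx in planted[n_up:]:
        truth.de_genes.append({"gene_id": genes[int(idx)], "direction": "down",
                               "log2fc": -cfg.lfc_magnitude})
    return counts, design, truth


def generate_term_annotations(gene_ids: Sequence[str], truth: TruthSet,
                              cfg: SimConfig, n_terms: int = 20,
                              term_size: int = 25) -> pd.DataFrame:
    """Random term-to-gene table plus one term enriched in planted DEGs."""
    rng = cfg.rng("terms")
    rows = []
    for i in range(n_terms):
        size = min(term_size, len(gene_ids))
        for idx in rng.choice(len(gene_ids), size=size, replace=False):
            rows.append((f"TERM:{i:04d}", gene_ids[int(idx)]))
    de_ids = [d["gene_id"] for d in truth.de_genes]
    if de_ids:
        for gid in de_ids[: min(len(de_ids), term_size)]:
            rows.append(("TERM:DEG", gid))
    return pd.DataFrame(rows, columns=["term_id", "gene_id"])


def generate_coding_training(cfg: SimConfig, n_seqs: int = 120,
                             n_codons: int = 220) -> tuple[list[str], list[str]]:
    """Codon-biased coding sequences vs uniform background for training
    the hexamer model.  The coding set draws codons from a skewed
    distribution (GC-rich codons favoured, stops excluded), giving the
    hexamer statistics a learnable signal."""
    rng = cfg.rng("coding")
    coding = [biased_codon_seq(rng, n_codons) for _ in range(n_seqs)]
    background = [random_dna(rng, 3 * n_codons) for _ in range(n_seqs)]
    return coding, background


def generate_morphometry(cfg: SimConfig, n_hybrids: int = 5,
                         n_per_organ: int = 6) -> pd.DataFrame:
    """Flat/natural length measurements for sepals and petals of several
    hybrids; sepals curl more (flat exceeds natural length by ~20-40%)."""
    rng = cfg.rng("morpho")
    rows = []
    for h in range(1, n_hybrids + 1):
        for organ, curl in (("sepal", 1.3), ("petal", 1.05)):
            for i in range(1, n_per_organ + 1):
                natural = float(rng.normal(30, 2))
                flat = natural * float(rng.normal(curl, 0.05))
                rows.append((f"H{h}", organ, i, round(flat, 2), round(natural, 2)))
    return pd.DataFrame(rows, columns=["hybrid_id", "organ", "organ_index",
                                       "flat_length_mm", "natural_length_mm"])


# ---------------------------------------------------------------------------
# truth serialization (plain TSV/JSON so fixed-seed runs are byte-stable)


def write_truth(truth: TruthSet, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth.as_events).to_csv(out / "truth_as_events.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "transcript_id": l.transcript_id, "start": l.start, "end": l.end,
        "motif": l.motif, "n_repeats": l.n_repeats, "category": l.category,
    } for l in truth.ssr_loci]).to_csv(out / "truth_ssr_loci.tsv", sep="\t", index=False)
    pd.DataFrame(truth.de_genes).to_csv(out / "truth_de_genes.tsv", sep="\t", index=False)
    with open(out / "truth_fl_status.json", "w") as fh:
        json.dump({"fl_status": truth.fl_status, "read_source": truth.read_source},
                  fh, indent=0, sort_keys=True)


def config_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
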