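"""End-to-end orchestration with plain-file handoff and a run manifest.

Stages communicate exclusively through files in the output directory, so
any stage can be re-run or resumed by deleting its outputs; the manifest
records the configuration hash, seed and per-stage record counts, and is
byte-identical across reruns with the same seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import __version__
from ._util import summarize_percentage
from .align import AlignParams
from .as_events import ASParams, call_as_events, write_events_tsv
from .expression import (SampleDesign, call_degs, cluster_expression, compute_tpm,
                         enrich_terms, nb_de_test, pca_samples)
from .io import read_fasta, write_fasta, write_fastq, Transcript
from .isoform import (classify_full_length, cluster_transcripts, extract_body,
                      length_bin_summary)
from .morphometrics import compare_groups, measurement_rates
from .orf import (orf_sequence, predict_orfs, train_coding_model,
                  write_orf_gff3)
from .read_qc import compute_qc, write_qc_report
from .ssr import find_ssrs, ssr_density, write_ssr_tsv
from . import synthetic
from .synthetic import SimConfig

log = logging.getLogger("isocurl")

STAGE_ORDER = ("simulate", "qc", "flnc", "cluster", "asdetect", "ssr",
               "orfs", "de", "morpho", "summary")

STAGE_OUTPUTS = {
    "simulate": ("transcripts.fasta", "reads.fastq", "counts.tsv", "design.tsv",
                 "term2gene.tsv", "morphometry.tsv", "truth_as_events.tsv",
                 "truth_ssr_loci.tsv", "truth_de_genes.tsv", "truth_fl_status.json"),
    "qc": ("qc_report.tsv",),
    "flnc": ("flnc_classifications.tsv", "flnc_bodies.fasta", "length_bins.tsv"),
    "cluster": ("clusters.tsv", "nonredundant.fasta"),
    "asdetect": ("as_events.tsv",),
    "ssr": ("ssr_loci.tsv", "ssr_density.tsv"),
    "orfs": ("orfs.gff3", "orf_cds.fasta", "orf_peptides.fasta"),
    "de": ("de_results.tsv", "degs.tsv", "deg_clusters.tsv", "pca.tsv",
           "enrichment.tsv"),
    "morpho": ("curvation.tsv",),
    "summary": ("summary.tsv",),
}


def _require(out: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (out / name).exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs missing input {out / name}; "
                "rerun the producing stage (see STAGE_OUTPUTS) or drop --resume")


def _count_records(path: Path) -> int:
    text = path.read_text()
    if path.suffix == ".fasta":
        return text.count(">")
    if path.suffix == ".fastq":
        return sum(1 for line in text.splitlines() if line.startswith("@read"))
    if path.suffix == ".json":
        return 1
    # tabular: data rows (skip comment and header lines)
    rows = [l for l in text.splitlines() if l and not l.startswith("#")]
    return max(len(rows) - 1, 0)


def _stage_simulate(cfg: SimConfig, out: Path) -> None:
    models = synthetic.generate_gene_models(cfg)
    transcripts, truth = synthetic.generate_isoform_pairs(models, cfg)
    as_ids = {e["transcript_id_a"] for e in truth.as_events} | {
        e["transcript_id_b"] for e in truth.as_events}
    inserts = synthetic.random_ssr_inserts(
        transcripts, n=max(3, cfg.n_genes // 10), rng=cfg.rng("ssr"),
        exclude_ids=as_ids)
    transcripts, truth = synthetic.embed_ssrs(transcripts, inserts, truth)
    reads, truth = synthetic.generate_fl_reads(transcripts, cfg, truth)
    counts, design, truth = synthetic.generate_count_matrix(cfg, truth)
    term2gene = synthetic.generate_term_annotations(list(counts.index), truth, cfg)
    morpho = synthetic.generate_morphometry(cfg)

    write_fasta(transcripts, out / "transcripts.fasta")
    write_fastq(reads, out / "reads.fastq")
    counts.rename_axis("gene_id").to_csv(out / "counts.tsv", sep="\t")
    design.to_csv(out / "design.tsv", sep="\t")
    term2gene.to_csv(out / "term2gene.tsv", sep="\t", index=False)
    morpho.to_csv(out / "morphometry.tsv", sep="\t", index=False)
    synthetic.write_truth(truth, out)


def _stage_qc(cfg: SimConfig, out: Path) -> None:
    _require(out, "qc", "reads.fastq")
    report = compute_qc(out / "reads.fastq")
    write_qc_report(report, out / "qc_report.tsv")


def _stage_flnc(cfg: SimConfig, out: Path) -> None:
    _require(out, "flnc", "reads.fastq")
    from .io import iter_fastq
    rows = []
    bodies = []
    lengths = []
    for read in iter_fastq(out / "reads.fastq"):
        cls = classify_full_length(read.id, read.seq, cfg.primer5, cfg.primer3)
        rows.append((read.id, cls.status, cls.trim_start, cls.trim_end, cls.strand))
        lengths.append(len(read.seq))
        if cls.status == "FL":
            bodies.append(Transcript(read.id, extract_body(read.seq, cls)))
    pd.DataFrame(rows, columns=["read_id", "status", "trim_start", "trim_end",
                                "strand"]).to_csv(
        out / "flnc_classifications.tsv", sep="\t", index=False)
    write_fasta(bodies, out / "flnc_bodies.fasta")
    bins = length_bin_summary(lengths)
    with open(out / "length_bins.tsv", "w") as fh:
        fh.write("bin\tcount\tmean_length\n")
        for lab in bins.counts:
            mean = bins.mean_lengths[lab]
            fh.write(f"{lab}\t{bins.counts[lab]}\t"
                     f"{'NA' if mean is None else f'{mean:.1f}'}\n")


def _stage_cluster(cfg: SimConfig, out: Path) -> None:
    _require(out, "cluster", "flnc_bodies.fasta")
    bodies = read_fasta(out / "flnc_bodies.fasta")
    clusters = cluster_transcripts(bodies, threshold=0.99)
    by_id = {t.id: t for t in bodies}
    with open(out / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\tmember_id\tis_representative\tidentity\n")
        for i, cl in enumerate(clusters):
            for member in cl.member_ids:
                fh.write(f"cluster{i:05d}\t{member}\t"
                         f"{int(member == cl.representative_id)}\t"
                         f"{cl.identity_to_rep[member]:.4f}\n")
    reps = [Transcript(f"isoform{i:05d}", by_id[cl.representative_id].seq)
            for i, cl in enumerate(clusters)]
    write_fasta(reps, out / "nonredundant.fasta")


def _stage_asdetect(cfg: SimConfig, out: Path) -> None:
    _require(out, "asdetect", "nonredundant.fasta")
    reps = read_fasta(out / "nonredundant.fasta")
    events = call_as_events(reps, ASParams(), AlignParams())
    write_events_tsv(events, out / "as_events.tsv")


def _stage_ssr(cfg: SimConfig, out: Path) -> None:
    _require(out, "ssr", "nonredundant.fasta")
    reps = read_fasta(out / "nonredundant.fasta")
    loci = find_ssrs(reps)
    write_ssr_tsv(loci, out / "ssr_loci.tsv")
    scanned = sum(len(t.seq) for t in reps if len(t.seq) > 500)
    with open(out / "ssr_density.tsv", "w") as fh:
        fh.write("category\tsites_per_mb\n")
        if scanned > 0:
            for cat, dens in ssr_density(loci, scanned).items():
                fh.write(f"{cat}\t{dens:.2f}\n")


def _stage_orfs(cfg: SimConfig, out: Path) -> None:
    _require(out, "orfs", "nonredundant.fasta")
    reps = read_fasta(out / "nonredundant.fasta")
    coding, background = synthetic.generate_coding_training(cfg)
    model = train_coding_model(coding, background)
    orfs = predict_orfs(reps, model, min_aa=100)
    write_orf_gff3(orfs, out / "orfs.gff3")
    by_id = {t.id: t for t in reps}
    cds, peptides = [], []
    for tid in sorted(orfs):
        for i, rec in enumerate(orfs[tid], 1):
            seq = orf_sequence(by_id[tid], rec)
            cds.append(Transcript(f"{tid}.orf{i}", seq))
            trimmed = seq[: 3 * (len(seq) // 3)]
            peptides.append(Transcript(f"{tid}.orf{i}",
                                       str(Seq(trimmed).translate()).rstrip("*")))
    write_fasta(cds, out / "orf_cds.fasta")
    write_fasta(peptides, out / "orf_peptides.fasta")


def _stage_de(cfg: SimConfig, out: Path) -> None:
    _require(out, "de", "counts.tsv", "design.tsv", "term2gene.tsv")
    counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col=0)
    design = SampleDesign(pd.read_csv(out / "design.tsv", sep="\t", index_col=0))
    term2gene = pd.read_csv(out / "term2gene.tsv", sep="\t")
    de = nb_de_test(counts, design)
    de.table.rename_axis("gene_id").to_csv(out / "de_results.tsv", sep="\t",
                                           float_format="%.6g")
    degs, summary = call_degs(de)
    degs.rename_axis("gene_id").to_csv(out / "degs.tsv", sep="\t",
                                       float_format="%.6g")
    # expression patterns of the DEG set (lengths are not tracked for the
    # count simulation, so TPM here normalizes by a unit length)
    lengths = pd.Series(1.0, index=counts.index)
    tpm = compute_tpm(counts, lengths)
    if len(degs) >= 4:
        labels = cluster_expression(tpm.loc[degs.index], k=4)
        labels.rename_axis("gene_id").to_csv(out / "deg_clusters.tsv", sep="\t")
    else:
        pd.Series(dtype=str, name="cluster").rename_axis("gene_id").to_csv(
            out / "deg_clusters.tsv", sep="\t")
    coords, _var_frac = pca_samples(np.log2(tpm + 1))
    coords.rename_axis("sample").to_csv(out / "pca.tsv", sep="\t",
                                        float_format="%.6g")
    enrichment = enrich_terms(set(degs.index), set(counts.index), term2gene)
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                      float_format="%.6g")


def _stage_morpho(cfg: SimConfig, out: Path) -> None:
    _require(out, "morpho", "morphometry.tsv")
    morpho = pd.read_csv(out / "morphometry.tsv", sep="\t")
    rates = measurement_rates(morpho)
    parts = []
    for organ, sub in rates.groupby("organ", sort=True):
        _, letters = compare_groups(sub["curvation_rate"], sub["hybrid_id"])
        sub = sub.copy()
        sub["letter"] = sub["hybrid_id"].map(letters)
        parts.append(sub)
    pd.concat(parts).to_csv(out / "curvation.tsv", sep="\t", index=False,
                            float_format="%.4f")


def _stage_summary(cfg: SimConfig, out: Path) -> None:
    _require(out, "summary", "flnc_classifications.tsv", "orfs.gff3", "degs.tsv")
    flnc = pd.read_csv(out / "flnc_classifications.tsv", sep="\t")
    n_reads = len(flnc)
    n_fl = int((flnc["status"] == "FL").sum())
    gff = [l for l in (out / "orfs.gff3").read_text().splitlines()
           if l and not l.startswith("#")]
    n_orfs = len(gff)
    n_complete = sum("completeness=complete" in l for l in gff)
    degs = pd.read_csv(out / "degs.tsv", sep="\t")
    n_deg = len(degs)
    n_up = int((degs["direction"] == "up").sum())
    rows = [
        ("fl_reads_pct", summarize_percentage(n_fl, n_reads) if n_reads else 0.0),
        ("complete_orf_pct", summarize_percentage(n_complete, n_orfs) if n_orfs else 0.0),
        ("deg_up_pct", summarize_percentage(n_up, n_deg, 1) if n_deg else 0.0),
        ("deg_down_pct", summarize_percentage(n_deg - n_up, n_deg, 1) if n_deg else 0.0),
    ]
    with open(out / "summary.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for key, val in rows:
            fh.write(f"{key}\t{val}\n")


_STAGES: dict[str, Callable[[SimConfig, Path], None]] = {
    "simulate": _stage_simulate, "qc": _stage_qc, "flnc": _stage_flnc,
    "cluster": _stage_cluster, "asdetect": _stage_asdetect, "ssr": _stage_ssr,
    "orfs": _stage_orfs, "de": _stage_de, "morpho": _stage_morpho,
    "summary": _stage_summary,
}


def config_hash(cfg: SimConfig) -> str:
    payload = json.dumps(synthetic.config_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: SimConfig, out_dir: str | Path,
                 resume: bool = False) -> dict:
    """Run all stages in dependency order; returns the manifest dict.

    With ``resume=True`` a stage is skipped when all its outputs already
    exist; a stage whose inputs are missing raises an error naming the
    stage and file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "isocurl",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "stage_order": list(STAGE_ORDER),
        "stages": {},
    }
    for stage in STAGE_ORDER:
        outputs = [out / name for name in STAGE_OUTPUTS[stage]]
        if resume and all(p.exists() for p in outputs):
            log.info("stage %s: outputs present, skipped (resume)", stage)
        else:
            log.info("stage %s: running", stage)
            _STAGES[stage](cfg, out)
        manifest["stages"][stage] = {
            "outputs": {p.name: _count_records(p) for p in outputs}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
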