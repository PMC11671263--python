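"""Expression quantification, differential expression, clustering, enrichment.

The organ contrast (sepal vs petal) is tested per gene with a
transparent negative-binomial Wald test: counts are normalized by
median-of-ratios size factors, the gene-wise NB dispersion is estimated
by the method of moments from within-organ replicate variation (pooling
the four developmental stages, matching the bulk organ contrast), and a
two-sided Wald p-value is computed for the organ log2 fold change with
Benjamini-Hochberg adjustment across genes.  This is a deliberately
simplified test — no shrinkage of dispersions or fold changes — whose
calibration is checked against null simulations rather than inherited
from a reference implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from ._util import summarize_percentage

ORGANS = ("sepal", "petal")
ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


@dataclass
class SampleDesign:
    """Organ / stage / replicate factors, one row per sample."""

    table: pd.DataFrame  # index: sample id; columns: organ, stage, replicate

    def __post_init__(self) -> None:
        missing = {"organ", "stage", "replicate"} - set(self.table.columns)
        if missing:
            raise ValueError(f"design lacks columns: {sorted(missing)}")
        bad = set(self.table["organ"]) - set(ORGANS)
        if bad:
            raise ValueError(f"unknown organs: {sorted(bad)}")

    def samples(self, organ: str) -> list[str]:
        return list(self.table.index[self.table["organ"] == organ])


def compute_tpm(counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates rescaled so every
    sample (column) sums to 1e6."""
    lengths = effective_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive effective length")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero samples have undefined TPM: {bad}")
    return rates.div(totals, axis=1) * 1e6


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, rescaled to geometric mean 1.

    The reference is the gene-wise geometric mean over samples, computed
    on genes with nonzero counts in every sample.
    """
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has nonzero counts in all samples; "
                         "filter the matrix before normalization")
    log_geo_mean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo_mean, axis=0)
    factors = np.exp(ratios.median(axis=0))
    factors /= np.exp(np.log(factors).mean())
    return factors


@dataclass
class DEResult:
    table: pd.DataFrame  # per gene: base_mean, log2fc, p_value, padj, direction
    excluded: list[str]  # all-zero genes, not tested


def nb_de_test(counts: pd.DataFrame, design: SampleDesign,
               dispersion_floor: float = 1e-8) -> DEResult:
    """Per-gene NB Wald test of the sepal-vs-petal organ effect.

    log2fc = log2((mean_sepal + 0.5) / (mean_petal + 0.5)) on normalized
    counts; SE by the delta method with Var(mean) = (mu + alpha mu^2)/n,
    alpha the pooled within-organ method-of-moments dispersion (floored).
    """
    sepal = design.samples("sepal")
    petal = design.samples("petal")
    if min(len(sepal), len(petal)) < 2:
        raise ValueError("need at least two replicates per organ")
    excluded = list(counts.index[(counts == 0).all(axis=1)])
    tested = counts.drop(index=excluded)
    sf = size_factors(counts)
    norm = tested.div(sf, axis=1)

    xs = norm[sepal].to_numpy(float)
    xp = norm[petal].to_numpy(float)
    ms, mp = xs.mean(axis=1), xp.mean(axis=1)
    ns, np_ = xs.shape[1], xp.shape[1]
    vs = xs.var(axis=1, ddof=1)
    vp = xp.var(axis=1, ddof=1)
    pooled_var = ((ns - 1) * vs + (np_ - 1) * vp) / (ns + np_ - 2)
    mbar = (ms + mp) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mbar > 0, (pooled_var - mbar) / mbar ** 2, 0.0)
    alpha = np.maximum(alpha, dispersion_floor)

    lfc = np.log2((ms + 0.5) / (mp + 0.5))
    var_ms = (ms + alpha * ms ** 2) / ns
    var_mp = (mp + alpha * mp ** 2) / np_
    u_s = var_ms / (ms + 0.5) ** 2
    u_p = var_mp / (mp + 0.5) ** 2
    se = np.sqrt(u_s + u_p) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
        # the SE is estimated from few replicates: reference the statistic
        # against a t distribution with Welch-Satterthwaite df, not a normal
        df = (u_s + u_p) ** 2 / (u_s ** 2 / (ns - 1) + u_p ** 2 / (np_ - 1))
    df = np.where(np.isfinite(df) & (df > 1), df, ns + np_ - 2)
    pval = 2 * stats.t.sf(np.abs(z), df)
    padj = multipletests(pval, method="fdr_bh")[1]

    table = pd.DataFrame({
        "base_mean": mbar,
        "log2fc": lfc,
        "p_value": pval,
        "padj": padj,
    }, index=tested.index)
    table["direction"] = _directions(table, padj_max=0.05, min_abs_lfc=1.0)
    return DEResult(table, excluded)


def _directions(table: pd.DataFrame, padj_max: float, min_abs_lfc: float) -> pd.Series:
    sig = (table["padj"] < padj_max) & (table["log2fc"].abs() >= min_abs_lfc)
    return pd.Series(np.where(sig, np.where(table["log2fc"] > 0, "up", "down"), "ns"),
                     index=table.index)


@dataclass
class DEGSummary:
    n_total: int
    n_up: int
    n_down: int
    up_pct: float
    down_pct: float


def call_degs(de: DEResult, padj_max: float = 0.05,
              min_abs_lfc: float = 1.0) -> tuple[pd.DataFrame, DEGSummary]:
    """Threshold the DE table into a DEG set with an up/down summary.

    ``up`` means sepal-higher (log2fc > 0).  Percentages use the shared
    half-up rounding of the reporting layer (one decimal, as fractions of
    DEGs are conventionally printed).
    """
    directions = _directions(de.table, padj_max, min_abs_lfc)
    degs = de.table[directions != "ns"].copy()
    degs["direction"] = directions[directions != "ns"]
    n_up = int((degs["direction"] == "up").sum())
    n_down = int((degs["direction"] == "down").sum())
    total = len(degs)
    summary = DEGSummary(
        total, n_up, n_down,
        summarize_percentage(n_up, total, 1) if total else 0.0,
        summarize_percentage(n_down, total, 1) if total else 0.0,
    )
    return degs, summary


def cluster_expression(tpm: pd.DataFrame, k: int = 4) -> pd.Series:
    """Hierarchical clustering of DEG expression patterns.

    Rows are log2(TPM+1)-transformed and z-scaled, then clustered with
    average-linkage Euclidean hierarchical clustering cut at ``k``
    clusters.  Labels are Roman numerals assigned in order of first
    appearance, so the output is deterministic.
    """
    if len(tpm) < k:
        raise ValueError(f"need at least k={k} genes, got {len(tpm)}")
    x = np.log2(tpm.to_numpy(float) + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant rows scaled to zeros")
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    link = hierarchy.linkage(z, method="average", metric="euclidean")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    mapping: dict[int, str] = {}
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = ROMAN[len(mapping)]
    return pd.Series([mapping[lab] for lab in raw], index=tpm.index, name="cluster")


def pca_samples(log_tpm: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples (columns) in gene space.

    Returns sample coordinates and the variance fraction of each
    component (summing to 1).  Component signs are fixed so the
    largest-magnitude gene loading is positive.
    """
    if log_tpm.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = log_tpm.to_numpy(float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for i in range(len(s)):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    coords = u * s
    total = (s ** 2).sum()
    var_frac = (s ** 2) / total if total > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=log_tpm.columns, columns=cols), var_frac


def enrich_terms(deg_set: Iterable[str], universe: Iterable[str],
                 term2gene: pd.DataFrame,
                 skip_zero_overlap: bool = False) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    ``term2gene`` has columns (term_id, gene_id).  p is the probability
    of the observed overlap or larger when drawing |DEG| genes from the
    universe; BH adjustment across reported terms.  Terms with zero
    overlap get p = 1 unless ``skip_zero_overlap``.
    """
    universe = set(universe)
    degs = set(deg_set)
    outside = degs - universe
    if outside:
        raise ValueError(f"DEG genes outside the universe: {sorted(outside)[:5]}")
    tcol, gcol = term2gene.columns[:2]
    rows = []
    m = len(universe)
    n_deg = len(degs)
    for term, group in term2gene.groupby(tcol, sort=True):
        members = set(group[gcol]) & universe
        overlap = len(members & degs)
        if overlap == 0 and skip_zero_overlap:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, m, len(members), n_deg)) if overlap else 1.0
        rows.append((term, len(members), overlap, p))
    table = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    if not table.empty:
        table["padj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["padj"] = []
    return table
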