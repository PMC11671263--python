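# Methods

This note documents the models, numerical choices and known limitations
of isocurl, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and data model

The pipeline operates entirely in transcript space. No genome, splice
coordinates or GTF are involved: the AS caller compares transcripts to
transcripts, so exon skipping and intron retention are indistinguishable
by design and no attempt is made to type events. Coordinates are
0-based half-open everywhere in memory; TSV outputs that are meant for
human consumption (SSR loci, ORF GFF3) use 1-based inclusive
coordinates and say so in their headers.

## Synthetic data generator

The generator produces every input the pipeline consumes, with planted
truth, and is first-class tested code. Its defaults describe the study
conditions the pipeline is validated under; they are fixed once and are
not tuned against test outcomes.

- **Gene models and transcripts.** `n_genes` genes with 2–8 exons of
  150–500 bp. Each transcript is mRNA-shaped: random UTRs (~15% of the
  length each) around a codon-biased CDS (`ATG` + stop-free codons +
  `TAA`) drawn from a GC-skewed codon usage. The coding signal exists
  so the hexamer model has something to learn end to end; transcripts
  too short for a ≥ 40-codon CDS fall back to uniform random sequence.
  Generated bodies are screened against the primer sequences and their
  reverse complements.
- **AS pairs.** A configured fraction of genes (default 20%) contributes
  a second isoform missing one internal contiguous segment (default
  120–300 bp, ≥ 150 bp flanks). Truth records the segment's position on
  the containing isoform and a `detectable` flag — gap > 100 bp and both
  end distances ≥ 100 bp, i.e. the caller's thresholds are met by
  construction, not calibration.
- **Reads.** Per transcript, `reads_per_transcript` reads of the form
  primer5 + body + poly(A)×30 + revcomp(primer3), half emitted on the
  minus strand. Degenerate fractions default to 8% missing tail, 10%
  missing 5' primer, 6% chimeric (two bodies joined by an interior
  primer copy), leaving ~76% proper FL — the yield typical of real
  full-length library classifications. The error model is
  substitution-only at rate 0.005 (the accuracy scale of polished
  long reads; configurable), which keeps all planted coordinates exact.
  Indels are deliberately not modelled; adding them would require truth
  tolerance windows.
- **SSRs.** Planted microsatellites overwrite (rather than insert into)
  transcript sequence, so the transcript length and all other planted
  coordinates stay valid. The single base on each side of a planted run
  is set to break the repeat period, making the truth locus maximal by
  construction. Random placement avoids members of AS pairs, whose two
  isoforms must remain alignable.
- **Counts.** Negative-binomial counts over the full 2 organs × 4
  stages × 3 replicates design (24 samples). Gene base means are
  log-normal (log-mean 4, log-sd 1, i.e. median ≈ 55); planted DEGs get
  an organ effect of ±2 log2 units on the sepal mean; the planted
  fractions default to 7.3% up / 2.7% down, mirroring the strong
  sepal-up bias reported for curled-sepal contrasts. Dispersion α
  defaults to 0.1 (variance μ + αμ²); a moment test in the suite checks
  the simulated variance tracks this relation. Stage effects are not
  simulated by default, because the organ contrast pools stages.

What the generator does **not** emulate: instrument-level structure
(ZMWs, subreads, quality-value error profiles), indels, expression-
dependent read depth, 5' degradation gradients, or correlated genes.
Passing tests therefore demonstrate algorithmic correctness under the
declared error model, not performance on raw instrument data.

## Full-length classification and trimming

Primer matching is a windowed Hamming search (both orientations, primer
allowed to start within 10 bp of the read end) tolerating
ceil(0.1 × primer length) substitutions; exact matching is available by
setting the tolerance to 0. The poly(A) test requires ≥ 20 A's
immediately before the 3'-primer site, allowing one single-base
interruption. An additional interior occurrence of either primer (5 bp
clear of the terminal matches) marks a chimera. Statuses are
prioritized FL > chimera > missing_polyA > missing_primer across the two
orientations.

A known, unavoidable ambiguity: a transcript body that naturally ends in
adenosines has those bases absorbed into the poly(A) tail during
trimming. Trimmed bodies are exact otherwise.

## Clustering

Greedy longest-first clustering against representatives only (standard
greedy-incremental semantics): a sequence joins the first cluster whose
representative it matches at identity ≥ 0.99, else founds a cluster.
Identity is matching columns over all columns (gaps included) of a
Needleman–Wunsch alignment computed by edlib; the length ratio
min/max < threshold is used as a provably safe skip. The denominator
choice penalizes length differences, which matches the redundancy-
removal intent. Note that at a 0.5% per-read error rate two reads of
the same transcript sit near identity 0.99, so the non-redundant set of
a noisy run is larger than the true isoform count; this mirrors the
behaviour of identity-threshold tools on unpolished input.

## Alternative-splicing caller

The built-in aligner uses exact 15-mer seeds grouped by diagonal, merged
within 60 bp along the diagonal, then ungapped x-drop extension
(match +1, mismatch −3, drop 12), keeping segments ≥ 40 bp at ≥ 95%
identity. Substitution-only data lies on single diagonals, so this
recovers local alignments exactly up to boundary jitter. Precomputed
BLAST outfmt-6 alignments are accepted interchangeably (1-based
inclusive coordinates converted on input; descending subject coordinates
mean minus-strand).

Classification evaluates all ordered same-orientation HSP pairs and
returns the best-scoring qualifying pair. Two numerical choices matter:

- **Junction reconciliation.** Greedy extension lets both HSPs claim the
  same junction-adjacent bases whenever the gap's flanking sequence
  matches the continuation by chance (a 4^-k event per extra base, so
  overlaps of several bp occur regularly in large pair sets). Overlapping
  coverage up to 20 bp is therefore trimmed from the second HSP (its
  diagonal preserved) before the rule is applied; larger overlaps
  disqualify the pair as real duplicated structure rather than jitter.
  Without this, a planted error-free event can be rejected because of a
  chance 6-bp overlap, and gap coordinates would be biased. After
  reconciliation the printed rule applies verbatim: |distance| < 5 bp on
  the continuous side, gap > 100 bp (strict), end distances ≥ 100 bp
  (inclusive), continuous coverage ≥ 0.95.
- **Boundary conventions.** Gap length strictly greater than 100 bp;
  end distance inclusive at 100 bp; both are exercised at their exact
  boundaries in the test suite. Called gap coordinates can shift by a
  few bases relative to planted truth where flanking sequence matches by
  chance — the event identity and gap length are stable, the placement
  is ambiguous in principle.

## SSR semantics

A locus is a maximal run of whole units of a primitive (non-periodic)
1–6 bp motif, reported at its smallest period and leftmost phase, so
each physical run yields exactly one record. Minimum repeat counts
default to 10/6/5/5/5/5 for motif lengths 1–6 (the conventional
definition file for transcriptome surveys); "over 500 bp" is read
strictly. Compound merging chains loci whose gap to the running
compound end is ≤ 100 bp; any negative gap makes the compound `c*`.
Motifs are canonicalized to the smallest rotation only — transcripts are
stranded, so no reverse-complement folding. The suite checks exact
agreement with an independent brute-force enumeration on hundreds of
random sequences and exact recovery of planted loci.

## ORF prediction

Within each of six frames, stop codons partition the codon stream into
runs. A run bounded upstream by a stop yields a candidate at its first
ATG; a run reaching the 5' edge yields the longest candidate (from the
run start), because the true start may lie upstream of the fragment.
Completeness is classified mechanically from the candidate's own ends
(ATG first codon / stop last codon). Protein length excludes the stop
codon; the minimum is 100 aa by default.

The coding score is the mean log(f_coding/f_background) over hexamers
stepped by 3 from the candidate's first base, with additive pseudocount
1 on both frequency tables (in-frame counting for the coding set,
position-free for the background). Zero is the decision threshold; the
frame-maximality test re-reads the same span in the five alternative
frames (ragged ends truncate to whole hexamers) and ties reject. Among
same-strand candidates where one span contains another, the longer is
reported. The Pfam-domain rescue clause is represented as a hook
accepting an external hit table; no domain search is implemented.

## Expression and differential expression

TPM divides counts by effective lengths and rescales each sample to
1e6. Size factors are median-of-ratios to the gene-wise geometric mean
over genes positive in all samples, rescaled to geometric mean 1.

The DE test is a deliberately transparent stand-in for heavier NB
machinery: per gene, organ means of normalized counts (stages pooled —
the bulk organ contrast), log2FC with pseudocount 0.5, method-of-moments
dispersion pooled within organs and floored at 1e-8, delta-method
standard error, and a two-sided p-value. The statistic is referenced
against a t distribution with Welch–Satterthwaite degrees of freedom
rather than a standard normal: with 12 replicates per group and an
estimated SE, the normal reference is anticonservative (type-I ≈ 0.065
in null simulations), while the t reference restores nominal calibration
(≈ 0.05); this is the standard small-sample correction for Wald-type
statistics. No shrinkage of dispersions or fold changes is applied, and
stage is not modelled as a covariate (a stratified option is a
possible extension, off by default, matching the pooled contrast).
DEG thresholds default to padj < 0.05 and |log2FC| ≥ 1, both
overridable; up/down percentages go through the shared half-up rounding
helper.

Expression-pattern clustering is average-linkage Euclidean hierarchical
clustering of log2(TPM+1), row-z-scaled, cut at k = 4; constant rows
scale to zeros with a warning; labels are Roman numerals in order of
first appearance so output is deterministic. PCA is a centered SVD of
samples in gene space with the sign of each component fixed by its
largest-magnitude loading. Enrichment is the one-sided hypergeometric
tail (overlap or more extreme) with BH across terms; zero-overlap terms
report p = 1 unless skipped by flag.

## Morphometrics

Curvation rate is flat length / natural length. The alternative
reciprocal definition exists in the literature of such measurements; the
flat/natural direction is adopted because it makes curled organs score
above 1 and so matches the reported ordering of curled sepals over flat
petals, and the reciprocal is available behind a flag. Group comparison
uses Welch (unequal-variance) t-tests; the compact letter display is a
greedy clique cover of the non-significance graph over groups in
descending-mean order, which guarantees the invariant that groups
sharing a letter are pairwise non-significant (it does not guarantee a
minimal number of letters).

## Pipeline

Stages hand off exclusively through plain files in the output directory
(inspectability and resumability); `--resume` skips stages whose outputs
all exist, and a stage with missing inputs fails naming the stage and
file. The manifest records tool version, a hash of the configuration,
the seed and per-stage record counts, and contains no timestamps, so
fixed-seed runs are byte-identical end to end. All randomness flows
from a single seed through named substreams, one per generator stage, so
reconfiguring one stage never perturbs another's draws.

## Problem sizes

The validation suite uses desk-scale problems chosen to exercise every
rule at its boundaries: 200 transcripts with 20 planted AS events,
500 random sequences for the SSR oracle, 100 × 2 kb sequences for the
ORF oracle, 2 000-gene null and power simulations for the DE test, and
the default 60-gene pipeline configuration (run twice) for
byte-determinism. Data-scale quantities from real sequencing runs
(hundreds of thousands of reads, tens of thousands of loci) are inputs
to the summary arithmetic, not reproduction targets.

## Known limitations

- No consensus polishing; clustering representatives are raw trimmed
  bodies, so sequencing errors propagate into downstream annotation.
- The AS caller reports at most one event per transcript pair and does
  not chain ≥ 3 HSPs into multi-gap events.
- No imperfect/approximate SSRs; no primer design.
- No start-codon refinement beyond the first in-frame ATG; no
  Pfam/HMM search.
- The DE test assumes independent genes and a common within-organ
  dispersion per gene; it is a calibration-checked simplification, not a
  replacement for shrinkage-based estimators at very low replication.
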