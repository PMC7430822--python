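# Methods

This note documents the models and procedures implemented in `markertyper`,
the parameter defaults and why they were chosen, the numerical conventions
that matter for reproducibility, and the limits of what the synthetic
benchmarks demonstrate.

## Marker databases

A marker database is an ordered collection of marker sets, each a list of
gene symbols characterising one cell type as described by one study.  The
dotted label `FirstAuthor.Year.Tissue.Category` identifies a study family;
several cell types share one label, so the uniqueness key within a database
is `(label, cell_type)`.  Gene symbols are matched case-insensitively but
displayed as spelled in the source; duplicate genes within a set are
dropped keeping the first occurrence.  A study is identified by
`(first_author, year, pmid)` — author and year alone can collide.

Summaries count sets, distinct cell types and distinct studies, plus
per-category tallies.  The category group `{TIL, TAM, Immune}` is reported
together as the immune repertoire, and the T-cell slice of that repertoire
is counted by cell types naming a T-cell state.

The two bundled databases are **synthetic reconstructions**: deterministic
builders that reproduce the summary statistics of well-known curated
resources (213/121/22 for the tumour-centric table, 2867/467/1764 for the
general one) without redistributing the originals.  Canonical human markers
(CD3D/CD3E for T cells, PECAM1/VWF for endothelium, …) are used for
well-characterised types; filler sets carry pool-sampled symbols.  Files
written from them are named `*.synthetic.tsv`.  They exercise every code
path a real curated table would; they are not a biological reference.

## Preprocessing

Counts are library-size normalized per cell and log-transformed:
`x[g,c] = ln(1 + count[g,c] / total[c] × 10⁴)`.  The scale factor 10⁴ is the
single-cell community convention; the transform is invariant to multiplying
any cell's counts by a positive constant.  Scaling standardizes each gene
across cells to mean 0, sample sd 1 (ddof = 1), zeroing zero-variance genes
and clipping to ±10.  Cluster-level profiles are unweighted means of member
cells, with columns in sorted label order.  Clustering itself is out of
scope: cluster labels arrive precomputed in the cell metadata, matching the
usual workflow where typing runs after a standard clustering pass.

Gene coordinates are 1-based inclusive internally; BED input (0-based
half-open) is converted at load.  Genes missing from the annotation are
excluded from CNV analysis only, never from marker scoring.

## Nearest template prediction

Each candidate type k is a binary template **t**ₖ over the union of marker
genes present in the matrix (genes shared between sets mark every owning
column).  The matrix is restricted to this feature space and each unit u is
scored with d(u, k) = (1 − cos(xᵤ, tₖ))/2 ∈ [0, 1]; the winner is the
argmin.  The (1 − cos)/2 normalization bounds the distance without
affecting the ranking.

Significance uses resampled gene labels: each of n_perm (default 1000)
null draws applies one random permutation to the template rows — preserving
every class's gene count *and* the between-class overlap structure — and
records the minimum distance across classes, mirroring the observed
statistic.  p(u) = (1 + #{null_min ≤ observed_min(u)}) / (1 + n_perm), with
add-one smoothing so p is never zero, then Benjamini–Hochberg FDR across
units; winners with FDR above the cutoff (default 0.05) are `Unresolved`.
Two properties motivated this null over drawing each class's random
template independently: (a) observed and null statistics are exchangeable
under a no-signal matrix, so p-values are uniform there (verified by a
Kolmogorov–Smirnov test in the suite); an independent-draw null ignores the
negative correlation between class distances induced by near-disjoint
templates and is measurably anti-conservative.  (b) It is the natural
multi-class version of size-matched template resampling.  Null draws are
shared across units for speed; p-values are therefore not independent
across units, which does not affect their marginal calibration.

All-zero profiles have undefined cosine distance and are flagged
`Unresolved` with p = 1.

## Pre-ranked GSEA

Per unit, genes are ranked by expression descending (stable sort, ties by
gene order).  For a set with N_hit of N genes, the running sum steps up by
|r|^w / Σ_hits |r|^w at hit genes and down by 1/(N − N_hit) at misses; ES is
the signed maximal deviation, always in [−1, 1].  Weight w = 1 (default)
is the classic weighted form; w = 0 gives the unweighted Kolmogorov–Smirnov
statistic, for which a set and its complement have exactly opposite scores.
If all hit metrics are zero the hit steps fall back to equal increments.  A
set covering every gene in the matrix is rejected (the miss step would be
undefined).  No permutation p-value is attached to ES; assignment is plain
argmax.  Down-regulated marker lists are not supported: templates and sets
are up-signatures only.

## Average expression

The mean z-scaled expression of a set's present genes; assignment is
argmax.  This is the simplest and fastest method and the natural baseline
for the other two.

Ties anywhere are broken deterministically toward the first declared class
and logged.

## Copy-number inference and malignant calling

Stages, in order, on the log-normalized matrix:

1. remove genes belonging to detected gene clusters (below);
2. remove genes with mean expression across all cells < 0.1;
3. center each gene on its mean over the reference cells;
4. clip to ±3;
5. smooth per chromosome with an unweighted moving average over 101 genes,
   the half-width shrinking symmetrically near chromosome ends so the
   window stays centered and never crosses a boundary (window 1 is the
   identity);
6. subtract each cell's median.

Defaults (window 101, clip 3, expression cutoff 0.1) follow standard
expression-based CNV practice.  The reference population is whichever cells
the metadata flags (`is_reference`); immune cells are the usual choice
because they are reliably diploid in tumour samples, but any designated set
works.

**Gene-cluster filtering.**  Families of functionally related genes that
sit close together on a chromosome (co-located paralogs and similar) can be
co-regulated and mimic a focal copy-number change.  For each functional
gene set, a 1 Mb window is anchored at each member gene's start; windows
holding ≥ 5 members are tested with the hypergeometric upper tail
(population = all annotated genes, successes = the set's annotated genes,
draws = genes in the window) and windows with unadjusted p < 0.05 are
reported, overlapping windows of one set merged (union of members, minimum
p; a merged cluster may span more than one window width).  The unadjusted
cutoff is deliberate: the filter prefers removing a borderline family over
letting it fake an amplification.  Functional sets are user-provided; the
marker database can be reused but is not assumed sufficient.

**Scoring and calling.**  A cell's CNV score is the sum of squared smoothed
values (a mean-absolute alternative is exposed); larger deviations anywhere
along the genome increase it.  The malignancy threshold is the 0.90
empirical quantile — linear interpolation between order statistics, numpy's
default (type 7), stated here for bit-reproducibility — of the reference
cells' scores.  A cell is called malignant when its score strictly exceeds
the threshold **or** marker typing assigned it to a designated malignant
class; called cells are relabelled `Malignant`.  Fewer than 10 reference
cells triggers an instability warning but still computes.  The sum-of-
squares statistic is a design choice: any unnormalized quadratic aggregate
ranks cells with broad aberrations above diploid cells, and exposing it as
a pluggable statistic keeps the threshold rule independent of the choice.

## Synthetic data

The generator emulates droplet scRNA-seq: per-gene baseline means are
log-normal (ln-mean 0, ln-sd 1, giving a median of ~3000 UMIs per cell over
2000 genes), per-cell library factors are log-normal (sigma 0.3), counts
are gamma–Poisson (negative binomial) with dispersion θ = 2
(var = μ + μ²/θ).  Cell types are planted by multiplying each group's
marker genes by 2^fold in that group; marker genes are disjoint between
groups, drawn away from declared CNV regions, and floored at a baseline
mean of 0.5 counts per cell — a curated marker that is never detected would
not be a marker.  Copy-number events rescale in-region counts to
expectation × 2^shift by Poisson augmentation (gains) or binomial thinning
(losses), which leaves a zero shift bit-identical and scales expectations
exactly.  The gene-family confound repositions a chosen run of genes to sit
densely within a declared span and over-expresses them in designated
non-malignant cells.

Canned study conditions: the *separation regime* (3 types × 100 cells,
2 log2-fold markers, low dispersion θ = 8) where every scoring method
should agree with the truth, and the *CNV regime* (150 malignant + 250
reference cells, a 200-gene single-copy gain on chromosome 1, ~5000
UMIs/cell as in a deeply sequenced run, where expression-based CNV
inference is at its best).

What the synthetic benchmarks do **not** show: real marker sets overlap
between related types, real clusters are impure, ambient RNA and doublets
blur profiles, and real CNV landscapes are aneuploid mixtures rather than
one clean block.  Passing the planted-recovery tests demonstrates that the
machinery is correct and calibrated, not that any given tissue will be
typed with these accuracies.

## Pipeline

Stages run in a fixed order (load → normalize → scale → [aggregate] →
score → assign → [CNV → malignant calling]) with skip flags: `normalize:
false` accepts an already log-normalized matrix, `run_cnv: false` stops
after assignment, `level: cluster` aggregates before scoring and broadcasts
labels back to member cells.  All randomness derives from the single config
seed.  Result tables are written atomically (temp file + rename); the
report echoes every configuration field, records per-stage gene/cell
attrition, and contains no timestamps, so regenerating it from the same run
is byte-identical.  Reports render as Markdown or a minimal self-contained
HTML wrapper.  Method comparison cross-tabulates assignments from several
scoring runs: per-method type proportions, pairwise agreement fractions,
and per-type Venn-style overlap counts keyed by the subset of methods
agreeing on each unit.

Raw-data stages (read QC, alignment, quantification, clustering) are
intentionally not wrapped; the pipeline's entry point is a prepared count
or log-normalized matrix with optional cluster labels.

## Problem sizes in the checked examples

The test suite and the acceptance script run on 300–500-cell matrices with
800–2000 genes, 1000 NTP permutations and 1000-cell threshold checks;
everything completes in seconds on one CPU.  These sizes were chosen to
make every statistical check (KS uniformity at 500 units, >5 sd CNV
separation, exact quantile counts at n = 1000) well-powered while staying
instant to rerun.

## Known limitations

* Binary up-templates only; no support for down-regulated marker halves.
* No GSEA permutation p-values; ES magnitudes are compared directly.
* CNV stage estimates relative, smoothed profiles only — no HMM state
  calling, no subclone reconstruction, no absolute copy numbers.
* The bundled databases are synthetic reconstructions (see above); supply a
  real curated TSV for biological work.
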