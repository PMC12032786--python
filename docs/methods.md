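# Methods

This note documents the models, conventions and design choices behind
`chiptargets`, in the spirit of a statistical-software methods appendix.

## Coordinates and gene models

All intervals are 0-based half-open internally. GFF3 input (1-based,
fully closed) is converted on read and back on write, so a round trip is
the identity on coordinates; narrowPeak/BED input is already half-open and
is taken verbatim. Gene records must carry a strand: the transcription
start site (TSS) is `start` on `+` and `end − 1` on `−`, and a strandless
gene has no TSS, so strand `.` on a gene record is a hard error rather
than a silent default. Biotype is read from the `biotype` or
`gene_biotype` attribute, falling back to the feature type for `tRNA`
records, since annotation sources differ in where they put it.

**Promoter windows.** "1000 bp before and after the TSS" is realized as a
2001 bp window that includes the TSS base itself; whether the TSS base
counts is genuinely ambiguous, and including it avoids a hole at the most
important coordinate. "Before" and "after" are directions of
transcription, so asymmetric extents flip genomically on the minus strand;
with the symmetric defaults strand is irrelevant. Windows of genes near
chromosome edges are clamped to the chromosome, never dropped.

## Consensus peak calling

Two peaks report the same locus when their intervals, each slackened by
`tol_bp` on both sides, overlap or touch — equivalently when the gap
between them is at most `2·tol_bp` (gap 0 for overlapping or abutting
intervals, so abutting peaks merge even at `tol_bp = 0`). The phrase
"± N bp on either side" admits a stricter single-sided reading (maximum
bridged gap N); both are implemented (`tol_mode = "both" | "single"`,
default `both`) because published peak counts cannot adjudicate between
them without the underlying data.

Clustering is single linkage — the transitive closure of the pairwise
rule — so chains are possible and accepted. On a line this is computed
exactly by a sort-and-sweep (a new cluster starts whenever the next peak's
start exceeds the running maximum end by more than the bridged gap), which
the test suite verifies against a brute-force all-pairs union-find oracle
on random instances. Support counts **distinct replicates**, not peaks:
several peaks from one replicate in a cluster count once. The consensus
interval is the **union span** of members: jittered replicate peaks can
satisfy the tolerance rule with an empty intersection, so the union is the
only span guaranteed to cover every supporting observation. Output order
and `cons_<k>` names are fixed by (chrom, start, end), making runs
deterministic regardless of input order.

## Annotation

Each consensus peak is reduced to one anchor point so that every peak gets
exactly one category and feature proportions are well defined
(whole-interval overlap assignment would let one peak occupy several
categories). The anchor is the **lower median of member summits** when any
member carries one — deterministic and robust to a single outlying
replicate — else the interval midpoint (floor).

Category precedence is promoter ≻ exon ≻ intron/gene body ≻ downstream ≻
distal intergenic. Exon/intron are only distinguished for genes with exon
structure; genes without it get the single category `gene_body` (no
transcript models are ingested, so UTR-level categories are deliberately
out of scope). `downstream` means within `downstream_bp` (default
3000 bp, the common annotator convention) past the transcription end site
in the direction of transcription. Among genes qualifying at the winning
category the one with the smallest |distance to TSS| is assigned, ties
broken by lexicographic gene id for cross-platform determinism; distal
peaks are assigned their chromosome's nearest gene by TSS distance (a
chromosome with no genes at all is an error). `distance_to_tss` is signed
along transcription: positive downstream of the TSS into the gene,
negative upstream. These conventions make annotation exactly symmetric
under mirroring the genome through a point, a property the tests exercise.

Target tables keep only promoter-category rows and drop excluded biotypes
(default `{tRNA}`: tRNA genes are short, dense and highly duplicated, and
their promoter hits otherwise flood target lists); unique-peak and
unique-gene counts are distinct counts over the retained rows.

## Statistics

**Overlap enrichment.** With q = |ours ∩ prior|, m = |prior|,
n = |universe − prior|, k = |ours|, the overlap under the null is
hypergeometric. Both the point probability P(X = q) and the upper tail
P(X ≥ q) are computed (via scipy's log-space implementation; exact
rational arithmetic and literal draw enumeration serve as test oracles).
The tail is the headline value: a point density is not a test of
enrichment. P(X ≥ 0) is exactly 1. No multiple-testing correction is
applied by default. The universe must be explicit — results are
meaningless without one — and elements outside it are dropped with a
warning.

**Mapping comparisons.** Welch's unequal-variance two-sample *t*-test
(the R default for `t.test`) on per-sample category **fractions**, so
library-size differences between samples do not drive the comparison; a
pooled-variance option exists. Orientation is fixed to
mean(group_b) − mean(group_a), so with a = original and b = updated
assembly, positive t means improvement. Two identical constant groups
return t = 0, p = 1 rather than NaN; zero variance with unequal means is
reported as a degenerate-input error.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not sequencing itself: no reads, fragment coverage, duplicates, or motif
content — so passing tests demonstrate the correctness and calibration of
the downstream logic, not robustness to alignment or peak-calling
artifacts.

Defaults describe a small but structurally faithful study: one 2 Mb
chromosome, 200 non-overlapping genes (10% tRNA, ≥ 2 kb apart, 0.5–3 kb
long), five conditions of three replicates each (more targets in adults
than juveniles, fewest in the singing state: 40/35/25/20/15), 90%
per-replicate detection of planted peaks, 2 bp boundary jitter, 150–400 bp
peak widths, and 50 replicate-private background peaks per replicate.

Key structural choices:

- **The binding site is a property of the locus.** Each planted target
  gets one anchor per condition, drawn uniformly within
  `promoter_offset_max` (default 500 bp) of the TSS; replicates then
  jitter interval boundaries around that shared anchor
  (Normal(0, `jitter_sd`), re-clamped to a valid width). Drawing anchors
  independently per replicate would make replicate peaks up to 1 kb apart
  — "replicates" that no ±5 bp rule should merge — and would misrepresent
  the reproducibility the consensus step is designed to measure.
- **Background avoids promoters** by rejection sampling, so false-positive
  target genes can arise only through the tolerance rule itself, which
  makes precision against the planted truth a meaningful metric.
- **Hierarchical seeding.** One integer seed spawns independent streams
  keyed by stable label hashes (genome; each condition; each replicate),
  so adding a condition perturbs nothing else and every output is a pure
  function of the configuration.
- Optional `n_trna_targets` plants control peaks on tRNA promoters to
  verify that biotype exclusion removes them completely.

Mapping tables draw per-sample fractions as assembly means plus Gaussian
noise (renormalized), with largest-remainder rounding to integer read
counts; zero dispersion reproduces the means exactly. The default means
(original 60/25/15 vs updated 75/15/10) encode a ~15-point gain in unique
mapping.

## Numerical and format conventions

Floats are written in shortest round-trip decimal form; round-trip
equality is therefore tested on parsed values, canonical-dialect outputs
are byte-stable. JSON reports are written with sorted keys, and the run
manifest records output paths relative to the run directory plus a SHA-256
hash of the effective configuration, so identical runs are byte-identical
wherever they are placed. The narrowPeak strand column is preserved but
ignored downstream (TF binding is unstranded).

## Problem sizes in tests

The test suite validates the consensus sweep against a quadratic
union-find oracle on 1000 random instances (≤ 50 peaks, 2–4 replicates),
checks hypergeometric exactness over all universes of ≤ 20 genes and
density normalization up to 60, measures planted-target recovery over 20
simulated studies at the default configuration (observed mean sensitivity
≈ 0.96, precision ≈ 1.0), and verifies Welch-test calibration over 1000
null simulations. These sizes give stable pass/fail behavior at
interactive runtimes while exercising every code path; none of the
algorithms depend on them.

## Known limitations

- Gene-level comparisons assume a shared gene-id namespace across the
  compared analyses; an optional synonym map is the only reconciliation
  offered.
- One category and one gene per peak: enhancer-style long-range or
  multi-gene assignment is out of scope.
- The annotator collapses UTR/exon detail absent transcript models.
- The generator's detection dropout is independent across replicates and
  targets; real replicate failures are correlated (antibody efficiency,
  library depth), so real-data sensitivity will be lower at equal nominal
  detection probability.
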