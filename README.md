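# chiptargets

Replicate-consensus ChIP-Seq peak calling and promoter target-gene
cataloging, with cross-condition comparisons and gene-set overlap
enrichment.

## The problem

A transcription-factor (TF) ChIP-Seq experiment — for example, FOXP2
pulldown from songbird brain tissue across sexes, ages and behavioral
states — yields per-replicate peak calls (MACS2 narrowPeak files). Turning
those into a defensible catalog of candidate target genes requires four
downstream steps that this package implements as a tested, reusable
library plus a small CLI:

1. **Consensus peak calling.** Peaks reported at the same genomic locus
   within a ±5 bp tolerance in ≥ 2 biological replicates are merged into
   high-confidence consensus peaks. Formally, peaks are clustered per
   chromosome by single linkage under the relation
   gap(a, b) ≤ 2·tol (each peak slackened by tol = 5 bp on both sides);
   a cluster is emitted when its members span ≥ *min_support* distinct
   replicates, with the union span as its interval.
2. **Promoter annotation.** Each consensus peak is reduced to an anchor
   point (member summit, else midpoint) and assigned one feature category
   — promoter ≻ exon ≻ intron/gene body ≻ downstream ≻ distal intergenic —
   and one target gene (smallest |distance to TSS|, ties by gene id).
   Putative promoters are the regions 1000 bp before and after the
   transcription start site, strand-aware; tRNA-gene promoters are
   excluded from target tables by default.
3. **Set comparisons.** Venn-style partitions of per-condition target-gene
   sets and assembly/analysis concordance as intersection-over-union.
4. **Overlap enrichment.** Hypergeometric test of the overlap between this
   study's target genes and a prior study's list within an explicit gene
   universe, in the q/m/n/k convention of R's `phyper`:
   q = |ours ∩ prior|, m = |prior|, n = |universe| − m, k = |ours|;
   both P(X = q) and the enrichment tail P(X ≥ q) are reported.

A mapping-statistics module compares per-sample fractions of uniquely /
multi / un-mapped reads between two genome assemblies with Welch's
two-sample *t*-test, and a fully seedable synthetic-data generator
produces gene models, replicate peak sets with planted promoter targets,
and mapping tables with known ground truth for validation.

## Worked example

```python
import io
from chiptargets import (
    SimConfig, ConditionSpec, simulate_genome, simulate_condition,
    read_narrowpeak, consensus_peaks, ToleranceParams,
    read_gene_annotation, GeneIndex, annotate_peaks,
    feature_distribution, target_table,
)

cfg = SimConfig(seed=1, conditions=(ConditionSpec("adult_male_ns", 3, 40),))
genes, gff3 = simulate_genome(cfg)                   # 200 genes on a 2 Mb chromosome
texts, truth = simulate_condition(cfg, genes, "adult_male_ns")

reps = [read_narrowpeak(t, replicate_id=r, condition="adult_male_ns")
        for r, t in texts.items()]
cons = consensus_peaks(reps, ToleranceParams(tol_bp=5, min_support=2))
index = GeneIndex(read_gene_annotation(io.StringIO(gff3), {"gene", "tRNA"}),
                  chrom_lengths=cfg.chrom_lengths)
annotated = annotate_peaks(cons, index)
table = target_table(annotated, "adult_male_ns")

print(len(cons), "consensus peaks")
print(round(feature_distribution(annotated)["promoter"], 3), "promoter fraction")
print(table.n_unique_genes, "target genes;",
      len(table.gene_ids & truth.planted), "of", len(truth.planted), "planted recovered")
```

Output:

```
41 consensus peaks
0.927 promoter fraction
38 target genes; 38 of 40 planted recovered
```

41 binding loci were reproduced in ≥ 2 of 3 replicates; 92.7% of them sit
in promoter windows (the generator plants targets at promoters, so the
remainder are chance background collisions elsewhere); the 38 recovered
target genes are all true planted targets — two targets were missed
because their peaks were detected in fewer than two replicates.

The same stages are available from the shell via
`chiptargets simulate|consensus|annotate|compare|enrich|run`
(see `chiptargets --help`); `run` drives everything from a TOML config and
writes BED/TSV/JSON outputs plus a manifest that records the exact
parameters used.

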