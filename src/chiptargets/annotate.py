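"""Assign consensus peaks a genomic feature category and a target gene.

Each peak is reduced to a single anchor point (the summit when any member
supplies one, else the interval midpoint) so that every peak gets exactly one
category and feature proportions are well defined.  Categories are assigned
with the precedence

    promoter > exon > intron / gene_body > downstream > distal_intergenic

where *promoter* means the anchor lies inside some gene's promoter window,
*exon*/*intron* apply only to genes with exon structure (*gene_body*
otherwise), and *downstream* means the anchor lies within ``downstream_bp``
past the transcription end site in the direction of transcription.  Among the
genes qualifying at the winning category, the one with the smallest absolute
TSS distance is assigned; ties break on lexicographic gene id.

``distance_to_tss`` is signed in the direction of transcription: positive
when the anchor lies downstream of (after) the TSS along the transcript.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .consensus import ConsensusPeak
from .genome_model import GeneModel, promoter_window, tss

__all__ = [
    "FEATURE_CATEGORIES",
    "AnnotatedPeak",
    "TargetTable",
    "GeneIndex",
    "annotate_peak",
    "annotate_peaks",
    "feature_distribution",
    "target_table",
    "write_annotated_tsv",
    "write_feature_distribution_tsv",
]

FEATURE_CATEGORIES = (
    "promoter",
    "exon",
    "intron",
    "gene_body",
    "downstream",
    "distal_intergenic",
)


@dataclass(frozen=True)
class AnnotatedPeak:
    """A consensus peak with its feature category and assigned gene."""

    peak: ConsensusPeak
    category: str
    gene_id: str
    gene_symbol: str
    biotype: str
    distance_to_tss: int


@dataclass(frozen=True)
class TargetTable:
    """Promoter-bound target genes for one condition, after biotype exclusion."""

    condition: str
    rows: pd.DataFrame  # consensus_id, gene_id, gene_symbol, biotype, category, distance_to_tss
    n_unique_peaks: int
    n_unique_genes: int

    @property
    def gene_ids(self) -> set[str]:
        return set(self.rows["gene_id"])


def _signed_distance(gene: GeneModel, anchor: int) -> int:
    t = tss(gene)
    return anchor - t if gene.strand == "+" else t - anchor


class GeneIndex:
    """Interval-tree index over genes, promoter windows and exons.

    Built once per annotation run; ``chrom_lengths`` (optional) clamps the
    promoter windows at chromosome edges.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        promoter_up: int = 1000,
        promoter_down: int = 1000,
        downstream_bp: int = 3000,
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> None:
        if not genes:
            raise ValueError("empty gene set")
        self.promoter_up = promoter_up
        self.promoter_down = promoter_down
        self.downstream_bp = downstream_bp
        self.genes: dict[str, GeneModel] = {}
        self._promoters: dict[str, IntervalTree] = {}
        self._spans: dict[str, IntervalTree] = {}
        self._exons: dict[str, IntervalTree] = {}
        self._downstream: dict[str, IntervalTree] = {}
        self._by_chrom: dict[str, list[GeneModel]] = {}

        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            self.genes[g.gene_id] = g
            chrom = g.interval.chrom
            clen = chrom_lengths.get(chrom) if chrom_lengths else None
            self._by_chrom.setdefault(chrom, []).append(g)

            pw = promoter_window(g, promoter_up, promoter_down, chrom_length=clen)
            self._promoters.setdefault(chrom, IntervalTree()).addi(
                pw.interval.start, pw.interval.end, g.gene_id
            )
            self._spans.setdefault(chrom, IntervalTree()).addi(
                g.interval.start, g.interval.end, g.gene_id
            )
            for ex in g.exons:
                self._exons.setdefault(chrom, IntervalTree()).addi(
                    ex.start, ex.end, g.gene_id
                )
            if g.strand == "+":
                lo, hi = g.interval.end, g.interval.end + downstream_bp
            else:
                lo, hi = max(0, g.interval.start - downstream_bp), g.interval.start
            if hi > lo:
                self._downstream.setdefault(chrom, IntervalTree()).addi(
                    lo, hi, g.gene_id
                )

    def _hits(self, trees: dict[str, IntervalTree], chrom: str, pos: int) -> list[str]:
        tree = trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))

    def promoter_hits(self, chrom: str, pos: int) -> list[str]:
        return self._hits(self._promoters, chrom, pos)

    def span_hits(self, chrom: str, pos: int) -> list[str]:
        return self._hits(self._spans, chrom, pos)

    def exon_hits(self, chrom: str, pos: int) -> list[str]:
        return self._hits(self._exons, chrom, pos)

    def downstream_hits(self, chrom: str, pos: int) -> list[str]:
        return self._hits(self._downstream, chrom, pos)

    def nearest_by_tss(self, chrom: str, pos: int) -> GeneModel:
        cands = self._by_chrom.get(chrom)
        if not cands:
            raise ValueError(f"no genes on chromosome {chrom!r}")
        return min(cands, key=lambda g: (abs(_signed_distance(g, pos)), g.gene_id))


def _pick(index: GeneIndex, gene_ids: Iterable[str], anchor: int) -> tuple[GeneModel, int]:
    best = min(
        (index.genes[g] for g in gene_ids),
        key=lambda g: (abs(_signed_distance(g, anchor)), g.gene_id),
    )
    return best, _signed_distance(best, anchor)


def annotate_peak(peak: ConsensusPeak, index: GeneIndex) -> AnnotatedPeak:
    """Categorize one consensus peak and assign its target gene."""
    chrom = peak.interval.chrom
    anchor = peak.anchor

    for category, hits in (
        ("promoter", index.promoter_hits(chrom, anchor)),
        ("exon", index.exon_hits(chrom, anchor)),
        ("_span", index.span_hits(chrom, anchor)),
        ("downstream", index.downstream_hits(chrom, anchor)),
    ):
        if not hits:
            continue
        gene, dist = _pick(index, hits, anchor)
        if category == "_span":
            category = "intron" if gene.exons else "gene_body"
        return AnnotatedPeak(
            peak=peak,
            category=category,
            gene_id=gene.gene_id,
            gene_symbol=gene.symbol,
            biotype=gene.biotype,
            distance_to_tss=dist,
        )

    gene = index.nearest_by_tss(chrom, anchor)
    return AnnotatedPeak(
        peak=peak,
        category="distal_intergenic",
        gene_id=gene.gene_id,
        gene_symbol=gene.symbol,
        biotype=gene.biotype,
        distance_to_tss=_signed_distance(gene, anchor),
    )


def annotate_peaks(
    peaks: Iterable[ConsensusPeak], index: GeneIndex
) -> list[AnnotatedPeak]:
    return [annotate_peak(p, index) for p in peaks]


def feature_distribution(annotated: Sequence[AnnotatedPeak]) -> dict[str, float]:
    """Fraction of peaks per feature category; fractions sum to one."""
    if not annotated:
        raise ValueError("cannot compute feature distribution of no peaks")
    n = len(annotated)
    counts = {c: 0 for c in FEATURE_CATEGORIES}
    for a in annotated:
        counts[a.category] += 1
    return {c: counts[c] / n for c in FEATURE_CATEGORIES}


def target_table(
    annotated: Sequence[AnnotatedPeak],
    condition: str,
    exclude_biotypes: set[str] | frozenset[str] = frozenset({"tRNA"}),
) -> TargetTable:
    """Promoter-bound target genes for one condition.

    Keeps only promoter-category rows, drops genes whose biotype is excluded
    (tRNA promoters by default: their dense, short gene bodies otherwise
    flood the target list), and counts distinct peaks and genes.
    """
    rows = [
        {
            "consensus_id": a.peak.name,
            "gene_id": a.gene_id,
            "gene_symbol": a.gene_symbol,
            "biotype": a.biotype,
            "category": a.category,
            "distance_to_tss": a.distance_to_tss,
        }
        for a in annotated
        if a.category == "promoter" and a.biotype not in exclude_biotypes
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "consensus_id", "gene_id", "gene_symbol", "biotype",
            "category", "distance_to_tss",
        ],
    )
    return TargetTable(
        condition=condition,
        rows=df,
        n_unique_peaks=df["consensus_id"].nunique(),
        n_unique_genes=df["gene_id"].nunique(),
    )


def write_annotated_tsv(annotated: Iterable[AnnotatedPeak], stream: IO[str]) -> None:
    w = csv.writer(stream, delimiter="\t", lineterminator="\n")
    w.writerow(
        [
            "consensus_id", "chrom", "start", "end", "support",
            "category", "gene_id", "gene_symbol", "biotype", "distance_to_tss",
        ]
    )
    for a in annotated:
        c = a.peak
        w.writerow(
            [
                c.name, c.interval.chrom, c.interval.start, c.interval.end,
                c.support, a.category, a.gene_id, a.gene_symbol, a.biotype,
                a.distance_to_tss,
            ]
        )


def write_feature_distribution_tsv(
    dist: Mapping[str, float], stream: IO[str]
) -> None:
    w = csv.writer(stream, delimiter="\t", lineterminator="\n")
    w.writerow(["category", "fraction"])
    for c in FEATURE_CATEGORIES:
        w.writerow([c, repr(float(dist.get(c, 0.0)))])
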