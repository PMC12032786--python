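"""Gene models, coordinate conventions, and strand-aware promoter windows.

All coordinates inside the package are 0-based half-open (BED convention).
GFF3 input (1-based, fully closed) is converted on read; the writer converts
back, so a read/write round-trip is the identity on coordinates.

The transcription start site (TSS) of a gene is its first transcribed base:
``interval.start`` on the plus strand and ``interval.end - 1`` on the minus
strand.  A promoter window extends a fixed number of bases "before" and
"after" the TSS *in the direction of transcription*, and always contains the
TSS base itself, so the default 1000/1000 window is 2001 bp wide.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from gffutils.feature import feature_from_line

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "PromoterWindow",
    "GFF3ParseError",
    "read_gene_annotation",
    "write_gene_annotation",
    "tss",
    "promoter_window",
]


class GFF3ParseError(ValueError):
    """Raised on malformed or unacceptable GFF3 records; names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, span, biotype and optional exon structure."""

    gene_id: str
    symbol: str
    interval: GenomicInterval
    strand: str
    biotype: str = "protein_coding"
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        return tss(self)


@dataclass(frozen=True)
class PromoterWindow:
    """The promoter region of one gene; always contains the TSS base."""

    gene_id: str
    interval: GenomicInterval
    upstream_bp: int
    downstream_bp: int


def tss(gene: GeneModel) -> int:
    """First transcribed base of *gene*: start on '+', end-1 on '-'."""
    if gene.strand == "+":
        return gene.interval.start
    return gene.interval.end - 1


def promoter_window(
    gene: GeneModel,
    upstream_bp: int = 1000,
    downstream_bp: int = 1000,
    chrom_length: int | None = None,
) -> PromoterWindow:
    """Strand-aware promoter window around the TSS.

    ``upstream_bp`` bases before and ``downstream_bp`` bases after the TSS are
    counted in the direction of transcription; on the minus strand the genomic
    window is therefore flipped.  The TSS base is always included, so the
    unclamped width is ``upstream_bp + downstream_bp + 1``.  When
    ``chrom_length`` is given the window is clamped to ``[0, chrom_length)``.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("promoter extents must be non-negative")
    pos = tss(gene)
    if gene.strand == "+":
        lo, hi = pos - upstream_bp, pos + downstream_bp + 1
    else:
        lo, hi = pos - downstream_bp, pos + upstream_bp + 1
    lo = max(lo, 0)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return PromoterWindow(
        gene_id=gene.gene_id,
        interval=GenomicInterval(gene.interval.chrom, lo, hi),
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
    )


def _as_lines(stream: IO[str] | str | Iterable[str]) -> Iterable[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def _attr_first(attrs, *keys: str) -> str | None:
    for key in keys:
        if key in attrs:
            vals = attrs[key]
            if vals:
                return vals[0]
    return None


def read_gene_annotation(
    annotation_stream: IO[str] | str | Iterable[str],
    feature_types: Sequence[str] | set[str] = ("gene",),
    exon_feature: str = "exon",
) -> list[GeneModel]:
    """Parse gene-level GFF3 records into :class:`GeneModel` objects.

    ``feature_types`` selects which column-3 types become genes (``tRNA``
    records may appear either as their own feature type or as genes carrying a
    ``biotype``/``gene_biotype`` attribute; both spellings are honoured, with
    the feature type itself as fallback for tRNA records).  Exon child records
    are attached to their parent gene via the ``Parent`` attribute.
    Coordinates are converted from 1-based closed to 0-based half-open.

    Raises :class:`GFF3ParseError` on malformed lines (naming the line
    number), duplicate gene ids, or gene records with strand ``.``.
    """
    wanted = set(feature_types)
    genes: dict[str, dict] = {}
    order: list[str] = []
    exons: dict[str, list[GenomicInterval]] = {}

    for lineno, raw in enumerate(_as_lines(annotation_stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # noqa: BLE001 - reported with line context
            raise GFF3ParseError(f"line {lineno}: malformed GFF3 line ({exc})") from exc
        if feat.start is None or feat.end is None:
            raise GFF3ParseError(f"line {lineno}: missing coordinates")
        if feat.end < feat.start:
            raise GFF3ParseError(
                f"line {lineno}: end {feat.end} < start {feat.start}"
            )
        if feat.featuretype in wanted:
            if feat.strand not in ("+", "-"):
                raise GFF3ParseError(
                    f"line {lineno}: gene record with strand {feat.strand!r} "
                    "(TSS undefined without strand)"
                )
            gene_id = _attr_first(feat.attributes, "ID")
            if gene_id is None:
                raise GFF3ParseError(f"line {lineno}: gene record without ID attribute")
            if gene_id in genes:
                raise GFF3ParseError(
                    f"line {lineno}: duplicate gene id {gene_id!r}"
                )
            biotype = _attr_first(feat.attributes, "biotype", "gene_biotype")
            if biotype is None:
                biotype = feat.featuretype if feat.featuretype == "tRNA" else "protein_coding"
            symbol = _attr_first(feat.attributes, "Name", "gene_name") or gene_id
            genes[gene_id] = {
                "symbol": symbol,
                "interval": GenomicInterval(feat.seqid, feat.start - 1, feat.end),
                "strand": feat.strand,
                "biotype": biotype,
            }
            order.append(gene_id)
        elif feat.featuretype == exon_feature:
            parent = _attr_first(feat.attributes, "Parent")
            if parent is not None:
                exons.setdefault(parent, []).append(
                    GenomicInterval(feat.seqid, feat.start - 1, feat.end)
                )

    out = []
    for gene_id in order:
        rec = genes[gene_id]
        ex = tuple(sorted(exons.get(gene_id, []), key=lambda iv: iv.start))
        out.append(
            GeneModel(
                gene_id=gene_id,
                symbol=rec["symbol"],
                interval=rec["interval"],
                strand=rec["strand"],
                biotype=rec["biotype"],
                exons=ex,
            )
        )
    return out


def write_gene_annotation(genes: Iterable[GeneModel], stream: IO[str]) -> None:
    """Write gene (and exon) records as GFF3, inverting the read conversion."""
    stream.write("##gff-version 3\n")
    for g in genes:
        iv = g.interval
        attrs = f"ID={g.gene_id};Name={g.symbol};biotype={g.biotype}"
        stream.write(
            f"{iv.chrom}\tchiptargets\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{g.strand}\t.\t{attrs}\n"
        )
        for i, ex in enumerate(g.exons, start=1):
            stream.write(
                f"{ex.chrom}\tchiptargets\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
            )
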