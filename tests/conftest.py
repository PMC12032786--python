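from __future__ import annotations

import io

import pytest

from chiptargets import (
    GeneIndex,
    GeneModel,
    GenomicInterval,
    Peak,
)


def make_gene(
    gene_id="g1",
    chrom="chr1",
    start=1000,
    end=3000,
    strand="+",
    biotype="protein_coding",
    exons=(),
):
    return GeneModel(
        gene_id=gene_id,
        symbol=gene_id.upper(),
        interval=GenomicInterval(chrom, start, end),
        strand=strand,
        biotype=biotype,
        exons=tuple(GenomicInterval(chrom, s, e) for s, e in exons),
    )


def make_peak(chrom="chr1", start=100, end=300, replicate_id="rep1", **kw):
    return Peak(interval=GenomicInterval(chrom, start, end),
                replicate_id=replicate_id, **kw)


@pytest.fixture
def toy_gff3():
    return (
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1;biotype=protein_coding\n"
        "chr1\tsrc\texon\t101\t140\t.\t+\t.\tID=g1.e1;Parent=g1\n"
        "chr1\tsrc\texon\t161\t200\t.\t+\t.\tID=g1.e2;Parent=g1\n"
        "chr1\tsrc\tgene\t3001\t5000\t.\t-\t.\tID=g2;Name=GTWO;biotype=protein_coding\n"
        "chr2\tsrc\tgene\t501\t560\t.\t+\t.\tID=t1;biotype=tRNA\n"
    )


@pytest.fixture
def toy_genes():
    # two well-separated genes on one chromosome plus a tRNA
    return [
        make_gene("g1", start=10_000, end=12_000, strand="+",
                  exons=((10_000, 10_400), (11_500, 12_000))),
        make_gene("g2", start=50_000, end=55_000, strand="-"),
        make_gene("t1", start=80_000, end=80_080, strand="+", biotype="tRNA"),
    ]


@pytest.fixture
def toy_index(toy_genes):
    return GeneIndex(toy_genes)
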