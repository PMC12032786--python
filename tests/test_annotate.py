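"""Feature categorization, TSS distances and target tables."""

import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from chiptargets.annotate import (
    FEATURE_CATEGORIES,
    GeneIndex,
    annotate_peak,
    annotate_peaks,
    feature_distribution,
    target_table,
)
from chiptargets.consensus import ConsensusPeak
from chiptargets.genome_model import GeneModel, GenomicInterval
from conftest import make_gene, make_peak


def cons_at(chrom, start, end, summit=None, name="c1"):
    """A one-member consensus peak whose anchor is `summit` (or midpoint)."""
    offset = -1 if summit is None else summit - start
    member = make_peak(chrom=chrom, start=start, end=end, summit_offset=offset)
    return ConsensusPeak(
        interval=GenomicInterval(chrom, start, end),
        support=1,
        members=(member,),
        name=name,
    )


class TestAnnotatePeak:
    def test_anchor_on_plus_tss_is_promoter_distance_zero(self, toy_index):
        a = annotate_peak(cons_at("chr1", 9_900, 10_100, summit=10_000), toy_index)
        assert (a.category, a.gene_id, a.distance_to_tss) == ("promoter", "g1", 0)

    def test_minus_strand_distance_positive_in_transcription_direction(self):
        # TSS at 4999 on the minus strand; an anchor at 4500 lies 499 bases
        # into the transcript, i.e. downstream of the TSS
        gene = make_gene("gm", start=3000, end=5000, strand="-")
        index = GeneIndex([gene])
        a = annotate_peak(cons_at("chr1", 4_400, 4_600, summit=4_500), index)
        assert a.category == "promoter"
        assert a.distance_to_tss == 499

    def test_upstream_anchor_has_negative_distance(self, toy_index):
        a = annotate_peak(cons_at("chr1", 9_400, 9_600, summit=9_500), toy_index)
        assert (a.category, a.distance_to_tss) == ("promoter", -500)

    def test_exon_beats_intron(self, toy_index):
        # inside g1's first exon but outside its promoter window (TSS 10_000)
        a = annotate_peak(cons_at("chr1", 11_550, 11_650, summit=11_600), toy_index)
        assert (a.category, a.gene_id) == ("exon", "g1")

    def test_intron_when_gene_has_exons(self, toy_index):
        a = annotate_peak(cons_at("chr1", 11_150, 11_250, summit=11_200), toy_index)
        assert (a.category, a.gene_id) == ("intron", "g1")

    def test_gene_body_when_no_exon_structure(self, toy_index):
        a = annotate_peak(cons_at("chr1", 52_400, 52_600, summit=52_500), toy_index)
        assert (a.category, a.gene_id) == ("gene_body", "g2")

    def test_downstream_past_tes_in_transcription_direction(self, toy_index):
        # g2 is minus-strand spanning 50_000..55_000: its TES side is 50_000,
        # so "downstream" lies genomically below the gene start
        a = annotate_peak(cons_at("chr1", 48_400, 48_600, summit=48_500), toy_index)
        assert (a.category, a.gene_id) == ("downstream", "g2")

    def test_distal_intergenic_assigns_nearest_gene(self, toy_index):
        a = annotate_peak(cons_at("chr1", 29_900, 30_100, summit=30_000), toy_index)
        assert a.category == "distal_intergenic"
        assert a.gene_id == "g1"  # 20_000 bp from g1's TSS vs 24_999 from g2's

    def test_equidistant_tie_breaks_on_gene_id(self):
        g_a = make_gene("ga", start=1_000, end=2_000, strand="+")   # TSS 1000
        g_b = make_gene("gb", start=8_000, end=9_000, strand="+")   # TSS 8000
        index = GeneIndex([g_b, g_a], downstream_bp=0)
        # anchor 4500 is exactly 3500 bp from both TSSs
        a = annotate_peak(cons_at("chr1", 4_450, 4_552, summit=4_500), index)
        assert abs(a.distance_to_tss) == 3_500
        assert a.gene_id == "ga"  # 'ga' < 'gb' at equal distance

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty gene set"):
            GeneIndex([])

    def test_anchor_prefers_summit_over_midpoint(self, toy_index):
        # summit in g1's promoter even though the midpoint is not
        c = cons_at("chr1", 9_990, 14_000, summit=10_000)
        a = annotate_peak(c, toy_index)
        assert a.category == "promoter"


class TestFeatureDistribution:
    def test_fractions(self, toy_index):
        peaks = [
            cons_at("chr1", 9_950, 10_050, summit=10_000, name=f"c{i}")
            for i in range(3)
        ] + [cons_at("chr1", 29_900, 30_100, summit=30_000, name="c3")]
        dist = feature_distribution(annotate_peaks(peaks, toy_index))
        assert dist["promoter"] == 0.75
        assert dist["distal_intergenic"] == 0.25
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(dist) == set(FEATURE_CATEGORIES)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            feature_distribution([])


class TestTargetTable:
    def test_trna_promoters_excluded(self, toy_index):
        peaks = [
            cons_at("chr1", 9_950, 10_050, summit=10_000, name="c1"),
            cons_at("chr1", 80_000, 80_100, summit=80_000, name="c2"),  # t1 TSS
        ]
        ann = annotate_peaks(peaks, toy_index)
        assert {a.category for a in ann} == {"promoter"}
        table = target_table(ann, "cond")
        assert table.gene_ids == {"g1"}
        assert table.n_unique_genes == 1
        no_excl = target_table(ann, "cond", exclude_biotypes=set())
        assert no_excl.gene_ids == {"g1", "t1"}

    def test_two_peaks_one_gene_counts(self, toy_index):
        peaks = [
            cons_at("chr1", 9_950, 10_050, summit=10_000, name="c1"),
            cons_at("chr1", 10_400, 10_600, summit=10_500, name="c2"),
        ]
        table = target_table(annotate_peaks(peaks, toy_index), "cond")
        assert table.n_unique_peaks == 2
        assert table.n_unique_genes == 1

    def test_non_promoter_rows_dropped(self, toy_index):
        peaks = [cons_at("chr1", 29_900, 30_100, summit=30_000)]
        table = target_table(annotate_peaks(peaks, toy_index), "cond")
        assert len(table.rows) == 0
        assert table.n_unique_genes == 0


@st.composite
def random_genome_and_anchors(draw):
    n_genes = draw(st.integers(1, 6))
    genes = []
    pos = draw(st.integers(0, 2_000))
    for i in range(n_genes):
        width = draw(st.integers(50, 3_000))
        strand = draw(st.sampled_from("+-"))
        exon_mode = draw(st.booleans())
        exons = ()
        if exon_mode and width >= 100:
            a = draw(st.integers(0, width // 2 - 1))
            b = draw(st.integers(a + 1, width // 2))
            c = draw(st.integers(width // 2 + 1, width - 1))
            exons = ((pos + a, pos + b), (pos + c, pos + width))
        genes.append(
            make_gene(f"g{i:02d}", start=pos, end=pos + width, strand=strand,
                      exons=exons)
        )
        pos += width + draw(st.integers(0, 8_000))
    anchors = draw(
        st.lists(st.integers(0, pos + 5_000), min_size=1, max_size=12)
    )
    return genes, anchors, pos + 10_000


def _mirror_gene(g: GeneModel, L: int) -> GeneModel:
    iv = g.interval
    return GeneModel(
        gene_id=g.gene_id,
        symbol=g.symbol,
        interval=GenomicInterval(iv.chrom, L - iv.end, L - iv.start),
        strand="-" if g.strand == "+" else "+",
        biotype=g.biotype,
        exons=tuple(
            sorted(
                (GenomicInterval(e.chrom, L - e.end, L - e.start) for e in g.exons),
                key=lambda e: e.start,
            )
        ),
    )


class TestAnnotationInvariants:
    @seed(20240921)
    @given(random_genome_and_anchors())
    @settings(max_examples=150, deadline=None)
    def test_mirror_symmetry(self, data):
        """Reflecting genes and anchors through L preserves category and
        TSS distance (distances are defined along transcription)."""
        genes, anchors, L = data
        idx = GeneIndex(genes)
        midx = GeneIndex([_mirror_gene(g, L) for g in genes])
        for i, anchor in enumerate(anchors):
            a = annotate_peak(
                cons_at("chr1", anchor, anchor + 1, summit=anchor, name=f"c{i}"), idx
            )
            m = annotate_peak(
                cons_at("chr1", L - 1 - anchor, L - anchor,
                        summit=L - 1 - anchor, name=f"c{i}"), midx
            )
            assert m.category == a.category
            assert m.distance_to_tss == a.distance_to_tss

    @seed(20240922)
    @given(random_genome_and_anchors())
    @settings(max_examples=100, deadline=None)
    def test_every_peak_gets_one_category_one_gene(self, data):
        genes, anchors, _ = data
        idx = GeneIndex(genes)
        for i, anchor in enumerate(anchors):
            a = annotate_peak(
                cons_at("chr1", anchor, anchor + 1, summit=anchor, name=f"c{i}"), idx
            )
            assert a.category in FEATURE_CATEGORIES
            assert a.gene_id in idx.genes

    @seed(20240923)
    @given(random_genome_and_anchors(), st.integers(0, 2000), st.integers(0, 2000))
    @settings(max_examples=100, deadline=None)
    def test_promoter_count_monotone_in_extents(self, data, up, down):
        genes, anchors, _ = data
        peaks = [
            cons_at("chr1", a, a + 1, summit=a, name=f"c{i}")
            for i, a in enumerate(anchors)
        ]
        small = GeneIndex(genes, promoter_up=up, promoter_down=down)
        big = GeneIndex(genes, promoter_up=up + 500, promoter_down=down + 500)
        n_small = sum(
            1 for p in peaks if annotate_peak(p, small).category == "promoter"
        )
        n_big = sum(
            1 for p in peaks if annotate_peak(p, big).category == "promoter"
        )
        assert n_big >= n_small
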