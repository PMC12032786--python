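"""Tolerance matching and replicate-consensus clustering."""

import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from chiptargets.consensus import (
    ConsensusPeak,
    ToleranceParams,
    consensus_peaks,
    match_with_tolerance,
)
from chiptargets.genome_model import GenomicInterval
from conftest import make_peak
from oracles import expand_and_touch, union_find_consensus


class TestMatchWithTolerance:
    @pytest.mark.parametrize(
        "a,b,tol,expected",
        [
            (("chr1", 100, 200), ("chr1", 150, 250), 0, True),   # direct overlap
            (("chr1", 100, 200), ("chr1", 208, 300), 5, True),   # gap 8 <= 10
            (("chr1", 100, 200), ("chr1", 215, 300), 5, False),  # gap 15 > 10
            (("chr1", 100, 200), ("chr1", 200, 300), 0, True),   # abutting, gap 0
            (("chr1", 100, 200), ("chr2", 100, 200), 50, False), # other chrom
        ],
    )
    def test_examples(self, a, b, tol, expected):
        ia, ib = GenomicInterval(*a), GenomicInterval(*b)
        assert match_with_tolerance(ia, ib, tol) is expected
        assert match_with_tolerance(ib, ia, tol) is expected  # symmetric

    def test_single_mode_bridges_half_the_gap(self):
        a, b = GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 108, 200)
        assert match_with_tolerance(a, b, 5, tol_mode="both")
        assert not match_with_tolerance(a, b, 5, tol_mode="single")
        assert match_with_tolerance(a, b, 8, tol_mode="single")

    @given(
        s1=st.integers(0, 500), w1=st.integers(1, 100),
        s2=st.integers(0, 500), w2=st.integers(1, 100),
        tol=st.sampled_from([0, 5, 10]),
        mode=st.sampled_from(["both", "single"]),
    )
    @settings(max_examples=500, deadline=None)
    def test_agrees_with_expansion_oracle(self, s1, w1, s2, w2, tol, mode):
        a = GenomicInterval("chr1", s1, s1 + w1)
        b = GenomicInterval("chr1", s2, s2 + w2)
        assert match_with_tolerance(a, b, tol, mode) == expand_and_touch(a, b, tol, mode)


class TestConsensusPeaks:
    def test_single_replicate_cannot_reach_support_two(self):
        reps = [[make_peak(start=100, end=200)]]
        assert consensus_peaks(reps, ToleranceParams(min_support=2)) == []

    def test_identical_peak_in_three_replicates(self):
        reps = [
            [make_peak(start=100, end=200, replicate_id=f"r{i}")] for i in range(3)
        ]
        (c,) = consensus_peaks(reps, ToleranceParams())
        assert (c.interval.start, c.interval.end) == (100, 200)
        assert c.support == 3
        assert c.name == "cons_1"

    def test_tolerance_bridged_chain_takes_union_span(self):
        reps = [
            [make_peak(start=100, end=200, replicate_id="r1")],
            [make_peak(start=208, end=300, replicate_id="r2")],
            [],
        ]
        (c,) = consensus_peaks(reps, ToleranceParams(tol_bp=5, min_support=2))
        assert (c.interval.start, c.interval.end) == (100, 300)
        assert c.support == 2

    def test_multiple_peaks_from_one_replicate_count_once(self):
        reps = [
            [make_peak(start=100, end=200, replicate_id="r1"),
             make_peak(start=150, end=250, replicate_id="r1")],
            [make_peak(start=190, end=260, replicate_id="r2")],
        ]
        (c,) = consensus_peaks(reps, ToleranceParams(min_support=2))
        assert c.support == 2
        assert len(c.members) == 3

    def test_mixed_condition_labels_rejected(self):
        reps = [
            [make_peak(condition="a")],
            [make_peak(condition="b", replicate_id="rep2")],
        ]
        with pytest.raises(ValueError, match="mixed condition"):
            consensus_peaks(reps, ToleranceParams())

    def test_output_sorted_by_chrom_start(self):
        reps = [
            [make_peak(chrom="chr2", start=10, end=20, replicate_id="r1"),
             make_peak(chrom="chr1", start=500, end=600, replicate_id="r1"),
             make_peak(chrom="chr1", start=5, end=15, replicate_id="r1")],
            [make_peak(chrom="chr2", start=12, end=22, replicate_id="r2"),
             make_peak(chrom="chr1", start=505, end=610, replicate_id="r2"),
             make_peak(chrom="chr1", start=6, end=14, replicate_id="r2")],
        ]
        cons = consensus_peaks(reps, ToleranceParams())
        keys = [(c.interval.chrom, c.interval.start) for c in cons]
        assert keys == sorted(keys)
        assert [c.name for c in cons] == ["cons_1", "cons_2", "cons_3"]

    def test_consensus_interval_invariant_enforced(self):
        with pytest.raises(ValueError, match="union span"):
            ConsensusPeak(
                interval=GenomicInterval("chr1", 0, 50),
                support=1,
                members=(make_peak(start=100, end=200),),
            )


@st.composite
def random_instance(draw):
    n_reps = draw(st.integers(2, 4))
    reps = []
    for r in range(n_reps):
        n = draw(st.integers(0, 12))
        peaks = []
        for i in range(n):
            start = draw(st.integers(0, 400))
            width = draw(st.integers(1, 60))
            chrom = draw(st.sampled_from(["chr1", "chr2"]))
            peaks.append(
                make_peak(chrom=chrom, start=start, end=start + width,
                          replicate_id=f"r{r}", name=f"r{r}_p{i}")
            )
        reps.append(peaks)
    tol = draw(st.sampled_from([0, 5, 10]))
    mode = draw(st.sampled_from(["both", "single"]))
    return reps, tol, mode


def _oracle_clusters(reps, tol, mode, min_support):
    flat = [p for rep in reps for p in rep]
    out = set()
    for cluster in union_find_consensus(flat, tol, mode):
        members = [flat[i] for i in cluster]
        if len({m.replicate_id for m in members}) >= min_support:
            out.add(frozenset((m.replicate_id, m.name) for m in members))
    return out


class TestOracleEquivalence:
    @seed(20240917)
    @given(random_instance())
    @settings(max_examples=300, deadline=None)
    def test_cluster_membership_and_support_match_union_find(self, instance):
        """Sweep-based single linkage equals brute-force all-pairs union-find."""
        reps, tol, mode = instance
        params = ToleranceParams(tol_bp=tol, min_support=2, tol_mode=mode)
        got = {
            frozenset((m.replicate_id, m.name) for m in c.members): c.support
            for c in consensus_peaks(reps, params)
        }
        expected = _oracle_clusters(reps, tol, mode, 2)
        assert set(got) == expected
        for key, support in got.items():
            assert support == len({rep for rep, _ in key})

    @seed(20240918)
    @given(random_instance())
    @settings(max_examples=200, deadline=None)
    def test_emitted_peaks_are_mutually_unmatchable(self, instance):
        """Maximality: no two consensus peaks on one chromosome still match."""
        reps, tol, mode = instance
        cons = consensus_peaks(reps, ToleranceParams(tol, 1, mode))
        for i, a in enumerate(cons):
            for b in cons[i + 1:]:
                if a.interval.chrom == b.interval.chrom:
                    assert not match_with_tolerance(
                        a.interval, b.interval, tol, mode
                    )

    @seed(20240919)
    @given(random_instance())
    @settings(max_examples=200, deadline=None)
    def test_min_support_one_partitions_all_input_peaks(self, instance):
        reps, tol, mode = instance
        cons = consensus_peaks(reps, ToleranceParams(tol, 1, mode))
        seen = [(m.replicate_id, m.name) for c in cons for m in c.members]
        flat = [(p.replicate_id, p.name) for rep in reps for p in rep]
        assert sorted(seen) == sorted(flat)

    @seed(20240920)
    @given(random_instance(), st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_input_order_permutation(self, instance, rnd):
        reps, tol, mode = instance
        params = ToleranceParams(tol_bp=tol, min_support=2, tol_mode=mode)
        baseline = consensus_peaks(reps, params)
        shuffled = [list(rep) for rep in reps]
        for rep in shuffled:
            rnd.shuffle(rep)
        rnd.shuffle(shuffled)
        assert consensus_peaks(shuffled, params) == baseline
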