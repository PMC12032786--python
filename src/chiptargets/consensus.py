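"""Replicate-consensus ("high confidence") peak calling.

Two peaks are treated as reporting the same binding locus when their
intervals, each slackened by a tolerance of ``tol_bp`` on both sides, overlap
or touch.  Peaks are clustered per chromosome by single linkage under this
relation (the transitive closure of the pairwise rule, so chains are possible
and accepted), and a cluster is emitted as a consensus peak when its members
come from at least ``min_support`` distinct replicates.  The consensus
interval is the union span of its members: jittered replicate peaks can
satisfy the tolerance rule while having an empty intersection, so the union
is the only span guaranteed to cover every supporting observation.

Two tolerance readings are supported.  The default, ``both``, slackens each
peak by ``tol_bp`` on each side, so two peaks separated by a gap of up to
``2 * tol_bp`` match; the stricter ``single`` mode bridges gaps of at most
``tol_bp``.  Abutting intervals (gap 0) always match.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from .genome_model import GenomicInterval
from .peaks_io import Peak

__all__ = [
    "ToleranceParams",
    "ConsensusPeak",
    "match_with_tolerance",
    "consensus_peaks",
    "write_consensus_bed",
    "write_consensus_members",
    "read_consensus_members",
]

_TOL_MODES = ("both", "single")


@dataclass(frozen=True)
class ToleranceParams:
    """Clustering parameters: coordinate slack and replicate support."""

    tol_bp: int = 5
    min_support: int = 2
    tol_mode: str = "both"

    def __post_init__(self) -> None:
        if self.tol_bp < 0:
            raise ValueError("tol_bp must be non-negative")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.tol_mode not in _TOL_MODES:
            raise ValueError(f"tol_mode must be one of {_TOL_MODES}")

    @property
    def max_gap(self) -> int:
        return 2 * self.tol_bp if self.tol_mode == "both" else self.tol_bp


@dataclass(frozen=True)
class ConsensusPeak:
    """A cluster of tolerance-matched peaks across replicates."""

    interval: GenomicInterval
    support: int
    members: tuple[Peak, ...]
    condition: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("consensus peak must have members")
        starts = [m.interval.start for m in self.members]
        ends = [m.interval.end for m in self.members]
        if self.interval.start != min(starts) or self.interval.end != max(ends):
            raise ValueError("consensus interval must be the union span of members")
        reps = {m.replicate_id for m in self.members}
        if self.support != len(reps):
            raise ValueError("support must equal the number of distinct replicates")

    @property
    def anchor(self) -> int:
        """Representative point: median member summit, else interval midpoint.

        The lower median of the absolute summit positions of members that
        carry one; deterministic and robust to a single outlying replicate.
        """
        summits = sorted(m.summit for m in self.members if m.summit is not None)
        if summits:
            return summits[(len(summits) - 1) // 2]
        return self.interval.start + self.interval.width // 2


def _gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Separation in bp; 0 for overlapping or adjacent intervals."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def match_with_tolerance(
    a: GenomicInterval,
    b: GenomicInterval,
    tol_bp: int,
    tol_mode: str = "both",
) -> bool:
    """True when *a* and *b* report the same locus within the tolerance.

    Equivalent to expanding each interval by ``tol_bp`` on both sides
    (``both`` mode) and testing for overlap or adjacency; i.e.
    ``gap(a, b) <= 2 * tol_bp``.  ``single`` mode tests ``gap <= tol_bp``.
    Intervals on different chromosomes never match.
    """
    if a.chrom != b.chrom:
        return False
    if tol_mode not in _TOL_MODES:
        raise ValueError(f"tol_mode must be one of {_TOL_MODES}")
    max_gap = 2 * tol_bp if tol_mode == "both" else tol_bp
    return _gap(a, b) <= max_gap


def consensus_peaks(
    replicate_sets: Sequence[Sequence[Peak]],
    params: ToleranceParams = ToleranceParams(),
) -> list[ConsensusPeak]:
    """Single-linkage consensus clustering of per-replicate peak calls.

    Peaks are grouped per chromosome; clusters whose members span at least
    ``params.min_support`` distinct replicates are emitted sorted by
    (chrom, start).  Multiple peaks from one replicate in a cluster count
    once toward support.  All peaks must share one condition label.
    """
    if not replicate_sets:
        raise ValueError("need at least one replicate set")

    all_peaks: list[Peak] = []
    for i, reps in enumerate(replicate_sets):
        for p in reps:
            q = p if p.replicate_id else p.relabel(replicate_id=f"rep{i + 1}")
            all_peaks.append(q)

    conditions = {p.condition for p in all_peaks}
    if len(conditions) > 1:
        raise ValueError(f"mixed condition labels in input: {sorted(conditions)}")
    condition = conditions.pop() if conditions else ""

    max_gap = params.max_gap
    by_chrom: dict[str, list[Peak]] = {}
    for p in all_peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)

    out: list[ConsensusPeak] = []
    for chrom in sorted(by_chrom):
        # deterministic within-cluster member order regardless of input order
        peaks = sorted(
            by_chrom[chrom],
            key=lambda p: (p.interval.start, p.interval.end, p.replicate_id, p.name),
        )
        # sweep: on a line, single-linkage clusters under "gap <= max_gap"
        # are exactly the connected runs where each peak starts within
        # max_gap of the running maximum end.
        cluster: list[Peak] = []
        cluster_end = -1
        for p in peaks:
            if cluster and p.interval.start > cluster_end + max_gap:
                out.extend(_emit(cluster, condition, params.min_support))
                cluster = []
                cluster_end = -1
            cluster.append(p)
            cluster_end = max(cluster_end, p.interval.end)
        if cluster:
            out.extend(_emit(cluster, condition, params.min_support))

    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return [
        ConsensusPeak(
            interval=c.interval,
            support=c.support,
            members=c.members,
            condition=c.condition,
            name=f"cons_{k + 1}",
        )
        for k, c in enumerate(out)
    ]


def _emit(cluster: list[Peak], condition: str, min_support: int) -> list[ConsensusPeak]:
    reps = {p.replicate_id for p in cluster}
    if len(reps) < min_support:
        return []
    iv = GenomicInterval(
        cluster[0].interval.chrom,
        min(p.interval.start for p in cluster),
        max(p.interval.end for p in cluster),
    )
    return [
        ConsensusPeak(
            interval=iv, support=len(reps), members=tuple(cluster), condition=condition
        )
    ]


def write_consensus_bed(consensus: Iterable[ConsensusPeak], stream: IO[str]) -> None:
    """BED6 output: name = cons_<k>, score = replicate support, strand '.'."""
    for c in consensus:
        stream.write(
            f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
            f"{c.name}\t{c.support}\t.\n"
        )


_MEMBER_COLS = [
    "consensus_id", "condition", "support",
    "cons_chrom", "cons_start", "cons_end",
    "replicate_id", "chrom", "start", "end", "name", "score", "strand",
    "signal_value", "pvalue_neglog10", "qvalue_neglog10", "summit_offset",
]


def write_consensus_members(consensus: Iterable[ConsensusPeak], stream: IO[str]) -> None:
    """TSV of every member peak keyed by its consensus id (lossless)."""
    w = csv.writer(stream, delimiter="\t", lineterminator="\n")
    w.writerow(_MEMBER_COLS)
    for c in consensus:
        for m in c.members:
            w.writerow(
                [
                    c.name, c.condition, c.support,
                    c.interval.chrom, c.interval.start, c.interval.end,
                    m.replicate_id, m.interval.chrom, m.interval.start,
                    m.interval.end, m.name, m.score, m.strand,
                    repr(m.signal_value), repr(m.pvalue_neglog10),
                    repr(m.qvalue_neglog10), m.summit_offset,
                ]
            )


def read_consensus_members(stream: IO[str]) -> list[ConsensusPeak]:
    """Rebuild consensus peaks from a members TSV written by this module."""
    r = csv.DictReader(stream, delimiter="\t")
    groups: dict[str, dict] = {}
    order: list[str] = []
    for row in r:
        cid = row["consensus_id"]
        if cid not in groups:
            groups[cid] = {
                "condition": row["condition"],
                "support": int(row["support"]),
                "interval": GenomicInterval(
                    row["cons_chrom"], int(row["cons_start"]), int(row["cons_end"])
                ),
                "members": [],
            }
            order.append(cid)
        groups[cid]["members"].append(
            Peak(
                interval=GenomicInterval(
                    row["chrom"], int(row["start"]), int(row["end"])
                ),
                name=row["name"],
                score=int(row["score"]),
                strand=row["strand"],
                signal_value=float(row["signal_value"]),
                pvalue_neglog10=float(row["pvalue_neglog10"]),
                qvalue_neglog10=float(row["qvalue_neglog10"]),
                summit_offset=int(row["summit_offset"]),
                replicate_id=row["replicate_id"],
                condition=row["condition"],
            )
        )
    return [
        ConsensusPeak(
            interval=g["interval"],
            support=g["support"],
            members=tuple(g["members"]),
            condition=g["condition"],
            name=cid,
        )
        for cid, g in ((cid, groups[cid]) for cid in order)
    ]
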