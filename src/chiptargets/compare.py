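"""Venn-style partitions of target-gene sets and assembly concordance.

Cross-condition and cross-assembly comparisons are made at the gene level
(genes with at least one promoter-bound consensus peak), the only level at
which identity across analyses is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

__all__ = ["SetPartition", "ConcordanceResult", "partition_gene_sets", "assembly_concordance"]


@dataclass(frozen=True)
class SetPartition:
    """Disjoint Venn-region counts over 2 or 3 labeled gene sets."""

    set_labels: tuple[str, ...]
    region_counts: dict[frozenset, int]
    universe_size: int

    def to_json_dict(self) -> dict:
        return {
            "set_labels": list(self.set_labels),
            "regions": {
                "&".join(sorted(k)): v for k, v in sorted(
                    self.region_counts.items(), key=lambda kv: sorted(kv[0])
                )
            },
            "universe_size": self.universe_size,
        }


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement between two gene sets (e.g. from two genome assemblies)."""

    only_a: int
    only_b: int
    both: int

    @property
    def concordance(self) -> float:
        """Intersection over union."""
        return self.both / (self.only_a + self.only_b + self.both)

    @property
    def concordance_vs_smaller(self) -> float:
        """Intersection over the smaller set (alternative convention)."""
        smaller = min(self.only_a + self.both, self.only_b + self.both)
        return self.both / smaller if smaller else 0.0

    def to_json_dict(self) -> dict:
        return {
            "only_a": self.only_a,
            "only_b": self.only_b,
            "both": self.both,
            "concordance_iou": self.concordance,
            "concordance_vs_smaller": self.concordance_vs_smaller,
        }


def partition_gene_sets(named_sets: Mapping[str, set[str]]) -> SetPartition:
    """Disjoint-region (Venn) counts over 2 or 3 labeled gene-id sets.

    Every element of the union is counted in exactly one region, keyed by the
    frozenset of labels whose sets contain it; regions sum to the universe.
    """
    labels = tuple(named_sets)
    if not 2 <= len(labels) <= 3:
        raise ValueError("partition_gene_sets takes 2 or 3 sets")
    sets = {lab: set(named_sets[lab]) for lab in labels}

    regions: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[lab] for lab in combo))
            outside = set.union(
                set(), *(sets[lab] for lab in labels if lab not in combo)
            )
            regions[frozenset(combo)] = len(inside - outside)

    universe = len(set.union(*sets.values()))
    return SetPartition(
        set_labels=labels, region_counts=regions, universe_size=universe
    )


def assembly_concordance(
    genes_a: set[str],
    genes_b: set[str],
    synonym_map: Mapping[str, str] | None = None,
) -> ConcordanceResult:
    """Shared/unshared counts and concordance of two gene-symbol sets.

    ``synonym_map`` optionally maps symbols to a shared namespace before the
    comparison (applied to both sets).
    """
    if synonym_map:
        genes_a = {synonym_map.get(g, g) for g in genes_a}
        genes_b = {synonym_map.get(g, g) for g in genes_b}
    if not genes_a and not genes_b:
        raise ValueError("concordance undefined for two empty sets")
    both = len(genes_a & genes_b)
    return ConcordanceResult(
        only_a=len(genes_a - genes_b),
        only_b=len(genes_b - genes_a),
        both=both,
    )
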