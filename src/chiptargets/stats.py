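"""Hypergeometric overlap enrichment and two-sample mapping-rate tests.

The enrichment test asks whether the overlap between the target genes found
here and a prior study's target list is larger than expected for random draws
from a common gene universe.  With q = observed overlap, m = prior-study
targets, n = universe minus prior targets, and k = targets in this study, the
overlap under the null is hypergeometric; both the point probability
P(X = q) and the enrichment tail P(X >= q) are reported, the tail being the
headline value (a point density is not a test of enrichment).

Mapping-summary comparisons use Welch's unequal-variance two-sample t-test
on per-sample category fractions, so library-size differences between
samples do not drive the comparison; a pooled-variance variant is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "MappingStats",
    "TwoSampleTestResult",
    "hypergeom_density",
    "hypergeom_upper_tail",
    "hypergeom_support_distribution",
    "overlap_enrichment",
    "compare_mapping_stats",
    "read_mapping_stats",
    "read_gene_list",
]

logger = logging.getLogger(__name__)

MAPPING_CATEGORIES = ("unique", "multi", "unmapped")


@dataclass(frozen=True)
class EnrichmentInput:
    """Overlap counts in the q/m/n/k convention of R's ``phyper``."""

    q: int  # genes in both this study and the prior study
    m: int  # prior-study target genes
    n: int  # universe genes not in the prior study
    k: int  # this study's target genes

    def __post_init__(self) -> None:
        if min(self.q, self.m, self.n, self.k) < 0:
            raise ValueError("q, m, n, k must be non-negative")
        if self.q > min(self.m, self.k):
            raise ValueError(f"q={self.q} exceeds min(m={self.m}, k={self.k})")
        if self.k > self.m + self.n:
            raise ValueError(f"k={self.k} exceeds universe m+n={self.m + self.n}")
        if self.k - self.q > self.n:
            raise ValueError(
                f"k-q={self.k - self.q} non-overlap draws exceed n={self.n}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    input: EnrichmentInput
    p_density: float
    p_upper: float
    expected_overlap: float
    fold_enrichment: float | None

    def to_json_dict(self) -> dict:
        d = self.input
        return {
            "q": d.q, "m": d.m, "n": d.n, "k": d.k,
            "p_density": self.p_density,
            "p_upper": self.p_upper,
            "expected_overlap": self.expected_overlap,
            "fold_enrichment": self.fold_enrichment,
        }


@dataclass(frozen=True)
class MappingStats:
    """Per-sample read-mapping summary for one assembly."""

    sample_id: str
    assembly_id: str
    n_unique: int
    n_multi: int
    n_unmapped: int

    def __post_init__(self) -> None:
        if min(self.n_unique, self.n_multi, self.n_unmapped) < 0:
            raise ValueError("read counts must be non-negative")
        if self.total == 0:
            raise ValueError(f"sample {self.sample_id}: zero total reads")

    @property
    def total(self) -> int:
        return self.n_unique + self.n_multi + self.n_unmapped

    def fraction(self, category: str) -> float:
        if category not in MAPPING_CATEGORIES:
            raise ValueError(f"category must be one of {MAPPING_CATEGORIES}")
        return getattr(self, f"n_{category}") / self.total


@dataclass(frozen=True)
class TwoSampleTestResult:
    category: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_a: float
    mean_b: float

    def to_json_dict(self) -> dict:
        return {
            "category": self.category,
            "t": self.t_statistic,
            "df": self.degrees_of_freedom,
            "p": self.p_value,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
        }


def hypergeom_density(inp: EnrichmentInput) -> float:
    """Point probability P(X = q) of the overlap under the null.

    C(m, q) * C(n, k - q) / C(m + n, k), evaluated in log space by scipy for
    numerical stability at genome-scale counts.  An empty universe admits
    only the empty draw, so its probability is 1.
    """
    if inp.m + inp.n == 0:
        return 1.0
    return float(_st.hypergeom.pmf(inp.q, inp.m + inp.n, inp.m, inp.k))


def hypergeom_support_distribution(
    m: int, n: int, k: int
) -> "tuple[list[int], list[float]]":
    """Overlap values with nonzero probability and their densities.

    Returns ``(qs, probs)`` over the support ``max(0, k-n) .. min(m, k)``;
    the probabilities sum to 1.  Useful for plotting the null distribution
    of an overlap and for expectation calculations.
    """
    qs = list(range(max(0, k - n), min(m, k) + 1))
    if m + n == 0:
        return qs, [1.0]
    probs = _st.hypergeom.pmf(np.array(qs), m + n, m, k)
    return qs, [float(p) for p in probs]


def hypergeom_upper_tail(inp: EnrichmentInput) -> float:
    """Enrichment tail P(X >= q); exactly 1 when q = 0."""
    if inp.q == 0:
        return 1.0
    return float(_st.hypergeom.sf(inp.q - 1, inp.m + inp.n, inp.m, inp.k))


def overlap_enrichment(
    our_genes: set[str],
    prior_genes: set[str],
    universe: set[str],
) -> EnrichmentResult:
    """Hypergeometric overlap enrichment of two gene sets in a universe.

    Elements outside the universe are dropped with a logged warning; the
    universe itself must be explicit and non-empty.
    """
    if not universe:
        raise ValueError("empty gene universe")
    ours = set(our_genes) & universe
    prior = set(prior_genes) & universe
    dropped = (len(our_genes) - len(ours)) + (len(prior_genes) - len(prior))
    if dropped:
        logger.warning(
            "overlap_enrichment: dropped %d gene(s) outside the universe", dropped
        )
    inp = EnrichmentInput(
        q=len(ours & prior),
        m=len(prior),
        n=len(universe) - len(prior),
        k=len(ours),
    )
    expected = inp.k * inp.m / (inp.m + inp.n)
    fold = inp.q / expected if expected > 0 else None
    return EnrichmentResult(
        input=inp,
        p_density=hypergeom_density(inp),
        p_upper=hypergeom_upper_tail(inp),
        expected_overlap=expected,
        fold_enrichment=fold,
    )


def compare_mapping_stats(
    group_a: Sequence[MappingStats],
    group_b: Sequence[MappingStats],
    category: str,
    equal_var: bool = False,
) -> TwoSampleTestResult:
    """Two-sample t-test on per-sample mapping fractions (Welch by default).

    Orientation is fixed: the t statistic has the sign of mean_b - mean_a,
    so with group_a = original assembly and group_b = updated assembly a
    positive t means the updated assembly improved the category fraction.
    Two identical constant groups give t = 0, p = 1 rather than NaN.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    xa = [s.fraction(category) for s in group_a]
    xb = [s.fraction(category) for s in group_b]
    mean_a = sum(xa) / len(xa)
    mean_b = sum(xb) / len(xb)

    var_a = sum((x - mean_a) ** 2 for x in xa)
    var_b = sum((x - mean_b) ** 2 for x in xb)
    if var_a == 0.0 and var_b == 0.0:
        if mean_a == mean_b:
            df = float(len(xa) + len(xb) - 2)
            return TwoSampleTestResult(category, 0.0, df, 1.0, mean_a, mean_b)
        raise ValueError(
            "degenerate input: zero variance in both groups with unequal means"
        )

    res = _st.ttest_ind(xb, xa, equal_var=equal_var)
    return TwoSampleTestResult(
        category=category,
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        mean_a=mean_a,
        mean_b=mean_b,
    )


def read_mapping_stats(stream: IO[str] | str) -> list[MappingStats]:
    """Read a mapping-summary TSV with the canonical five-column header."""
    df = pd.read_csv(stream, sep="\t")
    required = {"sample_id", "assembly_id", "n_unique", "n_multi", "n_unmapped"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mapping-stats table missing columns: {sorted(missing)}")
    return [
        MappingStats(
            sample_id=str(r.sample_id),
            assembly_id=str(r.assembly_id),
            n_unique=int(r.n_unique),
            n_multi=int(r.n_multi),
            n_unmapped=int(r.n_unmapped),
        )
        for r in df.itertuples()
    ]


def read_gene_list(stream: IO[str] | str) -> set[str]:
    """Read a gene list, one symbol per line; blank lines and '#' skipped."""
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream
    return {
        ln.strip() for ln in lines if ln.strip() and not ln.strip().startswith("#")
    }
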