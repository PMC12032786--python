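"""Seedable synthetic data emulating the statistical structure of a
transcription-factor ChIP-Seq study.

The generator produces (a) a small genome's worth of non-overlapping gene
models with a tRNA-biotype subset, (b) per-condition replicate peak sets in
which planted target genes receive promoter-proximal peaks with bounded
coordinate jitter and per-replicate detection dropout plus replicate-private
background peaks, and (c) per-sample read-mapping summary tables with
configurable between-assembly differences.  It does not model reads,
fragment coverage, or motif sequence content.

Randomness is hierarchical: one integer seed spawns an independent stream
for the genome, for each condition (keyed by a stable hash of its label) and
for each replicate, so adding a condition perturbs nothing else.  Background
peaks avoid promoter windows by rejection sampling, so false-positive
"target genes" can arise only through the consensus rule's tolerance —
making precision against the planted truth a meaningful metric.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome_model import (
    GeneModel,
    GenomicInterval,
    promoter_window,
    tss,
    write_gene_annotation,
)
from .peaks_io import Peak, write_narrowpeak
from .stats import MappingStats

__all__ = [
    "ConditionSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_condition",
    "simulate_mapping_stats",
    "mapping_stats_to_tsv",
]


@dataclass(frozen=True)
class ConditionSpec:
    label: str
    n_replicates: int = 3
    n_target_genes: int = 40


# Default study design: five conditions of three replicates each, with more
# targets in adults than juveniles and fewest in the singing state.
_DEFAULT_CONDITIONS = (
    ConditionSpec("adult_male_ns", 3, 40),
    ConditionSpec("adult_female_ns", 3, 35),
    ConditionSpec("juvenile_female_ns", 3, 20),
    ConditionSpec("juvenile_male_ns", 3, 25),
    ConditionSpec("juvenile_male_s", 3, 15),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe one 2 Mb chromosome with 200 genes (10% tRNA), three
    replicates per condition, a 90% per-replicate detection probability for
    planted promoter peaks, 2 bp boundary jitter, and 50 replicate-private
    background peaks — a scale at which the whole pipeline runs in seconds
    while preserving the qualitative structure of a real experiment.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 2_000_000
    n_genes: int = 200
    frac_trna: float = 0.10
    min_gene_gap: int = 2_000
    gene_length_range: tuple[int, int] = (500, 3_000)
    conditions: tuple[ConditionSpec, ...] = _DEFAULT_CONDITIONS
    detection_prob: float = 0.9
    jitter_sd: float = 2.0
    peak_width_range: tuple[int, int] = (150, 400)
    background_peaks_per_replicate: int = 50
    promoter_offset_max: int = 500
    promoter_up: int = 1_000
    promoter_down: int = 1_000
    n_trna_targets: int = 0  # deliberately planted tRNA-promoter controls

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")
        if not 0.0 <= self.frac_trna <= 1.0:
            raise ValueError("frac_trna must be in [0, 1]")
        if self.promoter_offset_max > min(self.promoter_up, self.promoter_down):
            raise ValueError(
                "promoter_offset_max must not exceed the promoter extents"
            )
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("invalid gene_length_range")
        if self.peak_width_range[0] > self.peak_width_range[1]:
            raise ValueError("invalid peak_width_range")

    def condition(self, label: str) -> ConditionSpec:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(f"condition {label!r} not in config")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one condition."""

    condition: str
    planted: frozenset[str]
    trna_planted: frozenset[str]
    emitted: Mapping[str, frozenset[str]] = field(default_factory=dict)


def _stream(seed: int, *keys) -> np.random.Generator:
    """Independent, label-keyed child stream of the master seed."""
    words = [seed & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            words.append(zlib.crc32(k.encode()))
        else:
            words.append(int(k))
    return np.random.default_rng(np.random.SeedSequence(words))


def simulate_genome(config: SimConfig) -> tuple[list[GeneModel], str]:
    """Place non-overlapping genes on the synthetic chromosomes.

    Returns the gene models and the equivalent GFF3 text; byte-identical
    under a fixed config.  Raises on infeasible packing.
    """
    max_len = config.gene_length_range[1]
    if config.n_genes * (max_len + config.min_gene_gap) > (
        config.n_chroms * config.chrom_length
    ):
        raise ValueError(
            "infeasible packing: genes plus gaps exceed total genome length"
        )
    rng = _stream(config.seed, "genome")

    # split genes across chromosomes as evenly as possible
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    n_trna = int(round(config.frac_trna * config.n_genes))
    trna_idx = set(
        rng.choice(config.n_genes, size=n_trna, replace=False).tolist()
    ) if n_trna else set()

    genes: list[GeneModel] = []
    gidx = 0
    for chrom, count in zip(config.chrom_names, per_chrom):
        if count == 0:
            continue
        lo, hi = config.gene_length_range
        lengths = rng.integers(lo, hi + 1, size=count)
        occupied = int(lengths.sum()) + (count - 1) * config.min_gene_gap
        slack = config.chrom_length - occupied
        if slack < 0:
            raise ValueError(f"infeasible packing on {chrom}")
        # distribute the slack over the count+1 inter-gene gaps
        extra = rng.multinomial(slack, np.full(count + 1, 1.0 / (count + 1)))
        pos = int(extra[0])
        for j in range(count):
            start = pos
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            is_trna = gidx in trna_idx
            gene_id = f"{'trna' if is_trna else 'gene'}{gidx + 1:04d}"
            exons: tuple[GenomicInterval, ...] = ()
            if not is_trna and end - start >= 40:
                n_ex = int(rng.integers(1, 4))
                cuts = np.sort(
                    rng.choice(end - start - 1, size=2 * n_ex, replace=False) + 1
                )
                exons = tuple(
                    GenomicInterval(chrom, start + int(cuts[2 * e]), start + int(cuts[2 * e + 1]))
                    for e in range(n_ex)
                    if cuts[2 * e + 1] > cuts[2 * e]
                )
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=gene_id.upper(),
                    interval=GenomicInterval(chrom, start, end),
                    strand=strand,
                    biotype="tRNA" if is_trna else "protein_coding",
                    exons=exons,
                )
            )
            pos = end + config.min_gene_gap + int(extra[j + 1])
            gidx += 1

    buf = io.StringIO()
    write_gene_annotation(genes, buf)
    return genes, buf.getvalue()


def _promoter_spans(config: SimConfig, genes: Sequence[GeneModel]):
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        pw = promoter_window(
            g, config.promoter_up, config.promoter_down,
            chrom_length=config.chrom_length,
        )
        spans.setdefault(g.interval.chrom, []).append(
            (pw.interval.start, pw.interval.end)
        )
    return spans


def _planted_peak(
    rng: np.random.Generator, config: SimConfig, chrom: str, anchor: int, name: str
) -> Peak:
    w_lo, w_hi = config.peak_width_range
    width = int(rng.integers(w_lo, w_hi + 1))
    start = anchor - width // 2
    end = start + width
    if config.jitter_sd > 0:
        start += int(round(rng.normal(0.0, config.jitter_sd)))
        end += int(round(rng.normal(0.0, config.jitter_sd)))
    # re-clamp the jittered interval to a valid width inside the chromosome
    if end - start < w_lo:
        end = start + w_lo
    elif end - start > w_hi:
        end = start + w_hi
    start = max(start, 0)
    end = min(end, config.chrom_length)
    if end <= start:
        start, end = max(0, end - w_lo), min(config.chrom_length, max(end, w_lo))
    summit = min(max(anchor, start), end - 1) - start
    signal = float(np.round(rng.uniform(3.0, 25.0), 3))
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        name=name,
        score=int(rng.integers(100, 1000)),
        strand=".",
        signal_value=signal,
        pvalue_neglog10=float(np.round(signal / 2.0, 3)),
        qvalue_neglog10=float(np.round(signal / 3.0, 3)),
        summit_offset=summit,
    )


def _background_peak(
    rng: np.random.Generator,
    config: SimConfig,
    promoters: Mapping[str, list[tuple[int, int]]],
    name: str,
) -> Peak:
    w_lo, w_hi = config.peak_width_range
    for _ in range(1000):
        chrom = config.chrom_names[int(rng.integers(0, config.n_chroms))]
        width = int(rng.integers(w_lo, w_hi + 1))
        start = int(rng.integers(0, config.chrom_length - width))
        end = start + width
        if any(start < e and s < end for s, e in promoters.get(chrom, [])):
            continue
        signal = float(np.round(rng.uniform(2.0, 8.0), 3))
        return Peak(
            interval=GenomicInterval(chrom, start, end),
            name=name,
            score=int(rng.integers(50, 400)),
            strand=".",
            signal_value=signal,
            pvalue_neglog10=float(np.round(signal / 2.0, 3)),
            qvalue_neglog10=float(np.round(signal / 3.0, 3)),
            summit_offset=width // 2,
        )
    raise RuntimeError("could not place a background peak outside promoters")


def simulate_condition(
    config: SimConfig,
    genes: Sequence[GeneModel],
    condition_label: str,
) -> tuple[dict[str, str], GroundTruth]:
    """Per-replicate narrowPeak texts plus the planted ground truth.

    Target genes are drawn without replacement from the non-tRNA genes; each
    replicate emits a promoter-proximal peak per target with probability
    ``detection_prob``, plus its own private background peaks.  When
    ``n_trna_targets`` > 0, control peaks are additionally planted on tRNA
    gene promoters (these must vanish from target tables under the default
    biotype exclusion).
    """
    spec = config.condition(condition_label)
    rng_cond = _stream(config.seed, "condition", condition_label)

    coding = sorted(g.gene_id for g in genes if g.biotype != "tRNA")
    trna = sorted(g.gene_id for g in genes if g.biotype == "tRNA")
    if spec.n_target_genes > len(coding):
        raise ValueError(
            f"{condition_label}: {spec.n_target_genes} targets requested but "
            f"only {len(coding)} non-tRNA genes available"
        )
    if config.n_trna_targets > len(trna):
        raise ValueError("more tRNA control targets requested than tRNA genes")

    planted = sorted(
        rng_cond.choice(coding, size=spec.n_target_genes, replace=False).tolist()
    )
    trna_planted = sorted(
        rng_cond.choice(trna, size=config.n_trna_targets, replace=False).tolist()
    ) if config.n_trna_targets else []

    by_id = {g.gene_id: g for g in genes}
    promoters = _promoter_spans(config, genes)

    # the binding site is a property of the locus, drawn once per gene from
    # the condition stream; replicates only jitter around it
    sites: dict[str, tuple[str, int]] = {}
    for gid in planted + trna_planted:
        gene = by_id[gid]
        anchor = tss(gene) + int(
            rng_cond.integers(
                -config.promoter_offset_max, config.promoter_offset_max + 1
            )
        )
        anchor = min(max(anchor, 0), config.chrom_length - 1)
        sites[gid] = (gene.interval.chrom, anchor)

    texts: dict[str, str] = {}
    emitted: dict[str, frozenset[str]] = {}
    for r in range(1, spec.n_replicates + 1):
        rep_id = f"{condition_label}_rep{r}"
        rng = _stream(config.seed, "replicate", condition_label, r)
        peaks: list[Peak] = []
        hit: set[str] = set()
        for i, gid in enumerate(planted + trna_planted):
            if rng.random() >= config.detection_prob:
                continue
            hit.add(gid)
            chrom, anchor = sites[gid]
            peaks.append(
                _planted_peak(rng, config, chrom, anchor, f"{rep_id}_t{i + 1}")
            )
        for b in range(config.background_peaks_per_replicate):
            peaks.append(
                _background_peak(rng, config, promoters, f"{rep_id}_bg{b + 1}")
            )
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
        buf = io.StringIO()
        write_narrowpeak(peaks, buf)
        texts[rep_id] = buf.getvalue()
        emitted[rep_id] = frozenset(hit)

    truth = GroundTruth(
        condition=condition_label,
        planted=frozenset(planted),
        trna_planted=frozenset(trna_planted),
        emitted=emitted,
    )
    return texts, truth


def simulate_mapping_stats(
    seed: int,
    n_samples: int,
    assembly_effects: Mapping[str, tuple[float, float, float]],
    dispersion: float = 0.02,
    total_reads: int = 1_000_000,
) -> list[MappingStats]:
    """Per-sample (unique, multi, unmapped) read counts around assembly means.

    ``assembly_effects`` maps each assembly label to its mean
    (unique, multi, unmapped) fractions, which must sum to 1.  Per-sample
    fractions are the means plus independent Gaussian noise of the given
    dispersion, renormalized; counts follow by largest-remainder rounding so
    they sum exactly to ``total_reads``.  Zero dispersion reproduces the
    means exactly (for means expressible at the read resolution).
    """
    out: list[MappingStats] = []
    for assembly in sorted(assembly_effects):
        means = np.asarray(assembly_effects[assembly], dtype=float)
        if means.shape != (3,) or (means < 0).any() or abs(means.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"assembly {assembly!r}: mean fractions must be 3 non-negative "
                "values summing to 1"
            )
        rng = _stream(seed, "mapping", assembly)
        for i in range(n_samples):
            if dispersion > 0:
                fr = means + rng.normal(0.0, dispersion, size=3)
                fr = np.clip(fr, 1e-9, None)
                fr = fr / fr.sum()
            else:
                fr = means
            raw = fr * total_reads
            counts = np.floor(raw).astype(int)
            rem = total_reads - counts.sum()
            order = np.argsort(-(raw - counts), kind="stable")
            for j in range(rem):
                counts[order[j % 3]] += 1
            out.append(
                MappingStats(
                    sample_id=f"{assembly}_s{i + 1}",
                    assembly_id=assembly,
                    n_unique=int(counts[0]),
                    n_multi=int(counts[1]),
                    n_unmapped=int(counts[2]),
                )
            )
    return out


def mapping_stats_to_tsv(stats: Sequence[MappingStats]) -> str:
    lines = ["sample_id\tassembly_id\tn_unique\tn_multi\tn_unmapped"]
    for s in stats:
        lines.append(
            f"{s.sample_id}\t{s.assembly_id}\t{s.n_unique}\t{s.n_multi}\t{s.n_unmapped}"
        )
    return "\n".join(lines) + "\n"
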