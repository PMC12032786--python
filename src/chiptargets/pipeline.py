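"""End-to-end orchestration: consensus -> annotation -> comparisons.

Stages communicate via files in standard formats (narrowPeak/BED/TSV/JSON),
so each stage is runnable and testable in isolation.  A run manifest records
the software version, a hash of the effective configuration, the parameters
actually used, and per-stage input/output counts, so silent filtering is
impossible and reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .annotate import (
    GeneIndex,
    annotate_peaks,
    feature_distribution,
    target_table,
    write_annotated_tsv,
    write_feature_distribution_tsv,
)
from .compare import assembly_concordance, partition_gene_sets
from .consensus import (
    ToleranceParams,
    consensus_peaks,
    write_consensus_bed,
    write_consensus_members,
)
from .genome_model import read_gene_annotation
from .peaks_io import read_narrowpeak
from .stats import (
    MAPPING_CATEGORIES,
    compare_mapping_stats,
    overlap_enrichment,
    read_gene_list,
    read_mapping_stats,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Validated inputs and parameters of one pipeline run."""

    gff3: Path
    conditions: Mapping[str, Sequence[Path]]  # label -> replicate narrowPeak paths
    out_dir: Path
    tol_bp: int = 5
    min_support: int = 2
    tol_mode: str = "both"
    promoter_up: int = 1000
    promoter_down: int = 1000
    downstream_bp: int = 3000
    exclude_biotypes: frozenset[str] = frozenset({"tRNA"})
    chrom_lengths: Mapping[str, int] | None = None
    comparisons: Sequence[Sequence[str]] = ()  # condition-label pairs/triples
    concordance_pairs: Sequence[tuple[Path, Path]] = ()  # gene-list file pairs
    enrichment_specs: Sequence[Mapping] = ()  # {condition, prior, universe}
    mapping_stats: Mapping | None = None  # {path, group_a, group_b}

    def validate(self) -> None:
        if not Path(self.gff3).exists():
            raise FileNotFoundError(f"GFF3 not found: {self.gff3}")
        labels = list(self.conditions)
        if len(labels) != len(set(labels)):
            raise ValueError("condition labels must be unique")
        for label, paths in self.conditions.items():
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"{label}: peak file not found: {p}")
        for combo in self.comparisons:
            unknown = set(combo) - set(labels)
            if unknown:
                raise ValueError(f"comparison names unknown conditions: {unknown}")

    def config_hash(self) -> str:
        payload = {
            "gff3": str(self.gff3),
            "conditions": {
                k: [str(p) for p in v] for k, v in sorted(self.conditions.items())
            },
            "tol_bp": self.tol_bp,
            "min_support": self.min_support,
            "tol_mode": self.tol_mode,
            "promoter_up": self.promoter_up,
            "promoter_down": self.promoter_down,
            "downstream_bp": self.downstream_bp,
            "exclude_biotypes": sorted(self.exclude_biotypes),
            "comparisons": [list(c) for c in self.comparisons],
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunReport:
    manifest_path: Path
    outputs: dict[str, Path] = field(default_factory=dict)
    counts: dict[str, dict] = field(default_factory=dict)
    target_genes: dict[str, set[str]] = field(default_factory=dict)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute consensus -> annotate -> target tables, then comparisons.

    Writes, per condition: consensus BED6 + members TSV, annotated TSV,
    feature-distribution TSV and a target-gene list; then partition /
    concordance / enrichment JSON reports and the run manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(config.gff3) as fh:
        genes = read_gene_annotation(fh, feature_types={"gene", "tRNA"})
    index = GeneIndex(
        genes,
        promoter_up=config.promoter_up,
        promoter_down=config.promoter_down,
        downstream_bp=config.downstream_bp,
        chrom_lengths=config.chrom_lengths,
    )
    params = ToleranceParams(
        tol_bp=config.tol_bp,
        min_support=config.min_support,
        tol_mode=config.tol_mode,
    )

    report = RunReport(manifest_path=out / "manifest.json")
    stage_counts: dict[str, dict] = {}

    for label in config.conditions:
        replicate_sets = []
        n_in = 0
        for path in config.conditions[label]:
            rep_peaks = read_narrowpeak(
                Path(path), replicate_id=Path(path).stem, condition=label
            )
            n_in += len(rep_peaks)
            replicate_sets.append(rep_peaks)
        cons = consensus_peaks(replicate_sets, params)

        bed = out / f"{label}.consensus.bed"
        members = out / f"{label}.consensus_members.tsv"
        with open(bed, "w") as fh:
            write_consensus_bed(cons, fh)
        with open(members, "w") as fh:
            write_consensus_members(cons, fh)

        annotated = annotate_peaks(cons, index) if cons else []
        ann_path = out / f"{label}.annotated.tsv"
        with open(ann_path, "w") as fh:
            write_annotated_tsv(annotated, fh)
        dist_path = out / f"{label}.feature_distribution.tsv"
        with open(dist_path, "w") as fh:
            dist = feature_distribution(annotated) if annotated else {}
            write_feature_distribution_tsv(dist, fh)

        table = target_table(annotated, label, config.exclude_biotypes)
        targets_path = out / f"{label}.target_genes.txt"
        targets_path.write_text(
            "".join(f"{g}\n" for g in sorted(table.gene_ids))
        )
        table_path = out / f"{label}.target_table.tsv"
        table.rows.to_csv(table_path, sep="\t", index=False)

        report.outputs[f"{label}.consensus_bed"] = bed
        report.outputs[f"{label}.members"] = members
        report.outputs[f"{label}.annotated"] = ann_path
        report.outputs[f"{label}.feature_distribution"] = dist_path
        report.outputs[f"{label}.target_genes"] = targets_path
        report.target_genes[label] = table.gene_ids
        stage_counts[label] = {
            "peaks_in": n_in,
            "consensus_out": len(cons),
            "promoter_fraction": dist.get("promoter", 0.0) if annotated else None,
            "n_unique_peaks": table.n_unique_peaks,
            "n_unique_genes": table.n_unique_genes,
        }

    if config.comparisons:
        partitions = []
        for combo in config.comparisons:
            part = partition_gene_sets(
                {label: report.target_genes[label] for label in combo}
            )
            partitions.append(part.to_json_dict())
        path = out / "partitions.json"
        _write_json(path, partitions)
        report.outputs["partitions"] = path

    if config.concordance_pairs:
        results = []
        for path_a, path_b in config.concordance_pairs:
            with open(path_a) as fa, open(path_b) as fb:
                res = assembly_concordance(read_gene_list(fa), read_gene_list(fb))
            entry = res.to_json_dict()
            entry["a"], entry["b"] = str(path_a), str(path_b)
            results.append(entry)
        path = out / "concordance.json"
        _write_json(path, results)
        report.outputs["concordance"] = path

    if config.enrichment_specs:
        results = []
        for spec in config.enrichment_specs:
            with open(spec["prior"]) as fh:
                prior = read_gene_list(fh)
            with open(spec["universe"]) as fh:
                universe = read_gene_list(fh)
            ours = report.target_genes[spec["condition"]]
            res = overlap_enrichment(ours, prior, universe)
            entry = res.to_json_dict()
            entry["condition"] = spec["condition"]
            entry["prior"] = str(spec["prior"])
            results.append(entry)
        path = out / "enrichment.json"
        _write_json(path, results)
        report.outputs["enrichment"] = path

    if config.mapping_stats:
        ms = config.mapping_stats
        all_stats = read_mapping_stats(str(ms["path"]))
        group_a = [s for s in all_stats if s.assembly_id == ms["group_a"]]
        group_b = [s for s in all_stats if s.assembly_id == ms["group_b"]]
        results = [
            compare_mapping_stats(group_a, group_b, cat).to_json_dict()
            for cat in MAPPING_CATEGORIES
        ]
        path = out / "mapping_tests.json"
        _write_json(path, results)
        report.outputs["mapping_tests"] = path

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "parameters": {
            "tol_bp": config.tol_bp,
            "min_support": config.min_support,
            "tol_mode": config.tol_mode,
            "promoter_up": config.promoter_up,
            "promoter_down": config.promoter_down,
            "downstream_bp": config.downstream_bp,
            "exclude_biotypes": sorted(config.exclude_biotypes),
            "assign_mode": "anchor",
        },
        "stage_counts": stage_counts,
        # paths are relative to the run directory so identical runs in
        # different directories produce identical manifests
        "outputs": {k: v.name for k, v in sorted(report.outputs.items())},
    }
    _write_json(report.manifest_path, manifest)
    report.counts = stage_counts
    return report
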