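"""End-to-end orchestration of the post-processing stages.

Fixed stage order: stratified FDR -> peptide QC -> group mapping ->
minimum-peptide filter -> contaminant/exclusion filter -> LCA taxonomy ->
genus quantitation -> clustering -> differential testing -> Bray-Curtis.
Each stage is a pure input->output transformation over files, so
subcommand-wise execution composes to the same artifacts as one run, and a
manifest with per-artifact row counts makes reruns comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import community_stats, genus_quant, group_filtering, stratified_fdr
from .config import PipelineConfig
from .tables_io import (
    read_lineage_table,
    read_peptide_table,
    read_protein_group_table,
    write_peptide_table,
    write_protein_group_table,
)
from .taxonomy_lca import (
    assign_groups,
    assignment_table,
    genus_assignment_rate,
    peptide_association_counts,
)

logger = logging.getLogger("metacalc")

__all__ = ["PipelineError", "PipelineResult", "run_all"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineResult:
    manifest: dict[str, dict]
    outputs: dict[str, Path] = field(default_factory=dict)


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> int:
    df.to_csv(path, sep="\t", index=kwargs.pop("index", False), **kwargs)
    return len(df)


def run_all(
    input_dir: str | Path,
    output_dir: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage on an input directory holding ``peptides.tsv``,
    ``protein_groups.tsv`` and ``lineages.tsv``; write all artifacts and a
    manifest to ``output_dir``."""
    config = config or PipelineConfig()
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    outputs: dict[str, Path] = {}
    audit = group_filtering.FilterAudit()

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    # --- load ---------------------------------------------------------------
    name = stage("load")
    try:
        peptides = read_peptide_table(
            input_dir / "peptides.tsv", decoy_prefix=config.fdr_decoy_prefix
        )
        groups = read_protein_group_table(input_dir / "protein_groups.tsv")
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # --- stratified FDR -----------------------------------------------------
    name = stage("fdr")
    try:
        accepted, fdr_results = stratified_fdr.control_fdr(
            peptides, config.fdr_q
        )
        summary = stratified_fdr.fdr_summary_table(fdr_results)
        outputs["fdr_summary"] = output_dir / "fdr_summary.tsv"
        manifest["fdr_summary"] = {
            "path": "fdr_summary.tsv",
            "rows": _write_tsv(summary, outputs["fdr_summary"]),
        }
        outputs["peptides_accepted"] = output_dir / "peptides_accepted.tsv"
        write_peptide_table(accepted, outputs["peptides_accepted"])
        manifest["peptides_accepted"] = {
            "path": "peptides_accepted.tsv",
            "rows": len(accepted),
        }
    except ValueError as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # --- QC + group filtering ----------------------------------------------
    name = stage("filter")
    try:
        qc_peptides = group_filtering.drop_razor_decoy_peptides(
            accepted, audit
        )
        mapped = group_filtering.map_groups_by_leading_razor(
            qc_peptides, groups, audit
        )
        counted = group_filtering.min_peptides_filter(
            mapped,
            config.filter_min_razor_unique,
            config.filter_drop_whole_group,
            audit,
        )
        filtered = group_filtering.drop_contaminants_and_excluded(
            counted, config.filter_excluded_patterns, audit
        )
        logger.info(
            "filter: %d -> %d peptides, %d -> %d groups",
            len(accepted), len(qc_peptides), len(groups), len(filtered),
        )
        outputs["protein_groups_filtered"] = (
            output_dir / "protein_groups_filtered.tsv"
        )
        write_protein_group_table(
            filtered, outputs["protein_groups_filtered"]
        )
        manifest["protein_groups_filtered"] = {
            "path": "protein_groups_filtered.tsv",
            "rows": len(filtered),
        }
        audit_df = pd.DataFrame(
            audit.entries, columns=["stage", "identifier", "reason"]
        )
        outputs["filter_audit"] = output_dir / "filter_audit.tsv"
        manifest["filter_audit"] = {
            "path": "filter_audit.tsv",
            "rows": _write_tsv(audit_df, outputs["filter_audit"]),
        }
    except ValueError as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # --- LCA taxonomy -------------------------------------------------------
    name = stage("lca")
    try:
        lineages = read_lineage_table(
            input_dir / "lineages.tsv", config.taxonomy_rank_ladder
        )
        if not lineages:
            raise ValueError("lineage table is empty")
        counts = peptide_association_counts(qc_peptides)
        assignments = assign_groups(
            filtered,
            lineages,
            counts,
            config.taxonomy_rank_ladder,
            config.taxonomy_human_trigger_taxa,
        )
        lca_df = assignment_table(assignments)
        outputs["lca_assignments"] = output_dir / "lca_assignments.tsv"
        manifest["lca_assignments"] = {
            "path": "lca_assignments.tsv",
            "rows": _write_tsv(lca_df, outputs["lca_assignments"]),
        }
        try:
            rate = genus_assignment_rate(
                assignments, config.taxonomy_rank_ladder
            )
            logger.info("bacterial genus assignment rate: %.3f", rate)
        except ValueError:
            rate = float("nan")
        manifest["lca_assignments"]["genus_assignment_rate"] = rate
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # --- genus quantitation --------------------------------------------------
    name = stage("quant")
    try:
        matrix = genus_quant.genus_fractions(
            filtered,
            assignments,
            lineages,
            config.quant_rank,
            config.taxonomy_rank_ladder,
        )
        fractions = matrix.fractions.copy()
        fractions["unassigned"] = matrix.unassigned
        outputs["genus_fractions"] = output_dir / "genus_fractions.tsv"
        manifest["genus_fractions"] = {
            "path": "genus_fractions.tsv",
            "rows": _write_tsv(
                fractions, outputs["genus_fractions"], index=True,
                index_label="sample",
            ),
        }
        top = genus_quant.top_genera(matrix, config.quant_top_n)
        outputs["top_genera"] = output_dir / "top_genera.tsv"
        manifest["top_genera"] = {
            "path": "top_genera.tsv",
            "rows": _write_tsv(top, outputs["top_genera"]),
        }
    except ValueError as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # --- statistics ----------------------------------------------------------
    name = stage("stats")
    try:
        lfq = genus_quant.lfq_matrix(filtered)
        observed = genus_quant.min_half_filter(lfq, list(lfq.columns))
        normalized = genus_quant.log2_median_normalize(observed)
        # center each protein row so sample correlations reflect deviations
        # from the shared abundance profile rather than the profile itself
        centered = normalized.sub(normalized.mean(axis=1), axis=0)
        cluster = community_stats.hierarchical_cluster(
            centered,
            linkage=config.stats_linkage,
            k=config.stats_k_groups,
        )
        labels = cluster.labels or {}
        label_df = pd.DataFrame(
            sorted(labels.items()), columns=["sample", "cluster"]
        )
        outputs["cluster_labels"] = output_dir / "cluster_labels.tsv"
        manifest["cluster_labels"] = {
            "path": "cluster_labels.tsv",
            "rows": _write_tsv(label_df, outputs["cluster_labels"]),
        }
        outputs["linkage"] = output_dir / "linkage.tsv"
        manifest["linkage"] = {
            "path": "linkage.tsv",
            "rows": _write_tsv(cluster.linkage_table(), outputs["linkage"]),
        }
        # flat clusters name the two community groups for the volcano;
        # the larger cluster is called G1 so the naming is size-stable
        sizes: dict[int, int] = {}
        for c in labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        ordered = sorted(sizes, key=lambda c: (-sizes[c], c))
        group_names = {c: f"G{i + 1}" for i, c in enumerate(ordered)}
        named = {s: group_names[c] for s, c in labels.items()}
        volcano = community_stats.two_group_t_test(
            matrix.fractions,
            named,
            alpha=config.stats_alpha,
            equal_var=config.stats_test_variant != "welch",
        )
        outputs["volcano"] = output_dir / "volcano.tsv"
        manifest["volcano"] = {
            "path": "volcano.tsv",
            "rows": _write_tsv(volcano, outputs["volcano"]),
        }
        percent = matrix.fractions.fillna(0.0) * 100.0
        counts_matrix = community_stats.scale_percent_to_counts(percent)
        bc = community_stats.bray_curtis(counts_matrix)
        outputs["bray_curtis"] = output_dir / "bray_curtis.tsv"
        manifest["bray_curtis"] = {
            "path": "bray_curtis.tsv",
            "rows": _write_tsv(bc, outputs["bray_curtis"], index=True,
                               index_label="sample"),
        }
    except ValueError as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    manifest_path = output_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = manifest_path
    return PipelineResult(manifest=manifest, outputs=outputs)
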