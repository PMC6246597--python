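"""Ground-truth evaluation studies on the synthetic generator.

Every function here runs the *pipeline's own operations* on freshly
simulated data and measures recovery against the generator's latent truth:
FDR control per stratum, group-label recovery by clustering, detection of
spiked genus effects, type-I error under the null, genus assignment rate,
and the unit-sum conservation of fractional abundances.  They power both
the acceptance checks and ad-hoc what-if studies.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import community_stats, genus_quant, group_filtering, stratified_fdr
from .synthetic_data import SimulationConfig, simulate_dataset
from .taxonomy_lca import (
    assign_groups,
    genus_assignment_rate,
    peptide_association_counts,
)

__all__ = [
    "fdr_study_config",
    "null_config",
    "fdr_control_study",
    "clustering_recovery_study",
    "spike_detection_study",
    "null_type1_study",
    "genus_rate_study",
    "conservation_study",
]


def fdr_study_config(seed: int) -> SimulationConfig:
    """Default conditions scaled so every stratum carries >= 1000 PSMs
    (the human and other strata are small under the defaults, as they are
    in real calculus data)."""
    return SimulationConfig(
        seed=seed, human_protein_count=40, other_protein_count=40
    )


def null_config(seed: int) -> SimulationConfig:
    """Default conditions with every genus effect set to zero."""
    base = SimulationConfig(seed=seed)
    genera = tuple(
        dataclasses.replace(g, log2_effect_g1_vs_g2=0.0)
        for g in base.genera
    )
    return dataclasses.replace(base, genera=genera)


def fdr_control_study(
    seeds: Sequence[int], q: float = 0.01
) -> pd.DataFrame:
    """Per seed and stratum: PSM count, estimated FDR at the selected
    cutoff, and the realized false-discovery proportion against the
    generator's per-PSM truth."""
    rows = []
    for seed in seeds:
        ds = simulate_dataset(fdr_study_config(seed))
        truth = ds.truth.psm_truth_lookup()
        by_stratum = stratified_fdr.split_by_stratum(ds.peptides)
        for stratum, records in by_stratum.items():
            result, accepted = stratified_fdr.accept_at_fdr(
                records, q, stratum=stratum
            )
            n_false = sum(
                not truth[(r.sequence, r.raw_file, r.score)]
                for r in accepted
            )
            rows.append(
                {
                    "seed": seed,
                    "stratum": stratum,
                    "n_psms": len(records),
                    "n_accepted": len(accepted),
                    "estimated_fdr": result.estimated_fdr,
                    "realized_fdp": n_false / len(accepted)
                    if accepted
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)


def _pipeline_fractions(ds):
    """Assignments and genus fractions from a simulated dataset, via the
    pipeline's own operations (QC order as in run_all, minus the FDR step
    which does not alter protein-group LFQ)."""
    groups = group_filtering.drop_contaminants_and_excluded(
        group_filtering.min_peptides_filter(ds.groups)
    )
    counts = peptide_association_counts(ds.peptides)
    assignments = assign_groups(groups, ds.lineages, counts)
    matrix = genus_quant.genus_fractions(groups, assignments, ds.lineages)
    return assignments, matrix


def clustering_recovery_study(seeds: Sequence[int]) -> list[float]:
    """Adjusted Rand index of the k=2 flat clustering (min-half filtered,
    log2-median-normalized, row-centered protein LFQ, Pearson distance,
    average linkage) against the generator's group labels."""
    aris = []
    for seed in seeds:
        ds = simulate_dataset(SimulationConfig(seed=seed))
        lfq = genus_quant.lfq_matrix(ds.groups)
        observed = genus_quant.min_half_filter(lfq, list(lfq.columns))
        normalized = genus_quant.log2_median_normalize(observed)
        centered = normalized.sub(normalized.mean(axis=1), axis=0)
        result = community_stats.hierarchical_cluster(centered, k=2)
        truth = ds.truth.group_labels
        order = sorted(result.labels)
        aris.append(
            adjusted_rand_score(
                [truth[s] for s in order],
                [result.labels[s] for s in order],
            )
        )
    return aris


def spike_detection_study(
    seeds: Sequence[int],
    alpha: float = 0.05,
    min_effect: float = 1.0,
) -> pd.DataFrame:
    """Per genus with |log2 effect| >= min_effect: the fraction of seeds in
    which the two-group t-test flags it significant (BH-adjusted p <= alpha)
    with the correct effect sign, using the true group labels."""
    detections: dict[str, list[bool]] = {}
    for seed in seeds:
        config = SimulationConfig(seed=seed)
        ds = simulate_dataset(config)
        _, matrix = _pipeline_fractions(ds)
        volcano = community_stats.two_group_t_test(
            matrix.fractions, ds.truth.group_labels, alpha=alpha
        ).set_index("genus")
        for spec in config.genera:
            if abs(spec.log2_effect_g1_vs_g2) < min_effect:
                continue
            if spec.name in volcano.index:
                row = volcano.loc[spec.name]
                hit = bool(row["significant"]) and (
                    np.sign(row["log2_ratio"])
                    == np.sign(spec.log2_effect_g1_vs_g2)
                )
            else:
                hit = False
            detections.setdefault(spec.name, []).append(hit)
    return pd.DataFrame(
        {
            "genus": list(detections),
            "detection_rate": [
                float(np.mean(v)) for v in detections.values()
            ],
            "n_seeds": [len(v) for v in detections.values()],
        }
    )


def null_type1_study(
    seeds: Sequence[int], alpha: float = 0.05
) -> tuple[float, int]:
    """Empirical rejection rate of the per-genus t-test (raw p <= alpha)
    across null simulations with zero group effects."""
    rejections = 0
    n_tests = 0
    for seed in seeds:
        ds = simulate_dataset(null_config(seed))
        _, matrix = _pipeline_fractions(ds)
        volcano = community_stats.two_group_t_test(
            matrix.fractions, ds.truth.group_labels, alpha=alpha
        )
        tested = volcano[volcano["tested"]]
        n_tests += len(tested)
        rejections += int((tested["p_value"] <= alpha).sum())
    return rejections / n_tests if n_tests else float("nan"), n_tests


def genus_rate_study(seeds: Sequence[int]) -> list[float]:
    """Bacterial genus-or-better assignment rate per simulated dataset."""
    rates = []
    for seed in seeds:
        ds = simulate_dataset(SimulationConfig(seed=seed))
        assignments, _ = _pipeline_fractions(ds)
        rates.append(genus_assignment_rate(assignments))
    return rates


def conservation_study(seeds: Sequence[int]) -> float:
    """Maximum |1 - (genus fractions + unassigned)| over samples and seeds."""
    worst = 0.0
    for seed in seeds:
        ds = simulate_dataset(SimulationConfig(seed=seed))
        _, matrix = _pipeline_fractions(ds)
        total = matrix.fractions.sum(axis=1) + matrix.unassigned
        defined = total.drop(index=matrix.undefined_samples)
        if len(defined):
            worst = max(worst, float((defined - 1.0).abs().max()))
    return worst
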