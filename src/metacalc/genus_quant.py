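"""Genus-level label-free quantitation.

Per sample, the fractional abundance of a genus is the summed LFQ intensity
of all bacterial protein groups resolved to that genus (species-level
assignments roll up to their genus), divided by the summed LFQ intensity of
ALL bacterial groups in that sample — including groups whose LCA stopped
above genus, which therefore absorb the remainder of the unit sum.  Missing
LFQ cells contribute nothing to either sum.

Also provides the matrix preparation used before clustering: the min-half
presence filter and log2 transformation with per-sample median subtraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import (
    DEFAULT_RANK_LADDER,
    Lineage,
    ProteinGroup,
    ValidationError,
)
from .taxonomy_lca import TaxonomicAssignment

__all__ = [
    "GenusAbundanceMatrix",
    "genus_fractions",
    "log2_median_normalize",
    "min_half_filter",
    "lfq_matrix",
    "top_genera",
]


@dataclass
class GenusAbundanceMatrix:
    """Samples x genera fractional abundances.

    ``fractions`` has samples as the index; ``unassigned`` carries the
    per-sample bacterial fraction not resolved to the target rank, so each
    row of ``fractions`` plus its ``unassigned`` entry sums to 1.  Samples
    with zero bacterial intensity are listed in ``undefined_samples`` and
    hold NaN rows.
    """

    fractions: pd.DataFrame
    unassigned: pd.Series
    undefined_samples: list[str]
    group_labels: dict[str, str] | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def genera(self) -> list[str]:
        return list(self.fractions.columns)


def _rank_taxon(
    assignment: TaxonomicAssignment,
    lineages: Mapping[str, Lineage],
    rank: str,
) -> str | None:
    """Taxon of ``assignment`` at ``rank``, rolling deeper LCAs up."""
    if assignment.lca_rank == rank:
        return assignment.lca_taxon
    for accession in assignment.representative_accessions:
        lineage = lineages.get(accession)
        if lineage is not None:
            taxon = lineage.taxon_at(rank)
            if taxon is not None:
                return taxon
    return None


def genus_fractions(
    groups: Sequence[ProteinGroup],
    assignments: Sequence[TaxonomicAssignment],
    lineages: Mapping[str, Lineage],
    rank: str = "genus",
    ladder: Sequence[str] = DEFAULT_RANK_LADDER,
    group_labels: Mapping[str, str] | None = None,
) -> GenusAbundanceMatrix:
    """Fractional LFQ abundance per genus (or any configured rank).

    Only bacterial-stratum groups enter either sum; human and other protein
    intensities have no effect on the fractions.
    """
    by_id = {a.group_id: a for a in assignments}
    rank_index = {r: i for i, r in enumerate(ladder)}
    target_index = rank_index[rank]

    samples: dict[str, None] = {}
    for g in groups:
        for r in g.razor_unique_counts:
            samples.setdefault(r)
        for r in g.lfq:
            samples.setdefault(r)
    sample_list = list(samples)

    totals = {s: 0.0 for s in sample_list}
    per_taxon: dict[str, dict[str, float]] = {}
    for group in groups:
        assignment = by_id.get(group.group_id)
        if assignment is None or assignment.effective_stratum != "bacteria":
            continue
        resolved = (
            assignment.lca_rank in rank_index
            and rank_index[assignment.lca_rank] >= target_index
        )
        taxon = _rank_taxon(assignment, lineages, rank) if resolved else None
        for sample, intensity in group.lfq.items():
            totals[sample] += intensity
            if taxon is not None:
                per_taxon.setdefault(taxon, {}).setdefault(sample, 0.0)
                per_taxon[taxon][sample] += intensity

    genera = sorted(per_taxon)
    fractions = pd.DataFrame(
        np.nan, index=sample_list, columns=genera, dtype=float
    )
    unassigned = pd.Series(np.nan, index=sample_list, dtype=float)
    undefined = []
    for sample in sample_list:
        total = totals[sample]
        if total <= 0:
            undefined.append(sample)
            continue
        assigned = 0.0
        for taxon in genera:
            value = per_taxon[taxon].get(sample, 0.0)
            fractions.loc[sample, taxon] = value / total
            assigned += value
        unassigned[sample] = (total - assigned) / total
    return GenusAbundanceMatrix(
        fractions=fractions,
        unassigned=unassigned,
        undefined_samples=undefined,
        group_labels=dict(group_labels) if group_labels else None,
    )


def lfq_matrix(groups: Sequence[ProteinGroup]) -> pd.DataFrame:
    """Protein groups x samples LFQ matrix (NaN where not quantified)."""
    samples: dict[str, None] = {}
    for g in groups:
        for r in g.razor_unique_counts:
            samples.setdefault(r)
        for r in g.lfq:
            samples.setdefault(r)
    matrix = pd.DataFrame(
        np.nan, index=[g.group_id for g in groups], columns=list(samples)
    )
    for g in groups:
        for sample, value in g.lfq.items():
            matrix.loc[g.group_id, sample] = value
    return matrix


def log2_median_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2-transform and subtract each sample column's median.

    Entries must be positive where present; missing values stay missing and
    are ignored by the median.  An all-missing column passes through.
    """
    if (matrix <= 0).any().any():
        raise ValidationError("intensities must be strictly positive")
    logged = np.log2(matrix)
    return logged - logged.median(axis=0, skipna=True)


def min_half_filter(
    matrix: pd.DataFrame, sample_subset: Sequence[str]
) -> pd.DataFrame:
    """Keep rows observed in at least ceil(n/2) of ``sample_subset``."""
    if len(sample_subset) == 0:
        raise ValidationError("sample_subset must be nonempty")
    threshold = math.ceil(len(sample_subset) / 2)
    present = matrix[list(sample_subset)].notna().sum(axis=1)
    return matrix.loc[present >= threshold]


def top_genera(matrix: GenusAbundanceMatrix, n: int = 20) -> pd.DataFrame:
    """Top-n genera by mean fractional abundance (the bar-chart table)."""
    means = matrix.fractions.mean(axis=0, skipna=True).sort_values(
        ascending=False
    )
    head = means.head(n)
    return pd.DataFrame(
        {"genus": head.index, "mean_fraction": head.to_numpy()}
    )
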