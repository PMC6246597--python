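"""Lowest-common-ancestor taxonomic assignment of protein groups.

Each group's majority protein IDs are narrowed to the accessions with the
most peptide associations (a peptide is associated with every accession in
its Proteins list); the LCA is the most specific taxon present in every
representative's lineage, computed by intersecting (rank, taxon) pairs so
homonymous taxa at different ranks cannot collide.

A human override mirrors common practice with hominid database redundancy:
any assignment landing on the parvorder Catarrhini (or another configured
trigger taxon), and any "other"-stratum group containing a human accession,
is set to Homo sapiens at species rank.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .tables_io import (
    DEFAULT_RANK_LADDER,
    Lineage,
    PeptideRecord,
    ProteinGroup,
    ValidationError,
)

__all__ = [
    "DEFAULT_HUMAN_TRIGGER_TAXA",
    "HUMAN_TAXON",
    "TaxonomicAssignment",
    "peptide_association_counts",
    "select_representatives",
    "lca",
    "stratum_of_lineage",
    "apply_human_override",
    "assign_groups",
    "genus_assignment_rate",
    "assignment_table",
]

UNASSIGNED = "unassigned"
HUMAN_TAXON = "Homo sapiens"
DEFAULT_HUMAN_TRIGGER_TAXA = ("Catarrhini", "Hominidae", "Homo", HUMAN_TAXON)


@dataclass(frozen=True)
class TaxonomicAssignment:
    group_id: int
    representative_accessions: tuple[str, ...]
    lca_taxon: str
    lca_rank: str
    effective_stratum: str  # human | bacteria | other


def peptide_association_counts(
    records: Iterable[PeptideRecord],
) -> Counter[str]:
    """Count peptide associations per accession.

    Every accession in a record's Proteins list gains one association; when
    the list is missing the leading razor protein is used instead so the
    record still contributes.
    """
    counts: Counter[str] = Counter()
    for rec in records:
        accessions = rec.proteins if rec.proteins is not None else (
            rec.leading_razor_protein,
        )
        counts.update(accessions)
    return counts


def select_representatives(
    majority_protein_ids: Sequence[str],
    peptide_counts: Mapping[str, int],
) -> tuple[str, ...]:
    """All majority accessions attaining the maximum association count
    (absent accessions count 0; ties are all retained)."""
    if not majority_protein_ids:
        raise ValidationError("empty majority protein ID list")
    best = max(peptide_counts.get(a, 0) for a in majority_protein_ids)
    return tuple(
        a for a in majority_protein_ids if peptide_counts.get(a, 0) == best
    )


def lca(
    lineages: Sequence[Lineage],
    ladder: Sequence[str] = DEFAULT_RANK_LADDER,
) -> tuple[str, str]:
    """Most specific (rank, taxon) pair present in every lineage.

    Returns ("unassigned", "unassigned") when the intersection is empty.
    """
    if not lineages:
        raise ValidationError("lca requires at least one lineage")
    shared = set(lineages[0].path)
    for lineage in lineages[1:]:
        shared &= set(lineage.path)
    if not shared:
        return UNASSIGNED, UNASSIGNED
    rank_index = {rank: i for i, rank in enumerate(ladder)}
    rank, taxon = max(shared, key=lambda pair: (rank_index[pair[0]], pair[1]))
    return taxon, rank


def stratum_of_lineage(lineage: Lineage) -> str:
    """human / bacteria / other, from the lineage content."""
    if lineage.taxon_at("species") == HUMAN_TAXON or lineage.taxon_at(
        "genus"
    ) == "Homo":
        return "human"
    if lineage.taxon_at("superkingdom") == "Bacteria":
        return "bacteria"
    return "other"


def _is_human_accession(
    accession: str, lineages: Mapping[str, Lineage]
) -> bool:
    lineage = lineages.get(accession)
    return lineage is not None and stratum_of_lineage(lineage) == "human"


def apply_human_override(
    assignment: TaxonomicAssignment,
    group: ProteinGroup,
    lineages: Mapping[str, Lineage],
    trigger_taxa: Sequence[str] = DEFAULT_HUMAN_TRIGGER_TAXA,
) -> TaxonomicAssignment:
    """Force Homo sapiens when the LCA hit a trigger taxon (Catarrhini by
    default) or an "other"-stratum group carries a human accession."""
    triggered = assignment.lca_taxon in trigger_taxa
    if not triggered and assignment.effective_stratum == "other":
        triggered = any(
            _is_human_accession(a, lineages) for a in group.protein_ids
        )
    if not triggered:
        return assignment
    return replace(
        assignment,
        lca_taxon=HUMAN_TAXON,
        lca_rank="species",
        effective_stratum="human",
    )


def _consensus_stratum(strata: set[str]) -> str:
    if strata == {"human"}:
        return "human"
    if strata == {"bacteria"}:
        return "bacteria"
    return "other"


def assign_groups(
    groups: Sequence[ProteinGroup],
    lineages: Mapping[str, Lineage],
    peptide_counts: Mapping[str, int],
    ladder: Sequence[str] = DEFAULT_RANK_LADDER,
    trigger_taxa: Sequence[str] = DEFAULT_HUMAN_TRIGGER_TAXA,
) -> list[TaxonomicAssignment]:
    """LCA-assign every group, then apply the human override.

    Accessions without a lineage are skipped; a group with no resolvable
    representative is reported unassigned with stratum "other" (the override
    can still rescue it via a human accession elsewhere in the group).
    """
    assignments = []
    for group in groups:
        reps = select_representatives(group.majority_protein_ids, peptide_counts)
        rep_lineages = [lineages[a] for a in reps if a in lineages]
        if rep_lineages:
            taxon, rank = lca(rep_lineages, ladder)
            stratum = _consensus_stratum(
                {stratum_of_lineage(l) for l in rep_lineages}
            )
        else:
            taxon = rank = UNASSIGNED
            stratum = "other"
        assignment = TaxonomicAssignment(
            group_id=group.group_id,
            representative_accessions=reps,
            lca_taxon=taxon,
            lca_rank=rank,
            effective_stratum=stratum,
        )
        assignments.append(
            apply_human_override(assignment, group, lineages, trigger_taxa)
        )
    return assignments


def genus_assignment_rate(
    assignments: Iterable[TaxonomicAssignment],
    ladder: Sequence[str] = DEFAULT_RANK_LADDER,
    stratum: str = "bacteria",
) -> float:
    """Fraction of the stratum's groups assigned at genus rank or deeper."""
    rank_index = {rank: i for i, rank in enumerate(ladder)}
    genus_index = rank_index["genus"]
    relevant = [a for a in assignments if a.effective_stratum == stratum]
    if not relevant:
        raise ValidationError(f"no {stratum} groups; rate undefined")
    resolved = sum(
        1
        for a in relevant
        if a.lca_rank in rank_index and rank_index[a.lca_rank] >= genus_index
    )
    return resolved / len(relevant)


def assignment_table(
    assignments: Sequence[TaxonomicAssignment],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_id": a.group_id,
                "representatives": ";".join(a.representative_accessions),
                "lca_taxon": a.lca_taxon,
                "lca_rank": a.lca_rank,
                "effective_stratum": a.effective_stratum,
            }
            for a in assignments
        ]
    )
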