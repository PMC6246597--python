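"""Quality-control filters on peptides and protein groups.

Order matters and is fixed by the pipeline: (1) drop peptides whose leading
razor protein is a reverse hit while the Proteins cell is valid, (2) map the
surviving leading razor accessions onto protein groups through the Protein
IDs column, (3) enforce the minimum razor+unique peptide count per raw file,
(4) drop decoy groups, contaminants, and excluded annotations (collagen and
keratin by default).  Every filter is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .tables_io import PeptideRecord, ProteinGroup, ValidationError

__all__ = [
    "DEFAULT_EXCLUDED_PATTERNS",
    "FilterAudit",
    "drop_razor_decoy_peptides",
    "map_groups_by_leading_razor",
    "min_peptides_filter",
    "drop_contaminants_and_excluded",
    "count_unique_peptides",
]

DEFAULT_EXCLUDED_PATTERNS = ("collagen", "keratin")


@dataclass
class FilterAudit:
    """Removal log: (stage, identifier, reason) triples."""

    entries: list[tuple[str, str, str]]

    def __init__(self) -> None:
        self.entries = []

    def record(self, stage: str, identifier: object, reason: str) -> None:
        self.entries.append((stage, str(identifier), reason))


def drop_razor_decoy_peptides(
    records: Iterable[PeptideRecord],
    audit: FilterAudit | None = None,
) -> list[PeptideRecord]:
    """Remove records whose leading razor protein is a reverse hit AND whose
    Proteins cell holds a valid (non-missing) entry; everything else stays."""
    kept = []
    for rec in records:
        if rec.is_decoy and rec.proteins is not None:
            if audit is not None:
                audit.record(
                    "qc_peptides", rec.sequence,
                    "leading razor protein is a reverse hit with valid Proteins",
                )
        else:
            kept.append(rec)
    return kept


def map_groups_by_leading_razor(
    records: Iterable[PeptideRecord],
    groups: Sequence[ProteinGroup],
    audit: FilterAudit | None = None,
) -> list[ProteinGroup]:
    """Retain a group iff some surviving record's leading razor accession is
    a member of its Protein IDs."""
    surviving = {rec.leading_razor_protein for rec in records}
    kept = []
    for group in groups:
        if surviving.intersection(group.protein_ids):
            kept.append(group)
        elif audit is not None:
            audit.record(
                "group_mapping", group.group_id,
                "no surviving leading razor protein among Protein IDs",
            )
    return kept


def min_peptides_filter(
    groups: Sequence[ProteinGroup],
    min_count: int = 2,
    drop_whole_group: bool = False,
    audit: FilterAudit | None = None,
) -> list[ProteinGroup]:
    """Enforce the minimum razor+unique peptide count per raw file.

    Default behaviour masks a group's LFQ to missing in every raw file where
    its razor+unique count falls below ``min_count`` and removes only groups
    masked in every raw file, preserving per-sample quantitation elsewhere.
    ``drop_whole_group=True`` selects the stricter reading: a group survives
    only if it reaches ``min_count`` in every raw file that has a count.
    """
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    kept: list[ProteinGroup] = []
    for group in groups:
        counts = group.razor_unique_counts
        below = {r for r, c in counts.items() if c < min_count}
        if drop_whole_group:
            if below:
                if audit is not None:
                    audit.record(
                        "min_peptides", group.group_id,
                        f"razor+unique < {min_count} in {len(below)} raw file(s)",
                    )
            else:
                kept.append(group)
            continue
        masked = group.masked(below)
        if any(counts.get(r, 0) >= min_count for r in counts):
            kept.append(masked)
        elif audit is not None:
            audit.record(
                "min_peptides", group.group_id,
                f"razor+unique < {min_count} in every raw file",
            )
    return kept


def drop_contaminants_and_excluded(
    groups: Sequence[ProteinGroup],
    excluded_patterns: Sequence[str] = DEFAULT_EXCLUDED_PATTERNS,
    audit: FilterAudit | None = None,
) -> list[ProteinGroup]:
    """Remove decoy groups, flagged contaminants, and groups whose annotation
    or accessions match an excluded pattern (case-insensitive substring)."""
    patterns = [p.lower() for p in excluded_patterns]
    kept = []
    for group in groups:
        haystack = " ".join((group.annotation, *group.protein_ids)).lower()
        reason = None
        if group.is_decoy_group:
            reason = "reverse hit"
        elif group.is_contaminant:
            reason = "potential contaminant"
        else:
            for pattern in patterns:
                if pattern in haystack:
                    reason = f"matches excluded pattern {pattern!r}"
                    break
        if reason is None:
            kept.append(group)
        elif audit is not None:
            audit.record("contaminants", group.group_id, reason)
    return kept


def count_unique_peptides(
    records: Iterable[PeptideRecord],
) -> dict[tuple[str, str], int]:
    """Distinct peptide sequences per (stratum, raw file)."""
    seen: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        seen.setdefault((rec.stratum, rec.raw_file), set()).add(
            rec.unique_sequence_key
        )
    return {key: len(val) for key, val in seen.items()}
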