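"""Dietary marker peptides: in-silico tryptic digestion and
deamidation-aware species attribution.

Milk and cereal proteins preserved in dental calculus are identified through
peptides that differ between species.  Trypsin cleaves C-terminal of K or R
except before P; digests are enumerated for 0..max_missed missed cleavages.
Species attribution must respect that asparagine (N) spontaneously
deamidates to aspartate (D) as proteins age, so a peptide differing from a
homolog only at N/D positions cannot distinguish the two species: such
candidates are moved from the "unique" sets into an "ambiguous" class.  The
classic case is beta-lactoglobulin's PTPEGDLEILLQK, which reads equally as
the bovine peptide or as the fully deamidated small-ruminant homolog.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

from .tables_io import AMINO_ACIDS, ValidationError, read_fasta

__all__ = [
    "DigestPeptide",
    "DiscriminationResult",
    "tryptic_digest",
    "deamidation_equivalent",
    "discriminating_peptides",
    "classify_observed_peptide",
    "load_blg_references",
]

# cleave after K or R, not before P; trypsin/p ignores the proline block
# (the search-engine convention that yields peptides such as PTPEGDLEILLQK)
_TRYPSIN_SITE = re.compile(r"(?<=[KR])(?!P)")
_TRYPSIN_P_SITE = re.compile(r"(?<=[KR])")


@dataclass(frozen=True)
class DigestPeptide:
    """An in-silico tryptic peptide, 0-based half-open in its parent."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    parent_id: str = ""


def _cleavage_points(
    sequence: str, cleave_before_proline: bool = False
) -> list[int]:
    """Internal cut positions (0 < p < len), trypsin rule."""
    pattern = _TRYPSIN_P_SITE if cleave_before_proline else _TRYPSIN_SITE
    return [
        m.start()
        for m in pattern.finditer(sequence)
        if 0 < m.start() < len(sequence)
    ]


def tryptic_digest(
    sequence: str,
    max_missed: int = 2,
    parent_id: str = "",
    cleave_before_proline: bool = False,
) -> list[DigestPeptide]:
    """All tryptic peptides with up to ``max_missed`` missed cleavages,
    ordered by (start, end)."""
    if not sequence or not set(sequence) <= AMINO_ACIDS:
        raise ValidationError("sequence must be a non-empty amino-acid string")
    if max_missed < 0:
        raise ValidationError("max_missed must be >= 0")
    bounds = [0, *_cleavage_points(sequence, cleave_before_proline),
              len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            peptides.append(
                DigestPeptide(
                    sequence=sequence[start:end],
                    start=start,
                    end=end,
                    missed_cleavages=missed,
                    parent_id=parent_id,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def deamidation_equivalent(
    pep_a: str,
    pep_b: str,
    q_e: bool = False,
) -> bool:
    """True iff the sequences match position-wise up to N<->D (and Q<->E when
    ``q_e``) equivalence; symmetric; requires equal length."""
    if len(pep_a) != len(pep_b):
        return False
    classes = {"N": "D", "D": "D"}
    if q_e:
        classes.update({"Q": "E", "E": "E"})
    for a, b in zip(pep_a, pep_b):
        if classes.get(a, a) != classes.get(b, b):
            return False
    return True


@dataclass(frozen=True)
class DiscriminationResult:
    unique_to_a: frozenset[str]
    unique_to_b: frozenset[str]
    ambiguous_under_deamidation: frozenset[str]


def _length_ok(pep: str, len_min: int | None, len_max: int | None) -> bool:
    if len_min is not None and len(pep) < len_min:
        return False
    if len_max is not None and len(pep) > len_max:
        return False
    return True


def discriminating_peptides(
    ref_a: str,
    ref_b: str,
    max_missed: int = 2,
    deamidation_aware: bool = True,
    q_e: bool = False,
    len_min: int | None = None,
    len_max: int | None = None,
    cleave_before_proline: bool = False,
) -> DiscriminationResult:
    """Partition the two digests' peptides into species-discriminating and
    deamidation-ambiguous classes.

    A peptide of A absent from B's digest is candidate-unique to A; with
    deamidation awareness, candidates having a deamidation-equivalent
    counterpart in the other digest move to the ambiguous class (and
    symmetrically for B).  Length bounds are applied after the uniqueness
    logic, to the reported sets only.
    """
    set_a = {
        p.sequence
        for p in tryptic_digest(ref_a, max_missed,
                                cleave_before_proline=cleave_before_proline)
    }
    set_b = {
        p.sequence
        for p in tryptic_digest(ref_b, max_missed,
                                cleave_before_proline=cleave_before_proline)
    }
    cand_a = set_a - set_b
    cand_b = set_b - set_a
    ambiguous: set[str] = set()
    if deamidation_aware:
        amb_a = {
            p
            for p in cand_a
            if any(deamidation_equivalent(p, q, q_e) for q in set_b)
        }
        amb_b = {
            p
            for p in cand_b
            if any(deamidation_equivalent(p, q, q_e) for q in set_a)
        }
        cand_a -= amb_a
        cand_b -= amb_b
        ambiguous = amb_a | amb_b
    keep = lambda s: frozenset(
        p for p in s if _length_ok(p, len_min, len_max)
    )
    return DiscriminationResult(
        unique_to_a=keep(cand_a),
        unique_to_b=keep(cand_b),
        ambiguous_under_deamidation=keep(ambiguous),
    )


def classify_observed_peptide(
    pep: str,
    references: Mapping[str, str],
    max_missed: int = 2,
    deamidation_aware: bool = True,
    q_e: bool = False,
    cleave_before_proline: bool = False,
) -> set[str]:
    """Species whose digest contains ``pep`` exactly or (when aware) up to
    deamidation equivalence; empty set means unmatched."""
    matched = set()
    for species, reference in references.items():
        digest = {
            p.sequence
            for p in tryptic_digest(
                reference, max_missed,
                cleave_before_proline=cleave_before_proline,
            )
        }
        if pep in digest:
            matched.add(species)
        elif deamidation_aware and any(
            deamidation_equivalent(pep, q, q_e) for q in digest
        ):
            matched.add(species)
    return matched


def load_blg_references() -> dict[str, str]:
    """Packaged mature beta-lactoglobulin reference pair.

    The bovine entry is the canonical mature bovine beta-lactoglobulin
    (162 residues).  The caprine entry is a synthetic homolog: the bovine
    scaffold carrying the four documented bovine/caprine diagnostic
    substitutions (I1, H20, N64, K130 in mature coordinates), built for
    testing the discrimination logic rather than curated from a sequence
    database.  Signal peptides are already removed; the digestion tool does
    not predict them.
    """
    path = resources.files("metacalc.data") / "blg_references_synthetic.fasta"
    with resources.as_file(path) as p:
        return read_fasta(p)
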