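"""Tabular I/O for the pipeline's file dialects.

The pipeline consumes search-engine output shaped like MaxQuant's
``peptides.txt`` and ``proteinGroups.txt``, a taxonomy lineage table, and
FASTA reference sequences.  Column names are resolved through a configurable
dialect map so both real exports (whose headers vary between versions) and
the synthetic dialect written by :mod:`metacalc.synthetic_data` parse with
the same code.  Write->read round trips are identity for all three table
kinds; tests rely on that.

Missing numeric cells are encoded as the empty string on disk and as an
absent entry (LFQ) or ``None`` (peptide ``proteins``) in memory — distinct
from 0, because "not quantified" must not corrupt fractional abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_RANK_LADDER",
    "DEFAULT_DECOY_PREFIX",
    "DEFAULT_CONTAMINANT_PREFIX",
    "DEFAULT_PEPTIDE_DIALECT",
    "FormatError",
    "ValidationError",
    "PeptideRecord",
    "ProteinGroup",
    "Lineage",
    "read_peptide_table",
    "write_peptide_table",
    "read_protein_group_table",
    "write_protein_group_table",
    "read_lineage_table",
    "write_lineage_table",
    "read_fasta",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ordered rank ladder, root to leaf.  ``parvorder`` sits between order and
#: family solely so primate lineages can carry Catarrhini (the human-override
#: trigger); bacterial lineages simply skip it.
DEFAULT_RANK_LADDER: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "parvorder",
    "family",
    "genus",
    "species",
)

DEFAULT_DECOY_PREFIX = "REV__"
DEFAULT_CONTAMINANT_PREFIX = "CON__"

#: Logical field -> column header.  Matches the synthetic dialect; override
#: entries to parse a real MaxQuant export.
DEFAULT_PEPTIDE_DIALECT: dict[str, str] = {
    "sequence": "Sequence",
    "score": "Score",
    "leading_razor_protein": "Leading razor protein",
    "proteins": "Proteins",
    "raw_file": "Raw file",
    "stratum": "Stratum",
}

STRATA = ("human", "bacteria", "other")


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """An operation's precondition is violated."""


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide-spectrum-derived row.

    ``score`` is the search engine's identification confidence (higher is
    better); ``is_decoy`` marks reverse-database hits and must agree with the
    decoy prefix on ``leading_razor_protein``; ``proteins`` is ``None`` when
    the source cell was missing (not the same as an empty list).
    """

    sequence: str
    score: float
    is_decoy: bool
    stratum: str
    leading_razor_protein: str
    proteins: tuple[str, ...] | None
    raw_file: str

    @property
    def unique_sequence_key(self) -> str:
        """Sequence string used for peptide counting."""
        return self.sequence

    def validate(self) -> None:
        if not self.sequence or not set(self.sequence) <= AMINO_ACIDS:
            raise ValidationError(
                f"invalid peptide sequence {self.sequence!r}"
            )
        if self.stratum not in STRATA:
            raise ValidationError(f"unknown stratum {self.stratum!r}")


@dataclass(frozen=True)
class ProteinGroup:
    """A set of accessions indistinguishable by the observed peptides.

    ``razor_unique_counts`` maps raw file -> razor+unique peptide count;
    ``lfq`` maps raw file -> label-free intensity, with missing raw files
    simply absent from the map (never stored as 0).
    """

    group_id: int
    protein_ids: tuple[str, ...]
    majority_protein_ids: tuple[str, ...]
    razor_unique_counts: Mapping[str, int] = field(default_factory=dict)
    lfq: Mapping[str, float] = field(default_factory=dict)
    is_contaminant: bool = False
    is_decoy_group: bool = False
    annotation: str = ""

    def validate(self) -> None:
        if not set(self.majority_protein_ids) <= set(self.protein_ids):
            raise ValidationError(
                f"group {self.group_id}: majority ids not a subset of protein ids"
            )
        for raw, value in self.lfq.items():
            if not value > 0:
                raise ValidationError(
                    f"group {self.group_id}: non-positive LFQ in {raw!r}"
                )

    def masked(self, raw_files_to_mask: Iterable[str]) -> "ProteinGroup":
        """Copy with LFQ removed for the given raw files."""
        drop = set(raw_files_to_mask)
        return replace(
            self, lfq={r: v for r, v in self.lfq.items() if r not in drop}
        )


@dataclass(frozen=True)
class Lineage:
    """Ordered rank->taxon path for one accession, root to leaf."""

    accession: str
    path: tuple[tuple[str, str], ...]

    def validate(self, ladder: Sequence[str] = DEFAULT_RANK_LADDER) -> None:
        idx = [ladder.index(rank) for rank, _ in self.path]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValidationError(
                f"{self.accession}: path does not follow the rank ladder"
            )

    def taxon_at(self, rank: str) -> str | None:
        for r, taxon in self.path:
            if r == rank:
                return taxon
        return None

    @property
    def leaf(self) -> tuple[str, str] | None:
        return self.path[-1] if self.path else None


# ---------------------------------------------------------------------------
# peptide tables


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_peptide_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> list[PeptideRecord]:
    """Parse a peptide-level identification table.

    The decoy flag is derived purely from ``decoy_prefix`` on the leading
    razor protein; a missing ``Proteins`` cell becomes ``None``.
    """
    dialect = {**DEFAULT_PEPTIDE_DIALECT, **(dialect or {})}
    df = _read_tsv(path)
    for logical, column in dialect.items():
        if column not in df.columns:
            raise FormatError(
                f"{path}: missing required column {column!r} (field {logical!r})"
            )
    records: list[PeptideRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        raw_score = row[dialect["score"]]
        try:
            score = float(raw_score)
        except ValueError:
            raise FormatError(
                f"{path}: unparseable score {raw_score!r} on line {i}"
            ) from None
        if math.isnan(score):
            raise FormatError(f"{path}: missing score on line {i}")
        proteins_cell = row[dialect["proteins"]]
        proteins = (
            tuple(p for p in proteins_cell.split(";") if p)
            if proteins_cell
            else None
        )
        leading = row[dialect["leading_razor_protein"]]
        rec = PeptideRecord(
            sequence=row[dialect["sequence"]],
            score=score,
            is_decoy=leading.startswith(decoy_prefix),
            stratum=row[dialect["stratum"]],
            leading_razor_protein=leading,
            proteins=proteins,
            raw_file=row[dialect["raw_file"]],
        )
        rec.validate()
        records.append(rec)
    return records


def write_peptide_table(
    records: Iterable[PeptideRecord],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    dialect = {**DEFAULT_PEPTIDE_DIALECT, **(dialect or {})}
    rows = []
    for rec in records:
        rows.append(
            {
                dialect["sequence"]: rec.sequence,
                dialect["score"]: repr(rec.score),
                dialect["leading_razor_protein"]: rec.leading_razor_protein,
                dialect["proteins"]: (
                    ";".join(rec.proteins) if rec.proteins is not None else ""
                ),
                dialect["raw_file"]: rec.raw_file,
                dialect["stratum"]: rec.stratum,
            }
        )
    pd.DataFrame(rows, columns=list(dialect.values())).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# protein-group tables

_PG_FIXED = ("id", "Protein IDs", "Majority protein IDs", "Annotation",
             "Reverse", "Potential contaminant")
_RU_PREFIX = "Razor + unique peptides "
_LFQ_PREFIX = "LFQ intensity "


def read_protein_group_table(path: str | Path) -> list[ProteinGroup]:
    """Parse a protein-group table (one ``Razor + unique peptides <raw>`` and
    ``LFQ intensity <raw>`` column pair per raw file)."""
    df = _read_tsv(path)
    for column in _PG_FIXED:
        if column not in df.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    raw_files = [
        c[len(_RU_PREFIX):] for c in df.columns if c.startswith(_RU_PREFIX)
    ]
    groups: list[ProteinGroup] = []
    for _, row in df.iterrows():
        counts: dict[str, int] = {}
        lfq: dict[str, float] = {}
        for raw in raw_files:
            cell = row[_RU_PREFIX + raw]
            if cell:
                counts[raw] = int(cell)
            lfq_cell = row.get(_LFQ_PREFIX + raw, "")
            if lfq_cell:
                lfq[raw] = float(lfq_cell)
        group = ProteinGroup(
            group_id=int(row["id"]),
            protein_ids=tuple(p for p in row["Protein IDs"].split(";") if p),
            majority_protein_ids=tuple(
                p for p in row["Majority protein IDs"].split(";") if p
            ),
            razor_unique_counts=counts,
            lfq=lfq,
            is_contaminant=row["Potential contaminant"] == "+",
            is_decoy_group=row["Reverse"] == "+",
            annotation=row["Annotation"],
        )
        group.validate()
        groups.append(group)
    return groups


def write_protein_group_table(
    groups: Sequence[ProteinGroup],
    path: str | Path,
    raw_files: Sequence[str] | None = None,
) -> None:
    if raw_files is None:
        seen: dict[str, None] = {}
        for g in groups:
            for r in g.razor_unique_counts:
                seen.setdefault(r)
            for r in g.lfq:
                seen.setdefault(r)
        raw_files = list(seen)
    rows = []
    for g in groups:
        row: dict[str, str] = {
            "id": str(g.group_id),
            "Protein IDs": ";".join(g.protein_ids),
            "Majority protein IDs": ";".join(g.majority_protein_ids),
            "Annotation": g.annotation,
            "Reverse": "+" if g.is_decoy_group else "",
            "Potential contaminant": "+" if g.is_contaminant else "",
        }
        for raw in raw_files:
            count = g.razor_unique_counts.get(raw)
            row[_RU_PREFIX + raw] = str(count) if count is not None else ""

            value = g.lfq.get(raw)
            row[_LFQ_PREFIX + raw] = repr(value) if value is not None else ""
        rows.append(row)
    columns = list(_PG_FIXED)
    columns += [_RU_PREFIX + r for r in raw_files]
    columns += [_LFQ_PREFIX + r for r in raw_files]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# lineage tables


def read_lineage_table(
    path: str | Path,
    ladder: Sequence[str] = DEFAULT_RANK_LADDER,
) -> dict[str, Lineage]:
    """Parse accession -> lineage; empty rank cells mean "rank absent"."""
    df = _read_tsv(path)
    if "accession" not in df.columns:
        raise FormatError(f"{path}: missing required column 'accession'")
    rank_columns = [r for r in ladder if r in df.columns]
    lineages: dict[str, Lineage] = {}
    for _, row in df.iterrows():
        accession = row["accession"]
        if accession in lineages:
            raise FormatError(f"{path}: duplicate accession {accession!r}")
        path_pairs = tuple(
            (rank, row[rank]) for rank in rank_columns if row[rank]
        )
        lineage = Lineage(accession=accession, path=path_pairs)
        lineage.validate(ladder)
        lineages[accession] = lineage
    return lineages


def write_lineage_table(
    lineages: Mapping[str, Lineage],
    path: str | Path,
    ladder: Sequence[str] = DEFAULT_RANK_LADDER,
) -> None:
    rows = []
    for accession, lineage in lineages.items():
        row = {"accession": accession, **{r: "" for r in ladder}}
        for rank, taxon in lineage.path:
            row[rank] = taxon
        rows.append(row)
    pd.DataFrame(rows, columns=["accession", *ladder]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into id -> uppercased sequence (id = first header token)."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty record {record.id!r}")
        sequences[record.id] = seq
    return sequences
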