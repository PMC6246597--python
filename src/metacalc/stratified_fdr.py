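"""Taxonomically stratified target-decoy FDR control.

The search space is stratified into three uneven groups — human, bacteria,
and other — and a score cutoff is selected independently within each stratum
by target-decoy accumulation: all identifications (forward and reverse) are
sorted by score in descending order and accepted while the accumulated
reverse/forward ratio stays at or below the configured level q (default 1%).

Because the ratio is non-monotone along the sorted list, "accepted until q
had accumulated" is resolved as the LONGEST prefix whose ratio is <= q,
maximizing identifications at controlled FDR.  Records tied at the boundary
score are admitted or rejected as a block, so the cutoff is always a pure
score threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

import pandas as pd

from .tables_io import STRATA, PeptideRecord, ValidationError

__all__ = [
    "FdrResult",
    "split_by_stratum",
    "accept_at_fdr",
    "estimated_fdr_curve",
    "control_fdr",
    "fdr_summary_table",
]


@dataclass(frozen=True)
class FdrResult:
    """Outcome of score-cutoff selection within one stratum."""

    stratum: str
    q_threshold: float
    cutoff_score: float | None  # None when nothing was accepted
    n_forward_accepted: int
    n_reverse_in_prefix: int
    estimated_fdr: float


def split_by_stratum(
    records: Iterable[PeptideRecord],
) -> dict[str, list[PeptideRecord]]:
    """Partition records by stratum label, preserving order within strata."""
    out: dict[str, list[PeptideRecord]] = {s: [] for s in STRATA}
    for rec in records:
        if rec.stratum not in out:
            raise ValidationError(f"unknown stratum label {rec.stratum!r}")
        out[rec.stratum].append(rec)
    return out


def _check_q(q: float) -> None:
    if not 0 < q < 1:
        raise ValidationError(f"q must lie in (0, 1), got {q}")


def accept_at_fdr(
    records: Sequence[PeptideRecord],
    q: float,
    stratum: str | None = None,
) -> tuple[FdrResult, list[PeptideRecord]]:
    """Select the score cutoff at FDR level ``q`` for one stratum.

    Returns the per-stratum summary and the accepted *forward* records
    (decoys in the accepted prefix are discarded from the output).  The
    accepted set is the longest score-sorted prefix, extended block-wise over
    score ties, whose reverse/forward ratio is <= q; 0/0 counts as 0 and a
    prefix with no forward hits never qualifies once a reverse hit is in it.
    """
    _check_q(q)
    if stratum is None:
        labels = {r.stratum for r in records}
        stratum = labels.pop() if len(labels) == 1 else "mixed"

    ordered = sorted(records, key=lambda r: -r.score)
    best = (0, 0, 0)  # (prefix length, n_forward, n_reverse)
    n_fwd = n_rev = length = 0
    for _, block in groupby(ordered, key=lambda r: r.score):
        for rec in block:
            length += 1
            if rec.is_decoy:
                n_rev += 1
            else:
                n_fwd += 1
        if n_rev == 0 or (n_fwd > 0 and n_rev / n_fwd <= q):
            best = (length, n_fwd, n_rev)

    cut, n_fwd, n_rev = best
    accepted = [r for r in ordered[:cut] if not r.is_decoy]
    result = FdrResult(
        stratum=stratum,
        q_threshold=q,
        cutoff_score=ordered[cut - 1].score if cut else None,
        n_forward_accepted=n_fwd,
        n_reverse_in_prefix=n_rev,
        estimated_fdr=n_rev / n_fwd if n_fwd else 0.0,
    )
    return result, accepted


def estimated_fdr_curve(
    records: Sequence[PeptideRecord],
    q_grid: Sequence[float],
) -> pd.DataFrame:
    """Diagnostic sweep of the cutoff over a grid of q values."""
    if len(q_grid) == 0:
        raise ValidationError("q_grid must be nonempty")
    rows = []
    for q in q_grid:
        result, accepted = accept_at_fdr(records, q)
        rows.append(
            {
                "q": q,
                "n_accepted": len(accepted),
                "cutoff_score": result.cutoff_score,
                "estimated_fdr": result.estimated_fdr,
            }
        )
    return pd.DataFrame(rows)


def control_fdr(
    records: Iterable[PeptideRecord],
    q: float,
) -> tuple[list[PeptideRecord], list[FdrResult]]:
    """Apply :func:`accept_at_fdr` independently within every stratum.

    The same q is used for each stratum.  Returns all accepted forward
    records (human, bacteria, other — in that order) and the three
    per-stratum summaries.
    """
    accepted_all: list[PeptideRecord] = []
    results: list[FdrResult] = []
    for stratum, stratum_records in split_by_stratum(records).items():
        result, accepted = accept_at_fdr(stratum_records, q, stratum=stratum)
        results.append(result)
        accepted_all.extend(accepted)
    return accepted_all, results


def fdr_summary_table(results: Sequence[FdrResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "q": r.q_threshold,
                "cutoff_score": r.cutoff_score,
                "n_accepted": r.n_forward_accepted,
                "n_reverse_in_prefix": r.n_reverse_in_prefix,
                "estimated_fdr": r.estimated_fdr,
            }
            for r in results
        ]
    )
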