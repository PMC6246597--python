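"""Target-decoy accumulation cutoff: examples, oracle equivalence, and
monotonicity."""

from itertools import accumulate, groupby

import numpy as np
import pytest

from metacalc.stratified_fdr import (
    accept_at_fdr,
    control_fdr,
    estimated_fdr_curve,
    split_by_stratum,
)
from metacalc.tables_io import PeptideRecord, ValidationError


def _rec(score, decoy=False, stratum="bacteria", seq=None):
    return PeptideRecord(
        sequence=seq or "PEPTIDEK",
        score=float(score),
        is_decoy=decoy,
        stratum=stratum,
        leading_razor_protein="REV__X" if decoy else "ACC",
        proteins=None if decoy else ("ACC",),
        raw_file="T01",
    )


def exhaustive_prefix_scan(records, q):
    """Independent oracle: evaluate every score-tie-respecting prefix and
    return the longest one with reverse/forward <= q."""
    ordered = sorted(records, key=lambda r: -r.score)
    boundaries = []
    i = 0
    for _, block in groupby(ordered, key=lambda r: r.score):
        i += len(list(block))
        boundaries.append(i)
    best = []
    for boundary in boundaries:
        prefix = ordered[:boundary]
        n_rev = sum(r.is_decoy for r in prefix)
        n_fwd = len(prefix) - n_rev
        ratio = 0.0 if n_rev == 0 else (n_rev / n_fwd if n_fwd else np.inf)
        if ratio <= q:
            best = prefix
    return [r for r in best if not r.is_decoy]


class TestSplitByStratum:
    def test_partitions_and_preserves_order(self):
        records = [
            _rec(10, stratum="human"),
            _rec(9, stratum="bacteria"),
            _rec(8, stratum="bacteria"),
        ]
        split = split_by_stratum(records)
        assert {k: len(v) for k, v in split.items()} == {
            "human": 1, "bacteria": 2, "other": 0,
        }
        assert split["bacteria"] == records[1:]

    def test_empty_input_gives_three_empty_lists(self):
        assert all(v == [] for v in split_by_stratum([]).values())

    def test_unknown_label_rejected(self):
        bad = PeptideRecord("PEPK", 1.0, False, "viral", "A", ("A",), "T01")
        with pytest.raises(ValidationError):
            split_by_stratum([bad])

    def test_sizes_conserved_on_random_input(self):
        rng = np.random.default_rng(0)
        records = [
            _rec(s, stratum=str(rng.choice(["human", "bacteria", "other"])))
            for s in rng.normal(50, 10, size=1000)
        ]
        split = split_by_stratum(records)
        assert sum(len(v) for v in split.values()) == 1000


class TestAcceptAtFdr:
    def test_no_decoys_accepts_everything(self):
        records = [_rec(s) for s in range(200)]
        result, accepted = accept_at_fdr(records, q=0.01)
        assert len(accepted) == 200
        assert result.estimated_fdr == 0.0

    def test_decoys_at_ranks_10_and_120(self):
        # descending distinct scores; decoys at sorted ranks 10 and 120:
        # the longest prefix with reverse/forward <= 1% stops just before
        # the second decoy (1 reverse / 118 forward ~ 0.85%)
        records = [
            _rec(1000 - rank, decoy=rank in (10, 120))
            for rank in range(1, 201)
        ]
        result, accepted = accept_at_fdr(records, q=0.01)
        assert len(accepted) == 118
        assert result.n_reverse_in_prefix == 1
        assert result.estimated_fdr == pytest.approx(1 / 118)

    def test_all_decoys_accepts_none(self):
        records = [_rec(s, decoy=True) for s in range(5)]
        result, accepted = accept_at_fdr(records, q=0.01)
        assert accepted == []
        assert result.n_forward_accepted == 0
        assert result.cutoff_score is None

    def test_ties_admitted_or_rejected_as_a_block(self):
        # 120 forwards at score 90, then a decoy and 30 forwards all tied
        # at score 50: including the block gives 1/150 <= 1%, so the whole
        # block including the decoy's tied forwards must come in
        records = (
            [_rec(90, seq=f"A{i}") for i in range(120)]
            + [_rec(50, decoy=True)]
            + [_rec(50, seq=f"B{i}") for i in range(30)]
        )
        result, accepted = accept_at_fdr(records, q=0.01)
        assert len(accepted) == 150
        # but with only 20 tied forwards the ratio 1/140 still passes while
        # a stricter q makes the block fall out entirely
        result2, accepted2 = accept_at_fdr(records, q=0.001)
        assert len(accepted2) == 120
        assert result2.n_reverse_in_prefix == 0

    @pytest.mark.parametrize("q", [-0.1, 0.0, 1.0, 1.5])
    def test_q_outside_unit_interval_rejected(self, q):
        with pytest.raises(ValidationError):
            accept_at_fdr([_rec(1)], q)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_prefix_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 500))
        # coarse integer scores force plenty of ties
        records = [
            _rec(
                int(rng.normal(30 if rng.random() < 0.3 else 60, 8)),
                decoy=rng.random() < 0.3,
                seq=f"P{i}",
            )
            for i in range(n)
        ]
        q = float(rng.choice([0.01, 0.05, 0.2]))
        _, accepted = accept_at_fdr(records, q)
        oracle = exhaustive_prefix_scan(records, q)
        assert sorted(r.sequence for r in accepted) == sorted(
            r.sequence for r in oracle
        )

    def test_accepted_count_monotone_in_q(self):
        rng = np.random.default_rng(3)
        records = [
            _rec(rng.normal(60 if rng.random() > 0.2 else 30, 10),
                 decoy=rng.random() < 0.2, seq=f"P{i}")
            for i in range(300)
        ]
        counts = [
            len(accept_at_fdr(records, q)[1])
            for q in (0.001, 0.005, 0.01, 0.05, 0.1, 0.3)
        ]
        assert counts == sorted(counts)

    def test_output_contains_no_decoys(self):
        rng = np.random.default_rng(4)
        records = [
            _rec(rng.normal(50, 20), decoy=rng.random() < 0.5, seq=f"P{i}")
            for i in range(200)
        ]
        _, accepted = accept_at_fdr(records, 0.3)
        assert not any(r.is_decoy for r in accepted)


class TestFdrCurve:
    def test_no_decoy_input_constant(self):
        records = [_rec(s) for s in range(50)]
        curve = estimated_fdr_curve(records, [0.001, 0.01, 0.05])
        assert set(curve["n_accepted"]) == {50}

    def test_single_forward_record(self):
        curve = estimated_fdr_curve([_rec(1)], [0.001, 0.01, 0.5])
        assert list(curve["n_accepted"]) == [1, 1, 1]

    def test_monotone_on_mixture(self):
        rng = np.random.default_rng(5)
        records = [
            _rec(rng.normal(60 if rng.random() > 0.3 else 35, 10),
                 decoy=rng.random() < 0.3, seq=f"P{i}")
            for i in range(400)
        ]
        curve = estimated_fdr_curve(records, [0.001, 0.01, 0.05])
        assert list(curve["n_accepted"]) == sorted(curve["n_accepted"])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            estimated_fdr_curve([_rec(1)], [])


def test_control_fdr_processes_each_stratum_independently(default_dataset):
    accepted, results = control_fdr(default_dataset.peptides, q=0.01)
    assert {r.stratum for r in results} == {"human", "bacteria", "other"}
    for result in results:
        if result.n_forward_accepted:
            assert result.estimated_fdr <= 0.01
    assert not any(r.is_decoy for r in accepted)
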