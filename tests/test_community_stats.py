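"""Differential testing, clustering, and Bray-Curtis dissimilarity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metacalc.community_stats import (
    bray_curtis,
    hierarchical_cluster,
    pearson_distance,
    scale_percent_to_counts,
    two_group_t_test,
)
from metacalc.tables_io import ValidationError


def _matrix(g1_values, g2_values, genus="g"):
    """samples x 1 genus matrix with G1/G2 labels."""
    samples = [f"a{i}" for i in range(len(g1_values))] + [
        f"b{i}" for i in range(len(g2_values))
    ]
    labels = {s: ("G1" if s.startswith("a") else "G2") for s in samples}
    frame = pd.DataFrame(
        {genus: list(g1_values) + list(g2_values)}, index=samples
    )
    return frame, labels


class TestTwoGroupTTest:
    def test_identical_groups_give_null_result(self):
        frame, labels = _matrix([0.5, 0.25, 0.125], [0.5, 0.25, 0.125])
        out = two_group_t_test(frame, labels)
        assert out.loc[0, "t_statistic"] == pytest.approx(0.0)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_separated_groups_reach_small_p(self):
        # log2 fractions -1.0/-1.1/-0.9 vs 1.0/0.9/1.1
        frame, labels = _matrix(
            [2.0 ** v for v in (-1.0, -1.1, -0.9)],
            [2.0 ** v for v in (1.0, 0.9, 1.1)],
        )
        out = two_group_t_test(frame, labels)
        assert out.loc[0, "p_value"] < 1e-3
        assert out.loc[0, "log2_ratio"] == pytest.approx(-2.0)

    def test_matches_pooled_t_distribution_oracle(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        frame, labels = _matrix(2.0 ** x, 2.0 ** y)
        out = two_group_t_test(frame, labels)
        nx, ny = len(x), len(y)
        sp = np.sqrt(
            ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
            / (nx + ny - 2)
        )
        t = (x.mean() - y.mean()) / (sp * np.sqrt(1 / nx + 1 / ny))
        p = 2 * sps.t.sf(abs(t), nx + ny - 2)
        assert out.loc[0, "t_statistic"] == pytest.approx(t)
        assert out.loc[0, "p_value"] == pytest.approx(p)

    def test_zeros_are_missing_and_sparse_genus_skipped(self):
        frame, labels = _matrix([0.4, 0.0, 0.0], [0.3, 0.2, 0.1])
        out = two_group_t_test(frame, labels)
        assert not out.loc[0, "tested"]
        assert np.isnan(out.loc[0, "p_value"])

    def test_adjusted_p_at_least_raw_p(self):
        rng = np.random.default_rng(12)
        frame = pd.DataFrame(
            2.0 ** rng.normal(0, 1, size=(10, 20)),
            index=[f"s{i}" for i in range(10)],
            columns=[f"g{i}" for i in range(20)],
        )
        labels = {f"s{i}": ("G1" if i < 5 else "G2") for i in range(10)}
        out = two_group_t_test(frame, labels)
        tested = out[out["tested"]]
        assert (tested["adjusted_p"] >= tested["p_value"] - 1e-15).all()
        assert (
            tested["significant"] == (tested["adjusted_p"] <= 0.05)
        ).all()

    def test_too_few_samples_rejected(self):
        frame, labels = _matrix([0.5], [0.5, 0.25])
        with pytest.raises(ValidationError):
            two_group_t_test(frame, labels)


class TestClustering:
    def test_duplicate_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 30)
        matrix = pd.DataFrame(
            {"a": base, "b": base, "c": rng.normal(0, 1, 30)}
        )
        result = hierarchical_cluster(matrix, k=2)
        assert result.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert result.labels["a"] == result.labels["b"] != result.labels["c"]

    def test_anticorrelated_profiles_at_distance_two(self):
        x = np.linspace(-1, 1, 20)
        matrix = pd.DataFrame({"a": x, "b": -x})
        dist, flagged = pearson_distance(matrix)
        assert dist.loc["a", "b"] == pytest.approx(2.0)
        assert flagged == []

    def test_pairs_with_few_shared_entries_are_flagged(self):
        matrix = pd.DataFrame(
            {
                "a": [1.0, 2.0, np.nan, np.nan, 3.0],
                "b": [np.nan, np.nan, 1.0, 2.0, np.nan],
                "c": [1.0, 2.5, 1.0, 2.0, 3.5],
                "d": [1.1, 2.4, 1.2, 2.2, 3.4],
            }
        )
        dist, flagged = pearson_distance(matrix)
        assert ("a", "b") in flagged
        assert np.isfinite(dist.loc["a", "b"])

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(
            rng.normal(0, 1, size=(40, 8)),
            columns=[f"s{i}" for i in range(8)],
        )
        matrix.iloc[:, 4:] += 3 * rng.normal(1, 0.1, size=(40, 4))
        first = hierarchical_cluster(matrix, k=2)
        shuffled = matrix[list(reversed(matrix.columns))]
        second = hierarchical_cluster(shuffled, k=2)
        partition_a = {
            frozenset(s for s, c in first.labels.items() if c == k)
            for k in set(first.labels.values())
        }
        partition_b = {
            frozenset(s for s, c in second.labels.items() if c == k)
            for k in set(second.labels.values())
        }
        assert partition_a == partition_b


class TestScalePercentToCounts:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.0, 0), (0.1234567, 123456), (100.0, 100000000)],
    )
    def test_truncation_rule(self, value, expected):
        out = scale_percent_to_counts(pd.DataFrame({"g": [value]}))
        assert out.loc[0, "g"] == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            scale_percent_to_counts(pd.DataFrame({"g": [-0.1]}))


class TestBrayCurtis:
    def test_identical_vectors_zero(self):
        counts = pd.DataFrame([[3, 5, 2], [3, 5, 2]], index=["a", "b"])
        assert bray_curtis(counts).loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        counts = pd.DataFrame([[3, 0], [0, 7]], index=["a", "b"])
        assert bray_curtis(counts).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_formula(self):
        counts = pd.DataFrame([[6, 4], [2, 8]], index=["a", "b"])
        assert bray_curtis(counts).loc["a", "b"] == pytest.approx(0.4)

    def test_all_zero_sample_flagged_nan(self):
        counts = pd.DataFrame([[1, 2], [0, 0]], index=["a", "b"])
        out = bray_curtis(counts)
        assert np.isnan(out.loc["a", "b"])
        assert np.isnan(out.loc["b", "b"])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(10, 8)),
            index=[f"s{i}" for i in range(10)],
        )
        out = bray_curtis(counts)
        for i in counts.index:
            for j in counts.index:
                x, y = counts.loc[i].to_numpy(), counts.loc[j].to_numpy()
                expected = 1 - 2 * np.minimum(x, y).sum() / (
                    x.sum() + y.sum()
                )
                assert out.loc[i, j] == pytest.approx(expected)
                assert out.loc[i, j] == pytest.approx(out.loc[j, i])
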