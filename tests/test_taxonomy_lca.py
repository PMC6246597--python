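"""LCA assignment, representative selection, and the human override."""

import numpy as np
import pytest

from metacalc.tables_io import Lineage, ProteinGroup, ValidationError
from metacalc.taxonomy_lca import (
    apply_human_override,
    assign_groups,
    genus_assignment_rate,
    lca,
    select_representatives,
    TaxonomicAssignment,
)

STREP_SANGUINIS = Lineage("S1", (
    ("superkingdom", "Bacteria"),
    ("phylum", "Firmicutes"),
    ("class", "Bacilli"),
    ("order", "Lactobacillales"),
    ("family", "Streptococcaceae"),
    ("genus", "Streptococcus"),
    ("species", "Streptococcus sanguinis"),
))
STREP_MUTANS = Lineage("S2", (
    ("superkingdom", "Bacteria"),
    ("phylum", "Firmicutes"),
    ("class", "Bacilli"),
    ("order", "Lactobacillales"),
    ("family", "Streptococcaceae"),
    ("genus", "Streptococcus"),
    ("species", "Streptococcus mutans"),
))
HUMAN = Lineage("H1", (
    ("superkingdom", "Eukaryota"),
    ("phylum", "Chordata"),
    ("class", "Mammalia"),
    ("order", "Primates"),
    ("parvorder", "Catarrhini"),
    ("family", "Hominidae"),
    ("genus", "Homo"),
    ("species", "Homo sapiens"),
))


class TestSelectRepresentatives:
    def test_ties_all_retained(self):
        assert select_representatives(
            ["A", "B", "C"], {"A": 5, "B": 5, "C": 2}
        ) == ("A", "B")

    def test_single_accession(self):
        assert select_representatives(["A"], {}) == ("A",)

    def test_all_equal_returns_full_list(self):
        assert select_representatives(["A", "B"], {"A": 1, "B": 1}) == (
            "A", "B",
        )

    def test_empty_majority_list_rejected(self):
        with pytest.raises(ValidationError):
            select_representatives([], {})


def brute_force_lca(lineages, ladder):
    """Independent oracle: walk the first path leaf-to-root and return the
    first (rank, taxon) pair found in every other path."""
    for rank, taxon in reversed(lineages[0].path):
        if all((rank, taxon) in l.path for l in lineages[1:]):
            return taxon, rank
    return "unassigned", "unassigned"


class TestLca:
    def test_single_lineage_returns_leaf(self):
        assert lca([STREP_SANGUINIS]) == (
            "Streptococcus sanguinis", "species",
        )

    def test_two_congeneric_species_meet_at_genus(self):
        assert lca([STREP_SANGUINIS, STREP_MUTANS]) == (
            "Streptococcus", "genus",
        )

    def test_disjoint_superkingdoms_unassigned(self):
        assert lca([STREP_SANGUINIS, HUMAN]) == ("unassigned", "unassigned")

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_leafward_walk_oracle(self, seed):
        from metacalc.tables_io import DEFAULT_RANK_LADDER
        rng = np.random.default_rng(seed)
        # random forest: a few shared prefixes with random divergence depth
        pool = []
        for i in range(20):
            depth = int(rng.integers(1, 8))
            family_tag = int(rng.integers(0, 3))
            path = []
            for j, rank in enumerate(
                r for r in DEFAULT_RANK_LADDER if r != "parvorder"
            ):
                if j >= depth:
                    break
                shared = j < int(rng.integers(1, 6))
                taxon = f"{rank}_{family_tag}" if shared else f"{rank}_{i}"
                path.append((rank, taxon))
            pool.append(Lineage(f"L{i}", tuple(path)))
        subset = list(
            rng.choice(len(pool), size=int(rng.integers(1, 8)),
                       replace=False)
        )
        lineages = [pool[i] for i in subset]
        assert lca(lineages) == brute_force_lca(
            lineages, DEFAULT_RANK_LADDER
        )

    def test_permutation_invariant_and_idempotent(self):
        forward = lca([STREP_SANGUINIS, STREP_MUTANS, HUMAN])
        assert forward == lca([HUMAN, STREP_MUTANS, STREP_SANGUINIS])
        assert lca([STREP_SANGUINIS, STREP_SANGUINIS]) == lca(
            [STREP_SANGUINIS]
        )

    def test_result_taxon_appears_in_every_input_path(self, default_dataset):
        lineages = list(default_dataset.lineages.values())[:10]
        taxon, rank = lca(lineages[:3])
        if taxon != "unassigned":
            assert all((rank, taxon) in l.path for l in lineages[:3])

    def test_adding_a_lineage_never_deepens_the_lca(self):
        from metacalc.tables_io import DEFAULT_RANK_LADDER
        depth = {r: i for i, r in enumerate(DEFAULT_RANK_LADDER)}
        depth["unassigned"] = -1
        base = [STREP_SANGUINIS]
        previous = depth[lca(base)[1]]
        for extra in (STREP_MUTANS, HUMAN):
            base.append(extra)
            current = depth[lca(base)[1]]
            assert current <= previous
            previous = current


def _assignment(taxon, rank, stratum):
    return TaxonomicAssignment(
        group_id=1,
        representative_accessions=("X",),
        lca_taxon=taxon,
        lca_rank=rank,
        effective_stratum=stratum,
    )


def _group(protein_ids):
    return ProteinGroup(
        group_id=1,
        protein_ids=tuple(protein_ids),
        majority_protein_ids=tuple(protein_ids),
    )


class TestHumanOverride:
    def test_catarrhini_becomes_homo_sapiens(self):
        out = apply_human_override(
            _assignment("Catarrhini", "parvorder", "other"),
            _group(["X"]), {},
        )
        assert (out.lca_taxon, out.lca_rank, out.effective_stratum) == (
            "Homo sapiens", "species", "human",
        )

    def test_other_group_with_human_accession_rescued(self):
        out = apply_human_override(
            _assignment("unassigned", "unassigned", "other"),
            _group(["X", "H1"]), {"H1": HUMAN},
        )
        assert out.effective_stratum == "human"

    def test_bacterial_assignment_untouched(self):
        before = _assignment("Streptococcus", "genus", "bacteria")
        assert apply_human_override(before, _group(["S1"]),
                                    {"S1": STREP_SANGUINIS}) == before


class TestGenusAssignmentRate:
    def test_all_species_level_is_one(self):
        assignments = [
            _assignment("S. x", "species", "bacteria") for _ in range(4)
        ]
        assert genus_assignment_rate(assignments) == 1.0

    def test_three_genus_one_family(self):
        assignments = [
            _assignment("G", "genus", "bacteria"),
            _assignment("G", "genus", "bacteria"),
            _assignment("G", "genus", "bacteria"),
            _assignment("F", "family", "bacteria"),
        ]
        assert genus_assignment_rate(assignments) == 0.75

    def test_zero_bacterial_groups_is_an_error(self):
        with pytest.raises(ValidationError):
            genus_assignment_rate(
                [_assignment("Homo sapiens", "species", "human")]
            )

    def test_generator_unresolvable_fraction_recovered(self):
        from metacalc.synthetic_data import SimulationConfig, simulate_dataset
        from metacalc.taxonomy_lca import peptide_association_counts

        rates = []
        for seed in range(3):
            ds = simulate_dataset(
                SimulationConfig(seed=seed, proteins_per_genus=12)
            )
            counts = peptide_association_counts(ds.peptides)
            bacterial = [
                g for g in ds.groups
                if ds.truth.group_stratum[g.group_id] == "bacteria"
            ]
            assignments = assign_groups(bacterial, ds.lineages, counts)
            rates.append(genus_assignment_rate(assignments))
        assert abs(np.mean(rates) - 0.9) < 0.08


def test_assign_groups_end_to_end(default_dataset):
    from metacalc.taxonomy_lca import peptide_association_counts

    ds = default_dataset
    counts = peptide_association_counts(ds.peptides)
    assignments = assign_groups(ds.groups, ds.lineages, counts)
    by_id = {a.group_id: a for a in assignments}
    for group in ds.groups:
        truth = ds.truth.group_stratum[group.group_id]
        if truth in ("bacteria", "human"):
            assert by_id[group.group_id].effective_stratum == truth
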