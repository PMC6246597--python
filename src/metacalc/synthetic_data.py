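"""Synthetic search-engine output with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a two-group community design (one group enriched for
periodontitis-associated genera, the other for oral commensals), forward and
reverse peptide-spectrum matches whose scores follow two normal
distributions with targets stochastically dominating decoys, protein groups
with razor+unique peptide counts and lognormal label-free intensities per
raw file, completely-at-random missing values, and a configurable share of
bacterial accessions whose lineage stops above genus.

Everything is deterministic given the seed, and every latent quantity the
pipeline is supposed to recover — group labels, per-sample genus fractions,
per-PSM correctness — is returned as ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .tables_io import (
    DEFAULT_DECOY_PREFIX,
    DEFAULT_RANK_LADDER,
    Lineage,
    PeptideRecord,
    ProteinGroup,
    ValidationError,
    write_lineage_table,
    write_peptide_table,
    write_protein_group_table,
)

__all__ = [
    "GenusSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "default_genus_panel",
    "simulate_dataset",
    "spike_effect",
]

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class GenusSpec:
    """One bacterial genus in the simulated community.

    ``base_mean_fraction`` is the genus's share of total bacterial protein
    mass before group effects and renormalization;
    ``log2_effect_g1_vs_g2`` shifts it symmetrically between the groups
    (+e/2 in G1, -e/2 in G2 on the log2 scale).
    """

    name: str
    base_mean_fraction: float
    log2_effect_g1_vs_g2: float = 0.0


def default_genus_panel() -> tuple[GenusSpec, ...]:
    """Panel mirroring the biology of a periodontitis-stratified oral
    community: G1 enriched for periopathogens (red-complex genera among
    them), G2 for commensals, with Actinomyces dominant in both."""
    return (
        GenusSpec("Actinomyces", 0.22, 0.0),
        GenusSpec("Olsenella", 0.10, 1.2),
        GenusSpec("Fretibacterium", 0.09, 1.5),
        GenusSpec("Porphyromonas", 0.06, 1.5),
        GenusSpec("Treponema", 0.05, 1.4),
        GenusSpec("Tannerella", 0.04, 1.3),
        GenusSpec("Desulfobulbus", 0.03, 1.2),
        GenusSpec("Lautropia", 0.08, -1.5),
        GenusSpec("Neisseria", 0.08, -1.4),
        GenusSpec("Streptococcus", 0.10, -1.5),
        GenusSpec("Cardiobacterium", 0.04, -1.2),
        GenusSpec("Leptotrichia", 0.05, -1.2),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    The sample design is 16 + 6 (the two groups the clustering of the
    medieval samples defines); ``genus_unresolvable_fraction`` of bacterial
    accessions get a lineage truncated at family so roughly 90% of bacterial
    groups resolve to genus; decoy and forward-false shares are matched so
    reverse hits estimate false forward hits about one-to-one.
    """

    seed: int = 0
    n_samples_g1: int = 16
    n_samples_g2: int = 6
    genera: tuple[GenusSpec, ...] = field(default_factory=default_genus_panel)
    proteins_per_genus: int = 14
    species_per_genus: int = 3
    human_protein_count: int = 40
    other_protein_count: int = 5
    peptides_per_protein: int = 3
    observation_rate: float = 0.8  # P(a peptide yields a PSM in a sample)
    decoy_fraction: float = 0.10  # decoy share of all PSM rows
    forward_false_fraction: float = 0.10  # false share of forward PSMs
    target_score_location: float = 80.0
    target_score_scale: float = 15.0
    decoy_score_location: float = 35.0
    decoy_score_scale: float = 10.0
    lfq_log_sd: float = 0.5  # natural-log sd of per-sample protein noise
    fraction_noise_sd: float = 0.20  # natural-log sd of genus fraction noise
    missing_rate: float = 0.08
    genus_unresolvable_fraction: float = 0.10
    total_bacterial_intensity: float = 1e10
    decoy_prefix: str = DEFAULT_DECOY_PREFIX
    contaminant_group_count: int = 3  # keratin/collagen-style entries
    decoy_group_count: int = 2  # reverse-hit protein groups

    def validate(self) -> None:
        if not self.genera:
            raise ValidationError("at least one genus is required")
        if all(g.base_mean_fraction <= 0 for g in self.genera):
            raise ValidationError("all base fractions are zero")
        for name, value in (
            ("decoy_fraction", self.decoy_fraction),
            ("forward_false_fraction", self.forward_false_fraction),
            ("missing_rate", self.missing_rate),
            ("genus_unresolvable_fraction", self.genus_unresolvable_fraction),
        ):
            if not 0 <= value < 1:
                raise ValidationError(f"{name} must lie in [0, 1)")
        if not 0 < self.observation_rate <= 1:
            raise ValidationError("observation_rate must lie in (0, 1]")
        if self.target_score_location <= self.decoy_score_location:
            raise ValidationError(
                "target score location must exceed decoy score location"
            )
        if self.n_samples_g1 < 1 or self.n_samples_g2 < 1:
            raise ValidationError("each group needs at least one sample")

    @property
    def samples(self) -> list[str]:
        n = self.n_samples_g1 + self.n_samples_g2
        return [f"T{i + 1:02d}" for i in range(n)]

    @property
    def group_labels(self) -> dict[str, str]:
        return {
            s: ("G1" if i < self.n_samples_g1 else "G2")
            for i, s in enumerate(self.samples)
        }


def spike_effect(
    config: SimulationConfig, genus: str, log2_effect: float
) -> SimulationConfig:
    """Copy of ``config`` with one genus's group effect overridden."""
    names = [g.name for g in config.genera]
    if genus not in names:
        raise ValidationError(f"unknown genus {genus!r}")
    genera = tuple(
        dataclasses.replace(g, log2_effect_g1_vs_g2=log2_effect)
        if g.name == genus
        else g
        for g in config.genera
    )
    return dataclasses.replace(config, genera=genera)


@dataclass
class GroundTruth:
    group_labels: dict[str, str]
    genus_fractions: pd.DataFrame  # samples x genera, pre-masking truth
    psm: pd.DataFrame  # sequence, raw_file, score, stratum, is_decoy, is_true
    group_stratum: dict[int, str]

    def psm_truth_lookup(self) -> dict[tuple[str, str, float], bool]:
        return {
            (row.sequence, row.raw_file, row.score): bool(row.is_true)
            for row in self.psm.itertuples(index=False)
        }


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    peptides: list[PeptideRecord]
    groups: list[ProteinGroup]
    lineages: dict[str, Lineage]
    truth: GroundTruth

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the four input tables plus the ground-truth directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "peptides": directory / "peptides.tsv",
            "protein_groups": directory / "protein_groups.tsv",
            "lineages": directory / "lineages.tsv",
        }
        write_peptide_table(self.peptides, paths["peptides"])
        write_protein_group_table(
            self.groups, paths["protein_groups"], self.config.samples
        )
        write_lineage_table(self.lineages, paths["lineages"])
        truth_dir = directory / "ground_truth"
        truth_dir.mkdir(exist_ok=True)
        labels = pd.DataFrame(
            sorted(self.truth.group_labels.items()),
            columns=["sample", "group"],
        )
        labels.to_csv(truth_dir / "group_labels.tsv", sep="\t", index=False)
        self.truth.genus_fractions.to_csv(
            truth_dir / "genus_fractions.tsv", sep="\t",
            index_label="sample",
        )
        self.truth.psm.to_csv(truth_dir / "psm.tsv", sep="\t", index=False)
        paths["ground_truth"] = truth_dir
        return paths


def _bacterial_lineage(
    genus: str, species_tag: int | None, resolvable: bool
) -> tuple[tuple[str, str], ...]:
    path = [
        ("superkingdom", "Bacteria"),
        ("phylum", f"{genus}_phylum"),
        ("class", f"{genus}_class"),
        ("order", f"{genus}_order"),
        ("family", f"{genus}aceae"),
    ]
    if resolvable:
        path.append(("genus", genus))
        if species_tag is not None:
            path.append(("species", f"{genus} species{species_tag}"))
    return tuple(path)


_HUMAN_PATH = (
    ("superkingdom", "Eukaryota"),
    ("phylum", "Chordata"),
    ("class", "Mammalia"),
    ("order", "Primates"),
    ("parvorder", "Catarrhini"),
    ("family", "Hominidae"),
    ("genus", "Homo"),
    ("species", "Homo sapiens"),
)

_OTHER_PATHS = (
    (
        ("superkingdom", "Archaea"),
        ("phylum", "Euryarchaeota"),
        ("class", "Methanobacteria"),
        ("order", "Methanobacteriales"),
        ("family", "Methanobacteriaceae"),
        ("genus", "Methanobrevibacter"),
        ("species", "Methanobrevibacter oralis"),
    ),
    (
        ("superkingdom", "Eukaryota"),
        ("phylum", "Streptophyta"),
        ("class", "Magnoliopsida"),
        ("order", "Poales"),
        ("family", "Poaceae"),
        ("genus", "Avena"),
        ("species", "Avena sativa"),
    ),
)


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 21))
    return "".join(rng.choice(_RESIDUES, size=length))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate peptide, protein-group, and lineage tables with ground truth.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = config.samples
    labels = config.group_labels

    # --- taxonomy and protein database -------------------------------------
    lineages: dict[str, Lineage] = {}
    proteins: list[dict] = []  # accession, stratum, genus, weight
    group_stratum: dict[int, str] = {}

    for gi, genus_spec in enumerate(config.genera):
        genus = genus_spec.name
        shares = rng.lognormal(0.0, 0.8, size=config.proteins_per_genus)
        shares /= shares.sum()
        for pi in range(config.proteins_per_genus):
            accession = f"{genus[:4].upper()}{gi:02d}_{pi:03d}"
            resolvable = rng.random() >= config.genus_unresolvable_fraction
            species_tag = pi % config.species_per_genus + 1
            lineages[accession] = Lineage(
                accession,
                _bacterial_lineage(genus, species_tag, resolvable),
            )
            proteins.append(
                {
                    "accession": accession,
                    "stratum": "bacteria",
                    "genus": genus,
                    "weight": shares[pi],
                }
            )

    human_shares = rng.lognormal(0.0, 0.8, size=config.human_protein_count)
    human_shares /= human_shares.sum()
    for pi in range(config.human_protein_count):
        accession = f"HUM_{pi:03d}"
        lineages[accession] = Lineage(accession, _HUMAN_PATH)
        proteins.append(
            {
                "accession": accession,
                "stratum": "human",
                "genus": None,
                "weight": human_shares[pi],
            }
        )

    other_shares = rng.lognormal(0.0, 0.8, size=config.other_protein_count)
    other_shares /= max(other_shares.sum(), 1e-12)
    for pi in range(config.other_protein_count):
        accession = f"OTH_{pi:03d}"
        lineages[accession] = Lineage(
            accession, _OTHER_PATHS[pi % len(_OTHER_PATHS)]
        )
        proteins.append(
            {
                "accession": accession,
                "stratum": "other",
                "genus": None,
                "weight": other_shares[pi],
            }
        )

    # --- true per-sample genus fractions ------------------------------------
    genus_names = [g.name for g in config.genera]
    base = np.array([g.base_mean_fraction for g in config.genera])
    effect = np.array([g.log2_effect_g1_vs_g2 for g in config.genera])
    fractions = np.empty((len(samples), len(genus_names)))
    for si, sample in enumerate(samples):
        shift = effect / 2 if labels[sample] == "G1" else -effect / 2
        noisy = (
            base
            * np.exp2(shift)
            * rng.lognormal(0.0, config.fraction_noise_sd, size=base.shape)
        )
        fractions[si] = noisy / noisy.sum()
    true_fractions = pd.DataFrame(
        fractions, index=samples, columns=genus_names
    )

    # --- protein groups with counts and LFQ ---------------------------------
    groups: list[ProteinGroup] = []
    peptide_rows: list[dict] = []
    bacterial_total = config.total_bacterial_intensity
    human_total = bacterial_total * 0.10
    other_total = bacterial_total * 0.005

    for group_id, protein in enumerate(proteins):
        accession = protein["accession"]
        protein_ids = [accession]
        # occasionally add a same-genus sister accession so the LCA resolves
        # at genus rather than species level
        if protein["stratum"] == "bacteria" and rng.random() < 0.25:
            sister = f"{accession}s"
            lineages[sister] = Lineage(
                sister,
                _bacterial_lineage(
                    protein["genus"],
                    int(rng.integers(1, config.species_per_genus + 1)),
                    True,
                ),
            )
            protein_ids.append(sister)
        counts: dict[str, int] = {}
        lfq: dict[str, float] = {}
        for si, sample in enumerate(samples):
            if protein["stratum"] == "bacteria":
                mean = (
                    bacterial_total
                    * true_fractions.iloc[si][protein["genus"]]
                    * protein["weight"]
                )
            elif protein["stratum"] == "human":
                mean = human_total * protein["weight"]
            else:
                mean = other_total * protein["weight"]
            observed = rng.random() < config.observation_rate
            if not observed:
                counts[sample] = 0
                continue
            # mostly well-supported groups, with a minority at a single
            # razor+unique peptide to exercise the per-raw-file mask
            counts[sample] = int(2 + rng.poisson(2.0)) \
                if rng.random() < 0.85 else 1
            if rng.random() >= config.missing_rate:
                lfq[sample] = float(
                    mean * rng.lognormal(0.0, config.lfq_log_sd)
                )
        groups.append(
            ProteinGroup(
                group_id=group_id,
                protein_ids=tuple(protein_ids),
                majority_protein_ids=tuple(protein_ids),
                razor_unique_counts=counts,
                lfq=lfq,
                annotation=f"{accession} protein",
            )
        )
        group_stratum[group_id] = protein["stratum"]

        # --- forward PSMs for this protein ----------------------------------
        pep_sequences = [
            _random_peptide(rng) for _ in range(config.peptides_per_protein)
        ]
        for sample in samples:
            if counts[sample] == 0:
                continue
            for seq in pep_sequences:
                if rng.random() >= config.observation_rate:
                    continue
                is_false = rng.random() < config.forward_false_fraction
                loc, scale = (
                    (config.decoy_score_location, config.decoy_score_scale)
                    if is_false
                    else (config.target_score_location,
                          config.target_score_scale)
                )
                peptide_rows.append(
                    {
                        "sequence": seq,
                        "score": float(rng.normal(loc, scale)),
                        "is_decoy": False,
                        "stratum": protein["stratum"],
                        "leading": accession,
                        "proteins": tuple(protein_ids),
                        "raw_file": sample,
                        "is_true": not is_false,
                    }
                )

    # --- contaminant and reverse-hit groups (filtered out downstream) -------
    contaminant_names = ("Keratin, type II cytoskeletal",
                         "Collagen alpha-1(I) chain",
                         "Serum albumin")
    next_id = len(groups)
    for ci in range(config.contaminant_group_count):
        accession = f"CON__CONT{ci:02d}"
        groups.append(
            ProteinGroup(
                group_id=next_id,
                protein_ids=(accession,),
                majority_protein_ids=(accession,),
                razor_unique_counts={s: 3 for s in samples},
                lfq={s: 1e7 for s in samples},
                is_contaminant=True,
                annotation=contaminant_names[ci % len(contaminant_names)],
            )
        )
        group_stratum[next_id] = "contaminant"
        next_id += 1
    for di in range(config.decoy_group_count):
        accession = config.decoy_prefix + f"DEC{di:02d}"
        groups.append(
            ProteinGroup(
                group_id=next_id,
                protein_ids=(accession,),
                majority_protein_ids=(accession,),
                razor_unique_counts={samples[0]: 2},
                lfq={},
                is_decoy_group=True,
                annotation="reverse hit",
            )
        )
        group_stratum[next_id] = "decoy"
        next_id += 1

    # --- decoy PSMs ----------------------------------------------------------
    n_forward = len(peptide_rows)
    n_decoys = round(
        config.decoy_fraction / (1 - config.decoy_fraction) * n_forward
    )
    strata = [r["stratum"] for r in peptide_rows]
    stratum_values, stratum_counts = np.unique(strata, return_counts=True)
    stratum_p = stratum_counts / stratum_counts.sum()
    accessions_by_stratum = {
        s: [p["accession"] for p in proteins if p["stratum"] == s]
        for s in stratum_values
    }
    for _ in range(n_decoys):
        stratum = str(rng.choice(stratum_values, p=stratum_p))
        source = str(rng.choice(accessions_by_stratum[stratum]))
        # a minority of decoys keep a valid Proteins cell; the QC filter
        # removes exactly those after FDR
        has_proteins = rng.random() < 0.2
        peptide_rows.append(
            {
                "sequence": _random_peptide(rng),
                "score": float(
                    rng.normal(
                        config.decoy_score_location, config.decoy_score_scale
                    )
                ),
                "is_decoy": True,
                "stratum": stratum,
                "leading": config.decoy_prefix + source,
                "proteins": (config.decoy_prefix + source,)
                if has_proteins
                else None,
                "raw_file": str(rng.choice(samples)),
                "is_true": False,
            }
        )

    records = [
        PeptideRecord(
            sequence=row["sequence"],
            score=row["score"],
            is_decoy=row["is_decoy"],
            stratum=row["stratum"],
            leading_razor_protein=row["leading"],
            proteins=row["proteins"],
            raw_file=row["raw_file"],
        )
        for row in peptide_rows
    ]
    psm_truth = pd.DataFrame(
        [
            {
                "sequence": row["sequence"],
                "raw_file": row["raw_file"],
                "score": row["score"],
                "stratum": row["stratum"],
                "is_decoy": row["is_decoy"],
                "is_true": row["is_true"],
            }
            for row in peptide_rows
        ]
    )
    truth = GroundTruth(
        group_labels=labels,
        genus_fractions=true_fractions,
        psm=psm_truth,
        group_stratum=group_stratum,
    )
    return SimulatedDataset(
        config=config,
        peptides=records,
        groups=groups,
        lineages=lineages,
        truth=truth,
    )
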