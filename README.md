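# metacalc

Quantitative metaproteomics post-processing for dental calculus (and other
host–microbiome samples): turn peptide- and protein-group-level search-engine
output into taxonomically controlled, quantified community profiles.

Dental calculus entombs proteins from the host, the oral microbiome, and
diet. Shotgun metaproteomics of such samples searches tandem mass spectra
against a huge combined database (host proteome + oral microbes + general
sequence collections), which makes error control and taxonomic attribution
the central post-processing problems. `metacalc` implements that
post-processing as a tested, reusable pipeline for bioinformaticians working
with MaxQuant-style output:

* **Stratified target–decoy FDR.** The search space is split into three
  uneven strata — human, bacteria, other — and a score cutoff is chosen
  independently in each: identifications (forward and reverse-database) are
  sorted by score descending and accepted while the accumulated ratio
  reverse/forward ≤ *q* (default 1%). The accepted set is the longest
  qualifying prefix, with score ties admitted or rejected as a block, so the
  cutoff is a pure score threshold.
* **Quality-control filters.** Peptides whose leading razor protein is a
  reverse hit (with a valid Proteins entry) are removed; protein groups are
  retained only if a surviving leading razor accession is among their
  Protein IDs; LFQ values are masked in raw files with fewer than two
  razor + unique peptides; decoy groups, contaminants, collagen and keratin
  are excluded.
* **LCA taxonomy.** Each group's majority protein IDs are narrowed to the
  accessions with the most peptide associations; the group's taxon is the
  lowest rank in the intersection of their lineages. Assignments landing on
  the primate parvorder Catarrhini — and "other" groups carrying a human
  accession — are set to *Homo sapiens* (hominid database redundancy).
* **Genus-level LFQ profiles.** Per sample, each genus's fraction is its
  summed LFQ intensity divided by the total bacterial LFQ intensity;
  bacterial groups unresolved at genus absorb the remainder, so fractions
  plus the unassigned remainder sum to exactly 1.
* **Community statistics.** Pearson-distance hierarchical clustering of
  samples (after a minimum-presence filter and log2 + median normalization),
  per-genus two-tailed *t*-tests on log2 fractions with Benjamini–Hochberg
  adjustment (the volcano table), and Bray–Curtis dissimilarity
  BC(i,j) = 1 − 2·Σ min(xᵢ, xⱼ) / Σ (xᵢ + xⱼ) on integer counts obtained by
  scaling percentages by 10⁶ with truncation.
* **Dietary peptide discrimination.** In-silico tryptic digestion (cleave
  after K/R, configurable proline rule, ≤ 2 missed cleavages) and
  species attribution that respects spontaneous N→D deamidation in aged
  proteins: peptides differing from a homolog only at N/D positions are
  *ambiguous*, not species-diagnostic — the classic beta-lactoglobulin
  PTPEGDLEILLQK case.
* **Synthetic data with ground truth.** A generator emulates the full input
  shape — two-group community design (periopathogen-enriched vs
  commensal-enriched genera), target/decoy score mixtures, razor+unique
  counts, lognormal LFQ with missing values, partially unresolvable
  lineages — so every stage is testable offline against known truth.

## Worked example

```sh
metacalc simulate --seed 5 --out demo/inputs
metacalc run-all --input demo/inputs --out demo/results
```

The run reports each stage and writes a manifest of artifacts:

```
INFO metacalc: stage: fdr
INFO metacalc: filter: 8134 -> 8134 peptides, 218 -> 213 groups
INFO metacalc: bacterial genus assignment rate: 0.857
...
fdr_summary      fdr_summary.tsv      3 rows
volcano          volcano.tsv          12 rows
bray_curtis      bray_curtis.tsv      22 rows
```

`fdr_summary.tsv` shows the per-stratum cutoffs — each stratum's estimated
FDR (reverse/forward at the cutoff) is at or below the 1% target:

```
stratum   q     cutoff_score  n_accepted  n_reverse_in_prefix  estimated_fdr
human     0.01  51.08         1496        14                   0.00936
bacteria  0.01  48.74         6452        64                   0.00992
other     0.01  46.98         186         1                    0.00538
```

`volcano.tsv` holds the differential genera between the two sample groups
found by clustering (positive log2 ratio = enriched in the larger group G1);
the significant genera recover the simulated design, periodontitis-associated
genera up in G1 and commensals up in G2:

```
genus           log2_ratio  t_statistic  p_value  adjusted_p
Lautropia          -2.1132      -6.0916   0.0000      0.0000
Porphyromonas       1.5912       6.0482   0.0000      0.0000
Streptococcus      -1.3750      -5.7110   0.0000      0.0001
Fretibacterium      1.1908       5.4930   0.0000      0.0001
Treponema           1.3255       5.3290   0.0000      0.0001
Olsenella           1.3296       4.6819   0.0001      0.0003
```

For dietary references, `metacalc diet --out demo/diet.tsv` classifies
tryptic peptides of the packaged beta-lactoglobulin pair into
species-unique vs deamidation-ambiguous classes:

```
6 unique to BLG_BOVINE, 9 unique to BLG_CAPRINE, 10 ambiguous
```

Every stage is also available as a library function
(`metacalc.stratified_fdr`, `metacalc.taxonomy_lca`, `metacalc.genus_quant`,
`metacalc.community_stats`, `metacalc.dietary_peptides`,
`metacalc.synthetic_data`) and as individual subcommands (`fdr`, `filter`,
`lca`, `quant`, `stats`, `diet`) that compose to the same artifacts as
`run-all`.

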