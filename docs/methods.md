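# Methods

This note documents the statistical model behind each pipeline stage, the
conditions the synthetic-data generator emulates, and the numerical and
design choices made where the underlying procedures are commonly described
only informally.

## Stratified target–decoy FDR

Peptide-spectrum matches are searched against a concatenated forward +
reversed database; reverse ("decoy") hits estimate the number of false
forward hits above any score threshold. Because the combined search space
(host proteome, oral microbial genomes, general collections) is dominated by
bacterial sequences, a single global cutoff would let the large stratum set
the threshold for the small ones. The pipeline therefore partitions PSMs
into three strata — human, bacteria, other — and controls the error rate
separately in each.

Within a stratum, records are sorted by identification score descending and
accepted while the accumulated ratio (number of reverse hits)/(number of
forward hits) is at most the level *q* (default 0.01). Two conventions are
fixed deliberately:

* **Longest qualifying prefix.** The ratio is non-monotone along the sorted
  list, so "accept until *q* has accumulated" is ambiguous between the first
  crossing and the longest prefix satisfying the bound. The longest prefix
  maximizes identifications at the same estimated FDR and is the convention
  adopted here.
* **Tie blocks.** Records sharing the boundary score enter or leave
  together, and a block is admitted only if the ratio including the whole
  block qualifies. This guarantees the published cutoff is a pure score
  threshold; whether any real-world implementation breaks ties by a
  secondary key is unknowable from a score list, so the block rule is this
  package's documented convention.

A prefix with forward = 0 and reverse > 0 never qualifies; 0/0 counts as 0.
The decoy flag is derived solely from the configured accession prefix
(default `REV__`), making classification a pure function of configuration.

## Quality control and group filtering

The filter chain runs in a fixed order: (1) remove peptides whose leading
razor protein is a reverse hit while the Proteins cell is valid — these are
decoy-driven rows that nonetheless reference real proteins; (2) keep a
protein group only if a surviving leading razor accession appears in its
Protein IDs; (3) enforce a minimum of two razor + unique peptides per raw
file; (4) remove decoy groups, flagged contaminants, and annotation matches
for excluded patterns (collagen, keratin by default; case-insensitive
substrings — these proteins are ubiquitous in both skin/dust contamination
and skeletal tissue, so they are uninformative for oral-community
composition).

The per-raw-file minimum is read as a **quantitation mask**: LFQ values are
set to missing in raw files below the threshold, and a group is dropped only
when masked everywhere. The stricter alternative — dropping any group that
misses the threshold in any raw file — is available via
`filter.drop_whole_group`. The mask reading preserves per-sample
quantitation in samples where the group is well supported, which is how
per-raw-file thresholds are ordinarily used with label-free data.

All filters are idempotent, and the retained-group set shrinks monotonically
in the minimum count; both properties are under test.

## LCA taxonomy

For each protein group the accessions in the majority protein IDs with the
most peptide associations are selected as representatives (a peptide is
associated with every accession in its Proteins list; ties keep all
attaining accessions). The group's taxon is the most specific (rank, taxon)
pair contained in every representative's lineage; the intersection is
computed on pairs rather than bare names so a homonymous taxon at two ranks
cannot produce a false meet. An empty intersection yields "unassigned";
unassigned groups stay in the pipeline and still count toward the bacterial
intensity total (below).

Human override: sequence databases carry many near-identical hominid
entries, so LCA searches over human proteins frequently terminate at the
primate parvorder Catarrhini instead of *Homo sapiens*. Any assignment
landing on a configured trigger taxon (Catarrhini, Hominidae, Homo, Homo
sapiens by default), and any "other"-stratum group containing a human
accession, is set to *Homo sapiens* at species rank with effective stratum
human.

## Genus-level quantitation

Per raw file, the fractional abundance of genus *g* is

    f(g, s) = Σ LFQ of bacterial groups resolved to g in sample s
              / Σ LFQ of all bacterial groups in sample s.

Species-level assignments roll up to their genus. The denominator includes
genus-unresolved bacterial groups, so Σ_g f(g, s) ≤ 1 with equality exactly
when every bacterial group resolves; the residual is reported as the
"unassigned" fraction and the identity Σ fractions + unassigned = 1 holds to
machine precision (tested at 10⁻⁹). Missing LFQ cells contribute nothing to
either sum but still count as missing for the presence filter and
normalization. Fractions are invariant to per-sample rescaling of
intensities by construction. The same operation parameterized by rank
produces species-level tables.

For clustering, the protein-group LFQ matrix is restricted to entries
observed in at least ⌈n/2⌉ of the samples (11 of 22 under the default
design; the ceiling is the stricter reading of "minimum half" for odd n),
log2-transformed, and median-centered per sample. Before computing
sample–sample Pearson correlations the pipeline additionally centers each
protein row; otherwise the correlation is dominated by the shared abundance
profile (every sample is positively correlated with every other) rather
than by between-sample deviations, which is what distinguishes the groups.
Row centering is the standard practice for correlation-based expression
heatmaps and is applied in the orchestration layer, leaving the distance
primitive itself the plain pairwise-complete 1 − r.

## Community statistics

* **Differential genera.** Two-tailed two-sample *t*-test per genus on log2
  fractions, Student's pooled-variance variant by default (Welch via
  config). Zero fractions are treated as missing — no pseudo-count is
  fabricated — and a genus is tested only with ≥ 2 present values per
  group; untested genera are reported with NaN statistics. Adjustment
  across tested genera is Benjamini–Hochberg at α = 0.05; the volcano table
  carries log2 ratio, t, p, adjusted p, and a significance flag. When both
  groups have zero within-group variance the statistic is defined as 0
  (equal means) or ±∞ (unequal), avoiding NaN propagation from degenerate
  input.
* **Clustering.** Agglomerative clustering with average linkage (complete
  and single via config) on the Pearson distance; sample pairs sharing
  fewer than three present entries are flagged and imputed with the maximum
  observed distance. The distance matrix is put into a canonical sample
  order first, so the tree is invariant to input order up to label
  permutation. Flat groups come from a maxclust cut; the larger cluster is
  named G1.
* **Bray–Curtis.** Fractions are expressed as percentages, scaled by 10⁶
  and truncated (not rounded) to integers, then
  BC(i,j) = 1 − 2·Σ min / Σ total. All-zero samples have undefined
  dissimilarity and produce NaN rows rather than an arbitrary value.

## Dietary peptide discrimination

Tryptic digestion cleaves after K or R, by default not before P; the
`cleave_before_proline` option reproduces the common search-engine
convention that ignores the proline block, which is required for peptides
such as beta-lactoglobulin's PTPEGDLEILLQK (preceded by K–P) to appear as
fully tryptic. Peptides are enumerated for 0..max_missed missed cleavages
(default 2) with exact parent coordinates.

Species attribution respects deamidation chemistry: asparagine converts
spontaneously to aspartate (and glutamine to glutamate) as proteins age, so
an observed D may have started as N. Candidate species-unique peptides with
a deamidation-equivalent counterpart (position-wise identity under N≡D;
Q≡E optional and off by default, since the discriminating chemistry at
issue is N→D) in the other species' digest are moved to an "ambiguous"
class. Enabling awareness can only shrink the unique sets. The reporting
length window (7–30 residues, a typical LC–MS/MS detectability range) is
applied after the uniqueness logic so the logic itself stays
parameter-free.

The packaged reference FASTA contains the canonical mature bovine
beta-lactoglobulin (162 aa) and a **synthetic caprine homolog**: the bovine
scaffold carrying the four documented bovine/caprine diagnostic
substitutions (I1, H20, N64, K130 in mature coordinates). It is a
constructed stand-in for a curated goat entry, sufficient for exercising
and testing the discrimination logic: at zero missed cleavages in the 7–30
window it yields exactly three bovine-unique peptides (LIVTQTMK,
VAGTWYSLAMAASDISLLDAQSAPLR, TPEVDDEALEK), two caprine-unique ones, and the
PTPEG[D/N]LEILLQK pair as deamidation-ambiguous. Users analyzing real
samples should supply curated, signal-peptide-trimmed references; the tool
does not predict signal peptides.

## The synthetic-data generator

The generator produces the complete input shape with known latent truth. It
emulates:

* **Sample design.** 16 + 6 samples in two groups, matching the two-group
  structure that sample clustering defines in calculus cohorts of this
  kind.
* **Community composition.** Twelve genera with a dominant shared genus
  (*Actinomyces*) plus periodontitis-associated genera enriched in G1
  (Olsenella, Fretibacterium, Porphyromonas, Treponema, Tannerella,
  Desulfobulbus; log2 effects 1.2–1.5) and commensals enriched in G2
  (Lautropia, Neisseria, Streptococcus, Cardiobacterium, Leptotrichia;
  −1.2 to −1.5). Effects are applied symmetrically (±e/2) around base
  fractions, perturbed per sample by lognormal noise (σ = 0.20 in natural
  log, ≈ 20% CV — consistent with the within-group homogeneity such
  cohorts show), and renormalized; the renormalized values are the
  ground-truth fractions.
* **Protein layer.** 14 proteins per genus with lognormal within-genus
  weights, 40 human and 5 "other" proteins (archaeal and dietary
  lineages); per-sample protein LFQ is the genus share times a lognormal
  factor (σ = 0.5). A protein is observed in a sample with probability 0.8;
  observed entries get a razor+unique count of 2 + Poisson(2) (15% of the
  time a single peptide, exercising the mask) and lose their LFQ value
  completely at random at rate 0.08. The protein count (~213 groups) is a
  deliberate desk-scale reduction of a real calculus cohort (thousands of
  groups) — large enough that sample–sample correlations, which average
  over proteins, are stable, and small enough that a full pipeline run
  takes a fraction of a second.
* **PSM layer.** ~3 peptides per protein per sample at the observation
  rate; forward scores are Normal(80, 15); 10% of forward PSMs are false
  and draw their score from the decoy distribution Normal(35, 10); decoys
  are added to make up 10% of all rows so reverse hits estimate false
  forward hits roughly one-to-one. Only stochastic dominance of target
  over decoy scores matters to the FDR machinery; the normal shapes are a
  convenience.
* **Taxonomy.** Each genus gets a private lineage; 10% of bacterial
  accessions have lineages truncated at family, reproducing the ≈ 90%
  genus-assignment rate typical of oral-microbiome databases. A quarter of
  bacterial groups carry a same-genus sister accession so LCAs resolve at
  genus rather than species. Contaminant (keratin/collagen-style) and
  reverse-hit groups are included and must be filtered out downstream.

Everything is deterministic given the seed; same-seed runs are
byte-identical on disk.

What the generator does **not** emulate: sequence-level peptide sampling
from real proteomes (peptide strings are random), intensity-dependent
missingness (missingness is completely at random; an intensity-dependent
mechanism would make genus sums *harder* to recover and is left as a config
extension), shared peptides across genera (razor assignment is consumed as
given, not recomputed), chimeric spectra, or retention-time structure.
Passing recovery tests on this generator therefore demonstrates the
correctness of the post-processing logic under its stated assumptions, not
robustness to every pathology of real LC–MS/MS data.

## Evaluation studies and problem sizes

`metacalc.evaluation` runs recovery studies used by the acceptance checks:
FDR control over 20 replicate mixtures sized ≥ 1000 PSMs per stratum (the
human/other strata are scaled up for this study only, since under the
defaults — as in real calculus data — "other" is a small minority);
clustering recovery over 20 replicates (adjusted Rand index ≈ 1 under
default conditions, reported as the replicate mean); spiked-effect
detection over 50 replicates (each genus with |log2 effect| ≥ 1 must reach
BH-adjusted p ≤ 0.05 with the correct sign in ≥ 90% of replicates);
type-I error over ≥ 1000 genus tests from zero-effect simulations
(empirical rejection within two binomial standard errors of the nominal
0.05); and unit-sum conservation of fractions. These sizes keep the whole
acceptance run around a minute on one CPU while leaving the binomial
uncertainty of each rate well inside the asserted bounds.

## Known limitations

* Protein-level FDR, posterior error probabilities, and per-peptide
  q-values are out of scope; control is at the peptide list level.
* The LCA consumes a pre-built lineage table; it does not ingest taxonomy
  database dumps or resolve strain-level structure.
* Absolute quantitation (iBAQ-style) is not implemented; all abundances
  are relative within a sample.
* The clustering/statistics layer assumes two groups when cutting the tree
  by default (`stats.k_groups`); other designs require configuration.
* The packaged caprine reference is synthetic (see above); real species
  attribution should use curated references.
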