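# Methods

`coreprof` implements a core-gene-based taxonomic profiler for shotgun
metagenomes, a read-level functional profiler with parsimony pathway
inference, and the community statistics commonly applied downstream
(diversity, PERMANOVA, biomarker effect sizes, CLR association, repeated-CV
classification).  All components are validated end-to-end on synthetic
communities with known ground truth.

## Two-pass taxonomic profiler

**Reference model.**  Each species is represented by a panel of single-copy
core genes (92 by default) rather than a whole genome.  The summed panel
length `L_s` per species is stored; it is the normalization constant that
converts read counts into length-unbiased abundances.

**Pass 1 — k-mer screening.**  Every canonical 35-mer of every core gene is
indexed to the lowest common ancestor (LCA) of the species containing it.
Canonical means the lexicographic minimum of a k-mer and its reverse
complement; k-mers with non-ACGT symbols are skipped.  A read is classified
by root-to-leaf path scoring: the path maximizing the summed k-mer hit
weight wins, ties resolve to the lowest taxon id, and the assignment is the
deepest node on that path that actually received hits (so a read whose hits
all sit at a genus is assigned to the genus).  Per sample, species with at
least `min_reads` supporting reads (default 1; reads assigned to internal
nodes support all their descendant species) become *candidates*.  Screening
is deliberately recall-oriented — its false positives are removed later by
the coverage filter.

**Pass 2 — restricted mapping.**  A reference holding only the candidates'
core genes is built and reads are aligned end-to-end without gaps: exact
31 bp seeds are taken every `floor(L/4)` bp of the read (plus one flush with
the read end), seed hits are extended by full-read Hamming comparison on
both strands, and the best hit (fewest mismatches, ties to the lowest
taxon/gene/position) is kept if it has at most `max_mismatches`
substitutions (default 5 per 150 bp).  With seeds every `floor(L/4)` bp a
150 bp read has four disjoint seed windows, so any alignment with ≤3
mismatches is provably found; 4–5-mismatch alignments are found best-effort,
as in any seeded mapper.  One best alignment is counted per read —
multi-mapping inflation would break mixture recovery.

**Breadth filter and quantification.**  Per sample and species, breadth of
coverage is the fraction of positions of the concatenated core-gene panel
covered by at least one read (each position counted once regardless of
depth).  A species is quantified only if breadth ≥ 25% (inclusive); reads
mapped to filtered-out species are dropped, not reassigned.  Retained
species get three abundance layers: `raw_count` (reads), `normalized =
raw_count / L_s` (reads per bp of core genes, removing the bias by which a
species with a longer panel attracts proportionally more reads), and
`relative` (normalized, renormalized to sum to 1 per sample).

## Functional profiler

Reads are translated in all six frames (stops as `*`, ambiguous codons as
`X`) and scored against a reference of ortholog peptide sequences by shared
amino-acid 5-mers; the top-scoring ortholog is assigned, with score 0 or a
tie yielding no assignment (a "top hit" is undefined under ties, so the
conservative choice is made).  The deterministic k-mer score replaces
translated-search bit scores so the top-hit rule is exactly reproducible and
oracle-checkable.  Pathway presence is inferred by parsimony: the smallest
set of pathways whose member orthologs cover all observed, coverable
orthologs — solved exactly by branch-and-bound for maps of ≤20 pathways and
by greedy set cover beyond that, flagged in the result.  Pathway abundance
is the sum of member-ortholog read counts over the kept pathways; an
ortholog belonging to two kept pathways contributes to both.

## Community statistics

* **Chao1** richness, bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))` by
  default; the classic `S_obs + F1²/(2F2)` is available and falls back to
  the corrected form when no doubletons exist.
* **Shannon** diversity with natural logarithm by default (base switchable).
* **Bray-Curtis** dissimilarity `Σ|x−y| / Σ(x+y)`; an all-zero sample pair
  is defined as distance 0 with a warning.
* **PERMANOVA** with pseudo-F from among/within sums of squared distances
  and `p = (#{F_perm ≥ F_obs}+1)/(B+1)`; raw labels are permuted (the study
  design is unpaired two-group), permutations are vectorized and seeded.
* **CLR** transform `log(x+δ)` centered per sample; δ defaults to half the
  smallest nonzero value of the table and is only required when zeros are
  present.
* **Mann-Whitney U** per feature (normal approximation with tie correction;
  constant features get p = 1) with Benjamini-Hochberg step-up q-values.
* **Linear association**: per-feature OLS of one table on a paired
  predictor, t-test on the slope, BH across features; intended to be applied
  to CLR-transformed relative abundances.
* **Two-proportion summaries** for cohort tables: percentages to one
  decimal and a chi-square test with continuity correction (Fisher's exact
  test when a margin is zero).

## LDA effect size (biomarker discovery)

Two-class LEfSe-style path (the study design has no subclasses).  Features
with mean relative abundance below 0.01% across all samples are removed
("in the data" is read as the mean; a per-sample-max mode is available).
Survivors are screened by Kruskal-Wallis at α = 0.05.  For each of 30
bootstrap rounds, two-thirds of each group is subsampled, abundances are
rescaled to [0, 1e6], and a two-class LDA is fit jointly on the screened
features.  With `w` the unit-norm discriminant direction, feature *f*'s
effect in a round is `0.5·(|Δmean_f| + |w_f|·|Δprojection|)` — its raw
abundance shift averaged with its share of the discriminant separation, the
canonical LDA-effect-size combination.  The score is
`log10(max(effect, 1))` averaged over rounds; a feature is selected when its
KW p is below α *and* its score reaches the cutoff (default 2.0; the 1e6
rescaling is what places meaningful effects on the familiar 2–5 range).
The raw-mean term makes the score monotone in a planted fold change, which a
pure projection-share score is not once scores saturate.

## Classifier protocol

Stratified 5-fold cross-validation repeated 20 times (re-randomized folds
per repeat from spawned sub-seeds), a random-forest learner behind a
pluggable factory, ROC AUC per held-out fold — exactly `n_repeats × n_folds`
fold-AUCs — per-repeat means, their grand mean, and a percentile
(2.5/97.5) 95% CI over repeat means.  Two runs are compared by a two-sided
Mann-Whitney U test on repeat-level AUCs (the comparison test is a package
choice; identical inputs give p = 1).

## Synthetic data: what it emulates and what it does not

The generator produces (i) a balanced root/phylum/genus/species taxonomy;
(ii) homologous core genes: one random ancestor per gene mutated
independently along every taxonomy edge — rate `divergence` per site on
internal edges and `divergence/2` on terminal edges, so sibling species
differ at ≈`divergence` of sites (two independent processes at rate d/2
give expected pairwise difference `d − d²/3`) while cross-genus pairs are
more distant, and shared k-mers acquire genuine LCA structure; (iii)
single-end 150 bp reads drawn from species with probability proportional to
(proportion × panel length), uniform positions and strands, substitution
errors at a configurable rate, and GC-matched random decoys as an
off-target fraction, with per-read truth labels; (iv) two-group
compositional count tables: log-normal baseline means, per-sample gamma
noise with squared CV `dispersion` (default 0.5), multinomial counts at
depth 50,000, and fold-change effects planted in group B only — with all
folds at 1 the groups are exactly exchangeable, which the type-I-error
tests rely on.

Deliberately not modelled: paired-end inserts (the profiler is per-read),
indels (the mapper is ungapped), platform-specific error profiles, and
host-read contamination.  Passing tests therefore demonstrate correctness
of the algorithms and their calibration under the stated generative model,
not robustness to structural variants or indel-rich real data.

## Numerical and design choices

* k = 35 (screening), seed length 31, max 5 mismatches per 150 bp,
  coverage threshold 0.25 inclusive, candidate `min_reads` 1 — all exposed
  as configuration.
* All random processes take `numpy` `SeedSequence`-derived seeds; a single
  global seed fixes every output byte-for-byte (FASTQ included).
* Tie-breaks are everywhere deterministic (lowest taxon id / gene id /
  position; unassigned on exact ortholog-score ties).
* Degenerate inputs: empty read sets yield empty tables with a warning;
  samples with no species past the coverage filter yield an all-zero row
  with a warning; all-zero samples have Chao1 0 and undefined Shannon
  (error).
* Validation problem sizes were chosen at desk scale: 6-species databases
  with 92 genes of 500–1000 bp, communities of 3 species at
  [0.5, 0.3, 0.2], 100k reads for mixture recovery, 200–400 null
  simulations for calibration, and a 300-sample null cohort for classifier
  chance-level checks (smaller cohorts leave enough per-dataset spurious
  feature-label association for a random forest to stray from AUC 0.5).

## Known limitations

* The k-mer index is an uncompacted hash map (no minimizers); memory scales
  with total panel length, which is fine at desk scale and simplest to
  verify against brute force.
* The exact set-cover solver is exponential in the worst case and is
  therefore capped at 20 pathways; beyond that the greedy solution (within
  the usual ln n factor) is returned and flagged.
* Abundances are corrected for core-gene panel length only — no
  genome-size or copy-number correction, and no strain-level deconvolution.
* The LDA effect size reimplements the two-class path only (no subclass
  Wilcoxon stage, no one-against-all multi-class mode).
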