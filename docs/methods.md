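# Methods

`varbuf` re-implements, as a tested library, a population-transcriptomics
analysis: quantify how variable each gene's expression is across genetically
distinct individuals (after removing the mean-expression dependence), explain
that variation from genomically encoded regulatory features with random
forests, and test whether the same model transfers to predicting which genes
respond to perturbations (differential expression). Every stage is exercised
on synthetic data with known ground truth; this note records the models,
defaults and design choices.

## Expression variation

Counts are normalized with DESeq-style median-of-ratios size factors
(reference genes = nonzero in all samples; factors rescaled to geometric
mean 1, an arbitrary-scale convention). Per gene we compute the median
normalized count and the coefficient of variation CV = sd/mean (sample sd,
`ddof=1`; the denominator convention is not dictated by the statistic and is
documented here once).

Because CV falls with expression level, the variation measure is the
residual from a LOESS regression (degree 1, span 0.75) of log2 CV on log2
median expression (`resid_cv`). Both axes are logged for scale stability; a
`log_response=False` switch regresses raw CV instead. Duplicated abscissae
are averaged before the fit (deterministic tie handling), fitted values are
interpolated back per gene, and residuals are centered so the mean over the
analysed gene set is exactly zero (a constant shift; all downstream
rank/correlation/classification analyses are invariant to it). Alternatives
`resid_sd`, `resid_mad`, `resid_iqr` apply the same recipe to other spread
statistics. A variance-stabilized-sd alternative is deliberately not
implemented (it would depend on a particular external variance fit).

The filtering ladder runs in a fixed, asserted order: (1) zero median
(non-expressed); (2) top and bottom 5% by median at the focal timepoint
(`floor(pct*n)` genes each, ties broken by gene id for determinism); (3)
genes whose median falls from the early to the focal timepoint (maternal /
decaying transcripts); (4) genes with non-imputable missing features.
Residual variation is re-fit on the final retained set, so no residual
expression-level dependence survives filtering.

Robustness analyses: `subsample_stability` recomputes `resid_cv` from
scratch (renormalization + LOESS) on random sample subsets and reports the
Pearson correlation with the full-data values (mean ± sd per subset size);
`neighbor_pair_correlation` forms all same-contig gene pairs closer than
100 kb, bins them into five distance quantiles split by TAD co-membership
(TSS-based TAD assignment), and reports the Spearman correlation between
pair members per cell (cells under 10 pairs are undefined).

## Promoter architecture

Promoter shape is measured on TSS tag (CTSS-style) data. Tags are
optionally mapped onto a reference power law (slope -1.25, total 1e6, the
conventional CAGE normalization reference): the fitted log-log slope of the
reverse-cumulative count is reported, each tag count is replaced by the
reference-law count at its own reverse-cumulative rank (rank-preserving;
data already on the reference law are a fixed point), and normalized counts
below 5 are dropped. Tags are clustered by single-linkage chaining with a
20 bp maximum gap, separately per contig/strand/dataset; clusters below a
minimum signal (default 10, per-dataset override) are removed.

Two shape metrics: the shape index `SI = 2 + sum p_i log2 p_i` (2 minus the
Shannon entropy in bits; 2 for a single initiation position, `2 - log2 L`
for a uniform spread over L positions), and the 5-95% inter-percentile
width (first positions where the cumulative tag fraction reaches 0.05 and
0.95, inclusive; computed in ascending coordinate order, hence
strand-symmetric). Gene calls use clusters overlapping a core-promoter
window (default -300/+200 of the TSS): the fly route classifies by the
highest-signal cluster's SI (broad iff SI strictly below -1; an `alt_shape`
flag marks genes whose secondary clusters disagree); the human route
thresholds the per-tissue width and aggregates `mean_promoter_width` and
`percent_of_broad` over tissues with signal.

Width thresholds come from a two-component mixture fitted by EM (gamma on
`(width-1)/10`-transformed values, or Gaussian on shape indices), with five
restarts, tolerance 1e-6, and the log-likelihood asserted non-decreasing at
every step. The separation threshold is the crossing point of the
weight-scaled component densities, root-found strictly between the
component means; if the densities do not cross there the midpoint is used
with a warning. Gamma M-steps use weighted ML via Newton on the digamma
equation (Minka-style initialization).

## Feature assembly

Intervals are 0-based half-open internally; BED is read as-is; annotation
TSS columns are declared 1-based and converted on use. Overlap requires at
least one shared base. TSS windows mirror on the minus strand. The
proximal promoter window is ±500 bp of the TSS; the distal region is the
(500 bp, 10 kb] flanks on both sides with the proximal window subtracted
exactly (a disjoint partition). Open-chromatin condition summaries use a
19-condition vocabulary (whole-embryo at five timepoints, three sorted
tissues at four timepoints — the 12 "sorted" conditions whose joint
presence defines a ubiquitous DHS — plus two extras), and report condition
counts, early/late and tissue/whole-embryo profiles per region. TF peak and
motif features count distinct track labels with at least one overlap.
GC content excludes N bases from the denominator; the 3'UTR variant index
is `n_variants * mean(allele_freq) / utr_width`. Gene-context features
count neighbouring TSSs within ±1 kb and ±20 kb (self excluded) and record
TAD id, size and TSS-to-border distance (TSS-less genes outside TADs are
missing-coded). Assembly joins blocks on gene id, zero-fills imputable
presence/count features (absence genuinely means zero), drops and reports
genes missing anything else, and refuses duplicate feature names.

## Predictive modelling

Feature selection is a from-scratch Boruta: each run appends shadow
features (fresh independent column permutations of every active feature;
never fewer than five shadows, so the shadow-max reference keeps several
competitors even when few features remain), fits a bagged forest of
decision trees (100 per run by default; explicit bootstrap so out-of-bag
sets are known), and scores features by the Z-score (mean/sd over trees) of
out-of-bag permutation importance (MSE increase after permuting the column
within at most 256 OOB rows per tree — a speed cap that does not change the
across-tree averaging). A feature hits when its Z beats the best shadow;
cumulative hits are tested two-sidedly against Binomial(runs, 1/2) at
p = 0.01 with Bonferroni correction over features (switchable); rejected
features leave the forest; after `max_runs` (500) the undecided are
tentative, with a median-importance-vs-median-shadow-max resolution
recorded. Columns are canonically ordered and permutation streams are
derived from feature names, making decisions invariant to input column
order. Tentative features are excluded from downstream models.

Prediction uses random-forest regression (500 trees, mtry = sqrt(p),
minimum node size 5 — the regression defaults of the ranger implementation
this analysis style is built on) with fivefold cross-validation. The
headline metric is the pooled out-of-fold R^2; per-fold mean ± sd is also
reported (the pooling rule is a genuine free choice; both are emitted).
The permutation null repeats the full CV on once-permuted labels. Pooled
null R^2 is slightly negative by construction (out-of-fold prediction
variance on pure noise), about -0.02 at these problem sizes. Robustness
designs rerun the model per expression/shape/expression-change quantile bin
or train/test across chromosomes, always on the feature set selected on the
full data; bins under 50 genes are skipped.

## Stratification and statistics

Genes stratify into broad, narrow-low and narrow-high: broad straight from
the promoter call; narrow genes split at the median `resid_cv` of narrow
genes, ties (≤ median) to narrow-low. The broad regulatory index is the
normalized rank average (ranks 1..n, ties broken uniformly at random with a
seeded per-column stream, divided by n, averaged) of proximal DHS-condition,
TF-peak and TF-motif counts; the narrow index uses distal DHS count, miRNA
motif count and pausing index. rank/n normalization is used (the
alternative (rank-0.5)/n differs by a constant shift only).

Enrichment uses Fisher's exact test with the conditional-MLE odds ratio
(noncentral hypergeometric convention; the sample cross-product ratio is
also emitted) and Benjamini-Hochberg adjustment across the declared family.
Effect sizes are Cohen's d with the classical pooled SD and a two-sided
Wilcoxon rank (Mann-Whitney) p-value (exact below 50 per group, normal
approximation with continuity correction above). Association measures:
Spearman, Pearson, point-biserial (Pearson with 0/1 coding) and phi
(Pearson on two 0/1 vectors).

## Variation-to-DE transfer

Per study, DE genes (union over conditions) are compared with non-DE genes
by Cohen's d of `resid_cv`; the share of studies with d > 0.2 summarizes
the scan. The transfer protocol per round: hold out a random 50% of DE
genes plus an equal-size non-DE sample as the test set; from the remaining
genes (optionally narrow-promoter only) take the top and bottom 30% by
`resid_cv` as training classes; train a 500-tree random-forest classifier
on the selected features; score the test genes by P(high-variation) and
record the ROC AUC (rank-based, average ranks for ties) of DE vs non-DE.
Train/test disjointness is asserted every round; ten rounds are summarized
by the median AUC. Labels may be partial (NaN outside a labelled top/bottom
prior set), which covers the DE-prior variant of the protocol. Non-DE test
genes are sampled uniformly without replacement; no class weights are used
(training classes are balanced by construction).

## Synthetic data

The generator emulates the statistical structure of a population
expression study, with full ground truth:

* counts: NB with variance mu + alpha mu^2; gene means lognormal
  (meanlog 4.0, sdlog 1.5 — median ≈ 55 counts, a realistic 3'-tag-seq
  scale); log dispersion `ln alpha = a0 + a1 ln mu + r` with baseline
  (-0.5, -0.25), so the binned CV falls with expression as in real data;
  `r` (the true residual dispersion) is a centered sum of standardized
  causal-feature effects plus N(0, 0.25) noise;
* features: 10 causal (proximal DHS conditions/TF peaks/TF motifs, distal
  DHS count, miRNA motifs, pausing index, housekeeping flag and broad
  promoter with negative effects 0.15-0.30; TATA-box and 3'UTR variant
  index with positive effects) and 90 pure-noise decoys (9:1), chosen once
  as a regulatory-complexity-buffers-variation structure; interval-track
  features are materialized as condition-labelled BED intervals placed
  strictly inside each gene's windows (genes spaced 30 kb on five contigs,
  so placements never leak into a neighbour's windows and feature assembly
  recovers the emitted counts exactly);
* timepoints: 3; a `decay_frac` = 0.4 share of genes lose expression
  towards the focal stage (uniform 0.2-0.8 factor; maternal-like filter
  fodder) while the rest drift mildly upward (uniform 1.1-1.5, zygotic
  activation), so the decreasing-gene rule targets the decay class rather
  than median sampling noise; per-sample size factors lognormal(0, 0.1)
  make normalization non-trivial; batch effects are off by default (a
  stress knob, not a study condition);
* TSS tags: narrow genes concentrate tags on 1-5 adjacent positions
  (Dirichlet 0.8), broad genes (fraction 0.4) spread over 40-100 positions
  (Dirichlet 1.5, keeping entropy above the SI = -1 boundary); at least 50
  tags per promoter;
* DE labels: per study, P(DE) = logistic(gamma0 + gamma1 r) with default
  (-1, 2), independent across studies given r.

All randomness derives from one seed via named sub-streams (per operation
and per feature name), so stages regenerate independently and runs are
byte-identical. What the generator does *not* emulate: read-level noise,
sequences and motifs (GC and motif features are scalar inputs), genetic
variants, spatial autocorrelation along chromosomes, batch structure and
cross-study heterogeneity of DE calling. Passing tests therefore
demonstrate correctness and statistical behaviour of the *methods* under
the assumed generating model, not performance figures transferable to any
real dataset.

## Problem sizes and defaults used in verification

The test suite and `scripts/acceptance.py` run the full default design
(4,000 genes x 75 samples, 3 timepoints; about 2,000 genes survive the
ladder) for variation recovery, the DE scan and the transfer protocol;
Boruta recovery uses a 2,000-gene design with the measured `resid_cv` as
response. The Boruta all-noise specificity check runs 50 features at
n = 1,000 with the run cap at 100 (the algorithm's conventional default;
stopping earlier can only reduce confirmations, so the specificity bound is
conservative), and the repeated-seed variant in the unit suite further
trims trees per run — scaled-down settings chosen so the whole suite runs
on one CPU in a coffee break. The end-to-end pipeline default profile is
1,200 genes x 40 samples with a lighter Boruta (60 trees, 60 runs), enough
to exercise every stage deterministically.

## Known limitations

* LOESS is degree-1 local linear only (the analysis's setting); no degree-2.
* The human-route promoter pipeline is implemented and tested on synthetic
  tags, but no real CAGE atlas ships with the package.
* Boruta's sequential binomial testing peeks at every run (as in the
  original algorithm); its type-I behaviour is controlled empirically by
  the shadow-max reference and the Bonferroni correction, not by a formal
  sequential-testing bound.
* `de_count_strata` compares declared count bins; it does not model
  study-to-study dependence.
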