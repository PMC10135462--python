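# Methods

This note documents the statistical models behind each stage, the
parameters that matter, what the synthetic cohorts do and do not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer.

## Cohort model and the synthetic generator

The generator emulates a merged, normalised log2 microarray design:
features × samples, two groups (control/case), several batches.

* **Baseline**: per-gene constant ~ N(7, 1) log2 units (typical array
  intensity scale); i.i.d. Gaussian noise per cell, `noise_sd` (default
  0.6) log2 units.
* **Modules** are latent-factor blocks: gene = loading × eigenvector +
  noise, loadings ~ U(0.6, 1.0), factor ~ N(0, 1) per sample.  The
  factor is centred *within each group*, so an unshifted module carries
  exactly zero trait association — chance module–trait correlation is
  removed by construction, and the disease association of the first
  `n_disease_modules` (default 2) modules is injected explicitly as a
  case-group factor shift (`module_trait_shift`, default 0.8), giving
  module–trait correlations of roughly 0.3–0.5 at n = 44, the scale
  reported for disease modules in this literature.
* **Differential expression**: `de_count` genes (default 60) receive an
  explicit ±`effect_lfc` (default 1.5) case shift; the companion miRNA
  cohort gets `mirna_de_count` (default 30) features at ±2.5, safely
  above the miRNA calling threshold of |log2FC| > 2.  Half the DE
  miRNAs are down-regulated, since ceRNA triplets need a shared *down*
  miRNA.
* **ceRNA triplets** (default 10) are combinations drawn from small
  pools of up-DE mRNAs planted inside disease modules, down-DE miRNAs,
  and lncRNA identifiers.  lncRNAs have no expression matrix: they
  exist only in the interaction tables and the direction-validation
  table, mirroring designs where lncRNA partners are predicted and then
  validated by qRT-PCR.  The generated interaction tables hide the true
  edges among decoys (defaults: 200 miRNA→mRNA decoys; 100 decoys per
  lncRNA database, with a configurable shared fraction so the database
  intersection is informative).
* **Batch effects** are additive per-feature offsets ~ N(0, `batch_sd`)
  constant within a batch; batches are assigned round-robin within each
  group so batch is never confounded with group.
* **Immune sets**: five sets of 30 background genes; the first two have
  their members' case means raised by 1.0 log2 units.

Everything flows through one seeded `numpy.random.Generator`; equal
parameters and seed give byte-identical bundles.

What the generator does **not** emulate: probe-level effects,
missing values, heavy-tailed noise, correlated noise between
modules, mixed tissue composition, and a realistic transcriptome size
(see Limitations).  Passing tests therefore demonstrate correctness of
the inference machinery under a clean factor-model world, not
performance on real arrays.

## Preprocessing

Merging intersects feature symbols and concatenates samples; duplicate
feature ids collapse to the row with the highest mean (the standard
array convention when several probes map to one symbol).  Batch removal
fits, per feature, least squares on `[1, group, batch-dummies]` and
subtracts only the batch component; with balanced designs this
reproduces the planted offsets exactly and leaves the group contrast
untouched.  Batch perfectly confounded with group is an error, not a
silent partial fix.  Missing values are rejected at parse time; no
stage defines an imputation rule, so none is offered.  Inputs are
assumed already normalised to log2 scale.

## Differential expression

The moderated t follows the standard empirical-Bayes formulation: the
prior (d₀, s₀²) is moment-matched on log s²_g — with
z = log s² − digamma(d/2) + log(d/2), solve
trigamma(d₀/2) = var(z) − trigamma(d/2) by Newton inversion; a
non-positive right-hand side gives d₀ = ∞ (pure prior, normal-limit
p-values); `prior_df=0` recovers the ordinary pooled t exactly (tested
to 1e-10).  Zero-variance features are flagged `degenerate` with t =
±∞, p = 0.  Thresholds are strict inequalities; log2FC is always case
minus control.  By default DE runs on batch-corrected values
(configurable).

## Co-expression modules

Unsigned Pearson network, a_ij = |cor|^β.  The scale-free fit bins
connectivity into 10 equal-count bins and regresses log10 density on
log10 mean-k; signed R² is positive when the slope is negative.  β is
the smallest power reaching R² ≥ 0.85.  When no power qualifies —
common for factor-model data, whose degree distribution is not
scale-free and whose R² rises monotonically with β — two fallbacks
exist: the maximal-R² power (default, which on such data simply picks
the largest power tested and over-sparsifies the TOM), or the
conventional sample-size default for unsigned networks (9/8/7/6 for
< 20/30/40/≥40 samples), which the pipeline uses.

Module extraction clusters 1−TOM by average linkage.  A static height
cut is unreliable here: empirically the merge heights form a continuum
(module branches coalesce at 0.75–0.95, unstructured background genes
chain at 0.955–1.0), so any fixed quantile lands inside the background
band.  Instead, modules are **persistent branches**: a branch is born
when it first reaches `min_module_size` (50), survives absorptions of
sub-minimum pieces, and dies when it merges with another branch of at
least minimum size; branches persisting over at least
`min_persistence_frac` (5%) of the tree's total height range are kept,
greedily by persistence.  Genes a branch absorbed after birth are kept
only if their correlation with the branch-core eigengene reaches
`min_kme` (0.5) — the usual module-membership filter — so late
background stragglers return to grey.  A branch spanning every gene is
only reported if it, too, persists; an explicit `cut_height` argument
restores the plain static cut.  Eigengenes are unit-norm first
principal components of the standardised module expression, oriented
positively along the module mean profile; modules with eigengene
dissimilarity 1 − cor < 0.15 are merged iteratively, closest pair
first.  Labels follow the conventional colour order by size; grey is
unassigned.  Module–trait correlation encodes control = 0 / case = 1,
so positive r means disease-associated; p-values are raw (no
multiplicity correction across modules).

The gene dendrogram uses 1−TOM; Euclidean distance is used only for
sample outlier detection (average linkage, largest cluster kept).

## Diagnostic signature

The λ path solver is glmnet-style: IRLS outer loop, cyclic coordinate
descent with an active-set strategy on the weighted quadratic
subproblem, warm starts along a 50-point geometric λ grid from λ_max =
max|X'(y−ȳ)|/n.  λ is chosen by 10-fold CV deviance (λ_min by default;
a 1-SE rule is available).  Coefficients are reported on the original
scale; features are standardised internally.  KKT conditions at the
solution hold to 1e-6 (tested).  A numba-compiled kernel runs the
identical algorithm; the pure-Python solver remains as fallback and for
objective tracing.

The forest is bagged regression trees on the 0/1 response — regression
rather than classification so both conventional importances are
defined: %IncMSE is the mean percentage increase of a tree's out-of-bag
MSE after permuting one feature; IncNodePurity is the total impurity
decrease credited to the feature.  Trees use √p features per split and
`min_samples_leaf = 5` (the classic regression-forest node size; fully
grown trees bias the null permutation importance upward).  AUC is the
Mann–Whitney rank formulation with ties counted ½; cross-validation
refits the *entire* selection + forest pipeline inside each stratified
fold.  External cohorts are scored by a frozen model; missing signature
features raise an error naming them.

## ceRNA network

"Negatively correlated" mRNA–miRNA pairs are operationalised as
*opposite DE direction*: the mRNA and miRNA profiles come from separate
cohorts with disjoint samples, so sample-level correlation is
undefined; a Pearson mode exists for matched designs.  Only the
up-mRNA / down-miRNA / up-lncRNA polarity is assembled by default (the
polarity the ceRNA hypothesis predicts when lncRNAs rise); the mirrored
polarity sits behind a flag.  miRNA identifiers are canonicalised
("mir" infix → "miR", whitespace trimmed, arm suffixes preserved)
because prediction databases disagree on casing.  Degree is computed on
the full network; the hub subnetwork is induced afterwards, so a hub
miRNA can keep only lncRNA edges inside the subnetwork and drop out
entirely once its lncRNAs fail validation — which is exactly how a
15-node hub set can prune to 3 mRNAs + 5 miRNAs + 3 lncRNAs.  Ties at
rank k break lexicographically.

## Immune scoring

ssGSEA per sample: genes ranked by expression (average ties), the
in-set empirical distribution accumulates weights rank^α (α = 0.25),
out-of-set genes accumulate uniformly, and the score is the sum of the
running difference over the full list; scores are min–max normalised
across the matrix (both configurable).  Scores depend on ranks only, so
any strictly monotone per-sample transform leaves them unchanged.
Spearman ρ uses tie-corrected ranks with the t approximation on n−2 df
(exact permutation for n ≤ 10); Mann–Whitney U uses exact enumeration
when both groups have ≤ 8 observations and the tie-corrected normal
approximation with continuity correction otherwise, reporting min(U₁,U₂).

## Numerical and degenerate-input conventions

Variance-filter ties break by ascending feature id; hub ties by node
id; constant vectors yield r/ρ = 0 with a degenerate flag rather than
NaN; BH is the exact step-up, returned in input order; empty selections
and empty networks warn rather than raise wherever a downstream stage
can still proceed.

## Problem sizes

Default experiments run at 1000 genes × 44 samples (modules, DE,
end-to-end), 30 candidate genes × 44 samples (signature selection), and
10 planted triplets among 200 decoy edges (network recovery) — sizes at
which every documented recovery experiment completes in a few minutes
on one CPU while keeping the planted structures statistically
recoverable.

## Limitations

* **ssGSEA rank coupling at small transcriptomes.**  Because ssGSEA
  scores are functions of within-sample ranks over the whole matrix,
  raising one gene set in the case group mechanically depresses every
  other set's case scores.  In a 1000-gene synthetic universe, planting
  two 30-gene sets shifted by +1.0 displaces enough ranks that
  *unshifted* sets test significant (Mann–Whitney, n = 20/20) in
  roughly a fifth of replicates — a real property of rank-based scoring
  at this universe size (the scorer itself matches a brute-force oracle
  to 1e-12 and its type-I error on shift-free data is nominal).  On
  transcriptome-scale data (~20k genes) the displacement is
  negligible.  Specificity claims for the immune stage should therefore
  be read against universe size.
* The persistence-based branch selection cannot represent a module
  spanning *all* genes unless it persists as a branch; a matrix that is
  one giant module plus nothing else is reported grey.
* The generator's clean factor model understates real-data difficulty:
  no probe noise, no outlier samples by default, Gaussian tails.
* Blockwise processing for very large gene sets (> 20k) is not
  implemented; TOM is dense O(p²).
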