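# Methods

This note documents the models, default parameters, numerical choices and
known limitations of `taxodelim`.

## Completeness-corrected gene sharing (FSG)

For two genomes with observed gene-family counts N₁, N₂ (per genome) and
N₁₂ (shared), and completeness estimates C₁, C₂ ∈ (0, 1], the corrected
counts are N̂₁ = N₁/C₁, N̂₂ = N₂/C₂ and N̂₁₂ = N₁₂/(C₁C₂), and

    FSG = N̂₁₂ / (N̂₁ + N̂₂ − N̂₁₂).

Under independent binomial thinning of each genome at rate C (genes lost
from the assembly, not the organism), each corrected count is unbiased
for its true value, which is the rationale for the correction; the test
suite verifies the resulting FSG is unbiased for the true Jaccard to
Monte-Carlo precision. The ratio can leave [0, 1] when the correction
overshoots (nearly complete overlap at low completeness): values are
clamped into [0, 1], and a non-positive denominator — only possible
through overshoot — maps to 1 with a logged warning. Contamination is
deliberately not used in the correction; it acts only as a quality
filter. Genes are unordered presence/absence of families (a family in
both genomes counts once in N₁₂). Pairs are stored once under a
lexicographically sorted key.

When FSG values are compared *across* gene categories (forward
sensitivity), category size is a confounder: larger categories average
away more per-gene noise. `rarefy_categories` therefore drops categories
below a minimum size (default 100 families) and subsamples the survivors
without replacement to the smallest surviving size. The ALL category is
rebuilt as the union of the rarefied survivors, preserving the schema
invariant that ALL is a union rather than a sampled set.

## Quality filtering and species binning

Genomes with completeness < 0.80 or contamination > 0.05 are dropped
(boundary values kept, matching the strict-inequality exclusion).
Survivors are clustered by average-linkage agglomeration on distance
100 − ANI, cut at distance 5 (i.e. 95% ANI); a pair with no computable
ANI gets distance 100, since uncomputable ANI implies divergence well
beyond the species level. Average linkage is the conventional choice for
ANI dereplication; single linkage would chain adjacent species through
intermediates. Each bin is represented by its most complete member, ties
broken by lexicographic genome id for determinism.

## Rank classifiers

One binary classifier per rank (phylum … genus) predicts whether a
genome pair is ingroup (same taxon) or outgroup. Pairs where either
genome is unresolved at the rank are "unknown" and excluded from
training, validation and testing.

Protocol:

* at most 2,000,000 labeled pairs are used; ~10% are held out as a test
  set; from the remainder, `n_splits` independent train/validation
  splits are drawn, each validation set ~10% of the non-test data;
* each training set is balanced by rarefaction — both classes subsampled
  to min(class sizes, (cap − 1)/2) with cap = 20,000, keeping the total
  strictly below the cap;
* hyperparameters (L2 strength α, activation, hidden-layer layout) are
  selected on a deterministic grid; each grid point is scored by the
  mean validation balanced accuracy over the splits. The full grid is
  α ∈ {10⁻⁵…10} (7 values) × {identity, logistic, tanh} × 1-or-2 hidden
  layers with widths scaled to the predictor count p: {max(2, p), 2p,
  4p} for one layer and all ordered pairs for two. Ties keep the first
  point in grid order (α ascending, activations in declared order,
  fewer layers first);
* predictors are selected by a sequential plus-1-minus-1 search: add the
  best single predictor, then optionally remove the single predictor
  (never the one just added, which would oscillate) whose removal does
  not decrease the score; halt when the best addition gains ≤ 0.005
  balanced accuracy absolute. The 0.5% halting gain is read as absolute
  because balanced accuracy is already a fraction — a relative reading
  would almost always halt immediately at high accuracies;
* the model (a scikit-learn `MLPClassifier`, log-loss minimized with
  LBFGS) is refit on all non-test labeled pairs (balanced) for test
  evaluation, then on all labeled pairs for downstream prediction.
  Predictors are standardized to zero mean / unit variance on training
  statistics — identity/tanh units need comparable scales. The
  classification threshold is 0.5 on the predicted ingroup probability,
  matching the balanced training classes.

Two readings of the hyperparameter-scoring protocol are possible (an
internal k-fold cross-validation versus the independent train/validation
splits); the implementation scores each grid point on the independent
splits, which keeps every score an out-of-sample estimate under the same
balancing as training. The halting criterion compares against the
best-so-far score.

`SearchConfig.reduced()` (2 α values × tanh × 1 layer, 3 splits) is used
throughout the tests and the acceptance script: on the synthetic
communities the class signal saturates the full grid, which then only
adds runtime. The full grid remains the default for real data.

## Sensitivity analyses

Forward: each similarity metric is forced to be the sole predictor;
hyperparameters are re-selected from scratch; the same splits are reused
across metrics at a rank so that balanced accuracies are comparable
(split noise cancels from the ranking). FSG columns should be recomputed
on the rarefied schema first. Backward: each selected predictor of a
trained model is removed in turn, hyperparameters re-selected on the
remainder, and ΔB = B(full) − B(without) reported; ΔB near zero or
negative flags redundancy.

## Greedy clustering (GG / GGR)

Both algorithms consume only the affinity matrix of pairwise ingroup
probabilities (symmetric, diagonal 1) and a threshold σ ∈ [0, 1].

* GG: genomes are visited in decreasing order of affinity row-sum (ties
  by lexicographic id). Each genome joins the existing cluster with the
  highest mean affinity to its current members if that mean is ≥ σ,
  otherwise it founds a new cluster. Mean (not minimum) affinity is the
  joining statistic for robustness to single noisy pairs.
* GGR: GG followed by reassignment passes in the same visit order — each
  genome is removed from its cluster (the cluster dissolves if emptied)
  and rejoins the best cluster by the GG rule — until a pass changes
  nothing (or 100 passes). A GG fixed point is returned unchanged. At
  termination no genome strictly prefers another cluster under the
  joining rule; note that each reassignment improves the *moved
  genome's* mean affinity to its own cluster, which does not imply the
  unweighted average of per-cluster within-affinities improves.

The published description of these algorithms fixes their greedy
character, the affinity input, and the σ range but leaves the concrete
visit order, joining statistic and refinement schedule unspecified in
the main text; the rules above are this package's concrete
reconstruction, validated against hand-traced executions and exact block
recovery on block-constant matrices (within > σ > between). Every
clustering log notes this reconstruction caveat.

Affinity Propagation, DBSCAN and HDBSCAN are delegated to scikit-learn
with default parameters behind the same partition contract (affinity
consumed directly, or 1 − affinity as a precomputed distance); their
noise points become singletons.

In the affinity matrix, "final" mode sets pairs with a-priori known
status to exactly 1/0 and predicts only unknown pairs — the enumeration
should use all available information. "cv" mode predicts every pair de
novo so that cluster-count cross-validation measures the classifier +
clustering pipeline rather than echoing labels. Cross-validation samples
labeled subsets (default sizes 50/100/200, 20 rounds each), compares
predicted and true taxon counts, and scores each algorithm by
R² = 1 − SS_res/SS_tot about the mean true count (so a constant
predictor scores ≤ 0). The highest-R² algorithm wins; ties prefer GG,
then GGR, then baselines, smaller σ first.

## Incidence-based richness

From a binary taxon × survey matrix, Q_n counts taxa detected in exactly
n of m surveys; taxa never detected are excluded from S_obs. A taxon is
"detected" in a survey when at least one member genome originates from
it.

* Chao2: S_obs + ((m−1)/m) Q₁²/(2Q₂); when Q₂ = 0 the bias-corrected
  form S_obs + ((m−1)/m) Q₁(Q₁−1)/2 (flagged). The standard error uses
  the standard analytic variance of the estimator.
* iChao2: Chao2 + ((m−3)/(4m)) (Q₃/Q₄) max(Q₁ − ((m−3)/(2(m−1))) Q₂Q₃/Q₄, 0);
  Q₄ = 0 is continuity-substituted with 1 and flagged. The correction is
  non-negative, so iChao2 ≥ Chao2. Its standard error is a bootstrap
  over surveys (200 resamples by default) — no simple closed form is
  reproduced here.
* ICE (classic γ² variant): frequent/infrequent split at > 10
  detections; coverage Ĉ = 1 − Q₁/N_inf with N_inf = Σ_{k≤10} k Q_k;
  γ̂² = max((S_inf/Ĉ)(m_inf/(m_inf−1)) Σ k(k−1)Q_k / N_inf² − 1, 0) with
  m_inf the number of surveys holding ≥ 1 infrequent taxon;
  ICE = S_freq + S_inf/Ĉ + (Q₁/Ĉ) γ̂². Degenerate inputs: no infrequent
  taxa → S_obs; Ĉ = 0 (all infrequent taxa singletons) → bias-corrected
  Chao2 with a flag, keeping pipelines running on degenerate
  simulations.
* tWLRM: weighted least squares of y_n = log(Q_{n+1}/Q_n) on n, with
  weights 1/(1/Q_n + 1/Q_{n+1}) (inverse delta-method variance of a
  log-ratio of Poisson counts), requiring ≥ 3 consecutive nonzero counts
  from Q₁. Extrapolating the line to n = 0 gives the ratio Q₁/Q₀, hence
  Q̂₀ = Q₁/exp(ŷ(0)) and the estimate S_obs + Q̂₀. Exactly geometric
  counts (constant ratio ρ) give Q̂₀ = Q₁/ρ; flat counts give Q̂₀ = Q₁.
  The estimate is flagged if it falls below S_obs.
* breakaway is exposed only as an optional external-package adapter; its
  absence degrades gracefully and its mixture machinery is not
  re-implemented.

Accumulation curves average the number of taxa detected in n randomly
chosen surveys over 10,000 resamples (exact enumeration when the number
of subsets is smaller; the n = m endpoint is always exact). The slope
ratio r = (S(m) − S(m−1)) / (S(1) − S(0)) with S(0) = 0 uses the single
first segment as the initial slope.

## The synthetic community simulator

The simulator emulates the statistical structure the pipeline assumes,
with tractable expectations:

* **Taxonomy**: each phylum spawns 1 + Poisson(mean − 1) classes, and so
  on down to species, so every taxon has ≥ 1 child. Defaults: 5 phyla,
  mean 1.8 children per internal rank, mean 2.0 species per genus, mean
  3.0 genomes per species — about 350 genomes and 120 species, a size at
  which every stage runs in seconds to minutes on one CPU.
* **Divergence**: a pair whose most recent common taxon is at rank r has
  divergence d_r; defaults 0.03 (species), 0.15 (genus), 0.25 (family),
  0.35 (order), 0.45 (class), 0.60 (phylum), 0.75 (cross-phylum).
  AAI = 100(1 − d) + Normal(0, 2) clipped to [0, 100], putting
  same-species pairs near 97% and cross-phylum pairs near 25% — the
  qualitative decay real AAI shows. ANI is analogous (noise SD 1) but
  reported missing beyond genus-level divergence, emulating alignment
  failure; AAI below a floor (default 20%) is likewise dropped. Missing
  identities are imputed as 0 when the predictor table is built.
* **Gene content**: each of ten base gene pools (100–200 families, loss
  rates λ from 0.6 for translation-like housekeeping families to 2.5 for
  signal-transduction-like accessory families) evolves by independent
  per-gene loss on the tree at rate λ per unit divergence, no regain,
  starting from a full ancestral pool. Conditional on presence at the
  common ancestor, a pair at divergence d retains a gene jointly with
  probability e^(−λd), giving expected Jaccard q/(2 − q) with
  q = e^(−λd/2) — equal to e^(−λd) to first order in λd. Tests validate
  against brute-force simulation of this two-lineage process rather than
  the first-order approximation. Tier-A categories are unions of tier-B
  pools, mirroring a two-level functional hierarchy; ALL is the union of
  everything.
* **Observation**: true completeness C ~ Uniform(0.8, 1.0); each true
  gene is retained with probability C (binomial thinning — exactly the
  model the FSG correction assumes); contamination genes are drawn from
  outside the genome at a fraction ~ Uniform(0, 0.05) of the true count.
  Reported completeness equals true C by default; a reporting-noise
  option exists to stress the correction's bias properties.
* **Surveys**: species prevalence p ~ Lognormal(−1, 1) truncated to
  (0, 1] by rejection; detection in each of 12 surveys is independent
  Bernoulli(p). The lognormal creates the rare/frequent heterogeneity
  the richness estimators are designed for. A species with genomes is
  guaranteed ≥ 1 detection (its genomes had to come from somewhere), and
  genomes are placed uniformly among their species' detected surveys.
* **Label masking**: per rank, exactly round(fraction · n) genomes lose
  their label at that rank and everything below (defaults 0–20% rising
  toward species), reproducing the nested partial resolution of
  reference-based taxonomy assignment.

Everything derives from a single integer seed and is byte-identical
across reruns.

What the simulator does **not** emulate — and what passing tests
therefore do not show about real data: sequence-level artifacts (no
FASTA, no assembler chimerism), phylogenetic branch-length heterogeneity
(all congeneric pairs share one divergence), gene gain/horizontal
transfer, correlated gene loss, contamination from specific foreign
lineages, taxonomically biased label missingness, or survey effort
differences. The near-perfect synthetic accuracies (balanced accuracy
≈ 1.0 at genus level, clustering R² ≈ 1.0) reflect the clean separation
the simulator produces by construction; on real MAGs the same protocol
yields high but imperfect accuracies. The value of the synthetic runs is
end-to-end correctness and parameter recovery, not a performance claim.

## Problem sizes used in tests and the acceptance script

Module tests run on an ~80-genome community (3 phyla, mean 1.5 children);
end-to-end checks use the default ~350-genome community; clustering
cross-validation uses subset sizes 50/100/200 with 20 rounds; richness
coverage uses 50 replicate incidence matrices of 200 species × 100
surveys. The reduced hyperparameter grid is used throughout (see above).
These sizes are the package's chosen test conditions; the library itself
has no such limits, though the dense affinity matrix makes clustering
quadratic in genome count (tens of thousands of genomes require
cluster-scale memory).

## Known limitations

* The GG/GGR reconstruction (visit order, joining statistic, refinement
  schedule) cannot be verified against the original supplementary
  pseudocode from the main text alone.
* Single-predictor threshold extraction is provided via the fitted
  network but not validated against external threshold tables.
* tWLRM follows the transformation documented above; other published
  weightings of the regression exist.
* Richness standard errors (and thus the coverage checks) treat surveys
  as independent; spatially correlated surveys would understate
  uncertainty.
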