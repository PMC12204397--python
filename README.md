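# taxodelim

Delineating, enumerating, and counting prokaryotic taxa from
metagenome-assembled genomes (MAGs), using pairwise genome similarity
metrics instead of reference phylogenies.

Given a collection of MAGs with quality estimates, gene-family
annotations, and pairwise average amino-acid / nucleotide identities
(AAI / ANI), the package:

1. **filters and dereplicates**: drops genomes below 80% completeness or
   above 5% contamination, and collapses the rest into species-level
   genome bins at the conventional 95% ANI cut-off (average-linkage
   clustering), keeping the most complete genome per bin;
2. **computes completeness-corrected gene-sharing metrics**: for each
   genome pair and each functional gene category, the fraction of shared
   genes (FSG) — a Jaccard index of gene-family presence corrected for
   assembly incompleteness,

   FSG = N̂₁₂ / (N̂₁ + N̂₂ − N̂₁₂),  with N̂₁ = N₁/C₁, N̂₂ = N₂/C₂,
   N̂₁₂ = N₁₂/(C₁C₂),

   where N₁, N₂, N₁₂ are observed gene counts (first genome, second
   genome, both) and C₁, C₂ are the completeness estimates;
3. **trains one ingroup/outgroup classifier per taxonomic rank** (phylum
   to genus): a small multilayer perceptron predicting whether two
   genomes belong to the same taxon, with predictors chosen from
   {AAI, ANI, per-category FSGs} by a sequential plus-1-minus-1 search
   and hyperparameters by grid search, both scored by balanced accuracy
   B = 0.5 (P + N) on held-out validation splits (P, N = true-positive
   and true-negative rates);
4. **enumerates taxa de novo**: the classifier's pairwise ingroup
   probabilities form an affinity matrix that greedy clustering
   algorithms (GG — "greedy groups" — and its refined variant GGR, plus
   Affinity Propagation / DBSCAN / HDBSCAN baselines) partition into
   taxa; the algorithm is chosen by cluster-count cross-validation (R²
   of predicted vs. true taxon counts on labeled subsets);
5. **estimates global richness** from taxon incidence across surveys:
   frequency counts Q₁, Q₂, … (taxa seen in exactly n surveys) feed the
   Chao2, iChao2, ICE and tWLRM estimators, and taxon accumulation
   curves with their final/initial slope ratio r quantify how much
   diversity remains undiscovered.

A built-in simulator (`taxodelim.synthetic_data`) generates MAG
communities with a known taxonomy, divergence-driven gene loss and
identity decay, incomplete contaminated assemblies, and lognormal
species prevalence across surveys — so every stage of the pipeline can
be exercised and validated offline against ground truth.

## Worked example

Simulate a community, then run the full pipeline at genus level:

```bash
taxodelim simulate --outdir sim --seed 1
# wrote 9 tables to sim (362 genomes, 123 species)
```

```python
import taxodelim as td
from taxodelim.classifier import SearchConfig, label_pairs, train_rank_classifier
from taxodelim.clustering import crossvalidate_algorithms, enumerate_taxa

community = td.simulate_community(td.SimulationConfig(seed=1))
metrics = td.build_pair_metrics(community.records, community.schema,
                                community.aai_table, community.ani_table)
pairs = label_pairs(community.records, "genus", metrics)
model, report, _ = train_rank_classifier(pairs, SearchConfig.reduced(seed=1))
print(report.balanced)                  # 1.0  (test balanced accuracy)

cv, selected = crossvalidate_algorithms(community.records, pairs, model, seed=1)
print(selected.label())                 # gg(sigma=0.5)
print(max(r.r_squared for r in cv))     # 1.0

partition, n = enumerate_taxa(community.records, pairs, model, selected)
true = len({lin["genus"] for lin in community.true_taxonomy.values()})
print(n, true)                          # 61 61
```

The genus classifier separates ingroup from outgroup pairs perfectly on
this synthetic community (test balanced accuracy 1.0), the greedy
clustering reproduces true taxon counts across cross-validation subsets
(R² = 1.0), and de novo enumeration recovers the simulated 61 genera
exactly. On the enumerated genera, the incidence-based estimators
extrapolate total richness beyond the 61 observed (Chao2 66.3, iChao2
67.6, ICE 70.2, tWLRM 75.1 for this seed), and the accumulation curve's
slope ratio r ≈ 7.3% says that about 7% of genera detected in one
additional survey would be new.

## Layout

| module | contents |
| --- | --- |
| `synthetic_data` | community simulator (taxonomy, gene loss, identities, surveys, label masking) |
| `metrics` | FSG, pair-metric table assembly, category rarefaction |
| `quality_binning` | quality filter, ANI species binning, representatives |
| `classifier` | splits, balancing, grid search, plus-1-minus-1 selection, evaluation |
| `sensitivity` | forward (single-metric) and backward (leave-one-out) analyses |
| `clustering` | affinity matrices, GG/GGR, delegated baselines, cluster-count CV |
| `richness` | incidence counts, Chao2/iChao2/ICE/tWLRM, accumulation curves |
| `io` / `pipeline` / `cli` | TSV formats, orchestration, `taxodelim` command |
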