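# sparseae

Sparse-autoencoder marker discovery for breast cancer subtypes: select
small, subtype-discriminative gene panels from bulk RNA-seq expression
matrices, validate them with a class-weighted random forest, and organize
them into interaction-network modules.

## Who this is for

Computational biologists working with FPKM-like expression matrices over
clinically labeled tumor cohorts — in particular the four hormone-receptor
defined breast cancer subtypes: luminal A (ER+/PR+/HER2−), luminal B
(ER+, HER2±), HER2-enriched (ER−/HER2+) and triple-negative
(ER−/PR−/HER2−). The same machinery applies to any multi-class expression
dataset with non-negative values.

## The method

For each subtype, a shallow autoencoder is trained to reconstruct that
class's samples through a narrow bottleneck:

    f(X) = σ₁(X W⁽¹⁾),   X̂ = σ₂(f(X) W⁽²⁾),   σ₁ = σ₂ = ReLU

with X ∈ ℝ^{n_v×d} min-max scaled per gene to [0, 1], W⁽¹⁾ ∈ ℝ^{d×h},
W⁽²⁾ ∈ ℝ^{h×d}, and no bias terms. Training minimizes the row-sparsity
regularized reconstruction objective

    J(Θ) = 1/(2 n_v) ‖X − X̂‖²_F + λ ‖W⁽¹⁾‖₂,₁,
    ‖W⁽¹⁾‖₂,₁ = Σᵢ ‖wᵢ‖₂

by mini-batch Adam (batch 64), keeping the weights of the best
validation-loss epoch. Penalizing the ℓ2,1 norm drives whole encoder rows
toward zero, so the surviving row norms sᵢ = ‖wᵢ‖₂ score how much gene i
feeds the latent representation; the top-k genes (k = 3000 at cohort
scale) are that run's candidate set.

Because single runs are stochastic, candidates are stabilized by a
replicate-and-intersect protocol: the autoencoder is run 30 times from one
seeded generator and the 30 top-k sets are intersected; the whole block is
repeated for 16 independent seeds and the per-seed intersections are
intersected again. Genes surviving every intersection are the subtype's
markers.

Markers are validated two ways:

- **Classification.** A random forest (1000 trees, grid-searched with
  stratified 10-fold CV) is trained on the union of the four marker sets
  with class weights w_v = n/(k·n_v) compensating class imbalance via the
  weighted Gini impurity G_u = 1 − Σ_v w_v p²_{u,v}; performance is
  reported as accuracy, support-weighted precision/recall/F1, and
  one-vs-rest ROC/AUC per class.
- **Network modules.** The markers' STRING-style interaction subgraph
  (combined score > 0.7) is partitioned by Markov clustering
  (inflation 2.5) into candidate functional modules.

A synthetic-data module generates multi-subtype matrices with planted,
co-expressed marker programs, zero-inflation and outlier genes, so the
whole chain is testable without downloads.

## Worked example

Synthetic cohort at the default conditions (130 samples in 4 imbalanced
classes, 500 genes, 50 planted markers per class), full pipeline with a
desk-scale consensus (3 seeds × 5 runs, top-200 per run) and a 100-tree
forest:

```python
import sparseae as sa
from sparseae.pipeline import synthetic_train_config

X, labels, truth = sa.simulate(sa.SimConfig(seed=1))
result = sa.marker_discovery_pipeline(
    X, labels,
    synthetic_train_config(),
    sa.ConsensusConfig(runs_per_seed=5, n_seeds=3, k=200, master_seed=1),
    rf_config=sa.RFConfig(n_trees=100, grid=None, seed=0),
    split_seed=0,
)
print("genes after filtering:", result.stage_info["genes_after_outlier_filter"])
print("marker counts:", result.stage_info["marker_counts"])
print("test accuracy: %.3f" % result.report.accuracy)
print("weighted AUC : %.3f" % result.report.weighted_auc)
```

prints

```
genes after filtering: 473
marker counts: {'HER2-enriched': 89, 'LuminalA': 56, 'LuminalB': 61, 'TNBC': 71}
test accuracy: 0.962
weighted AUC : 1.000
```

Reading: the zero/outlier filters drop 27 of 500 genes (including the 10
planted outliers); each subtype's consensus keeps 56–89 genes; the
class-weighted forest trained on their union classifies the 26 held-out
samples with 96% accuracy and near-perfect one-vs-rest AUCs — the planted
subtype programs are recovered well enough to separate the classes.

The same stages are available as a CLI:

```bash
sparseae simulate --seed 1 --out sim/
sparseae preprocess --expr sim/expr.tsv --meta sim/labels.tsv --out prep/
sparseae consensus --expr prep/tnbc.tsv --runs 5 --seeds 3 --top-k 200 \
    --hidden 16 --lam 1e-2 --epochs 800 --lr 1e-2 --master-seed 1 \
    --out markers_tnbc.tsv
sparseae classify --expr sim/expr.tsv --labels sim/labels.tsv \
    --markers markers_tnbc.tsv ... --trees 100 --no-grid --out report/
sparseae modules --edges string_edges.tsv --markers markers_tnbc.tsv \
    --out modules.tsv
```

All commands are byte-deterministic under their seeds.

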