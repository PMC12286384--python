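# Methods

## Preprocessing

Raw input is a non-negative FPKM-like matrix (samples × genes) plus
per-sample hormone-receptor status (ER/PR/HER2) or precomputed subtype
labels. The chain is:

1. **Zero filter.** Drop genes zero in strictly more than 75% of samples
   (a gene at exactly 75% is kept).
2. **Outlier filter.** Summarize each gene by its mean expression; compute
   the mean μ and *population* standard deviation σ of those per-gene
   means; drop genes strictly outside [μ − σ, μ + σ]. The axis (per-gene
   means) and SD convention are implementation decisions — the natural
   reading that actually removes genes and is deterministic; σ = 0 removes
   nothing and warns. The order is fixed (zero filter first) and the two
   filters do not commute.
3. **Subtype assignment.** (ER−,PR−,HER2−)→TNBC; (ER−,HER2+)→HER2-enriched
   (PR ignored); (ER+,PR+,HER2−)→luminal A; (ER+,HER2+)→luminal B (any
   PR). ER+/PR−/HER2− is mapped to luminal B: the luminal B receptor
   definition ("some PR+") overlaps luminal A's, and we resolve the
   overlap by requiring PR+ explicitly for luminal A. Any pattern needing
   an unknown field is left unassigned. An override table can remap any
   explicit triple.
4. **Scaling.** Per-gene min-max to [0, 1], fit on training data only and
   applied unchanged to held-out data (values may leave [0, 1]; they are
   not clipped). Constant genes map to 0.
5. **Split.** Stratified 80/20: per class, ⌊0.8·n_v⌋ training samples with
   leftovers by largest fractional remainder, at least one sample per
   class on each side, deterministic under a seed.

## Autoencoder and feature scores

Two fully connected layers, ReLU on both, **no biases** (a config flag can
enable them; default off, matching the all-matrix-product formulation).
The objective is mean reconstruction error plus a row-sparsity penalty on
the encoder:

J = 1/(2m)‖X − X̂‖²_F + λ·P(W⁽¹⁾)

with P either the ℓ2,1 norm (sum of row ℓ2 norms; the default) or the
plain sum of squares. The two penalties give different objective values
but identical feature *rankings*, since the score is the row ℓ2 norm
either way; both forms are exposed because the regularizer is sometimes
written without the square root.

Training: mini-batch Adam (step 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7 by
default), batch 64, an internal 80/20 validation split per class matrix,
and best-validation-epoch checkpointing (earliest epoch on ties). The
ReLU subgradient at exactly 0 is taken as 0. Analytic gradients are
verified against central finite differences to ~1e-9 relative error in
the test suite. All randomness flows through one numpy Generator, so a
run is bitwise reproducible; replicate runs share a single advancing
generator (see below).

Reference-scale defaults mirror the cohort workflow: bottleneck h = 500,
35 epochs, per-subtype λ of 1e-5 (TNBC), 1e-4 (HER2-enriched), 1e-6
(luminals). At the synthetic scale (d = 500, 15–60 samples per class, one
batch per epoch) the same *amount* of optimization requires a wider step
and more epochs; `synthetic_train_config()` freezes h = 16, λ = 1e-2,
step 1e-2, 800 epochs, chosen once by pilot calibration on the default
synthetic conditions.

Known numerical property: with no biases and ReLU on both layers, a tiny
instance can initialize with most hidden units (or output coordinates)
permanently inactive — positive data never revives a unit whose
pre-activation is negative for every sample. At realistic widths this is
benign; unit tests that assert optimizer progress on tiny instances pin a
seed with enough live units.

## Stability selection

One seed block = seed the generator once, then run train → score → top-k
`runs_per_seed` times *without reseeding* (runs differ through the
advancing generator state — under the alternative reading, reseeding
every run, all runs would be identical and their intersection
uninformative). Blocks for `n_seeds` distinct seeds (derived
deterministically from a master seed, all below 2³¹, overridable) are
intersected per block and then across blocks. The final set is ordered by
mean score over all contributing runs. An empty consensus is a warning,
not an error. Consensus size is non-increasing in both the number of runs
and the number of seeds by construction.

## Class-weighted random forest

Class weights w_v = n/(k·n_v) (so Σ_v w_v n_v = n exactly). The weighted
Gini impurity used in tree growing is

G_u = 1 − Σ_v w_v p²_{u,v}

which reduces to the ordinary impurity at unit weights. Note this form
places the weight *outside* the squared proportion, whereas standard
class-weighted CART reweights the proportions themselves; the two differ
whenever weights ≠ 1. The default forest is scikit-learn's
RandomForestClassifier with these class weights (mature, fast, the
standard weighting); the literal formula above is implemented in a
bundled small tree/forest grower (`impurity="literal"`) and unit-tested,
intended for small problems and for studying the criterion itself.
Hyperparameters are grid-searched (max depth {None, 10, 20}, features per
split {sqrt, log2}, min samples per leaf {1, 5} by default) with
stratified 10-fold CV, folds reduced with a warning if the smallest class
is smaller.

Evaluation: accuracy; support-weighted precision/recall/F1; per-class
one-vs-rest ROC with trapezoidal AUC (equal to the Mann–Whitney
statistic, asserted in tests); the weighted-average AUC uses test-set
class support as weights. A class absent from the test set has no defined
ROC and is excluded from the average with a warning.

## Network modules

The interaction graph is the marker-induced subgraph of a STRING-style
edge list; 0–1000 integer scores are rescaled by 1/1000; edges with
confidence ≤ 0.7 are dropped (strictly-greater retained); duplicate edges
keep the maximum score; self-loops are removed. MCL then adds self-loops
of weight 1 (standard practice, guarantees convergence), column-normalizes,
and alternates expansion (matrix square) with inflation (elementwise power
2.5, column renormalization), pruning entries below 1e-5, until the
matrix changes by less than 1e-6 or 100 iterations (non-convergence
returns the current partition with a warning). Clusters are read off
attractor systems; every node joins the system holding most of its column
mass, ties to the lowest node id. Modules with more than two genes are
the reporting convention. Merging modules into "super-modules" by shared
functional profiles is curation work and out of computational scope.

## Synthetic data

The generator emulates an FPKM matrix: per-gene log-normal baselines
(meanlog ~ N(1, 0.8²) across genes, within-gene noise sd 0.35 on the log
scale), Bernoulli zero-inflation (5%), four imbalanced classes
(30/15/60/25 — luminal A largest, HER2-enriched smallest), and 10 outlier
genes pinned at a fixed inflated level (meanlog 4) so "designed outlier"
is unambiguous and the outlier filter removes exactly them.

Each class owns 50 planted markers sharing a per-sample *program
activity* a_s = Bernoulli(p)/p + N(0, 0.12) with p = 0.92; markers are
multiplied by exp(effect·a_s) in their class only, so the mean log-shift
equals `effect_size` and the markers are co-expressed and bimodal across
patients (ON in 92% of the class), the way amplification- and
proliferation-driven programs behave in tumor cohorts. Two properties
drove this design: (a) a *constant* multiplicative shift is nearly
invisible after per-gene min-max scaling (the gene's own boosted samples
set its max), so recovery would be ill-posed; and (b) heavy-tailed
continuous activity is strongly compressed by the per-gene max, whereas
bounded bimodal activity survives scaling. Under the defaults a
brute-force variance/PCA-loading oracle recovers 49–50 of 50 planted
markers per class, i.e. the recovery task is well-posed, and the Bayes
accuracy of the 4-class problem is well above 0.9 (program-OFF samples
carry no class signal, which is why p is high). At `effect_size = 0`
markers are exactly identically distributed with background genes.

What the generator does *not* emulate: gene–gene correlation outside the
planted programs, library-size variation, batch effects, count noise at
low expression, or any quantitative match to a real cohort's gene-level
statistics. Passing tests therefore demonstrate the machinery and its
contracts, not performance on real tumors.

## Limitations of encoder-norm feature scoring at small scale

An extensive feasibility study during development showed that the
encoder-row-norm score is a much weaker marker detector than a variance
oracle at desk scale (d = 500, 15–60 samples, h = 16): the ℓ2,1 cost of
*sensing* a shared program is identical for any subset of its genes (a
flat valley), and nothing penalizes the decoder, which can absorb scale —
so long training makes the allocation of encoder mass among co-expressed
markers arbitrary and unstable across runs. Single runs place roughly a
third to two thirds of the planted markers in their top-k; the strict
15-run intersection at a tight k is therefore close to empty, and the
planted-recovery test that demands consensus precision and recall ≥ 0.8
at top-60 fails honestly. With a looser per-run cut (top-200, i.e.
top-40%, analogous to the reference top-3000 of ~29k), the consensus
retains enough true markers that the end-to-end pipeline classifies the
synthetic subtypes with ≥ 0.9 test accuracy. At the reference scale the
init-noise spread of row norms is ~3% (1/√(2h) with h = 500) instead of
18%, which is substantially more favorable to the protocol; we make no
claim either way about recovery rates on real cohorts.
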