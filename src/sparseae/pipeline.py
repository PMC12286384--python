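"""End-to-end orchestration: preprocessing -> per-subtype consensus markers
-> class-weighted random-forest validation.

This is the programmatic equivalent of chaining the CLI stages. The min-max
scaler is fit on the training split only and applied unchanged to the test
split; each subtype's autoencoder sees only that subtype's scaled training
samples; the random forest is trained on the union of the four marker sets
and evaluated on the untouched test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .autoencoder import DEFAULT_LAMBDA, MarkerSet, TrainConfig
from .classify import (
    ClassWeights,
    EvalReport,
    RFConfig,
    class_weights,
    evaluate,
    fit_rf,
    marker_matrix,
)
from .preprocess import (
    ExpressionMatrix,
    SubtypeLabelSet,
    apply_minmax,
    filter_zero_genes,
    fit_minmax,
    remove_outlier_genes,
    stratified_split,
)
from .stability import ConsensusConfig, ConsensusResult, consensus_markers

#: Regularization strength used for the synthetic default conditions
#: (selected once by pilot calibration on the synthetic default data).
DEFAULT_SYNTH_LAMBDA = 1e-2


def synthetic_train_config(seed: int = 0, lam: float = DEFAULT_SYNTH_LAMBDA) -> TrainConfig:
    """Training settings scaled to the synthetic default conditions.

    The reference workflow's settings (h=500, 35 epochs at step 1e-3, batch
    64) are sized for ~29k genes and hundreds of samples; at the synthetic
    scale (500 genes, 15-60 samples per class, one batch per epoch) the
    equivalent amount of optimization needs a wider step and more epochs,
    and a bottleneck well below the sample count.
    """
    return TrainConfig(
        h=16, lam=lam, epochs=800, learning_rate=1e-2, batch_size=64, seed=seed
    )


@dataclass
class PipelineResult:
    markers: dict[str, MarkerSet]
    funnels: dict[str, dict]
    report: EvalReport
    weights: ClassWeights
    feature_space: list[str]
    stage_info: dict = field(default_factory=dict)


def marker_discovery_pipeline(
    X: ExpressionMatrix,
    labels: SubtypeLabelSet,
    train_config: TrainConfig,
    consensus_config: ConsensusConfig,
    rf_config: RFConfig | None = None,
    lam: float | Mapping[str, float] | None = None,
    max_zero_fraction: float = 0.75,
    outlier_sd: float = 1.0,
    train_fraction: float = 0.8,
    split_seed: int = 0,
) -> PipelineResult:
    """Run the whole marker-discovery and validation chain.

    ``lam`` overrides ``train_config.lam``: a scalar applies to every
    subtype, a mapping gives per-subtype values (missing subtypes fall back
    to the reference per-subtype defaults).
    """
    X1 = filter_zero_genes(X, max_zero_fraction)
    X2 = remove_outlier_genes(X1, outlier_sd)
    assigned = set(labels.assigned_sample_ids())
    X2 = X2.subset_samples([s for s in X2.sample_ids if s in assigned])

    split = stratified_split(X2, labels.subset(X2.sample_ids), train_fraction, split_seed)
    scaler = fit_minmax(split.x_train)
    x_train = apply_minmax(split.x_train, scaler)
    x_test = apply_minmax(split.x_test, scaler)

    markers: dict[str, MarkerSet] = {}
    funnels: dict[str, dict] = {}
    for subtype in sorted(split.y_train.class_counts):
        members = split.y_train.samples_of(subtype)
        class_x = x_train.subset_samples(members)
        if lam is None:
            sub_lam = train_config.lam
        elif isinstance(lam, Mapping):
            sub_lam = lam.get(subtype, DEFAULT_LAMBDA.get(subtype, train_config.lam))
        else:
            sub_lam = float(lam)
        cfg = replace(train_config, lam=sub_lam)
        result: ConsensusResult = consensus_markers(
            class_x.values, class_x.gene_ids, cfg, consensus_config, subtype=subtype
        )
        markers[subtype] = result.markers
        funnels[subtype] = result.funnel

    nonempty = [m for m in markers.values() if len(m)]
    if not nonempty:
        raise RuntimeError("every subtype produced an empty consensus marker set")
    x_train_m = marker_matrix(x_train, nonempty)
    x_test_m = x_test.subset_genes(x_train_m.gene_ids)

    weights = class_weights(split.y_train)
    clf = fit_rf(x_train_m, split.y_train, rf_config, weights)
    report = evaluate(clf, x_test_m, split.y_test)

    return PipelineResult(
        markers,
        funnels,
        report,
        weights,
        list(x_train_m.gene_ids),
        stage_info={
            "genes_input": X.d,
            "genes_after_zero_filter": X1.d,
            "genes_after_outlier_filter": X2.d,
            "n_train": split.x_train.n,
            "n_test": split.x_test.n,
            "marker_counts": {k: len(v) for k, v in markers.items()},
        },
    )
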