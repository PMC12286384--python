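"""Synthetic multi-subtype expression matrices with planted markers.

The generator emulates an FPKM-like bulk expression matrix: per-gene
log-normal baselines (heavy-tailed, non-negative), Bernoulli zero-inflation,
a handful of outlier genes with strongly inflated means (to exercise the
outlier filter), and four imbalanced classes. Each class owns a set of
planted marker genes that are multiplicatively up-shifted in that class
only: sample ``s`` of class ``v`` multiplies its markers by
``exp(effect_size * a_s)`` where the per-sample program activity

    a_s = Bernoulli(program_active_prob) / program_active_prob
          + Normal(0, activity_sd)

is shared by all markers of the class. ``E[a_s] = 1``, so the mean log-shift
is exactly ``effect_size``, and the markers of a class are co-expressed -
the structure a bottleneck autoencoder can latch onto, and the structure
real subtype programs exhibit. Activity is bimodal across patients (ON in
``program_active_prob`` of the class), the way amplification- and
proliferation-driven programs behave in tumor cohorts; bounded bimodal
activity also survives per-gene min-max scaling, which strongly compresses
heavy-tailed continuous shifts (the gene's own extreme draws set its max).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import SUBTYPES, ExpressionMatrix, SubtypeLabelSet

#: Default class sizes; imbalanced in the proportions typical of receptor-
#: defined breast-cancer cohorts (luminal A largest, HER2-enriched smallest).
DEFAULT_N_PER_CLASS = {
    "TNBC": 30,
    "HER2-enriched": 15,
    "LuminalA": 60,
    "LuminalB": 25,
}


@dataclass
class SimConfig:
    """Generator settings; defaults define the standard study conditions."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_CLASS)
    )
    d: int = 500
    m_per_class: int = 50
    effect_size: float = 1.0
    base_log_mean: float = 1.0
    base_log_sd: float = 0.8  # spread of per-gene baselines (across genes)
    noise_log_sd: float = 0.35  # within-gene sample-to-sample spread
    program_active_prob: float = 0.92  # fraction of the class with the program ON
    activity_sd: float = 0.12  # log-jitter of program activity
    zero_inflation_prob: float | np.ndarray = 0.05
    n_outlier_genes: int = 10
    outlier_log_shift: float = 3.0
    shared_marker_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        classes = set(self.n_per_class)
        if not classes <= set(SUBTYPES):
            raise ValueError(f"unknown classes {classes - set(SUBTYPES)}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 < self.program_active_prob <= 1.0):
            raise ValueError("program_active_prob must be in (0, 1]")
        if not (0.0 <= self.shared_marker_fraction <= 1.0):
            raise ValueError("shared_marker_fraction must be in [0, 1]")
        p = np.asarray(self.zero_inflation_prob, dtype=float)
        if (p < 0).any() or (p > 1).any():
            raise ValueError("zero_inflation_prob must lie in [0, 1]")
        needed = self._n_marker_genes() + self.n_outlier_genes
        if needed > self.d:
            raise ValueError(
                f"need {needed} marker+outlier genes but only d={self.d} genes"
            )

    def _n_marker_genes(self) -> int:
        n_classes = len(self.n_per_class)
        shared = int(round(self.shared_marker_fraction * self.m_per_class))
        return shared + n_classes * (self.m_per_class - shared)


@dataclass
class SimTruth:
    """Ground truth of the generated matrix."""

    markers: dict[str, list[str]]
    outlier_genes: list[str]
    config: SimConfig


def simulate(
    config: SimConfig | None = None,
) -> tuple[ExpressionMatrix, SubtypeLabelSet, SimTruth]:
    """Generate (expression, labels, truth); bitwise-deterministic under
    ``config.seed``."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    d = config.d
    classes = [c for c in SUBTYPES if c in config.n_per_class]
    gene_ids = [f"g{i:04d}" for i in range(d)]

    # Assign roles: shared markers, class-exclusive markers, outliers.
    shared_n = int(round(config.shared_marker_fraction * config.m_per_class))
    excl_n = config.m_per_class - shared_n
    pool = rng.permutation(d)
    cursor = 0
    shared_idx = pool[cursor : cursor + shared_n]
    cursor += shared_n
    marker_idx: dict[str, np.ndarray] = {}
    for c in classes:
        own = pool[cursor : cursor + excl_n]
        cursor += excl_n
        marker_idx[c] = np.sort(np.concatenate([shared_idx, own])).astype(int)
    outlier_idx = np.sort(pool[cursor : cursor + config.n_outlier_genes]).astype(int)
    cursor += config.n_outlier_genes

    mu = rng.normal(config.base_log_mean, config.base_log_sd, size=d)
    # Outliers sit at a fixed, unambiguously inflated level rather than a
    # shifted random baseline, so "designed outlier" is well defined.
    mu[outlier_idx] = config.base_log_mean + config.outlier_log_shift

    sample_ids: list[str] = []
    labels: list[str] = []
    for c in classes:
        for i in range(config.n_per_class[c]):
            sample_ids.append(f"s_{c}_{i:03d}")
            labels.append(c)
    n = len(sample_ids)
    lab = np.asarray(labels, dtype=object)

    log_x = mu[None, :] + rng.normal(0.0, config.noise_log_sd, size=(n, d))
    for c in classes:
        rows = np.flatnonzero(lab == c)
        on = rng.random(rows.size) < config.program_active_prob
        activity = on / config.program_active_prob + rng.normal(
            0.0, config.activity_sd, size=rows.size
        )
        shift = config.effect_size * activity
        log_x[np.ix_(rows, marker_idx[c])] += shift[:, None]
    values = np.exp(log_x)

    p = np.broadcast_to(np.asarray(config.zero_inflation_prob, float), (d,))
    zero_mask = rng.random(size=(n, d)) < p[None, :]
    values = np.where(zero_mask, 0.0, values)

    X = ExpressionMatrix(values, gene_ids, sample_ids)
    label_set = SubtypeLabelSet(sample_ids, labels)
    truth = SimTruth(
        markers={c: [gene_ids[i] for i in marker_idx[c]] for c in classes},
        outlier_genes=[gene_ids[i] for i in outlier_idx],
        config=config,
    )
    return X, label_set, truth


def imbalanced_binary_toy(
    n_major: int = 380,
    n_minor: int = 20,
    n_test_per_class: int = 150,
    d: int = 6,
    separation: float = 1.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Overlapping two-class Gaussians with an imbalanced (default 95:5)
    training set and a balanced test set, for demonstrating the effect of
    class weighting on minority recall. Returns (X_train, y_train, X_test,
    y_test)."""
    rng = np.random.default_rng(seed)
    shift = separation / np.sqrt(d)

    def draw(n_maj, n_min):
        X = np.vstack(
            [
                rng.normal(0.0, 1.0, size=(n_maj, d)),
                rng.normal(shift, 1.0, size=(n_min, d)),
            ]
        )
        y = np.array(["major"] * n_maj + ["minor"] * n_min, dtype=object)
        return X, y

    X_train, y_train = draw(n_major, n_minor)
    X_test, y_test = draw(n_test_per_class, n_test_per_class)
    return X_train, y_train, X_test, y_test


def random_edges(
    gene_ids: list[str], p: float = 0.1, seed: int = 0
) -> list[tuple[str, str, float]]:
    """Toy random weighted edge list over ``gene_ids`` (for module tests)."""
    rng = np.random.default_rng(seed)
    out = []
    for i, u in enumerate(gene_ids):
        for v in gene_ids[i + 1 :]:
            if rng.random() < p:
                out.append((u, v, float(rng.uniform(0.5, 1.0))))
    return out
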