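"""L2,1 row-sparsity-regularized shallow autoencoder for feature selection.

The network is two fully connected layers without biases by default:

    H = relu(X W1),  Xhat = relu(H W2)

with ``W1`` of shape (d, h) and ``W2`` of shape (h, d), trained by
mini-batch Adam on

    J = 1/(2 m) ||X - Xhat||_F^2 + lambda * ||W1||_{2,1}

where ``||W1||_{2,1}`` is the sum over rows of the row Euclidean norm.
Penalizing it drives entire encoder rows to zero, so the surviving row norms
``s_i = ||W1[i, :]||_2`` rank input genes by how much they feed the
bottleneck representation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

#: Per-subtype regularization strengths used in the reference workflow.
DEFAULT_LAMBDA = {
    "TNBC": 1e-5,
    "HER2-enriched": 1e-4,
    "LuminalA": 1e-6,
    "LuminalB": 1e-6,
}


@dataclass
class AEModel:
    """Encoder/decoder weights (optionally with biases)."""

    W1: np.ndarray
    W2: np.ndarray
    b1: np.ndarray | None = None
    b2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        d, h = self.W1.shape
        if self.W2.shape != (h, d):
            raise ValueError(
                f"decoder shape {self.W2.shape} incompatible with encoder "
                f"{self.W1.shape}"
            )
        if not (np.all(np.isfinite(self.W1)) and np.all(np.isfinite(self.W2))):
            raise ValueError("non-finite weights")

    @property
    def d(self) -> int:
        return self.W1.shape[0]

    @property
    def h(self) -> int:
        return self.W1.shape[1]

    def copy(self) -> "AEModel":
        return AEModel(
            self.W1.copy(),
            self.W2.copy(),
            None if self.b1 is None else self.b1.copy(),
            None if self.b2 is None else self.b2.copy(),
        )


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``h`` is the bottleneck width (500 in the reference workflow; smaller for
    toy data), ``lam`` the L2,1 penalty weight, and ``penalty_form`` selects
    the standard L2,1 norm (``"l21"``) or the plain sum of squared entries
    (``"sum_of_squares"``); the two rank features identically but give
    different objective values.
    """

    h: int = 500
    lam: float = 0.0
    batch_size: int = 64
    epochs: int = 35
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    seed: int = 0
    val_fraction: float = 0.2
    penalty_form: str = "l21"
    use_bias: bool = False

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValueError("h must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.penalty_form not in ("l21", "sum_of_squares"):
            raise ValueError(f"unknown penalty_form {self.penalty_form!r}")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass
class TrainHistory:
    """Per-epoch losses and the checkpointed best epoch (earliest tie)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


@dataclass
class MarkerSet:
    """An ordered gene list with optional aligned scores and provenance."""

    gene_ids: list[str]
    scores: np.ndarray | None = None
    subtype: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("marker gene_ids are not unique")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.size != len(self.gene_ids):
                raise ValueError("scores misaligned with gene_ids")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.gene_ids)


def init_model(
    d: int,
    h: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    use_bias: bool = False,
) -> AEModel:
    """Glorot-uniform initialization, reproducible under seed/rng."""
    if not (1 <= h < d):
        raise ValueError(f"need 1 <= h < d, got h={h}, d={d}")
    if rng is None:
        rng = np.random.default_rng(seed)
    limit = np.sqrt(6.0 / (d + h))
    W1 = rng.uniform(-limit, limit, size=(d, h))
    W2 = rng.uniform(-limit, limit, size=(h, d))
    b1 = np.zeros(h) if use_bias else None
    b2 = np.zeros(d) if use_bias else None
    return AEModel(W1, W2, b1, b2)


def _forward_full(X: np.ndarray, model: AEModel):
    Z1 = X @ model.W1
    if model.b1 is not None:
        Z1 = Z1 + model.b1
    H = np.maximum(Z1, 0.0)
    Z2 = H @ model.W2
    if model.b2 is not None:
        Z2 = Z2 + model.b2
    Xhat = np.maximum(Z2, 0.0)
    return Z1, H, Z2, Xhat


def forward(X: np.ndarray, model: AEModel) -> np.ndarray:
    """Reconstruction relu(relu(X W1) W2); non-negative by construction."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.d:
        raise ValueError(f"X shape {X.shape} incompatible with d={model.d}")
    return _forward_full(X, model)[3]


def l21_norm(W: np.ndarray) -> float:
    """Sum over rows of the row-wise Euclidean norm; 0 iff W == 0."""
    W = np.asarray(W, dtype=float)
    return float(np.sqrt((W**2).sum(axis=1)).sum())


def _penalty(W: np.ndarray, form: str) -> float:
    if form == "l21":
        return l21_norm(W)
    if form == "sum_of_squares":
        return float((W**2).sum())
    raise ValueError(f"unknown penalty_form {form!r}")


def _penalty_grad(W: np.ndarray, form: str) -> np.ndarray:
    if form == "sum_of_squares":
        return 2.0 * W
    norms = np.sqrt((W**2).sum(axis=1, keepdims=True))
    out = np.zeros_like(W)
    nz = norms[:, 0] > 0
    out[nz] = W[nz] / norms[nz]
    return out


def objective(
    X: np.ndarray, model: AEModel, lam: float, penalty_form: str = "l21"
) -> float:
    """1/(2 m) ||X - Xhat||_F^2 + lam * penalty(W1)."""
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if m == 0:
        raise ValueError("objective undefined on an empty matrix")
    Xhat = forward(X, model)
    mse = float(((X - Xhat) ** 2).sum()) / (2.0 * m)
    return mse + lam * _penalty(model.W1, penalty_form)


def gradients(
    X: np.ndarray, model: AEModel, lam: float, penalty_form: str = "l21"
) -> dict[str, np.ndarray]:
    """Analytic gradient of the objective w.r.t. all weights.

    ReLU subgradient at exactly 0 is taken as 0 (strict positivity masks).
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    Z1, H, Z2, Xhat = _forward_full(X, model)
    dZ2 = ((Xhat - X) / m) * (Z2 > 0)
    dW2 = H.T @ dZ2
    dH = dZ2 @ model.W2.T
    dZ1 = dH * (Z1 > 0)
    dW1 = X.T @ dZ1 + lam * _penalty_grad(model.W1, penalty_form)
    grads = {"W1": dW1, "W2": dW2}
    if model.b1 is not None:
        grads["b1"] = dZ1.sum(axis=0)
    if model.b2 is not None:
        grads["b2"] = dZ2.sum(axis=0)
    return grads


class _Adam:
    def __init__(self, shapes: dict, lr: float, b1: float, b2: float, eps: float):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    X: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AEModel, TrainHistory]:
    """Mini-batch Adam training with best-validation checkpointing.

    An internal validation split of ``config.val_fraction`` is held out
    (under the run's generator) and the model with the lowest validation
    objective across epochs is returned, not the final-epoch model. Passing
    an external ``rng`` lets replicate runs share one advancing generator
    stream; otherwise a fresh generator is seeded from ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples to train")
    if config.h >= d:
        raise ValueError(f"bottleneck h={config.h} must be < d={d}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    model = init_model(d, config.h, rng=rng, use_bias=config.use_bias)

    n_val = int(round(config.val_fraction * n)) if config.val_fraction > 0 else 0
    n_val = min(max(n_val, 1 if config.val_fraction > 0 else 0), n - 1)
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    X_tr, X_val = X[train_idx], X[val_idx]

    params = {"W1": model.W1, "W2": model.W2}
    if config.use_bias:
        params["b1"] = model.b1
        params["b2"] = model.b2
    opt = _Adam(
        {k: v.shape for k, v in params.items()},
        config.learning_rate,
        config.beta1,
        config.beta2,
        config.eps,
    )

    history = TrainHistory()
    best_val = np.inf
    best_model = model.copy()
    for epoch in range(config.epochs):
        order = rng.permutation(len(X_tr))
        for start in range(0, len(X_tr), config.batch_size):
            batch = X_tr[order[start : start + config.batch_size]]
            grads = gradients(batch, model, config.lam, config.penalty_form)
            opt.step(params, grads)
        tr_loss = objective(X_tr, model, config.lam, config.penalty_form)
        val_loss = (
            objective(X_val, model, config.lam, config.penalty_form)
            if n_val > 0
            else tr_loss
        )
        if not (np.isfinite(tr_loss) and np.isfinite(val_loss)):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: train={tr_loss}, val={val_loss}"
            )
        history.train_loss.append(tr_loss)
        history.val_loss.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_model = model.copy()
            history.best_epoch = epoch
    return best_model, history


def feature_scores(model: AEModel) -> np.ndarray:
    """Per-gene score s_i = ||W1[i, :]||_2 (zero iff the row is zero)."""
    return np.sqrt((model.W1**2).sum(axis=1))


def top_k_features(
    scores: np.ndarray,
    gene_ids: Sequence[str],
    k: int = 3000,
    subtype: str | None = None,
) -> MarkerSet:
    """The k highest-scoring genes, descending score, ties by gene id."""
    scores = np.asarray(scores, dtype=float)
    gene_ids = list(gene_ids)
    if scores.size != len(gene_ids):
        raise ValueError("scores and gene_ids misaligned")
    if not (1 <= k <= len(gene_ids)):
        raise ValueError(f"k={k} out of range for d={len(gene_ids)}")
    order = sorted(range(len(gene_ids)), key=lambda i: (-scores[i], gene_ids[i]))
    top = order[:k]
    return MarkerSet(
        [gene_ids[i] for i in top], scores[top], subtype=subtype
    )


def save_model(
    model: AEModel,
    path: str,
    config: TrainConfig | None = None,
    history: TrainHistory | None = None,
    gene_ids: Sequence[str] | None = None,
) -> None:
    """Portable archive: weights as .npy plus JSON config/history."""
    os.makedirs(path, exist_ok=True)
    np.save(os.path.join(path, "W1.npy"), model.W1)
    np.save(os.path.join(path, "W2.npy"), model.W2)
    if model.b1 is not None:
        np.save(os.path.join(path, "b1.npy"), model.b1)
        np.save(os.path.join(path, "b2.npy"), model.b2)
    meta: dict = {}
    if config is not None:
        meta["config"] = asdict(config)
    if history is not None:
        meta["history"] = {
            "train_loss": history.train_loss,
            "val_loss": history.val_loss,
            "best_epoch": history.best_epoch,
        }
    if gene_ids is not None:
        meta["gene_ids"] = list(gene_ids)
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def load_model(path: str) -> tuple[AEModel, dict]:
    W1 = np.load(os.path.join(path, "W1.npy"))
    W2 = np.load(os.path.join(path, "W2.npy"))
    b1 = b2 = None
    if os.path.exists(os.path.join(path, "b1.npy")):
        b1 = np.load(os.path.join(path, "b1.npy"))
        b2 = np.load(os.path.join(path, "b2.npy"))
    meta_path = os.path.join(path, "meta.json")
    meta = {}
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
    return AEModel(W1, W2, b1, b2), meta
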