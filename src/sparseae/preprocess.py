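"""Expression-matrix containers and preprocessing for subtype marker discovery.

The preprocessing chain mirrors a standard FPKM workflow: drop genes that are
zero in more than 75% of samples, drop genes whose mean expression is an
outlier (more than ``n_sd`` standard deviations from the mean of the per-gene
means), assign each sample to a hormone-receptor subtype, and min-max scale
each gene into [0, 1] (fit on training data only).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: The four hormone-receptor-defined breast cancer subtypes.
SUBTYPES = ("TNBC", "HER2-enriched", "LuminalA", "LuminalB")
UNASSIGNED = "unassigned"

_POSITIVE_TOKENS = {"positive", "pos", "+", "p"}
_NEGATIVE_TOKENS = {"negative", "neg", "-", "−", "n"}


class ExpressionMatrix:
    """A non-negative expression matrix (samples x genes) with aligned ids.

    Parameters
    ----------
    values
        2-D array, shape ``(n_samples, n_genes)``.
    gene_ids, sample_ids
        Unique identifiers aligned with the columns / rows of ``values``.
    require_nonnegative
        Raw expression is non-negative by construction; matrices produced by
        applying a fitted min-max scaler to *new* data may legitimately leave
        [0, 1], so scaler outputs disable this check.
    """

    def __init__(
        self,
        values: np.ndarray,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        *,
        require_nonnegative: bool = True,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        gene_ids = list(gene_ids)
        sample_ids = list(sample_ids)
        if values.shape != (len(sample_ids), len(gene_ids)):
            raise ValueError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(sample_ids)} samples x {len(gene_ids)} genes"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample_ids are not unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain non-finite entries")
        if require_nonnegative and (values < 0).any():
            raise ValueError("expression values must be non-negative")
        self.values = values
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return np.array([pos[g] for g in gene_ids], dtype=int)

    def subset_genes(self, keep: Sequence[str] | np.ndarray) -> "ExpressionMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
            genes = [self.gene_ids[i] for i in idx]
        else:
            genes = list(keep)
            idx = self.gene_index(genes)
        return ExpressionMatrix(
            self.values[:, idx], genes, self.sample_ids, require_nonnegative=False
        )

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        idx = np.array([pos[s] for s in keep], dtype=int)
        return ExpressionMatrix(
            self.values[idx, :], self.gene_ids, list(keep), require_nonnegative=False
        )

    def to_frame(self, orient: str = "genes_by_samples") -> pd.DataFrame:
        """Render as a DataFrame; on-disk convention is genes x samples."""
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)
        if orient == "genes_by_samples":
            return df.T
        if orient == "samples_by_genes":
            return df
        raise ValueError(f"unknown orient {orient!r}")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, orient: str = "genes_by_samples"
    ) -> "ExpressionMatrix":
        if orient == "genes_by_samples":
            df = df.T
        elif orient != "samples_by_genes":
            raise ValueError(f"unknown orient {orient!r}")
        return cls(
            df.to_numpy(dtype=float),
            [str(g) for g in df.columns],
            [str(s) for s in df.index],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix(n={self.n}, d={self.d})"


class SubtypeLabelSet:
    """Per-sample subtype assignment among the four classes (+ unassigned)."""

    def __init__(self, sample_ids: Sequence[str], labels: Sequence[str]) -> None:
        sample_ids = list(sample_ids)
        labels = list(labels)
        if len(sample_ids) != len(labels):
            raise ValueError("sample_ids and labels length mismatch")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample_ids are not unique")
        allowed = set(SUBTYPES) | {UNASSIGNED}
        bad = sorted(set(labels) - allowed)
        if bad:
            raise ValueError(f"unknown subtype labels: {bad}")
        self.sample_ids = sample_ids
        self.labels = np.asarray(labels, dtype=object)

    @property
    def class_counts(self) -> dict[str, int]:
        """Counts per assigned subtype (n_v); excludes unassigned samples."""
        return {
            s: int((self.labels == s).sum())
            for s in SUBTYPES
            if (self.labels == s).any()
        }

    @property
    def n_assigned(self) -> int:
        return int(sum(self.class_counts.values()))

    def label_of(self, sample_id: str) -> str:
        return str(self.labels[self.sample_ids.index(sample_id)])

    def subset(self, sample_ids: Sequence[str]) -> "SubtypeLabelSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return SubtypeLabelSet(list(sample_ids), [self.labels[i] for i in idx])

    def assigned_sample_ids(self) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l != UNASSIGNED]

    def samples_of(self, subtype: str) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == subtype]

    def as_array(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        if sample_ids is None:
            return self.labels.copy()
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([self.labels[pos[s]] for s in sample_ids], dtype=object)


@dataclass(frozen=True)
class ReceptorStatus:
    """ER / PR / HER2 status, each 'positive', 'negative' or 'unknown'."""

    er: str
    pr: str
    her2: str

    def __post_init__(self) -> None:
        for name in ("er", "pr", "her2"):
            v = getattr(self, name)
            if v not in ("positive", "negative", "unknown"):
                raise ValueError(f"{name}={v!r} not in positive/negative/unknown")


def parse_receptor_value(raw: object) -> str:
    """Normalize a free-text receptor annotation to positive/negative/unknown."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return "unknown"
    token = str(raw).strip().lower()
    if token in _POSITIVE_TOKENS:
        return "positive"
    if token in _NEGATIVE_TOKENS:
        return "negative"
    return "unknown"


def assign_subtype(
    status: ReceptorStatus,
    overrides: Mapping[tuple[str, str, str], str] | None = None,
) -> str:
    """Map hormone-receptor status to a subtype.

    Rules: (ER-, PR-, HER2-) -> TNBC; (ER-, HER2+) -> HER2-enriched (PR
    ignored); (ER+, PR+, HER2-) -> LuminalA; (ER+, HER2+) -> LuminalB (any
    PR); (ER+, PR-, HER2-) -> LuminalB (luminal A requires PR+ explicitly).
    Anything else, including patterns that need an unknown field, is
    ``unassigned``. ``overrides`` maps explicit (er, pr, her2) triples to a
    subtype and takes precedence.
    """
    key = (status.er, status.pr, status.her2)
    if overrides and key in overrides:
        label = overrides[key]
        if label not in set(SUBTYPES) | {UNASSIGNED}:
            raise ValueError(f"override maps {key} to unknown label {label!r}")
        return label
    er, pr, her2 = key
    if er == "negative" and her2 == "positive":
        return "HER2-enriched"
    if er == "negative" and her2 == "negative":
        return "TNBC" if pr == "negative" else UNASSIGNED
    if er == "positive" and her2 == "positive":
        return "LuminalB"
    if er == "positive" and her2 == "negative":
        if pr == "positive":
            return "LuminalA"
        if pr == "negative":
            return "LuminalB"
    return UNASSIGNED


def labels_from_receptor_status(
    statuses: Mapping[str, ReceptorStatus],
    overrides: Mapping[tuple[str, str, str], str] | None = None,
) -> SubtypeLabelSet:
    ids = list(statuses)
    return SubtypeLabelSet(ids, [assign_subtype(statuses[s], overrides) for s in ids])


def filter_zero_genes(
    X: ExpressionMatrix, max_zero_fraction: float = 0.75
) -> ExpressionMatrix:
    """Drop genes that are zero in strictly more than ``max_zero_fraction``
    of samples; a gene at exactly the threshold is kept."""
    frac = (X.values == 0).mean(axis=0)
    keep = frac <= max_zero_fraction
    if not keep.any():
        raise ValueError(
            f"no genes survive the zero filter (max_zero_fraction="
            f"{max_zero_fraction})"
        )
    return X.subset_genes(keep)


def remove_outlier_genes(X: ExpressionMatrix, n_sd: float = 1.0) -> ExpressionMatrix:
    """Drop genes whose mean expression is an outlier.

    The per-gene means are summarized by their mean mu and population
    standard deviation sigma; genes strictly outside [mu - n_sd*sigma,
    mu + n_sd*sigma] are removed. sigma = 0 removes nothing (warning).
    """
    if X.d < 2:
        raise ValueError("need at least 2 genes for outlier detection")
    gene_means = X.values.mean(axis=0)
    mu = gene_means.mean()
    sigma = gene_means.std(ddof=0)
    if sigma == 0:
        warnings.warn(
            "gene means have zero spread; outlier filter removed nothing",
            stacklevel=2,
        )
        return X.subset_genes(np.ones(X.d, dtype=bool))
    if math.isinf(n_sd):
        return X.subset_genes(np.ones(X.d, dtype=bool))
    keep = np.abs(gene_means - mu) <= n_sd * sigma
    if not keep.any():
        raise ValueError(f"no genes survive the outlier filter (n_sd={n_sd})")
    return X.subset_genes(keep)


@dataclass
class ScalingParams:
    """Per-gene min/max fitted on a reference (training) set."""

    gene_ids: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if not (len(self.gene_ids) == self.mins.size == self.maxs.size):
            raise ValueError("ScalingParams fields misaligned")
        if (self.maxs < self.mins).any():
            raise ValueError("max < min for some gene")


def fit_minmax(X: ExpressionMatrix) -> ScalingParams:
    return ScalingParams(
        list(X.gene_ids), X.values.min(axis=0), X.values.max(axis=0)
    )


def apply_minmax(X: ExpressionMatrix, params: ScalingParams) -> ExpressionMatrix:
    """Per-gene (x - min) / (max - min); constant genes map to 0.

    Applied to data outside the fitting set the output may leave [0, 1];
    it is deliberately not clipped.
    """
    if list(X.gene_ids) != list(params.gene_ids):
        try:
            idx = X.gene_index(params.gene_ids)
        except KeyError as exc:
            raise ValueError(f"gene ids do not match scaling params: {exc}") from exc
        if len(params.gene_ids) != X.d:
            raise ValueError(
                "matrix has genes absent from scaling params; subset first"
            )
        X = X.subset_genes([X.gene_ids[i] for i in idx])
    span = params.maxs - params.mins
    out = np.zeros_like(X.values)
    nz = span > 0
    out[:, nz] = (X.values[:, nz] - params.mins[nz]) / span[nz]
    return ExpressionMatrix(
        out, list(X.gene_ids), list(X.sample_ids), require_nonnegative=False
    )


class Split(NamedTuple):
    x_train: ExpressionMatrix
    x_test: ExpressionMatrix
    y_train: SubtypeLabelSet
    y_test: SubtypeLabelSet


def stratified_split(
    X: ExpressionMatrix,
    labels: SubtypeLabelSet,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> Split:
    """Per-class stratified train/test partition.

    Each class contributes floor(train_fraction * n_v) training samples,
    with leftover slots (to reach round(train_fraction * n)) granted by
    largest fractional remainder; every class keeps at least one sample on
    each side. Deterministic under ``seed``.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    order = {s: i for i, s in enumerate(X.sample_ids)}
    lab = labels.as_array(X.sample_ids)
    if (lab == UNASSIGNED).any():
        raise ValueError("all samples must be assigned to a subtype before splitting")
    classes = sorted(set(lab))
    counts = {c: int((lab == c).sum()) for c in classes}
    for c, n_v in counts.items():
        if n_v < 2:
            raise ValueError(f"class {c!r} has {n_v} sample(s); need >= 2")
    n = X.n
    base = {c: int(math.floor(train_fraction * counts[c])) for c in classes}
    base = {c: min(max(b, 1), counts[c] - 1) for c, b in base.items()}
    target = int(math.floor(train_fraction * n + 0.5))
    leftover = target - sum(base.values())
    rema = sorted(
        classes,
        key=lambda c: (-(train_fraction * counts[c] - math.floor(train_fraction * counts[c])), c),
    )
    i = 0
    while leftover > 0 and i < len(rema):
        c = rema[i]
        if base[c] + 1 <= counts[c] - 1:
            base[c] += 1
            leftover -= 1
        i += 1

    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for c in classes:
        members = [s for s, l in zip(X.sample_ids, lab) if l == c]
        perm = rng.permutation(len(members))
        chosen = {members[j] for j in perm[: base[c]]}
        train_ids.extend(s for s in members if s in chosen)
        test_ids.extend(s for s in members if s not in chosen)
    train_ids.sort(key=order.__getitem__)
    test_ids.sort(key=order.__getitem__)
    return Split(
        X.subset_samples(train_ids),
        X.subset_samples(test_ids),
        labels.subset(train_ids),
        labels.subset(test_ids),
    )


@dataclass
class PreprocessReport:
    """Gene/sample bookkeeping for each preprocessing stage."""

    stages: dict = field(default_factory=dict)

    def record(self, stage: str, **info: object) -> None:
        self.stages[stage] = info


def preprocess(
    X: ExpressionMatrix,
    labels: SubtypeLabelSet,
    max_zero_fraction: float = 0.75,
    outlier_sd: float = 1.0,
) -> tuple[dict[str, ExpressionMatrix], ScalingParams, PreprocessReport]:
    """Full preprocessing: zero filter, outlier filter, per-subtype scaled
    matrices (scaler fit on all retained samples).

    Returns (class_matrices, scaler, report); class matrices are scaled to
    [0, 1] and keyed by subtype.
    """
    report = PreprocessReport()
    report.record("input", n_genes=X.d, n_samples=X.n)
    X1 = filter_zero_genes(X, max_zero_fraction)
    report.record("zero_filter", n_genes=X1.d, removed=X.d - X1.d)
    X2 = remove_outlier_genes(X1, outlier_sd)
    report.record("outlier_filter", n_genes=X2.d, removed=X1.d - X2.d)
    assigned = labels.assigned_sample_ids()
    assigned = [s for s in X2.sample_ids if s in set(assigned)]
    X3 = X2.subset_samples(assigned)
    report.record(
        "subtype_assignment",
        n_samples=X3.n,
        class_counts=labels.subset(assigned).class_counts,
    )
    scaler = fit_minmax(X3)
    scaled = apply_minmax(X3, scaler)
    out: dict[str, ExpressionMatrix] = {}
    for subtype in SUBTYPES:
        members = [s for s in assigned if labels.label_of(s) == subtype]
        if members:
            out[subtype] = scaled.subset_samples(members)
    report.record("scaled", subtypes={k: v.n for k, v in out.items()})
    return out, scaler, report
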