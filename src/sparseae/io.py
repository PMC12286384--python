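"""Reading and writing the delimited-text formats the tool exchanges.

Expression matrices are TSV/CSV with gene ids in the first column and sample
ids in the header (``orient="samples_by_genes"`` accepts the transpose);
gzip is handled transparently by pandas. Metadata is a TSV with either
receptor-status columns (sample_id, er, pr, her2) or a precomputed subtype
column (sample_id, subtype). Edge lists are STRING-style
(protein1, protein2, combined_score) with 0-1000 integer scores rescaled to
[0, 1] automatically.
"""

from __future__ import annotations

import json
from typing import Mapping

import numpy as np
import pandas as pd

from .autoencoder import MarkerSet
from .preprocess import (
    ExpressionMatrix,
    ReceptorStatus,
    SubtypeLabelSet,
    labels_from_receptor_status,
    parse_receptor_value,
)

_FLOAT_FMT = "%.10g"  # fixed format so reruns are byte-identical


def _sep(path: str) -> str:
    base = str(path)
    if base.endswith(".gz"):
        base = base[:-3]
    return "," if base.endswith(".csv") else "\t"


def read_expression(
    path: str, orient: str = "genes_by_samples"
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return ExpressionMatrix.from_frame(df, orient=orient)


def write_expression(X: ExpressionMatrix, path: str) -> None:
    df = X.to_frame("genes_by_samples")
    df.index.name = "gene_id"
    df.to_csv(path, sep=_sep(path), float_format=_FLOAT_FMT)


def read_metadata(
    path: str,
    overrides: Mapping[tuple[str, str, str], str] | None = None,
) -> SubtypeLabelSet:
    """Subtype labels from a metadata table, deriving them from receptor
    status when no explicit subtype column is present."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols:
        raise ValueError("metadata needs a sample_id column")
    sid = df[cols["sample_id"]].astype(str)
    if "subtype" in cols:
        return SubtypeLabelSet(list(sid), list(df[cols["subtype"]].astype(str)))
    for req in ("er", "pr", "her2"):
        if req not in cols:
            raise ValueError(
                "metadata needs either a subtype column or er/pr/her2 columns"
            )
    statuses = {
        s: ReceptorStatus(
            parse_receptor_value(e), parse_receptor_value(p), parse_receptor_value(h)
        )
        for s, e, p, h in zip(
            sid, df[cols["er"]], df[cols["pr"]], df[cols["her2"]]
        )
    }
    return labels_from_receptor_status(statuses, overrides)


def write_labels(labels: SubtypeLabelSet, path: str) -> None:
    pd.DataFrame(
        {"sample_id": labels.sample_ids, "subtype": list(labels.labels)}
    ).to_csv(path, sep=_sep(path), index=False)


def write_markers(markers: MarkerSet, path: str, n_runs_present=None) -> None:
    df = pd.DataFrame({"gene_id": markers.gene_ids})
    if markers.scores is not None:
        df["mean_score"] = markers.scores
    if n_runs_present is not None:
        df["n_runs_present"] = [n_runs_present.get(g, 0) for g in markers.gene_ids]
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df.to_csv(path, sep=_sep(path), index=False, float_format=_FLOAT_FMT)


def read_markers(path: str, subtype: str | None = None) -> MarkerSet:
    df = pd.read_csv(path, sep=_sep(path))
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols:
        raise ValueError(f"{path}: marker file needs a gene_id column")
    scores = None
    for name in ("mean_score", "score"):
        if name in cols:
            scores = df[cols[name]].to_numpy(float)
            break
    return MarkerSet(list(df[cols["gene_id"]].astype(str)), scores, subtype=subtype)


def read_edges(path: str) -> list[tuple[str, str, float]]:
    """STRING-style edge list; integer 0-1000 scores are rescaled to [0, 1]."""
    df = pd.read_csv(path, sep=_sep(path))
    cols = {c.lower(): c for c in df.columns}
    for req in ("protein1", "protein2", "combined_score"):
        if req not in cols:
            raise ValueError(f"{path}: edge list needs a {req} column")
    scores = df[cols["combined_score"]].to_numpy(float)
    bad = ~np.isfinite(scores)
    if bad.any():
        raise ValueError(
            f"{path}: non-numeric combined_score at data row "
            f"{int(np.flatnonzero(bad)[0]) + 1}"
        )
    if scores.size and scores.max() > 1.0:
        scores = scores / 1000.0
    return list(
        zip(
            df[cols["protein1"]].astype(str),
            df[cols["protein2"]].astype(str),
            scores,
        )
    )


def write_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
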