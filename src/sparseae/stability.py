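"""Replicate-and-intersect consensus ("stability selection by intersection").

A single regularized-autoencoder run yields a stochastic top-k gene set.
The consensus protocol repeats training ``runs_per_seed`` times from one
seeded generator (the generator is seeded once per block and its state
advances across runs, so the runs differ), intersects the per-run sets, then
repeats the whole block for ``n_seeds`` independent seeds and intersects
across blocks. Genes surviving every intersection are the marker set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autoencoder import (
    MarkerSet,
    TrainConfig,
    feature_scores,
    top_k_features,
    train,
)


@dataclass
class ConsensusConfig:
    """Replication layout: 30 runs per seed x 16 seeds, top-3000 per run,
    in the reference workflow; seeds are derived deterministically from
    ``master_seed`` unless given explicitly."""

    runs_per_seed: int = 30
    n_seeds: int = 16
    seeds: list[int] | None = None
    k: int = 3000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.runs_per_seed < 1 or self.n_seeds < 1:
            raise ValueError("runs_per_seed and n_seeds must be >= 1")
        if self.seeds is not None:
            if len(self.seeds) != self.n_seeds:
                raise ValueError("len(seeds) must equal n_seeds")
            if len(set(self.seeds)) != len(self.seeds):
                raise ValueError("seeds must be distinct")

    def resolved_seeds(self) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        return generate_seeds(self.master_seed, self.n_seeds)


def generate_seeds(master_seed: int, n: int) -> list[int]:
    """A documented deterministic seed sequence below 2**31."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    seeds = [int(s % (2**31)) for s in state]
    if len(set(seeds)) != n:  # pragma: no cover - astronomically unlikely
        extra = np.random.SeedSequence(master_seed + 1).generate_state(
            4 * n, dtype=np.uint32
        )
        pool = list(dict.fromkeys(seeds + [int(s % (2**31)) for s in extra]))
        seeds = pool[:n]
    return seeds


def run_replicates(
    X_class: np.ndarray,
    gene_ids: list[str],
    train_config: TrainConfig,
    consensus_config: ConsensusConfig,
    seed: int,
) -> list[MarkerSet]:
    """One seed block: seed the generator once, run train->score->top_k
    ``runs_per_seed`` times without reseeding, return one MarkerSet per run."""
    rng = np.random.default_rng(seed)
    out: list[MarkerSet] = []
    for run in range(consensus_config.runs_per_seed):
        try:
            model, _ = train(X_class, train_config, rng=rng)
        except Exception as exc:
            raise RuntimeError(f"training failed in run {run} of seed {seed}") from exc
        scores = feature_scores(model)
        ms = top_k_features(scores, gene_ids, consensus_config.k)
        ms.provenance = {"seed": seed, "run": run}
        out.append(ms)
    return out


def intersect_sets(sets: list) -> list[str]:
    """Exact intersection of gene-id collections, ascending gene id."""
    if not sets:
        raise ValueError("need at least one set")
    acc: set[str] = set(
        sets[0].gene_ids if isinstance(sets[0], MarkerSet) else sets[0]
    )
    for s in sets[1:]:
        acc &= set(s.gene_ids if isinstance(s, MarkerSet) else s)
    return sorted(acc)


@dataclass
class ConsensusResult:
    markers: MarkerSet
    funnel: dict = field(default_factory=dict)


def consensus_markers(
    X_class: np.ndarray,
    gene_ids: list[str],
    train_config: TrainConfig,
    consensus_config: ConsensusConfig,
    subtype: str | None = None,
) -> ConsensusResult:
    """Full protocol: per-seed intersections, then intersection across seeds.

    The final set is ordered by mean score across every contributing run
    (descending, ties by gene id); an empty consensus is returned with a
    warning, not raised.
    """
    seeds = consensus_config.resolved_seeds()
    per_seed_sets: list[list[str]] = []
    per_run_sizes: list[list[int]] = []
    score_sum = np.zeros(len(gene_ids))
    n_runs = 0
    present_count: dict[str, int] = {}
    for seed in seeds:
        replicates = run_replicates(
            X_class, gene_ids, train_config, consensus_config, seed
        )
        per_run_sizes.append([len(r) for r in replicates])
        for r in replicates:
            for g in r.gene_ids:
                present_count[g] = present_count.get(g, 0) + 1
        for r in replicates:
            if r.scores is not None:
                idx = {g: i for i, g in enumerate(gene_ids)}
                for g, s in zip(r.gene_ids, r.scores):
                    score_sum[idx[g]] += s
        n_runs += len(replicates)
        per_seed_sets.append(intersect_sets(replicates))
    final = intersect_sets(per_seed_sets)
    mean_score = score_sum / max(n_runs, 1)
    idx = {g: i for i, g in enumerate(gene_ids)}
    ordered = sorted(final, key=lambda g: (-mean_score[idx[g]], g))
    if not ordered:
        warnings.warn(
            f"consensus for subtype {subtype!r} is empty", stacklevel=2
        )
    markers = MarkerSet(
        ordered,
        np.array([mean_score[idx[g]] for g in ordered]),
        subtype=subtype,
        provenance={
            "seeds": seeds,
            "runs_per_seed": consensus_config.runs_per_seed,
            "k": consensus_config.k,
        },
    )
    funnel = {
        "k": consensus_config.k,
        "per_run_sizes": per_run_sizes,
        "per_seed_intersection_sizes": [len(s) for s in per_seed_sets],
        "final_size": len(ordered),
        "n_runs_present": {g: present_count.get(g, 0) for g in ordered},
    }
    return ConsensusResult(markers, funnel)
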