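"""Synthetic 2D reference embeddings for stage-label transfer.

Gaussian clusters, one per developmental stage, stand in for a reference
UMAP embedding; query points (neighborhood centroids) are drawn from the
same clusters with their stage recorded as truth; membership lists link
cells to the neighborhoods containing them, so the kNN labelling and the
label-consolidation rules can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimConfig

__all__ = ["ReferenceEmbedding", "gen_reference_embedding"]


@dataclass
class ReferenceEmbedding:
    ref_points: np.ndarray  # (n_ref, 2)
    ref_labels: list[str]
    query_points: np.ndarray  # (n_query, 2)
    query_truth: list[str]
    memberships: list[list[int]]  # per cell, indices of neighborhoods containing it
    cell_truth: list[str]


def gen_reference_embedding(config: SimConfig) -> ReferenceEmbedding:
    cfg = config.reference
    rng = config.rng("reference")
    if len(cfg.stages) * cfg.n_per_stage < 3:
        raise ValueError("reference smaller than the default neighborhood size k=3")
    centroids = {
        s: np.array([i * cfg.centroid_spacing, (i % 2) * cfg.centroid_spacing])
        for i, s in enumerate(cfg.stages)
    }
    ref_points, ref_labels = [], []
    for s in cfg.stages:
        pts = centroids[s] + rng.normal(0, cfg.cluster_sd, size=(cfg.n_per_stage, 2))
        ref_points.append(pts)
        ref_labels.extend([s] * cfg.n_per_stage)
    ref_points = np.vstack(ref_points)

    q_stage = [cfg.stages[i % len(cfg.stages)] for i in range(cfg.n_queries)]
    query_points = np.array(
        [centroids[s] + rng.normal(0, cfg.cluster_sd, size=2) for s in q_stage]
    )

    # cells: each belongs to a stage and to 1..m neighborhoods of that stage
    lo, hi = cfg.neighborhoods_per_cell
    by_stage = {s: [i for i, t in enumerate(q_stage) if t == s] for s in cfg.stages}
    memberships, cell_truth = [], []
    n_cells = cfg.n_queries * 3
    for i in range(n_cells):
        s = cfg.stages[i % len(cfg.stages)]
        pool = by_stage[s]
        n = int(rng.integers(lo, hi + 1))
        memberships.append(sorted(rng.choice(pool, size=min(n, len(pool)), replace=False).tolist()))
        cell_truth.append(s)
    return ReferenceEmbedding(
        ref_points=ref_points,
        ref_labels=ref_labels,
        query_points=query_points,
        query_truth=q_stage,
        memberships=memberships,
        cell_truth=cell_truth,
    )
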