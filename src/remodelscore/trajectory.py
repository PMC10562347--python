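"""Pseudo-temporal scoring on a minimum spanning tree.

Subjects are embedded in the contrastive subspace; a pseudo-node at the
centroid of the normotensive projections anchors the healthy end of the
trajectory. The minimum spanning tree of the complete Euclidean graph
over subjects + centroid is built, and each subject's raw distance is
the length of the unique tree path to the centroid. Min–max
normalization over the fitting cohort maps the distances onto a
remodelling score in [0, 1]: 0 = healthy state, 1 = disease state.
Held-out subjects attach to the tree by an edge to their nearest
training node and are normalized with the training bounds (clipped),
so training scores stay frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree
from scipy.spatial.distance import cdist, pdist, squareform


@dataclass
class TrajectoryModel:
    node_coordinates: np.ndarray      # (n_subjects + 1) × d; last row = centroid
    mst_edges: list[tuple[int, int, float]]
    centroid_index: int
    raw_distances: np.ndarray         # per subject, path length to centroid
    norm_min: float
    norm_max: float


@dataclass
class ScoreSet:
    scores: np.ndarray
    model: TrajectoryModel


def build_trajectory(
    projections: np.ndarray, normotensive_mask: np.ndarray
) -> TrajectoryModel:
    """Build the MST over subjects plus the normotensive-centroid node
    and compute per-subject path distances to the centroid.

    Coincident points are allowed (zero-weight edges). Deterministic
    given the input ordering.
    """
    P = np.atleast_2d(np.asarray(projections, dtype=float))
    mask = np.asarray(normotensive_mask, dtype=bool)
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 subjects required to build a trajectory")
    if mask.shape[0] != n:
        raise ValueError("normotensive mask length must match subjects")
    if not mask.any():
        raise ValueError("empty normotensive set: no centroid anchor")

    centroid = P[mask].mean(axis=0)
    nodes = np.vstack([P, centroid])
    D = squareform(pdist(nodes))
    # sparse MST drops explicit zeros, so shift all weights by +1; the
    # shift is strictly monotone and leaves the tree unchanged
    tree = minimum_spanning_tree(csr_matrix(D + 1.0))
    rows, cols = tree.nonzero()
    edges = [(int(i), int(j), float(D[i, j])) for i, j in zip(rows, cols)]

    m = len(nodes)
    data = np.array([w for _, _, w in edges])
    graph = csr_matrix(
        (np.concatenate([data, data]),
         (np.concatenate([[i for i, _, _ in edges], [j for _, j, _ in edges]]),
          np.concatenate([[j for _, j, _ in edges], [i for i, _, _ in edges]]))),
        shape=(m, m),
    )
    centroid_index = m - 1
    dist = dijkstra(graph, directed=False, indices=centroid_index)
    raw = dist[:n]
    if not np.all(np.isfinite(raw)):
        raise RuntimeError("MST is disconnected; this should not happen")
    return TrajectoryModel(
        node_coordinates=nodes,
        mst_edges=sorted((min(i, j), max(i, j), w) for i, j, w in edges),
        centroid_index=centroid_index,
        raw_distances=raw,
        norm_min=float(raw.min()),
        norm_max=float(raw.max()),
    )


def score(model: TrajectoryModel) -> ScoreSet:
    """Min–max normalize raw path distances over the fitting cohort."""
    d = model.raw_distances
    if model.norm_max <= model.norm_min:
        raise ValueError("degenerate trajectory: all path distances equal")
    s = (d - model.norm_min) / (model.norm_max - model.norm_min)
    return ScoreSet(scores=s, model=model)


def score_new_projections(model: TrajectoryModel, projections: np.ndarray) -> np.ndarray:
    """Score held-out subjects by nearest-node attachment.

    Each new point gets an edge to its nearest tree node (the centroid
    included, at raw distance 0); its raw distance is the node's path
    distance plus the attachment edge, normalized with the training
    bounds and clipped to [0, 1].
    """
    P = np.atleast_2d(np.asarray(projections, dtype=float))
    if P.shape[1] != model.node_coordinates.shape[1]:
        raise ValueError("projection dimensionality does not match the trajectory")
    node_raw = np.append(model.raw_distances, 0.0)  # centroid raw distance
    d = cdist(P, model.node_coordinates)
    nearest = d.argmin(axis=1)
    raw = node_raw[nearest] + d[np.arange(len(P)), nearest]
    s = (raw - model.norm_min) / (model.norm_max - model.norm_min)
    return np.clip(s, 0.0, 1.0)
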