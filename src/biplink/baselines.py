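"""Projection-based link-prediction baselines.

These methods collapse the bipartite network onto one side: a square
similarity matrix between same-side nodes is computed from their
neighbourhood profiles (rows of the training biadjacency), and the score
of a candidate pair (v, w) aggregates the similarity of v to the known
neighbours of w.  Network-Based Inference (NBI) instead spreads resource
along the bipartite edges in two normalised steps.

The per-side metrics are Jaccard (|∩|/|∪| of neighbour sets), cosine,
Euclidean (transformed to a similarity as 1/(1+d)), and the Pearson
correlation of profile vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network import EdgeSplit

PROJECTION_METRICS = ("jac", "cos", "euc", "pea")

__all__ = [
    "PROJECTION_METRICS",
    "ProjectionScores",
    "same_side_similarity",
    "projection_scores",
    "nbi_scores",
]


@dataclass
class ProjectionScores:
    """Score matrix over all (v, w) pairs from one projection method."""

    method: str
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("projection scores contain non-finite entries")


def _dense(adj) -> np.ndarray:
    A = adj.toarray() if sp.issparse(adj) else np.asarray(adj, dtype=float)
    if A.size and not np.all((A == 0) | (A == 1)):
        raise ValueError("adjacency must be binary")
    return A


def same_side_similarity(adj, side: str = "v", metric: str = "jac") -> np.ndarray:
    """Square similarity matrix between nodes of one side.

    Profiles are rows of the biadjacency (side "v") or of its transpose
    (side "w").  Self-similarity is set to 0, and 0/0 cases (empty or
    constant profiles) yield 0.
    """
    metric = metric.lower()
    if metric not in PROJECTION_METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; choose one of {', '.join(PROJECTION_METRICS)}"
        )
    A = _dense(adj)
    P = A if side == "v" else A.T if side == "w" else None
    if P is None:
        raise ValueError("side must be 'v' or 'w'")

    deg = P.sum(axis=1)
    inter = P @ P.T
    if metric == "jac":
        union = deg[:, None] + deg[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    elif metric == "cos":
        norms = np.sqrt(deg)
        denom = norms[:, None] * norms[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(denom > 0, inter / np.maximum(denom, 1e-300), 0.0)
    elif metric == "euc":
        d2 = np.maximum(deg[:, None] + deg[None, :] - 2.0 * inter, 0.0)
        S = 1.0 / (1.0 + np.sqrt(d2))
    else:  # pea
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.corrcoef(P) if P.shape[0] > 1 else np.ones((1, 1))
        S = np.atleast_2d(S)
        S = np.nan_to_num(S, nan=0.0)  # zero-variance profiles
    np.fill_diagonal(S, 0.0)
    return S


def projection_scores(split: EdgeSplit, metric: str, side: str = "v") -> ProjectionScores:
    """Collaborative scores from a one-mode projection.

    With the default V-side projection,
    ``score(v_i, w_j) = Σ_{v_u ∈ N(w_j)} sim(v_i, v_u)`` over training
    neighbours of w_j; the W-side variant is symmetric.
    """
    A = _dense(split.train)
    if A.sum() == 0:
        raise ValueError("training set is empty")
    S = same_side_similarity(A, side=side, metric=metric)
    scores = S @ A if side == "v" else A @ S
    return ProjectionScores(method=metric.lower(), scores=scores)


def nbi_scores(split: EdgeSplit) -> ProjectionScores:
    """Network-Based Inference: two-step resource allocation.

    For a target V-node, unit resource sits on each of its training
    W-neighbours; each W-node splits its resource equally among its
    V-neighbours, then each V-node splits equally among its W-neighbours.
    The resource arriving on w_j is the score.  In matrix form
    ``scores = A D_W⁻¹ Aᵀ D_V⁻¹ A``, with zero-degree nodes contributing
    nothing.
    """
    A = _dense(split.train)
    deg_v = A.sum(axis=1)
    deg_w = A.sum(axis=0)
    with np.errstate(divide="ignore"):
        inv_v = np.where(deg_v > 0, 1.0 / np.maximum(deg_v, 1e-300), 0.0)
        inv_w = np.where(deg_w > 0, 1.0 / np.maximum(deg_w, 1e-300), 0.0)
    scores = (A * inv_w[None, :]) @ A.T @ (A * inv_v[:, None])
    return ProjectionScores(method="nbi", scores=scores)
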