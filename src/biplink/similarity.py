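"""Bipartite similarity indices, including the Local Community Paradigm family.

For a candidate pair (x, y) with x on the V side and y on the W side, the
*common neighbours* are the nodes sitting on quadrangles through x and y:

* ``cn_v`` — V-side nodes u ≠ x adjacent to y that share at least one
  W-neighbour with x (formally N(y) ∩ N(N(x)));
* ``cn_w`` — W-side nodes w ≠ y adjacent to x that share at least one
  V-neighbour with y (formally N(x) ∩ N(N(y))).

The two sets are type-disjoint, so CN = |cn_v| + |cn_w|.  The Local
Community Paradigm (LCP) additionally counts LCL, the number of links
running between ``cn_v`` and ``cn_w`` — the internal connectivity of the
pair's local community — and |γ(z)|, the number of those links incident
to each common neighbour z.  The external degree e(x) counts neighbours
of x outside the local community.

Ten indices are provided: the neighbourhood counts CN, JC, AA, RA, PA
and their LCP counterparts CAR, CJC, CAA, CRA, CPA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

INDEX_NAMES = ("cn", "jc", "aa", "ra", "pa", "car", "cjc", "caa", "cra", "cpa")

__all__ = [
    "INDEX_NAMES",
    "LCPContext",
    "SimilarityMatrix",
    "lcp_context",
    "pair_score",
    "similarity_matrix",
]


def _normalize_index(name: str) -> str:
    low = str(name).lower()
    if low not in INDEX_NAMES:
        raise ValueError(
            f"unknown similarity index {name!r}; choose one of {', '.join(INDEX_NAMES)}"
        )
    return low


def _dense_binary(adj) -> np.ndarray:
    A = adj.toarray() if sp.issparse(adj) else np.asarray(adj, dtype=float)
    if A.size and not np.all((A == 0) | (A == 1)):
        raise ValueError("adjacency must be binary")
    return A.astype(bool)


@dataclass(frozen=True)
class LCPContext:
    """Local community of one candidate pair (x, y).

    Attributes
    ----------
    cn_v, cn_w : frozenset of int
        V-side and W-side common neighbours.
    lcl : int
        Number of links between ``cn_v`` and ``cn_w``.
    gamma : dict
        Local community degree |γ(z)| keyed by ``("v", u)`` / ``("w", w)``.
    e_x, e_y : int
        External degrees of x and y (neighbours outside the community).
    """

    cn_v: frozenset
    cn_w: frozenset
    lcl: int
    gamma: dict = field(hash=False)
    e_x: int
    e_y: int

    @property
    def cn(self) -> int:
        return len(self.cn_v) + len(self.cn_w)


@dataclass
class SimilarityMatrix:
    """Nonnegative n×m score matrix for one similarity index."""

    index_name: str
    S: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.index_name = _normalize_index(self.index_name)
        self.S = np.asarray(self.S, dtype=float)
        if not np.all(np.isfinite(self.S)):
            raise ValueError("similarity matrix contains non-finite entries")
        if (self.S < 0).any():
            raise ValueError("similarity matrix contains negative entries")

    def to_sparse(self) -> sp.csr_matrix:
        return sp.csr_matrix(self.S)


def lcp_context(adj, x: int, y: int) -> LCPContext:
    """Enumerate the local community of pair (x, y) on a training adjacency."""
    A = _dense_binary(adj)
    n, m = A.shape
    if not (0 <= x < n and 0 <= y < m):
        raise IndexError(f"pair ({x}, {y}) out of range for shape {A.shape}")
    nx = A[x]        # W-side neighbours of x (bool over m)
    ny = A[:, y]     # V-side neighbours of y (bool over n)
    # u in cn_v: u adjacent to y, u != x, and u shares a W-neighbour w != y
    # with x (quadrangle x-w-u-y; the endpoints themselves are not corners)
    nx_sans_y = nx.copy()
    nx_sans_y[y] = False
    shares_with_x = (A @ nx_sans_y.astype(int)) > 0
    cn_v_mask = ny & shares_with_x
    cn_v_mask[x] = False
    # w in cn_w: w adjacent to x, w != y, shares a V-neighbour u != x with y
    ny_sans_x = ny.copy()
    ny_sans_x[x] = False
    shares_with_y = (A.T @ ny_sans_x.astype(int)) > 0
    cn_w_mask = nx & shares_with_y
    cn_w_mask[y] = False

    sub = A[cn_v_mask][:, cn_w_mask]
    lcl = int(sub.sum())
    gamma: dict = {}
    v_ids = np.flatnonzero(cn_v_mask)
    w_ids = np.flatnonzero(cn_w_mask)
    for u, g in zip(v_ids, sub.sum(axis=1)):
        gamma[("v", int(u))] = int(g)
    for w, g in zip(w_ids, sub.sum(axis=0)):
        gamma[("w", int(w))] = int(g)
    return LCPContext(
        cn_v=frozenset(int(u) for u in v_ids),
        cn_w=frozenset(int(w) for w in w_ids),
        lcl=lcl,
        gamma=gamma,
        e_x=int(nx.sum()) - len(w_ids),
        e_y=int(ny.sum()) - len(v_ids),
    )


def _degree_weight(deg: int, log2: bool, warn: bool = False) -> float:
    """AA/CAA weight 1/log2(deg) or RA/CRA weight 1/deg; 0-weight guard for deg<=1."""
    if deg <= 1:
        if log2 and warn and deg == 1:
            logger.warning(
                "common neighbour with degree 1 encountered; its AA/CAA term is skipped"
            )
        return 0.0 if log2 else (1.0 / deg if deg == 1 else 0.0)
    return 1.0 / np.log2(deg) if log2 else 1.0 / deg


def pair_score(adj, x: int, y: int, index_name: str) -> float:
    """Similarity score of one pair under one of the ten indices."""
    name = _normalize_index(index_name)
    A = _dense_binary(adj)
    ctx = lcp_context(A, x, y)
    deg_v = A.sum(axis=1).astype(int)
    deg_w = A.sum(axis=0).astype(int)
    dx, dy = int(deg_v[x]), int(deg_w[y])

    if name == "pa":
        return float(dx * dy)
    if name == "cn":
        return float(ctx.cn)
    if name == "jc":
        union = dx + dy  # N(x) ⊆ W and N(y) ⊆ V are disjoint sets
        return ctx.cn / union if union else 0.0
    if name in ("aa", "ra"):
        log2 = name == "aa"
        total = sum(_degree_weight(int(deg_v[u]), log2, warn=True) for u in ctx.cn_v)
        total += sum(_degree_weight(int(deg_w[w]), log2, warn=True) for w in ctx.cn_w)
        return float(total)
    car = float(ctx.cn * ctx.lcl)
    if name == "car":
        return car
    if name == "cjc":
        union = dx + dy
        return car / union if union else 0.0
    if name in ("caa", "cra"):
        log2 = name == "caa"
        total = sum(
            ctx.gamma[("v", u)] * _degree_weight(int(deg_v[u]), log2, warn=True) for u in ctx.cn_v
        )
        total += sum(
            ctx.gamma[("w", w)] * _degree_weight(int(deg_w[w]), log2, warn=True) for w in ctx.cn_w
        )
        return float(total)
    # cpa
    return float(ctx.e_x * ctx.e_y + (ctx.e_x + ctx.e_y) * car + car * car)


def similarity_matrix(adj, index_name: str) -> SimilarityMatrix:
    """All-pairs similarity scores on a training adjacency.

    Scores are computed for every (i, j) pair, including observed
    training links — the regulariser of the factorization model sums
    over all pairs.  Matches :func:`pair_score` entrywise.
    """
    name = _normalize_index(index_name)
    A = _dense_binary(adj).astype(float)
    n, m = A.shape
    deg_v = A.sum(axis=1)
    deg_w = A.sum(axis=0)

    if name == "pa":
        return SimilarityMatrix(name, np.outer(deg_v, deg_w))

    # Shared-neighbour counts between same-side nodes, diagonal excluded.
    # Quadrangle semantics: when the pair (x, y) is itself linked, a
    # co-neighbour whose only shared node is the endpoint (shared count 1
    # and both adjacent to the endpoint) is not a quadrangle corner —
    # subtract those cases, which arise only on linked pairs.
    P = A @ A.T
    Q = A.T @ A
    C = (P > 0).astype(float)
    np.fill_diagonal(C, 0.0)
    E1 = (P == 1).astype(float)
    np.fill_diagonal(E1, 0.0)
    D = (Q > 0).astype(float)
    np.fill_diagonal(D, 0.0)
    F1 = (Q == 1).astype(float)
    np.fill_diagonal(F1, 0.0)

    cnv = C @ A - A * (E1 @ A)       # |cn_v| per pair
    cnw = A @ D - A * (A @ F1)       # |cn_w| per pair
    CN = cnv + cnw

    if name == "cn":
        return SimilarityMatrix(name, CN)
    union = deg_v[:, None] + deg_w[None, :]
    if name == "jc":
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(union > 0, CN / np.maximum(union, 1), 0.0)
        return SimilarityMatrix(name, S)
    if name in ("aa", "ra"):
        log2 = name == "aa"
        wv = np.array([_degree_weight(int(d), log2) for d in deg_v])
        ww = np.array([_degree_weight(int(d), log2) for d in deg_w])
        Sv = (C * wv[None, :]) @ A - A * ((E1 * wv[None, :]) @ A)
        Sw = A @ (D * ww[:, None]) - A * (A @ (F1 * ww[:, None]))
        S = np.maximum(Sv + Sw, 0.0)  # clip float roundoff of the subtraction
        return SimilarityMatrix(name, S)

    # LCP family: LCL and gamma sums need the community of each pair.
    # Only pairs with common neighbours on both sides can have LCL > 0.
    LCL = np.zeros((n, m))
    if name in ("caa", "cra"):
        log2 = name == "caa"
        wv = np.array([_degree_weight(int(d), log2) for d in deg_v])
        ww = np.array([_degree_weight(int(d), log2) for d in deg_w])
        G = np.zeros((n, m))  # Σ_z γ(z)·weight(z)
    Ab = A.astype(bool)
    cand_x, cand_y = np.nonzero((cnv > 0) & (cnw > 0))
    for x, y in zip(cand_x, cand_y):
        # shared counts with the endpoint's own contribution removed
        cn_v_mask = Ab[:, y] & ((P[x] - A[x, y] * A[:, y]) > 0)
        cn_v_mask[x] = False
        cn_w_mask = Ab[x] & ((Q[y] - A[x, y] * A[x]) > 0)
        cn_w_mask[y] = False
        sub = Ab[cn_v_mask][:, cn_w_mask]
        lcl = sub.sum()
        if lcl == 0:
            continue
        LCL[x, y] = lcl
        if name in ("caa", "cra"):
            G[x, y] = sub.sum(axis=1) @ wv[cn_v_mask] + sub.sum(axis=0) @ ww[cn_w_mask]

    CAR = CN * LCL
    if name == "car":
        return SimilarityMatrix(name, CAR)
    if name == "cjc":
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(union > 0, CAR / np.maximum(union, 1), 0.0)
        return SimilarityMatrix(name, S)
    if name in ("caa", "cra"):
        return SimilarityMatrix(name, G)
    # cpa: external degrees e(x) = |N(x)| - |cn_w|, e(y) = |N(y)| - |cn_v|
    ex = deg_v[:, None] - cnw
    ey = deg_w[None, :] - cnv
    S = ex * ey + (ex + ey) * CAR + CAR**2
    return SimilarityMatrix(name, S)
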