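"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written by direct enumeration or plain
dense algebra, structured differently from the library code it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_lcp_context(A: np.ndarray, x: int, y: int) -> dict:
    """Local community of (x, y) by explicit quadrangle enumeration.

    A quadrangle through x (V side) and y (W side) is a 4-cycle
    x - w - u - y with u ≠ x, w ≠ y.  Its corners u and w are the
    common neighbours.
    """
    A = np.asarray(A, dtype=int)
    n, m = A.shape
    cn_v: set[int] = set()
    cn_w: set[int] = set()
    for u in range(n):
        if u == x or A[u, y] == 0:
            continue
        for w in range(m):
            if w != y and A[x, w] and A[u, w]:
                cn_v.add(u)
                break
    for w in range(m):
        if w == y or A[x, w] == 0:
            continue
        for u in range(n):
            if u != x and A[u, y] and A[u, w]:
                cn_w.add(w)
                break
    lcl = 0
    gamma: dict = {}
    for u in cn_v:
        gamma[("v", u)] = 0
    for w in cn_w:
        gamma[("w", w)] = 0
    for u in cn_v:
        for w in cn_w:
            if A[u, w]:
                lcl += 1
                gamma[("v", u)] += 1
                gamma[("w", w)] += 1
    return {
        "cn_v": cn_v,
        "cn_w": cn_w,
        "lcl": lcl,
        "gamma": gamma,
        "e_x": int(A[x].sum()) - len(cn_w),
        "e_y": int(A[:, y].sum()) - len(cn_v),
    }


def brute_pair_score(A: np.ndarray, x: int, y: int, name: str) -> float:
    """Evaluate one similarity index from the enumerated local community.

    Degree-1 common neighbours contribute 0 to the log-weighted indices
    (AA/CAA), matching the library's guard convention.
    """
    A = np.asarray(A, dtype=int)
    ctx = brute_lcp_context(A, x, y)
    deg_v = A.sum(axis=1)
    deg_w = A.sum(axis=0)
    dx, dy = int(deg_v[x]), int(deg_w[y])
    cn = len(ctx["cn_v"]) + len(ctx["cn_w"])
    union = dx + dy
    car = cn * ctx["lcl"]
    name = name.lower()
    if name == "cn":
        return float(cn)
    if name == "jc":
        return cn / union if union else 0.0
    if name == "pa":
        return float(dx * dy)
    if name == "car":
        return float(car)
    if name == "cjc":
        return car / union if union else 0.0
    if name == "cpa":
        ex, ey = ctx["e_x"], ctx["e_y"]
        return float(ex * ey + ex * car + ey * car + car * car)
    total = 0.0
    for u in ctx["cn_v"]:
        d = int(deg_v[u])
        total += _oracle_term(name, d, ctx["gamma"][("v", u)])
    for w in ctx["cn_w"]:
        d = int(deg_w[w])
        total += _oracle_term(name, d, ctx["gamma"][("w", w)])
    return total


def _oracle_term(name: str, deg: int, gamma: int) -> float:
    if name == "aa":
        return 0.0 if deg <= 1 else 1.0 / math.log2(deg)
    if name == "ra":
        return 1.0 / deg
    if name == "caa":
        return 0.0 if deg <= 1 else gamma / math.log2(deg)
    if name == "cra":
        return gamma / deg
    raise ValueError(name)


def plain_nmf_trace(A: np.ndarray, X0: np.ndarray, Y0: np.ndarray,
                    n_iter: int, eps: float = 1e-12) -> list:
    """Plain Euclidean multiplicative-update NMF, dense, alternating X then Y.

    Returns the ½‖A−XY‖² objective before each update and after the last.
    """
    A = np.asarray(A, dtype=float)
    X = np.array(X0, dtype=float)
    Y = np.array(Y0, dtype=float)

    def obj() -> float:
        R = A - np.dot(X, Y)
        return 0.5 * float((R * R).sum())

    trace = [obj()]
    for _ in range(n_iter):
        X = X * np.dot(A, Y.T) / (np.dot(np.dot(X, Y), Y.T) + eps)
        Y = Y * np.dot(X.T, A) / (np.dot(np.dot(X.T, X), Y) + eps)
        trace.append(obj())
    return trace


def rank_auc(probe_scores: np.ndarray, nonexistent_scores: np.ndarray) -> float:
    """Exhaustive AUC via the Mann–Whitney rank statistic."""
    from scipy.stats import rankdata

    p = np.asarray(probe_scores, dtype=float)
    q = np.asarray(nonexistent_scores, dtype=float)
    ranks = rankdata(np.concatenate([p, q]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * q.size))
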