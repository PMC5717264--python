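"""Bipartite network data model, text I/O, train/probe splitting, degree statistics.

A bipartite network G(V, W, E) has two disjoint node sets and links only
between sets.  It is held as a binary biadjacency matrix ``A`` with ``n``
rows (V side) and ``m`` columns (W side): ``A[i, j] == 1`` iff node
``v_i`` is linked to ``w_j``.  Node identity lives in the ordered label
lists; matrix indices are 0-based and assigned by first appearance when
reading edge lists.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "BipartiteNetwork",
    "EdgeSplit",
    "NetworkStats",
    "read_edgelist",
    "write_edgelist",
    "read_biadjacency",
    "write_biadjacency",
    "split_edges",
    "degree_stats",
    "degree_stats_from_counts",
]


def _as_binary_csr(A) -> sp.csr_matrix:
    """Coerce to a 0/1 float CSR matrix, rejecting anything non-binary."""
    M = sp.csr_matrix(A, dtype=float)
    M.eliminate_zeros()
    if M.nnz and not np.all(M.data == 1.0):
        raise ValueError("biadjacency matrix must be binary (0/1 entries)")
    return M


@dataclass
class BipartiteNetwork:
    """An undirected, unweighted bipartite network.

    Parameters
    ----------
    v_labels : sequence of str
        Ordered identifiers of the V-side nodes (matrix rows).
    w_labels : sequence of str
        Ordered identifiers of the W-side nodes (matrix columns).
    A : sparse or dense matrix
        Binary biadjacency matrix of shape ``(len(v_labels), len(w_labels))``.
    """

    v_labels: list
    w_labels: list
    A: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        self.v_labels = list(self.v_labels)
        self.w_labels = list(self.w_labels)
        if len(self.v_labels) < 1 or len(self.w_labels) < 1:
            raise ValueError("both node sets must be nonempty")
        if len(set(self.v_labels)) != len(self.v_labels):
            raise ValueError("duplicate labels on the V side")
        if len(set(self.w_labels)) != len(self.w_labels):
            raise ValueError("duplicate labels on the W side")
        self.A = _as_binary_csr(self.A)
        if self.A.shape != (len(self.v_labels), len(self.w_labels)):
            raise ValueError(
                f"matrix shape {self.A.shape} does not match label counts "
                f"({len(self.v_labels)}, {len(self.w_labels)})"
            )

    # -- basic queries -------------------------------------------------
    @property
    def n(self) -> int:
        """Number of V-side nodes."""
        return len(self.v_labels)

    @property
    def m(self) -> int:
        """Number of W-side nodes."""
        return len(self.w_labels)

    @property
    def n_edges(self) -> int:
        return int(self.A.nnz)

    def edges(self) -> Iterator[tuple[int, int]]:
        """Yield (row, col) index pairs in row-major order."""
        coo = sp.coo_matrix(self.A)
        order = np.lexsort((coo.col, coo.row))
        for i, j in zip(coo.row[order], coo.col[order]):
            yield int(i), int(j)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (
            self.v_labels == other.v_labels
            and self.w_labels == other.w_labels
            and (self.A != other.A).nnz == 0
        )


@dataclass
class EdgeSplit:
    """Disjoint train/probe partition of the observed links.

    ``train + probe`` equals the full biadjacency elementwise; both carry
    the shape of the original matrix so isolated nodes keep their rows
    and columns.
    """

    train: sp.csr_matrix = field(repr=False)
    probe: sp.csr_matrix = field(repr=False)
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        self.train = _as_binary_csr(self.train)
        self.probe = _as_binary_csr(self.probe)
        if self.train.shape != self.probe.shape:
            raise ValueError("train and probe matrices must share a shape")
        if (self.train.multiply(self.probe)).nnz != 0:
            raise ValueError("train and probe sets must be disjoint")

    @property
    def shape(self) -> tuple[int, int]:
        return self.train.shape

    @property
    def n_train(self) -> int:
        return int(self.train.nnz)

    @property
    def n_probe(self) -> int:
        return int(self.probe.nnz)

    @property
    def full(self) -> sp.csr_matrix:
        """The original adjacency, reassembled."""
        return _as_binary_csr(self.train + self.probe)


@dataclass(frozen=True)
class NetworkStats:
    """Size and density summary of a bipartite network.

    ``ld`` is the link density |E|/(|V||W|), ``ad`` the average degree
    |E|/(|V|+|W|), and ``lad``/``rad`` the side-wise average degrees
    |E|/|V| and |E|/|W|.
    """

    n_v: int
    n_w: int
    n_e: int
    ld: float
    ad: float
    lad: float
    rad: float


def degree_stats_from_counts(n_v: int, n_w: int, n_e: int) -> NetworkStats:
    """Descriptive statistics from raw node/edge counts."""
    if n_v < 1 or n_w < 1:
        raise ValueError("node counts must be positive")
    return NetworkStats(
        n_v=n_v,
        n_w=n_w,
        n_e=n_e,
        ld=n_e / (n_v * n_w),
        ad=n_e / (n_v + n_w),
        lad=n_e / n_v,
        rad=n_e / n_w,
    )


def degree_stats(net: BipartiteNetwork) -> NetworkStats:
    """Descriptive statistics of a network (full precision; round at display)."""
    return degree_stats_from_counts(net.n, net.m, net.n_edges)


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def read_edgelist(path, delimiter: str | None = None) -> BipartiteNetwork:
    """Read a two-column edge list into a :class:`BipartiteNetwork`.

    One edge per line: V-side label, W-side label.  ``delimiter=None``
    splits on any whitespace.  Lines starting with ``#`` and blank lines
    are ignored.  Duplicate edges collapse to a single link; node indices
    follow first appearance.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"edge list not found: {path}")
    v_index: dict = {}
    w_index: dict = {}
    rows: list[int] = []
    cols: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)} "
                    f"({line!r}); weighted or malformed input is not supported"
                )
            a, b = fields
            if a not in v_index:
                v_index[a] = len(v_index)
            if b not in w_index:
                w_index[b] = len(w_index)
            rows.append(v_index[a])
            cols.append(w_index[b])
    if not rows:
        raise ValueError(f"{path}: no edges found (empty or all-comment file)")
    n, m = len(v_index), len(w_index)
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, m))
    A.data[:] = 1.0  # collapse duplicate rows
    return BipartiteNetwork(list(v_index), list(w_index), A)


def write_edgelist(net: BipartiteNetwork, path, delimiter: str = "\t") -> None:
    """Write one edge per line (V label, W label), row-major over ``A``."""
    with open(path, "w") as fh:
        for i, j in net.edges():
            fh.write(f"{net.v_labels[i]}{delimiter}{net.w_labels[j]}\n")


def read_biadjacency(path) -> BipartiteNetwork:
    """Read a sparse biadjacency in coordinate text form.

    First non-comment line is ``n m``; each following line is a 0-based
    ``i j`` pair.  Labels are generated as ``v{i}`` / ``w{j}``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"matrix file not found: {path}")
    header = None
    rows: list[int] = []
    cols: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 integers")
            a, b = int(fields[0]), int(fields[1])
            if header is None:
                header = (a, b)
            else:
                rows.append(a)
                cols.append(b)
    if header is None:
        raise ValueError(f"{path}: missing 'n m' header line")
    n, m = header
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, m))
    A.data[:] = 1.0
    return BipartiteNetwork([f"v{i}" for i in range(n)], [f"w{j}" for j in range(m)], A)


def write_biadjacency(net: BipartiteNetwork, path) -> None:
    """Write the coordinate text form read by :func:`read_biadjacency`."""
    with open(path, "w") as fh:
        fh.write(f"{net.n} {net.m}\n")
        for i, j in net.edges():
            fh.write(f"{i} {j}\n")


# ---------------------------------------------------------------------------
# Train/probe splitting
# ---------------------------------------------------------------------------

def split_edges(net: BipartiteNetwork, train_fraction: float, seed: int) -> EdgeSplit:
    """Randomly partition the observed links into train and probe sets.

    The training set receives ``round(train_fraction * |E|)`` links
    (ties-to-even), drawn uniformly without replacement; the rest form
    the probe set.  Deterministic for a fixed seed.  Both matrices keep
    the full shape of ``A`` (isolated nodes are not pruned).
    """
    if not (0.0 < train_fraction <= 1.0):
        raise ValueError(f"train_fraction must lie in (0, 1], got {train_fraction}")
    n_e = net.n_edges
    if n_e < 1:
        raise ValueError("cannot split a network with no edges")
    edges = np.array(list(net.edges()), dtype=int)
    n_train = int(np.round(train_fraction * n_e))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_e)
    train_idx, probe_idx = perm[:n_train], perm[n_train:]

    def _build(idx: np.ndarray) -> sp.csr_matrix:
        if len(idx) == 0:
            return sp.csr_matrix(net.A.shape)
        e = edges[idx]
        return sp.csr_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=net.A.shape
        )

    return EdgeSplit(
        train=_build(train_idx),
        probe=_build(probe_idx),
        train_fraction=train_fraction,
        seed=seed,
    )
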