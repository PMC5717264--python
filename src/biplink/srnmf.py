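"""Similarity-regularized nonnegative matrix factorization (SRNMF).

The model approximates a binary training biadjacency ``A`` (n×m) by a
product of nonnegative latent factors, ``A ≈ XY`` with ``X`` (n×K) and
``Y`` (K×m), while a similarity matrix ``S`` built from the training
topology pulls the reconstruction towards agreeing with ``A`` most
strongly on pairs the local structure already deems similar.  The
objective minimised is

    O = ½ Σ_ij (A_ij − (XY)_ij)²
      + ½ γ Σ_ij (A_ij − (XY)_ij)² S_ij
      + ½ λ (‖X‖_F² + ‖Y‖_F²)

with γ, λ ≥ 0.  The λ-term is the standard variational surrogate of the
nuclear norm ‖XY‖_*, so large λ drives the solution low-rank.  The
objective is minimised by alternating multiplicative updates

    x_ik ← x_ik · [A Yᵀ + γ (S∘A) Yᵀ]_ik / [X Y Yᵀ + γ (S∘(XY)) Yᵀ + λX]_ik
    y_kj ← y_kj · [Xᵀ A + γ Xᵀ(S∘A)]_kj / [XᵀX Y + γ Xᵀ(S∘(XY)) + λY]_kj

(∘ elementwise), which preserve nonnegativity and do not increase the
objective.  Products are arranged so that the dense n×m reconstruction
is never materialised: ``XYYᵀ`` goes through the K×K Gram matrix and
``S∘(XY)`` is evaluated only on the sparse support of S, giving a per-
iteration cost linear in the number of stored similarity/adjacency
entries times K.

With γ = 0 the model reduces to Frobenius-regularized NMF and with
γ = λ = 0 to plain Euclidean (Lee–Seung) NMF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .network import EdgeSplit
from .similarity import SimilarityMatrix, similarity_matrix

__all__ = [
    "SRNMFConfig",
    "LatentFactors",
    "ScoreMatrix",
    "SRNMF",
    "SRNMFResults",
    "select_k",
    "init_factors",
    "objective",
    "update_step",
    "predict_scores",
]


@dataclass(frozen=True)
class SRNMFConfig:
    """Hyperparameters of the SRNMF model.

    gamma : weight of the similarity-regularized residual term (default 1/2).
    lam : weight of the Frobenius/nuclear-norm term (default 2).
    k : latent dimension, or "auto" to choose it from the spectrum of the
        training adjacency (95% cumulative contribution).
    max_iter : iteration cap for the multiplicative updates.
    tol : relative objective-change stopping threshold.
    eps : small additive guard on update denominators.
    """

    gamma: float = 0.5
    lam: float = 2.0
    k: int | str = "auto"
    max_iter: int = 300
    tol: float = 1e-6
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.lam < 0:
            raise ValueError("gamma and lam must be nonnegative")
        if isinstance(self.k, str):
            if self.k != "auto":
                raise ValueError("k must be a positive integer or 'auto'")
        elif self.k < 1:
            raise ValueError("k must be a positive integer or 'auto'")
        if self.tol <= 0 or self.eps <= 0:
            raise ValueError("tol and eps must be positive")
        if self.max_iter < 0:
            raise ValueError("max_iter must be nonnegative")


@dataclass
class LatentFactors:
    """Nonnegative factor pair with fit metadata."""

    X: np.ndarray = field(repr=False)
    Y: np.ndarray = field(repr=False)
    objective_trace: list = field(default_factory=list)
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2 or self.X.shape[1] != self.Y.shape[0]:
            raise ValueError("factor shapes do not conform")
        if (self.X < 0).any() or (self.Y < 0).any():
            raise ValueError("factors must be nonnegative")

    @property
    def k(self) -> int:
        return self.X.shape[1]


@dataclass
class ScoreMatrix:
    """Predicted scores A* = XY with a candidate mask (1 off the training edges)."""

    A_star: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)

    def candidate_scores(self) -> np.ndarray:
        return self.A_star[self.mask.astype(bool)]


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def select_k(adj, threshold: float = 0.95) -> int:
    """Latent dimension by cumulative spectral contribution.

    Returns the smallest K such that the top-K squared singular values of
    the training adjacency carry at least ``threshold`` of the total
    squared spectrum (principal-component style variance criterion,
    uncentered to respect the nonnegative matrix semantics).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    A = adj.toarray() if sp.issparse(adj) else np.asarray(adj, dtype=float)
    if not A.any():
        raise ValueError("cannot select a latent dimension for an all-zero adjacency")
    sv = scipy.linalg.svd(A, compute_uv=False)
    energy = sv**2
    frac = np.cumsum(energy) / energy.sum()
    # float roundoff can leave the last entry at 1 - 1e-16
    frac[-1] = 1.0
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


def init_factors(n: int, m: int, k: int, seed: int) -> LatentFactors:
    """Uniform(0,1) strictly-positive initialization, deterministic per seed."""
    if k > min(n, m):
        warnings.warn(
            f"latent dimension k={k} exceeds min(n, m)={min(n, m)}; "
            "the factorization is over-complete",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, k))
    Y = rng.uniform(size=(k, m))
    return LatentFactors(X=X, Y=Y)


def _csr(M) -> sp.csr_matrix:
    return M.tocsr() if sp.issparse(M) else sp.csr_matrix(np.asarray(M, dtype=float))


def _xy_at(X: np.ndarray, Y: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Entries of XY at given coordinates without forming the full product."""
    if len(rows) == 0:
        return np.zeros(0)
    return np.einsum("ik,ik->i", X[rows], Y[:, cols].T)


def objective(adj, S, X, Y, gamma: float, lam: float) -> float:
    """Evaluate the SRNMF objective (see module docstring).

    ``adj`` and ``S`` may be sparse or dense; the reconstruction XY is
    only evaluated on their supports.
    """
    A = _csr(adj)
    Sm = S.to_sparse() if isinstance(S, SimilarityMatrix) else _csr(S)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if A.shape != Sm.shape or X.shape[0] != A.shape[0] or Y.shape[1] != A.shape[1]:
        raise ValueError("shape mismatch between adjacency, similarity and factors")
    if (X < 0).any() or (Y < 0).any() or (Sm.data < 0).any():
        raise ValueError("factors and similarity must be nonnegative")

    G = X.T @ X
    H = Y @ Y.T
    xy_norm2 = float(np.sum(G * H))          # ‖XY‖_F² = tr(XᵀX · YYᵀ)
    Ac = A.tocoo()
    cross = float(np.dot(Ac.data, _xy_at(X, Y, Ac.row, Ac.col)))
    frob = float((Ac.data**2).sum()) - 2.0 * cross + xy_norm2
    # roundoff can push an exact fit a hair below zero
    frob = max(frob, 0.0)

    reg = 0.0
    if gamma != 0.0 and Sm.nnz:
        Sc = Sm.tocoo()
        a_at_s = np.asarray(A[Sc.row, Sc.col]).ravel()
        resid = a_at_s - _xy_at(X, Y, Sc.row, Sc.col)
        reg = float(np.dot(Sc.data, resid**2))

    return 0.5 * frob + 0.5 * gamma * reg + 0.5 * lam * (
        float((X**2).sum()) + float((Y**2).sum())
    )


def _check_finite(M: np.ndarray, term: str) -> None:
    if not np.all(np.isfinite(M)):
        raise FloatingPointError(f"non-finite values appeared in {term}")


def update_step(adj, S, factors: LatentFactors, gamma: float, lam: float,
                eps: float = 1e-12) -> LatentFactors:
    """One alternating multiplicative update (X first, then Y seeing the new X)."""
    A = _csr(adj)
    Sm = S.to_sparse() if isinstance(S, SimilarityMatrix) else _csr(S)
    X, Y = factors.X, factors.Y
    Sc = Sm.tocoo()
    SA = Sm.multiply(A).tocsr()

    def s_hadamard_xy(Xc: np.ndarray, Yc: np.ndarray) -> sp.csr_matrix:
        vals = Sc.data * _xy_at(Xc, Yc, Sc.row, Sc.col)
        return sp.csr_matrix((vals, (Sc.row, Sc.col)), shape=Sm.shape)

    # X update
    num = (A @ Y.T) + gamma * (SA @ Y.T)
    den = X @ (Y @ Y.T) + gamma * (s_hadamard_xy(X, Y) @ Y.T) + lam * X
    X_new = X * num / (den + eps)
    _check_finite(X_new, "the X update (A·Yᵀ terms over XYYᵀ terms)")

    # Y update with the fresh X
    num = (A.T @ X_new).T + gamma * (SA.T @ X_new).T
    den = (X_new.T @ X_new) @ Y + gamma * (
        (s_hadamard_xy(X_new, Y).T @ X_new).T
    ) + lam * Y
    Y_new = Y * num / (den + eps)
    _check_finite(Y_new, "the Y update (Xᵀ·A terms over XᵀXY terms)")

    return LatentFactors(X=X_new, Y=Y_new,
                         objective_trace=factors.objective_trace,
                         n_iter=factors.n_iter)


def predict_scores(factors: LatentFactors, split: EdgeSplit) -> ScoreMatrix:
    """Reconstructed scores A* = XY with training edges masked out of the candidates."""
    A_star = factors.X @ factors.Y
    if A_star.shape != split.shape:
        raise ValueError(
            f"factor product shape {A_star.shape} does not match split shape {split.shape}"
        )
    mask = np.ones(split.shape)
    mask[split.train.toarray().astype(bool)] = 0.0
    return ScoreMatrix(A_star=A_star, mask=mask)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class SRNMF:
    """Similarity-regularized NMF link-prediction model.

    Parameters
    ----------
    train : sparse/dense binary matrix or :class:`~biplink.network.EdgeSplit`
        Training biadjacency.  Only training links enter the model —
        the similarity matrix is built from them alone, so held-out
        probe links never leak into the fit.
    similarity : str
        One of the ten index names ("cn", "jc", "aa", "ra", "pa",
        "car", "cjc", "caa", "cra", "cpa"), or ``None`` to drop the
        similarity term entirely (plain regularized NMF).
    config : SRNMFConfig, optional
        Hyperparameters; keyword overrides are applied on top.
    """

    def __init__(self, train, similarity: str | None = "cn",
                 config: SRNMFConfig | None = None, **overrides):
        if isinstance(train, EdgeSplit):
            self.split: EdgeSplit | None = train
            self.train = train.train
        else:
            self.split = None
            self.train = _csr(train)
        if self.train.nnz == 0:
            raise ValueError("training adjacency has no edges")
        self.config = replace(config or SRNMFConfig(), **overrides)
        self.similarity = None if similarity is None else str(similarity).lower()
        if self.similarity is None:
            n, m = self.train.shape
            self.S: SimilarityMatrix | sp.csr_matrix = sp.csr_matrix((n, m))
        else:
            self.S = similarity_matrix(self.train, self.similarity)

    @classmethod
    def from_split(cls, split: EdgeSplit, similarity: str | None = "cn",
                   config: SRNMFConfig | None = None, **overrides) -> "SRNMF":
        return cls(split, similarity=similarity, config=config, **overrides)

    @property
    def k_(self) -> int:
        """Resolved latent dimension (spectral selection when k='auto')."""
        if isinstance(self.config.k, str):
            return select_k(self.train)
        return int(self.config.k)

    def fit(self, seed: int = 0, init: LatentFactors | None = None) -> "SRNMFResults":
        """Run the multiplicative updates to (local) convergence.

        Stops when the relative objective change drops below ``tol`` or
        after ``max_iter`` iterations.  Deterministic for a fixed seed.
        """
        cfg = self.config
        n, m = self.train.shape
        k = self.k_
        factors = init if init is not None else init_factors(n, m, k, seed)
        trace = [objective(self.train, self.S, factors.X, factors.Y,
                           cfg.gamma, cfg.lam)]
        converged = False
        it = 0
        for it in range(1, cfg.max_iter + 1):
            factors = update_step(self.train, self.S, factors,
                                  cfg.gamma, cfg.lam, cfg.eps)
            trace.append(objective(self.train, self.S, factors.X, factors.Y,
                                   cfg.gamma, cfg.lam))
            prev, cur = trace[-2], trace[-1]
            if abs(prev - cur) <= cfg.tol * max(abs(prev), 1e-30):
                converged = True
                break
        factors = LatentFactors(X=factors.X, Y=factors.Y,
                                objective_trace=list(trace),
                                n_iter=it if cfg.max_iter else 0)
        return SRNMFResults(self, factors, converged=converged, seed=seed)


class SRNMFResults:
    """Fitted SRNMF factors plus diagnostics.

    Attributes
    ----------
    factors : LatentFactors
        Nonnegative X (n×K) and Y (K×m) with the objective trace.
    converged : bool
        Whether the relative-change stopping rule fired before max_iter.
    """

    def __init__(self, model: SRNMF, factors: LatentFactors,
                 converged: bool, seed: int):
        self.model = model
        self.factors = factors
        self.converged = converged
        self.seed = seed

    # convenient aliases
    @property
    def X(self) -> np.ndarray:
        return self.factors.X

    @property
    def Y(self) -> np.ndarray:
        return self.factors.Y

    @property
    def objective_trace(self) -> list:
        return self.factors.objective_trace

    @property
    def n_iter(self) -> int:
        return self.factors.n_iter

    def predict(self) -> np.ndarray:
        """Reconstructed score matrix A* = XY."""
        return self.X @ self.Y

    def score_matrix(self, split: EdgeSplit | None = None) -> ScoreMatrix:
        """A* with the training edges masked out of the candidate set."""
        split = split or self.model.split
        if split is None:
            n, m = self.model.train.shape
            split = EdgeSplit(train=self.model.train,
                              probe=sp.csr_matrix((n, m)),
                              train_fraction=1.0, seed=self.seed)
        return predict_scores(self.factors, split)

    def summary(self) -> str:
        cfg = self.model.config
        sim = self.model.similarity or "none"
        n, m = self.model.train.shape
        lines = [
            "SRNMF results",
            "=" * 46,
            f"{'network size':<24}{n} x {m}",
            f"{'training links':<24}{self.model.train.nnz}",
            f"{'similarity index':<24}{sim}",
            f"{'latent dimension K':<24}{self.factors.k}",
            f"{'gamma':<24}{cfg.gamma:g}",
            f"{'lambda':<24}{cfg.lam:g}",
            f"{'iterations':<24}{self.n_iter}",
            f"{'converged':<24}{self.converged}",
            f"{'initial objective':<24}{self.objective_trace[0]:.6g}",
            f"{'final objective':<24}{self.objective_trace[-1]:.6g}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_objective(self, ax=None):
        """Objective trace across iterations (semilog-y)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(range(len(self.objective_trace)), self.objective_trace,
                    marker=".", lw=1)
        ax.set_xlabel("iteration")
        ax.set_ylabel("objective")
        sim = self.model.similarity or "none"
        ax.set_title(f"SRNMF-{sim.upper()} objective trace")
        return ax
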