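"""Graph regularization for the broad learning system.

Two binary k-nearest-neighbour graphs are built on the training samples:

* the *intrinsic* graph connects same-label neighbour pairs; minimizing
  Tr(Yhat^T L_w Yhat) pulls the predictions of similar same-class samples
  together;
* the *penalty* graph connects different-label neighbour pairs; its
  Laplacian is used as an inverse-square-root whitening, pushing the
  predictions of nearby different-class samples apart.

The composed regularizer is

    L = B^T L_w B,   B = (L_p + zeta I)^(-1/2),

where zeta > 0 is a small diagonal disturbance making L_p invertible. The
graph-regularized output weights solve

    min_W  ||Y - A W||^2 + lambda1 Tr((A W)^T L (A W)) + lambda2 ||W||^2
    =>  W = (A^T A + lambda1 A^T L A + lambda2 I)^(-1) A^T Y.

Graphs are built once per training set in the raw input-feature space
(Euclidean distance), independent of the evolving node parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .bls import _solve_spd
from .errors import DimensionError, ParameterError, ValidationError


@dataclass
class NeighborGraphSpec:
    """Configuration of the intrinsic/penalty graphs and their weights.

    k1/k2 are the neighbour counts of the intrinsic and penalty graphs,
    zeta the diagonal disturbance, lambda1/lambda2 the weights of the graph
    and ridge terms of the objective.

    Note on the lambda1 scale: when the penalty graph is sparse (well
    separated classes) the composed regularizer is close to L_w / zeta, so
    the graph term is effectively amplified by 1/zeta. The default
    lambda1 = 1e-4 with zeta = 1e-5 therefore weights the raw intrinsic
    Laplacian by roughly 10 - heavy relative to the ridge term, without
    drowning the data-fit term and dragging every score below the fixed
    0.5 decision threshold.
    """

    k1: int = 5
    k2: int = 5
    zeta: float = 1e-5
    lambda1: float = 1e-4
    lambda2: float = 0.1

    def validate(self, n_samples: int | None = None) -> None:
        if self.k1 < 1 or self.k2 < 1:
            raise ParameterError("neighbour counts k1, k2 must be >= 1")
        if n_samples is not None and (self.k1 >= n_samples or self.k2 >= n_samples):
            raise ParameterError(
                f"neighbour counts must be < number of samples ({n_samples})"
            )
        if self.zeta <= 0:
            raise ParameterError("zeta must be > 0")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ParameterError("lambda1, lambda2 must be >= 0")


@dataclass
class GraphOperators:
    """Adjacencies, Laplacians and the composed regularizer for one dataset."""

    V_w: np.ndarray
    V_p: np.ndarray
    L_w: np.ndarray
    L_p: np.ndarray
    L_ipgbls: np.ndarray


def build_neighbor_graph(
    X: np.ndarray,
    labels: np.ndarray,
    k: int,
    mode: str,
) -> np.ndarray:
    """Binary symmetric kNN adjacency under a label condition.

    V_ij = 1 iff the mode's label condition holds (``intrinsic``: same
    label; ``penalty``: different label) and x_i is among the k nearest
    neighbours of x_j or vice versa. Self-neighbours are excluded; distance
    ties are broken toward the lower sample index so graphs are
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise DimensionError(
            f"X has {X.shape[0]} rows but labels has {labels.shape[0]}"
        )
    N = X.shape[0]
    if k >= N:
        raise ParameterError(f"k={k} must be < number of samples N={N}")
    if mode not in ("intrinsic", "penalty"):
        raise ParameterError(f"mode must be 'intrinsic' or 'penalty', got {mode!r}")

    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    # stable sort => equal distances resolved toward the lower index
    order = np.argsort(d, axis=1, kind="stable")
    neighbour = np.zeros((N, N), dtype=bool)
    rows = np.repeat(np.arange(N), k)
    neighbour[rows, order[:, :k].ravel()] = True  # neighbour[i, j]: j in N_k(i)

    same = labels[:, None] == labels[None, :]
    cond = same if mode == "intrinsic" else ~same
    V = (cond & (neighbour | neighbour.T)).astype(float)
    np.fill_diagonal(V, 0.0)
    return V


def graph_laplacian(V: np.ndarray) -> np.ndarray:
    """Unnormalized Laplacian L = D - V with D the diagonal of row sums."""
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1] or not np.allclose(V, V.T):
        raise ValidationError("adjacency must be a square symmetric matrix")
    if (V < 0).any():
        raise ValidationError("adjacency entries must be nonnegative")
    return np.diag(V.sum(axis=1)) - V


def compose_ipgbls_laplacian(
    L_w: np.ndarray, L_p: np.ndarray, zeta: float
) -> np.ndarray:
    """Compose B^T L_w B with B = (L_p + zeta I)^(-1/2).

    The inverse square root is taken by symmetric eigendecomposition;
    eigenvalues of L_p + zeta I are clipped below at zeta/10 to guard
    against round-off negativity. The result is symmetrized.
    """
    L_w = np.asarray(L_w, dtype=float)
    L_p = np.asarray(L_p, dtype=float)
    if L_w.shape != L_p.shape:
        raise DimensionError(
            f"Laplacians must share a shape, got {L_w.shape} and {L_p.shape}"
        )
    if not np.allclose(L_w, L_w.T) or not np.allclose(L_p, L_p.T):
        raise ValidationError("Laplacians must be symmetric")
    if zeta <= 0:
        raise ParameterError(f"zeta must be > 0, got {zeta}")
    w, U = np.linalg.eigh(L_p + zeta * np.eye(L_p.shape[0]))
    w = np.clip(w, zeta / 10.0, None)
    B = (U * (w ** -0.5)) @ U.T
    L = B.T @ L_w @ B
    return (L + L.T) / 2.0


def build_graph_operators(
    X: np.ndarray, labels: np.ndarray, spec: NeighborGraphSpec
) -> GraphOperators:
    """Build both graphs and the composed regularizer for one training set."""
    spec.validate(n_samples=np.asarray(X).shape[0])
    V_w = build_neighbor_graph(X, labels, spec.k1, "intrinsic")
    V_p = build_neighbor_graph(X, labels, spec.k2, "penalty")
    L_w = graph_laplacian(V_w)
    L_p = graph_laplacian(V_p)
    L = compose_ipgbls_laplacian(L_w, L_p, spec.zeta)
    return GraphOperators(V_w, V_p, L_w, L_p, L)


def solve_gbls_weights(
    A: np.ndarray,
    Y: np.ndarray,
    L_ipgbls: np.ndarray,
    lambda1: float,
    lambda2: float,
) -> np.ndarray:
    """Graph-regularized closed-form output weights.

    W = (A^T A + lambda1 A^T L A + lambda2 I)^(-1) A^T Y. With lambda1 = 0
    this reduces exactly to the plain ridge solution.
    """
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if A.shape[0] != Y.shape[0]:
        raise DimensionError(f"A has {A.shape[0]} rows but Y has {Y.shape[0]}")
    if lambda1 < 0 or lambda2 < 0:
        raise ParameterError("lambda1, lambda2 must be >= 0")
    G = A.T @ A + lambda2 * np.eye(A.shape[1])
    if lambda1 != 0.0:
        G = G + lambda1 * (A.T @ np.asarray(L_ipgbls, dtype=float) @ A)
    return _solve_spd(G, A.T @ Y)


def write_edge_list(V: np.ndarray, path: str | Path) -> None:
    """Export an adjacency as plain-text edges ``i<TAB>j<TAB>weight`` (i < j)."""
    V = np.asarray(V)
    ii, jj = np.nonzero(np.triu(V, 1))
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{V[i, j]:g}\n")
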