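"""Broad learning system core.

A broad learning system (BLS) is a flat network: the input X (N samples x M
features) is mapped by n groups of k random *feature nodes*
Z_i = xi(X W_zi + alpha_zi), the concatenated feature block Z^n (N x nk) is
mapped once more by m random *enhancement nodes* H = eta(Z^n W_h + gamma_h),
and the state matrix A = [Z^n | H^m] is connected to the output by a single
weight matrix W solved in closed form by ridge regression:

    W = (A^T A + lambda I)^(-1) A^T Y.

Only W is trained; the node parameters are random. This module provides the
random parameter container (which doubles, flattened, as an individual of
the evolutionary optimizer), the state-matrix construction, the ridge solve,
prediction, and a versioned on-disk model bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .activations import get_activation
from .errors import DimensionError, ParameterError, SingularSystemError

_FORMAT_VERSION = 1


@dataclass
class BLSArchitecture:
    """Node-count configuration of a broad learning system.

    Parameters
    ----------
    n_feature_groups : int
        Number of feature-node groups (n). Each group applies its own random
        linear map to the input.
    nodes_per_group : int
        Nodes per feature group (k); the mapped feature block has n*k columns.
    n_enhancement : int
        Number of enhancement nodes (m).
    feature_activation, enhancement_activation : str
        Activation names (sigmoid, tanh, tansig, relu).
    """

    n_feature_groups: int = 2
    nodes_per_group: int = 5
    n_enhancement: int = 20
    feature_activation: str = "tanh"
    enhancement_activation: str = "sigmoid"

    def dim(self, n_inputs: int) -> int:
        """Flattened parameter dimension for inputs of width ``n_inputs``."""
        n, k, m = self.n_feature_groups, self.nodes_per_group, self.n_enhancement
        return n * k * (n_inputs + 1) + m * (n * k + 1)


@dataclass
class NodeParameterSet:
    """All random weights and biases of the feature and enhancement nodes.

    ``flatten`` / ``unflatten`` convert to and from a single 1-D vector of
    length n*k*(M+1) + m*(n*k+1), the representation used by the
    differential-evolution optimizer.
    """

    feature_weights: list[np.ndarray]  # n matrices, each (M, k)
    feature_biases: list[np.ndarray]  # n vectors, each (k,)
    enhancement_weights: np.ndarray  # (n*k, m)
    enhancement_biases: np.ndarray  # (m,)
    feature_activation: str = "tanh"
    enhancement_activation: str = "sigmoid"

    @property
    def n_feature_groups(self) -> int:
        return len(self.feature_weights)

    @property
    def nodes_per_group(self) -> int:
        return self.feature_weights[0].shape[1]

    @property
    def n_enhancement(self) -> int:
        return self.enhancement_weights.shape[1]

    @property
    def n_inputs(self) -> int:
        return self.feature_weights[0].shape[0]

    @property
    def dim(self) -> int:
        n, k, m, M = (
            self.n_feature_groups,
            self.nodes_per_group,
            self.n_enhancement,
            self.n_inputs,
        )
        return n * k * (M + 1) + m * (n * k + 1)

    def flatten(self) -> np.ndarray:
        """Concatenate all parameters into one float vector.

        Order: per feature group, W_z (row-major) then alpha_z; then the
        enhancement weights W_h (row-major) then gamma_h.
        """
        parts = []
        for W, a in zip(self.feature_weights, self.feature_biases):
            parts.append(W.ravel())
            parts.append(a.ravel())
        parts.append(self.enhancement_weights.ravel())
        parts.append(self.enhancement_biases.ravel())
        return np.concatenate(parts)

    @classmethod
    def unflatten(
        cls,
        theta: np.ndarray,
        n_inputs: int,
        arch: BLSArchitecture,
    ) -> "NodeParameterSet":
        """Inverse of :meth:`flatten` for a conforming architecture."""
        theta = np.asarray(theta, dtype=float).ravel()
        n, k, m = arch.n_feature_groups, arch.nodes_per_group, arch.n_enhancement
        M = n_inputs
        expected = arch.dim(M)
        if theta.size != expected:
            raise DimensionError(
                f"flattened vector has length {theta.size}, expected {expected} "
                f"for n={n}, k={k}, m={m}, M={M}"
            )
        pos = 0
        fw, fb = [], []
        for _ in range(n):
            fw.append(theta[pos : pos + M * k].reshape(M, k).copy())
            pos += M * k
            fb.append(theta[pos : pos + k].copy())
            pos += k
        ew = theta[pos : pos + n * k * m].reshape(n * k, m).copy()
        pos += n * k * m
        eb = theta[pos : pos + m].copy()
        return cls(fw, fb, ew, eb, arch.feature_activation, arch.enhancement_activation)


@dataclass
class BLSModel:
    """A trained broad learning model: node parameters plus output weights.

    ``graph_lambda`` is nonzero when the output weights were solved with the
    graph-regularized objective; prediction is identical either way.
    """

    params: NodeParameterSet
    output_weights: np.ndarray  # (nk+m, C)
    ridge_lambda: float
    graph_lambda: float = 0.0


def init_node_parameters(
    n: int,
    k: int,
    m: int,
    n_inputs: int,
    bounds: tuple[float, float] = (-1.0, 1.0),
    rng_seed: int | np.random.Generator | None = None,
    feature_activation: str = "tanh",
    enhancement_activation: str = "sigmoid",
) -> NodeParameterSet:
    """Draw all node weights and biases uniformly from ``bounds``.

    Reproducible for a fixed ``rng_seed``.
    """
    if min(n, k, m, n_inputs) < 1:
        raise DimensionError(
            f"all node counts must be >= 1, got n={n}, k={k}, m={m}, M={n_inputs}"
        )
    lo, hi = bounds
    if lo > hi:
        raise ParameterError(f"invalid bounds: low {lo} > high {hi}")
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    fw = [rng.uniform(lo, hi, size=(n_inputs, k)) for _ in range(n)]
    fb = [rng.uniform(lo, hi, size=k) for _ in range(n)]
    ew = rng.uniform(lo, hi, size=(n * k, m))
    eb = rng.uniform(lo, hi, size=m)
    return NodeParameterSet(fw, fb, ew, eb, feature_activation, enhancement_activation)


def build_state_matrix(X: np.ndarray, params: NodeParameterSet) -> np.ndarray:
    """Map inputs through feature then enhancement nodes: A = [Z^n | H^m].

    Column order is all feature-node columns in group order, then the
    enhancement columns. Deterministic given ``params``: permuting the rows
    of X permutes the rows of A identically.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.n_inputs:
        raise DimensionError(
            f"X must be 2-D with {params.n_inputs} columns, got shape {X.shape}"
        )
    xi = get_activation(params.feature_activation)
    eta = get_activation(params.enhancement_activation)
    Z = np.hstack(
        [
            xi(X @ W + a)
            for W, a in zip(params.feature_weights, params.feature_biases)
        ]
    )
    H = eta(Z @ params.enhancement_weights + params.enhancement_biases)
    return np.hstack([Z, H])


def _solve_spd(G: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve G W = rhs for symmetric positive-definite G via Cholesky."""
    try:
        c, low = scipy.linalg.cho_factor(G)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise SingularSystemError(
            "normal-equations matrix is singular or indefinite; use a "
            "strictly positive ridge weight (lambda > 0)"
        ) from exc
    return scipy.linalg.cho_solve((c, low), rhs)


def solve_output_weights(A: np.ndarray, Y: np.ndarray, ridge_lambda: float) -> np.ndarray:
    """Closed-form ridge output weights W = (A^T A + lambda I)^(-1) A^T Y.

    Minimizes ||Y - A W||_F^2 + lambda ||W||_F^2. With lambda = 0 the state
    Gram matrix must be nonsingular.
    """
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if A.shape[0] != Y.shape[0]:
        raise DimensionError(
            f"A has {A.shape[0]} rows but Y has {Y.shape[0]}"
        )
    if ridge_lambda < 0:
        raise ParameterError(f"ridge lambda must be >= 0, got {ridge_lambda}")
    G = A.T @ A + ridge_lambda * np.eye(A.shape[1])
    return _solve_spd(G, A.T @ Y)


def predict(
    model: BLSModel,
    X: np.ndarray,
    threshold: float = 0.5,
    positive_class: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Score samples and derive hard labels.

    Scores are the raw linear outputs Yhat = A W against one-hot targets.
    For two output columns the hard label is the positive (seizure) class
    iff its score is >= ``threshold``; a score exactly at the threshold is
    called positive, favouring sensitivity. For more than two columns the
    argmax is taken and ``threshold`` is ignored.

    Returns
    -------
    (scores, labels)
        ``scores`` is N x C; ``labels`` is an int vector of class indices.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"threshold must lie in [0, 1], got {threshold}")
    A = build_state_matrix(X, model.params)
    scores = A @ model.output_weights
    C = scores.shape[1]
    if C == 2:
        pos = (scores[:, positive_class] >= threshold)
        labels = np.where(pos, positive_class, 1 - positive_class)
    else:
        labels = scores.argmax(axis=1)
    return scores, labels.astype(int)


def save_model(model: BLSModel, path: str | Path) -> None:
    """Write a model bundle: ``meta.json`` + ``weights.npz`` in a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    p = model.params
    meta = {
        "format_version": _FORMAT_VERSION,
        "n_feature_groups": p.n_feature_groups,
        "nodes_per_group": p.nodes_per_group,
        "n_enhancement": p.n_enhancement,
        "n_inputs": p.n_inputs,
        "feature_activation": p.feature_activation,
        "enhancement_activation": p.enhancement_activation,
        "ridge_lambda": model.ridge_lambda,
        "graph_lambda": model.graph_lambda,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    arrays = {"output_weights": model.output_weights,
              "enhancement_weights": p.enhancement_weights,
              "enhancement_biases": p.enhancement_biases}
    for i, (W, a) in enumerate(zip(p.feature_weights, p.feature_biases)):
        arrays[f"feature_weights_{i}"] = W
        arrays[f"feature_biases_{i}"] = a
    np.savez(path / "weights.npz", **arrays)


def load_model(path: str | Path) -> BLSModel:
    """Read a model bundle written by :func:`save_model`."""
    from .errors import FormatError

    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("format_version") != _FORMAT_VERSION:
        raise FormatError(
            f"unsupported model bundle version {meta.get('format_version')!r}"
        )
    with np.load(path / "weights.npz") as z:
        n = meta["n_feature_groups"]
        params = NodeParameterSet(
            feature_weights=[z[f"feature_weights_{i}"] for i in range(n)],
            feature_biases=[z[f"feature_biases_{i}"] for i in range(n)],
            enhancement_weights=z["enhancement_weights"],
            enhancement_biases=z["enhancement_biases"],
            feature_activation=meta["feature_activation"],
            enhancement_activation=meta["enhancement_activation"],
        )
        W = z["output_weights"]
    return BLSModel(params, W, meta["ridge_lambda"], meta["graph_lambda"])
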