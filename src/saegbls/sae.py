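"""Self-adaptive differential evolution over broad-learning node parameters.

The random feature/enhancement node parameters of the graph-regularized
broad learning system are flattened into a vector theta and evolved by
differential evolution (DE). Four classic mutation strategies form a
*strategy pool*:

    St 1  DE/rand/1            v = t_r1 + F (t_r2 - t_r3)
    St 2  DE/rand-to-best/2    v = t_r1 + F (t_best - t_r1) + F (t_r2 - t_r3)
                                   + F (t_r4 - t_r5)
    St 3  DE/rand/2            v = t_r1 + F (t_r2 - t_r3) + F (t_r4 - t_r5)
    St 4  DE/current-to-rand/1 v = t_i + K (t_r1 - t_i) + F (t_r2 - t_r3)

During a *learning period* of LP generations each strategy is picked with
probability 1/4; afterwards the probabilities adapt to the success ratio

    s_l = sum(ns_l) / (sum(ns_l) + sum(nf_l)) + eps,   p_l = s_l / sum(s_l)

accumulated over a sliding window of the last LP generations, where ns/nf
count trial vectors produced by strategy l that did / did not enter the
next generation.

Fitness of an individual is the training RMSE of the closed-form
graph-regularized classifier it parameterizes,
RMSE = ||A W - Y||_F / sqrt(N C). Survivor selection keeps the trial vector
when it clearly improves the parent (relative tolerance eps_sel) or when it
is a near-tie with a smaller output-weight norm ||W||_F, which favours
better-generalizing solutions.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bls import BLSArchitecture, BLSModel, NodeParameterSet, build_state_matrix
from .errors import DimensionError, ParameterError, ValidationError
from .graphs import (
    GraphOperators,
    NeighborGraphSpec,
    build_graph_operators,
    solve_gbls_weights,
)

N_STRATEGIES = 4
# distinct non-self parent indices required by each strategy
_INDICES_NEEDED = {1: 3, 2: 5, 3: 5, 4: 3}


@dataclass
class SaEConfig:
    """Hyperparameters of the self-adaptive DE run.

    population_size (NP) must be >= 6 so that five mutually distinct
    non-self parents can be drawn. ``rmse_threshold`` <= 0 disables the
    early stop. ``epsilon_success`` is the small positive offset of the
    success-ratio update; ``epsilon_select`` the relative fault tolerance
    of survivor selection.
    """

    population_size: int = 20
    learning_period: int = 5
    max_generations: int = 50
    rmse_threshold: float = 0.0
    epsilon_success: float = 1e-2
    epsilon_select: float = 1e-3
    cr_mean: float = 0.5
    cr_sd: float = 0.3
    f_mean: float = 0.5
    f_sd: float = 0.1
    bounds: tuple[float, float] = (-1.0, 1.0)
    seed: int | None = None

    def validate(self) -> None:
        if self.population_size < 6:
            raise ParameterError(
                f"population size must be >= 6 (five distinct non-self parents "
                f"are drawn), got {self.population_size}"
            )
        if self.learning_period < 1:
            raise ParameterError("learning period must be >= 1")
        if self.max_generations < 0:
            raise ParameterError("max_generations must be >= 0")
        if self.epsilon_success <= 0 or self.epsilon_select < 0:
            raise ParameterError("epsilon_success must be > 0, epsilon_select >= 0")
        if self.bounds[0] > self.bounds[1]:
            raise ParameterError(f"invalid bounds {self.bounds}")


@dataclass
class Population:
    """DE individuals (rows), their fitness and output-weight norms."""

    individuals: np.ndarray  # (NP, D)
    fitness: np.ndarray  # (NP,)
    weight_norms: np.ndarray  # (NP,)
    generation: int = 0

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitness))

    @property
    def best_fitness(self) -> float:
        return float(self.fitness[self.best_index])

    @property
    def best_vector(self) -> np.ndarray:
        return self.individuals[self.best_index]


class StrategyMemory:
    """Sliding-window success/failure counts and strategy probabilities."""

    def __init__(self, learning_period: int, epsilon: float):
        if learning_period < 1:
            raise ParameterError("learning period must be >= 1")
        if epsilon <= 0:
            raise ParameterError("epsilon must be > 0")
        self.learning_period = learning_period
        self.epsilon = epsilon
        self.ns: deque[np.ndarray] = deque(maxlen=learning_period)
        self.nf: deque[np.ndarray] = deque(maxlen=learning_period)

    def record_generation(self, ns: np.ndarray, nf: np.ndarray) -> None:
        ns = np.asarray(ns, dtype=float)
        nf = np.asarray(nf, dtype=float)
        if ns.shape != (N_STRATEGIES,) or nf.shape != (N_STRATEGIES,):
            raise DimensionError(f"expected {N_STRATEGIES} per-strategy counts")
        if (ns < 0).any() or (nf < 0).any():
            raise ValidationError("success/failure counts must be nonnegative")
        self.ns.append(ns)
        self.nf.append(nf)

    def probabilities(self, generation: int) -> np.ndarray:
        """Strategy probabilities for the given (1-based) generation."""
        return update_probabilities(self, generation)


def update_probabilities(memory: StrategyMemory, generation: int) -> np.ndarray:
    """Per-strategy selection probabilities.

    Uniform 1/4 during the learning period (generation <= LP); afterwards
    proportional to the windowed success ratio plus the epsilon guard, so
    every probability stays strictly positive and the vector sums to 1.
    """
    if generation <= memory.learning_period or not memory.ns:
        return np.full(N_STRATEGIES, 1.0 / N_STRATEGIES)
    ns = np.sum(memory.ns, axis=0)
    nf = np.sum(memory.nf, axis=0)
    total = ns + nf
    ratio = np.divide(ns, total, out=np.zeros_like(ns, dtype=float), where=total > 0)
    s = ratio + memory.epsilon
    return s / s.sum()


def select_strategy(probabilities: np.ndarray, rng: np.random.Generator) -> int:
    """Roulette-sample a strategy index in {1, 2, 3, 4}."""
    p = np.asarray(probabilities, dtype=float)
    return int(rng.choice(N_STRATEGIES, p=p)) + 1


def initialize_population(
    config: SaEConfig, dim: int, rng: np.random.Generator | None = None
) -> Population:
    """Uniform random population theta = theta_min + rand*(theta_max - theta_min)."""
    config.validate()
    if dim < 1:
        raise DimensionError(f"dimension must be >= 1, got {dim}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    inds = lo + rng.random((config.population_size, dim)) * (hi - lo)
    nan = np.full(config.population_size, np.inf)
    return Population(inds, nan.copy(), nan.copy(), generation=0)


def mutate(
    pop: Population,
    i: int,
    strategy: int,
    F: float,
    K: float,
    rng: np.random.Generator,
    bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Build the mutant vector for individual ``i`` with the given strategy.

    Parent indices r1..r5 are drawn mutually distinct and different from
    ``i``. Entries leaving ``bounds`` are clipped to the bound.
    """
    if strategy not in _INDICES_NEEDED:
        raise ParameterError(f"strategy must be in 1..4, got {strategy}")
    NP = pop.individuals.shape[0]
    need = _INDICES_NEEDED[strategy]
    if NP - 1 < need:
        raise ParameterError(
            f"population of {NP} too small to draw {need} distinct non-self parents"
        )
    candidates = np.delete(np.arange(NP), i)
    r = rng.choice(candidates, size=need, replace=False)
    t = pop.individuals
    if strategy == 1:
        v = t[r[0]] + F * (t[r[1]] - t[r[2]])
    elif strategy == 2:
        best = pop.best_vector
        v = (
            t[r[0]]
            + F * (best - t[r[0]])
            + F * (t[r[1]] - t[r[2]])
            + F * (t[r[3]] - t[r[4]])
        )
    elif strategy == 3:
        v = t[r[0]] + F * (t[r[1]] - t[r[2]]) + F * (t[r[3]] - t[r[4]])
    else:  # strategy 4
        v = t[i] + K * (t[r[0]] - t[i]) + F * (t[r[1]] - t[r[2]])
    if bounds is not None:
        v = np.clip(v, bounds[0], bounds[1])
    return v


def crossover(
    parent: np.ndarray,
    mutant: np.ndarray,
    cr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial crossover with a guaranteed mutant component.

    Draw order (relied on by stream-replay tests): first ``j_rand`` via
    ``rng.integers(D)``, then the D uniform variates. Component j takes the
    mutant value iff rand_j <= CR or j == j_rand.
    """
    parent = np.asarray(parent, dtype=float)
    mutant = np.asarray(mutant, dtype=float)
    if parent.shape != mutant.shape:
        raise DimensionError(
            f"parent and mutant lengths differ: {parent.shape} vs {mutant.shape}"
        )
    if not 0.0 <= cr < 1.0:
        raise ParameterError(f"CR must lie in [0, 1), got {cr}")
    D = parent.size
    j_rand = int(rng.integers(D))
    take = rng.random(D) <= cr
    take[j_rand] = True
    return np.where(take, mutant, parent)


def evaluate_individual(
    theta: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    arch: BLSArchitecture,
    L_ipgbls: np.ndarray,
    lambda1: float,
    lambda2: float,
) -> tuple[float, float]:
    """Training RMSE and output-weight norm of the classifier theta encodes.

    RMSE = ||A W - Y||_F / sqrt(N C) with W the closed-form graph-regularized
    solution; the norm returned is ||W||_F.
    """
    params = NodeParameterSet.unflatten(theta, X.shape[1], arch)
    A = build_state_matrix(X, params)
    W = solve_gbls_weights(A, Y, L_ipgbls, lambda1, lambda2)
    resid = A @ W - Y
    rmse = float(np.linalg.norm(resid) / np.sqrt(Y.shape[0] * Y.shape[1]))
    return rmse, float(np.linalg.norm(W))


def select_survivor(
    parent_fit: float,
    trial_fit: float,
    parent_norm: float,
    trial_norm: float,
    epsilon_sel: float,
) -> str:
    """Tolerance-based survivor selection; returns ``'trial'`` or ``'parent'``.

    The trial enters the next generation if it improves the parent fitness
    by more than the relative tolerance, or if the two are within the
    tolerance of each other and the trial's output-weight norm is smaller.
    """
    if parent_fit - trial_fit > epsilon_sel * parent_fit:
        return "trial"
    if abs(parent_fit - trial_fit) < epsilon_sel * parent_fit and trial_norm < parent_norm:
        return "trial"
    return "parent"


@dataclass
class SaEResult:
    """Outcome of a DE run: refitted best model, trace, final population."""

    model: BLSModel
    trace: pd.DataFrame  # columns: generation, best_rmse, p1..p4
    population: Population
    best_theta: np.ndarray
    initial_best_rmse: float
    best_rmse: float
    graph: GraphOperators
    memory: StrategyMemory | None = None


def _one_hot(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(y)
    Y = (y[:, None] == classes[None, :]).astype(float)
    return Y, classes


def run_sae(
    config: SaEConfig,
    X: np.ndarray,
    y: np.ndarray,
    arch: BLSArchitecture,
    graph_spec: NeighborGraphSpec,
    graph_ops: GraphOperators | None = None,
) -> SaEResult:
    """Full self-adaptive DE optimization of the node parameters.

    ``y`` may be a 1-D label vector (one-hot encoded internally) or an
    already one-hot target matrix. The neighbour graphs are built once from
    the raw training features and reused for every fitness evaluation. Per
    individual and generation, CR ~ N(cr_mean, cr_sd) truncated to [0, 1),
    F ~ N(f_mean, f_sd) clipped to (0, 2], K ~ U[0, 1]. The run is
    bit-reproducible for a fixed ``config.seed``.

    Returns the best individual refitted into a :class:`BLSModel` plus a
    per-generation trace of the best RMSE and strategy probabilities
    (including a generation-0 row for the initial population).
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.ndim == 1:
        labels = y
        Y, _ = _one_hot(y)
    else:
        Y = np.asarray(y, dtype=float)
        labels = Y.argmax(axis=1)
    if np.unique(labels).size < 2:
        raise ValidationError("training labels must contain at least two classes")

    if graph_ops is None:
        graph_ops = build_graph_operators(X, labels, graph_spec)
    L = graph_ops.L_ipgbls
    l1, l2 = graph_spec.lambda1, graph_spec.lambda2

    rng = np.random.default_rng(config.seed)
    D = arch.dim(X.shape[1])
    pop = initialize_population(config, D, rng)
    for i in range(config.population_size):
        pop.fitness[i], pop.weight_norms[i] = evaluate_individual(
            pop.individuals[i], X, Y, arch, L, l1, l2
        )
    initial_best = pop.best_fitness

    memory = StrategyMemory(config.learning_period, config.epsilon_success)
    uniform = np.full(N_STRATEGIES, 1.0 / N_STRATEGIES)
    rows = [(0, initial_best, *uniform)]

    tiny = np.finfo(float).tiny
    cr_hi = np.nextafter(1.0, 0.0)
    for G in range(1, config.max_generations + 1):
        p = update_probabilities(memory, G)
        ns = np.zeros(N_STRATEGIES)
        nf = np.zeros(N_STRATEGIES)
        new_inds = pop.individuals.copy()
        new_fit = pop.fitness.copy()
        new_norm = pop.weight_norms.copy()
        for i in range(config.population_size):
            strat = select_strategy(p, rng)
            F = float(np.clip(rng.normal(config.f_mean, config.f_sd), tiny, 2.0))
            CR = float(np.clip(rng.normal(config.cr_mean, config.cr_sd), 0.0, cr_hi))
            K = float(rng.uniform(0.0, 1.0))
            v = mutate(pop, i, strat, F, K, rng, bounds=config.bounds)
            u = crossover(pop.individuals[i], v, CR, rng)
            fit_u, norm_u = evaluate_individual(u, X, Y, arch, L, l1, l2)
            if (
                select_survivor(
                    pop.fitness[i], fit_u, pop.weight_norms[i], norm_u,
                    config.epsilon_select,
                )
                == "trial"
            ):
                new_inds[i], new_fit[i], new_norm[i] = u, fit_u, norm_u
                ns[strat - 1] += 1
            else:
                nf[strat - 1] += 1
        pop = Population(new_inds, new_fit, new_norm, generation=G)
        memory.record_generation(ns, nf)
        rows.append((G, pop.best_fitness, *p))
        if config.rmse_threshold > 0 and pop.best_fitness <= config.rmse_threshold:
            break

    best_theta = pop.best_vector.copy()
    params = NodeParameterSet.unflatten(best_theta, X.shape[1], arch)
    A = build_state_matrix(X, params)
    W = solve_gbls_weights(A, Y, L, l1, l2)
    model = BLSModel(params, W, ridge_lambda=l2, graph_lambda=l1)
    trace = pd.DataFrame(
        rows, columns=["generation", "best_rmse", "p1", "p2", "p3", "p4"]
    )
    return SaEResult(
        model=model,
        trace=trace,
        population=pop,
        best_theta=best_theta,
        initial_best_rmse=initial_best,
        best_rmse=pop.best_fitness,
        graph=graph_ops,
        memory=memory,
    )


def write_trace(trace: pd.DataFrame, path) -> None:
    """Write a convergence trace as tab-separated columnar text."""
    trace.to_csv(path, sep="\t", index=False, float_format="%.10g")
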