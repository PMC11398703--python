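"""Agent-based play of the distancing game on a social network.

Each individual holds a strategy ``x`` (a frequency vector over activities)
and, once per generation, observes the average strategy ``y`` of its
k-neighborhood and the per-activity potential risks ``p_i(y)``.  The update
follows a replicator-style rule: frequency moves away from activities whose
risk exceeds the neighborhood-weighted average ``p_bar = sum_i y_i p_i(y)``
and toward activities below it.  Moves toward the neighborhood frequency are
aggressive (90% of the gap); moves past it are cautious (10% of the headroom);
activities whose risk is within 0.01 of the average relax halfway toward the
neighborhood frequency.  After the sweep the strategy is renormalized to the
simplex.

A generation is a sequential (Gauss-Seidel) sweep: individuals update in
index order and every observation uses the *current* population state, so an
individual sees the already-updated strategies of lower-indexed neighbors.
The immediate refresh propagates information across the network within a
single generation and is what lets the population home in on the equilibrium
geometrically; with start-of-generation snapshots the dispersion between
individuals collapses before the population mean has finished moving and the
dynamics freeze short of the equilibrium.  The sweep order is fixed and the
update itself draws no random numbers, so runs are reproducible.

Convergence is tracked as the population-mean Euclidean distance
``<||x - x*||>`` to the analytic equilibrium and declared when it falls below
a prescribed tolerance (1e-4 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx

from .catalog import ActivityCatalog, RiskProfile, ValidationError, as_strategy
from .equilibrium import solve_equilibrium
from .network import neighborhood, reachability_matrix

__all__ = [
    "SimulationConfig",
    "PopulationState",
    "Trajectory",
    "initialize_population",
    "neighborhood_strategy",
    "update_strategy",
    "mean_distance",
    "run_simulation",
]

#: Half-width of the near-average risk band (absolute scale of p).
RISK_BAND = 0.01

#: Relative improvement below which a generation counts as stalled.
STALL_RTOL = 1e-6

#: Consecutive stalled generations that terminate a run.
STALL_PATIENCE = 10


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration for a networked simulation run.

    Attributes
    ----------
    k : int
        Neighborhood size (maximum link distance of interaction partners).
    rho : float
        Initial perturbation fraction in [0, 1]; see
        :func:`initialize_population`.
    tol : float
        Convergence threshold on the mean distance to equilibrium.
    max_generations : int
        Hard cap on generations per repetition.
    repetitions : int
        Independent repetitions averaged into the reported trajectory.
    seed : int
        Master seed; every stream of the run derives from it.
    """

    k: int = 3
    rho: float = 0.2
    tol: float = 1e-4
    max_generations: int = 100
    repetitions: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.tol <= 0:
            raise ValidationError("convergence tolerance must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError("perturbation fraction rho must lie in [0, 1]")
        if self.repetitions < 1:
            raise ValidationError("need at least one repetition")
        if self.k < 0:
            raise ValidationError("neighborhood size k must be nonnegative")


@dataclass
class PopulationState:
    """Per-individual strategies at a given generation."""

    strategies: np.ndarray  # (m, n), every row on the simplex
    generation: int = 0

    @property
    def m(self) -> int:
        return self.strategies.shape[0]

    def mean_strategy(self) -> np.ndarray:
        return self.strategies.mean(axis=0)


@dataclass
class Trajectory:
    """Per-generation mean distance to equilibrium, with convergence flag.

    ``distances[0]`` is the distance of the initial population;
    ``distances[g]`` the distance after generation ``g``.
    """

    distances: np.ndarray
    converged: bool
    generations: int


def _rep_seed_sequences(seed: int, repetitions: int):
    """Child seed sequences, one per repetition, derived from a master seed.

    Each repetition receives its own ``SeedSequence`` which is further split
    into purpose-specific streams (initialization, group assignment, leader
    assignment) so that model variants consuming different subsets of the
    streams still draw identical initial populations.
    """
    master = np.random.default_rng(int(seed))
    rep_seeds = master.integers(0, 2**31 - 1, size=int(repetitions))
    return [np.random.SeedSequence(int(s)).spawn(3) for s in rep_seeds]


def initialize_population(x_star, m: int, rho: float, seed) -> PopulationState:
    """Random initial strategies scattered around a perturbed equilibrium.

    Each individual's starting point is drawn in two stages: first a
    perturbed center ``c_i = x*_i (1 + U(-rho, rho))`` per coordinate, then
    a value within 100% deviation of that center, ``x_i = c_i * U(0, 2)``.
    Rows are renormalized to the simplex.  The two-stage draw is symmetric
    around ``x*``, so the initial population mean is unbiased (deviating
    only by Monte-Carlo error of order ``1/sqrt(m)``).

    ``seed`` may be an int, a ``SeedSequence`` or a ``Generator``.
    """
    x_star = as_strategy(x_star)
    rng = np.random.default_rng(seed)
    shape = (int(m), x_star.size)
    center = x_star[None, :] * (1.0 + rng.uniform(-rho, rho, size=shape))
    X = center * rng.uniform(0.0, 2.0, size=shape)
    X = np.clip(X, 0.0, None)
    sums = X.sum(axis=1, keepdims=True)
    # a degenerate all-zero draw (probability ~0) falls back to the equilibrium
    bad = sums[:, 0] <= 0
    if np.any(bad):
        X[bad] = x_star
        sums = X.sum(axis=1, keepdims=True)
    return PopulationState(strategies=X / sums, generation=0)


def neighborhood_strategy(
    state: PopulationState, net: nx.Graph, node: int, k: int
) -> np.ndarray:
    """Coordinate-wise mean strategy over the node's k-neighborhood
    (focal node included)."""
    members = sorted(neighborhood(net, node, k))
    return state.strategies[members].mean(axis=0)


def _update_row(x: np.ndarray, y: np.ndarray, P: np.ndarray, pbar: float):
    """Core strategy-update rule for one individual (no validation).

    The three rule blocks apply sequentially: an activity whose risk is
    inside the near-average band is first moved by the below/above-average
    rule and then relaxed halfway toward the neighborhood frequency.
    """
    # below-average risk: raise frequency
    mask = P < pbar
    step = np.where(x < y, 0.9 * (y - x), 0.1 * np.minimum(1.0 - x, x - y))
    x = np.where(mask, x + step, x)
    # above-average risk: lower frequency
    mask = P > pbar
    step = np.where(x > y, 0.9 * (x - y), 0.1 * np.minimum(x, y - x))
    x = np.where(mask, x - step, x)
    # near-average risk: relax halfway toward the neighborhood frequency
    mask = np.abs(P - pbar) < RISK_BAND
    x = np.where(mask, x + 0.5 * (y - x), x)
    x = np.clip(x, 0.0, None)
    return x / x.sum()


def update_strategy(
    x, y, profile: RiskProfile, catalog: ActivityCatalog
) -> np.ndarray:
    """One individual's strategy update given neighborhood strategy ``y``."""
    x = as_strategy(x)
    y = as_strategy(y)
    P = profile.w * catalog.sigma(y)
    pbar = float(y @ P)
    return _update_row(x, y, P, pbar)


def mean_distance(state, x_star) -> float:
    """Population-mean Euclidean distance ``<||x - x*||>`` to equilibrium."""
    X = state.strategies if isinstance(state, PopulationState) else np.asarray(state)
    d = np.linalg.norm(X - np.asarray(x_star)[None, :], axis=1)
    return float(d.mean())


def _neighbor_lists(R) -> list:
    """Per-node arrays of k-neighborhood members from a reachability matrix."""
    indptr, indices = R.indptr, R.indices
    return [indices[indptr[i] : indptr[i + 1]] for i in range(R.shape[0])]


def _simulate_once(X0, x_star, nbrs, w, kappa, theta, tol, max_generations):
    """One repetition of the homogeneous-population simulation.

    Returns (distances, converged, final strategies).
    """
    X = X0.copy()
    m = X.shape[0]
    distances = [mean_distance(X, x_star)]
    converged = distances[0] < tol
    stalled = 0
    gen = 0
    while not converged and gen < max_generations:
        for i in range(m):
            y = X[nbrs[i]].mean(axis=0)
            P = w / (1.0 + np.exp(-kappa * (y - theta)))
            X[i] = _update_row(X[i], y, P, float(y @ P))
        gen += 1
        d = mean_distance(X, x_star)
        distances.append(d)
        if d < tol:
            converged = True
            break
        if distances[-2] - d < STALL_RTOL * distances[-2]:
            stalled += 1
            if stalled >= STALL_PATIENCE:
                break
        else:
            stalled = 0
    return np.array(distances), converged, X


def _mean_trajectory(runs):
    """Average per-generation trajectories of unequal length; shorter runs
    are held at their final value."""
    length = max(len(d) for d, _, _ in runs)
    padded = np.vstack(
        [np.pad(d, (0, length - len(d)), mode="edge") for d, _, _ in runs]
    )
    return padded.mean(axis=0)


def run_simulation(
    catalog: ActivityCatalog,
    profile: RiskProfile,
    net: nx.Graph,
    config: SimulationConfig,
):
    """Run the networked distancing game against the analytic equilibrium.

    Each repetition initializes the population independently (child seeds
    derived from ``config.seed``), sweeps generations until the mean
    distance to ``x*`` drops below ``config.tol``, progress stalls, or
    ``config.max_generations`` is reached.  With several repetitions the
    reported trajectory is the per-generation mean and ``converged`` requires
    every repetition to converge.

    Returns
    -------
    (Trajectory, PopulationState)
        The (averaged) trajectory and the final state of the first
        repetition.
    """
    eq = solve_equilibrium(profile, catalog)
    R = reachability_matrix(net, config.k)
    nbrs = _neighbor_lists(R)
    m = R.shape[0]
    runs = []
    for streams in _rep_seed_sequences(config.seed, config.repetitions):
        state0 = initialize_population(eq.x_star, m, config.rho, streams[0])
        runs.append(
            _simulate_once(
                state0.strategies,
                eq.x_star,
                nbrs,
                profile.w,
                catalog.kappa,
                catalog.theta,
                config.tol,
                config.max_generations,
            )
        )
    distances = _mean_trajectory(runs)
    converged = all(c for _, c, _ in runs)
    traj = Trajectory(
        distances=distances, converged=converged, generations=len(distances) - 1
    )
    final = PopulationState(strategies=runs[0][2], generation=len(runs[0][0]) - 1)
    return traj, final
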