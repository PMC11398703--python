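"""Distancing games in heterogeneous populations.

The population splits into ``M`` groups that perceive activity risks
differently: group ``j`` carries its own severity ``delta^(j)`` and hence
its own risk factors ``w^(j)``.  A group-``j`` individual evaluates the
potential risk of activity ``i`` from the group-wise neighborhood averages
``y^(k)`` as

    p_i^(j) = sum_k s_jk w_i^(k) sigma_i(y_i^(k)),    s_jk = 1 + s if k = j else 1,

giving extra weight ``1 + s`` to its own group (individuals interact more
within their group).  The comparison baseline is the own-group average
``p_bar = sum_i y_i^(j) p_i^(j)``, and the frequency comparisons of the
update rule use the own-group neighborhood strategy.  At equilibrium the
coupling is an additive, group-constant shift, so each group converges to
the equilibrium it would reach playing alone, and the population strategy is
the fraction-weighted mixture of the group equilibria.

If a neighborhood contains no member of some group, the missing group
average falls back to that group's population-wide mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx

from .catalog import ActivityCatalog, ValidationError
from .dynamics import (
    STALL_PATIENCE,
    STALL_RTOL,
    PopulationState,
    SimulationConfig,
    Trajectory,
    _mean_trajectory,
    _neighbor_lists,
    _rep_seed_sequences,
    _update_row,
    initialize_population,
    mean_distance,
)
from .equilibrium import GroupSpec, solve_multigroup
from .network import reachability_matrix

__all__ = ["GroupedPopulationState", "group_risk", "assign_groups", "run_group_simulation"]


@dataclass
class GroupedPopulationState:
    """Per-individual strategies with group labels (0-based, 0..M-1)."""

    strategies: np.ndarray
    groups: np.ndarray
    generation: int = 0

    @property
    def m(self) -> int:
        return self.strategies.shape[0]

    def group_mean(self, j: int) -> np.ndarray:
        return self.strategies[self.groups == j].mean(axis=0)


def group_risk(y_by_group, j: int, w_by_group, s: float, catalog: ActivityCatalog):
    """Per-activity potential risk perceived by a group-``j`` individual.

    ``y_by_group`` and ``w_by_group`` hold one strategy / risk-factor vector
    per group (shape ``(M, n)``).
    """
    if s <= 0:
        raise ValidationError("own-group coupling weight s must be positive")
    Y = np.asarray(y_by_group, dtype=float)
    W = np.asarray(w_by_group, dtype=float)
    if Y.shape != W.shape or Y.ndim != 2:
        raise ValidationError("need matching (M, n) group strategies and factors")
    if not 0 <= j < Y.shape[0]:
        raise ValidationError("group index out of range")
    contrib = W * catalog.sigma(Y)  # (M, n)
    return contrib.sum(axis=0) + s * contrib[j]


def assign_groups(m: int, fractions, seed) -> np.ndarray:
    """Proportional group assignment, shuffled uniformly.

    Group ``j`` receives ``round(fractions[..j] * m)`` members (largest-
    remainder on the cumulative counts, so totals are exact) and labels are
    randomly permuted over the network's nodes.
    """
    fractions = np.asarray(fractions, dtype=float)
    bounds = np.round(np.cumsum(fractions) * m).astype(int)
    bounds[-1] = m
    labels = np.zeros(m, dtype=int)
    start = 0
    for j, stop in enumerate(bounds):
        labels[start:stop] = j
        start = stop
    rng = np.random.default_rng(seed)
    return rng.permutation(labels)


def run_group_simulation(
    catalog: ActivityCatalog,
    spec: GroupSpec,
    net: nx.Graph,
    config: SimulationConfig,
):
    """Play the multi-group distancing game on a network.

    As :func:`distgame.dynamics.run_simulation`, except that risks are the
    coupled group risks, comparisons use own-group neighborhood averages,
    and convergence is tracked per group against that group's own analytic
    equilibrium.  The run converges only when every group meets
    ``config.tol``.

    Returns
    -------
    (list[Trajectory], GroupedPopulationState)
        Per-group (averaged) trajectories and the final state of the first
        repetition.
    """
    mg = solve_multigroup(spec, catalog)
    x_stars = [r.x_star for r in mg.groups]
    W = np.vstack([p.w for p in spec.profiles(catalog)])  # (M, n)
    M = spec.n_groups
    R = reachability_matrix(net, config.k)
    nbrs = _neighbor_lists(R)
    m = R.shape[0]
    runs = []
    for streams in _rep_seed_sequences(config.seed, config.repetitions):
        labels = assign_groups(m, spec.fractions, streams[1])
        init_streams = streams[0].spawn(M)
        X0 = np.empty((m, catalog.n_activities))
        for j in range(M):
            rows = labels == j
            X0[rows] = initialize_population(
                x_stars[j], int(rows.sum()), config.rho, init_streams[j]
            ).strategies
        dists, conv, X, labels = _simulate_group_once(
            X0, labels, x_stars, nbrs, W, spec.s, catalog, config
        )
        runs.append((dists, conv, X, labels))
    trajs = []
    for j in range(M):
        per_rep = [(d[:, j], c, None) for d, c, _, _ in runs]
        trajs.append(
            Trajectory(
                distances=_mean_trajectory(per_rep),
                converged=all(c for _, c, _ in per_rep),
                generations=max(len(d) for d, _, _ in per_rep) - 1,
            )
        )
    final = GroupedPopulationState(
        strategies=runs[0][2], groups=runs[0][3], generation=len(runs[0][0]) - 1
    )
    return trajs, final


def _group_distances(X, labels, x_stars) -> np.ndarray:
    return np.array(
        [mean_distance(X[labels == j], x_stars[j]) for j in range(len(x_stars))]
    )


def _group_neighborhood_means(Xnb, lab, M, group_means):
    """Group-wise means over a neighborhood with global-mean fallback."""
    Y = np.empty((M, Xnb.shape[1]))
    for k in range(M):
        sel = lab == k
        Y[k] = Xnb[sel].mean(axis=0) if sel.any() else group_means[k]
    return Y


def _regular_row(x, j, Y, W, s, kappa, theta):
    """Regular-player update of one individual in group ``j`` given the
    group-wise neighborhood averages ``Y``."""
    contrib = W / (1.0 + np.exp(-kappa * (Y - theta)))
    P = contrib.sum(axis=0) + s * contrib[j]
    yown = Y[j]
    return _update_row(x, yown, P, float(yown @ P))


def _simulate_group_once(X0, labels, x_stars, nbrs, W, s, catalog, config):
    """One repetition of the multi-group simulation (sequential sweeps)."""
    X = X0.copy()
    m = X.shape[0]
    M = W.shape[0]
    kappa, theta = catalog.kappa, catalog.theta
    tol, max_generations = config.tol, config.max_generations
    distances = [_group_distances(X, labels, x_stars)]
    converged = bool(np.all(distances[0] < tol))
    member_labels = [labels[nb] for nb in nbrs]
    stalled = 0
    gen = 0
    while not converged and gen < max_generations:
        group_means = np.vstack([X[labels == j].mean(axis=0) for j in range(M)])
        for i in range(m):
            # empty-group neighborhoods fall back to the global group mean
            Y = _group_neighborhood_means(X[nbrs[i]], member_labels[i], M, group_means)
            X[i] = _regular_row(X[i], labels[i], Y, W, s, kappa, theta)
        gen += 1
        d = _group_distances(X, labels, x_stars)
        distances.append(d)
        if np.all(d < tol):
            converged = True
            break
        prev, cur = distances[-2].mean(), d.mean()
        if prev - cur < STALL_RTOL * prev:
            stalled += 1
            if stalled >= STALL_PATIENCE:
                break
        else:
            stalled = 0
    return np.vstack(distances), converged, X, labels
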