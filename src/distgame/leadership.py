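"""Leader-follower variant of the networked distancing game.

A fixed fraction of individuals are designated leaders at initialization.
Leaders update as regular players of the (multi-group) distancing game.  A
follower searches its neighborhood for leaders of its own group and copies
their average strategy.  When no same-group leader is in reach, the follower
falls back to one of two policies:

* ``follow-crowd`` — copy the average strategy of same-group members of the
  neighborhood;
* ``self-decide`` — perform the regular player update.

Followers never copy leaders of other groups.  The leader search is over the
follower's *closest* neighbors — the direct (1-link) neighborhood by default,
configurable via ``search_radius``.  A small search set is what makes the
leader fraction matter: with the full play neighborhood almost every
follower finds a leader and the fallback policies never differentiate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx

from .catalog import ActivityCatalog, ValidationError
from .dynamics import (
    STALL_PATIENCE,
    STALL_RTOL,
    SimulationConfig,
    Trajectory,
    _mean_trajectory,
    _neighbor_lists,
    _rep_seed_sequences,
    initialize_population,
)
from .equilibrium import GroupSpec, solve_multigroup
from .heterogeneity import (
    GroupedPopulationState,
    _group_distances,
    _group_neighborhood_means,
    _regular_row,
    assign_groups,
)
from .network import reachability_matrix

__all__ = [
    "FALLBACK_POLICIES",
    "LeaderConfig",
    "assign_leaders",
    "follower_update",
    "run_leader_simulation",
]

FALLBACK_POLICIES = ("follow-crowd", "self-decide")


@dataclass(frozen=True)
class LeaderConfig:
    """Leader-follower configuration.

    Attributes
    ----------
    leader_fraction : float
        Fraction of the population designated as leaders, in [0, 1].
    fallback_policy : str
        What a follower does when no same-group leader is in reach:
        ``"follow-crowd"`` or ``"self-decide"``.
    search_radius : int
        Neighborhood size for the leader search; 1 (direct neighbors) by
        default.
    """

    leader_fraction: float
    fallback_policy: str = "follow-crowd"
    search_radius: int = 1

    def __post_init__(self):
        if not 0.0 <= self.leader_fraction <= 1.0:
            raise ValidationError("leader fraction must lie in [0, 1]")
        if self.fallback_policy not in FALLBACK_POLICIES:
            raise ValidationError(
                f"fallback policy must be one of {FALLBACK_POLICIES}"
            )


def assign_leaders(m: int, fraction: float, seed) -> np.ndarray:
    """Select exactly ``round(fraction * m)`` leaders uniformly without
    replacement; returns a boolean flag per individual."""
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("leader fraction must lie in [0, 1]")
    m = int(m)
    n_leaders = int(round(fraction * m))
    rng = np.random.default_rng(seed)
    flags = np.zeros(m, dtype=bool)
    flags[rng.choice(m, size=n_leaders, replace=False)] = True
    return flags


def follower_update(
    node: int,
    state: GroupedPopulationState,
    net: nx.Graph,
    leader_flags,
    leader_config: LeaderConfig,
    spec: GroupSpec,
    catalog: ActivityCatalog,
    k: int,
) -> np.ndarray:
    """One follower's strategy update (reference implementation).

    Copies the mean strategy of same-group leaders within the search
    radius; otherwise applies the configured fallback policy.
    """
    leader_flags = np.asarray(leader_flags, dtype=bool)
    if leader_flags[node]:
        raise ValidationError("follower_update called on a leader")
    radius = leader_config.search_radius
    R = reachability_matrix(net, radius)
    Rk = reachability_matrix(net, k)
    W = np.vstack([p.w for p in spec.profiles(catalog)])
    group_means = np.vstack(
        [state.group_mean(j) for j in range(spec.n_groups)]
    )
    nb_search = R.indices[R.indptr[node] : R.indptr[node + 1]]
    nb_play = Rk.indices[Rk.indptr[node] : Rk.indptr[node + 1]]
    return _follower_row(
        node,
        state.strategies,
        state.groups,
        leader_flags,
        nb_search,
        nb_play,
        group_means,
        W,
        spec.s,
        catalog,
        leader_config.fallback_policy,
    )


def _follower_row(
    i, X, labels, leaders, nb_search, nb_play, group_means, W, s, catalog, policy
):
    j = labels[i]
    peers = nb_search[(labels[nb_search] == j) & leaders[nb_search]]
    if peers.size:
        return X[peers].mean(axis=0)
    if policy == "follow-crowd":
        crowd = nb_play[labels[nb_play] == j]
        if crowd.size:
            return X[crowd].mean(axis=0)
        return group_means[j].copy()
    # self-decide: regular player update on the play neighborhood
    Y = _group_neighborhood_means(X[nb_play], labels[nb_play], W.shape[0], group_means)
    return _regular_row(X[i], j, Y, W, s, catalog.kappa, catalog.theta)


def run_leader_simulation(
    catalog: ActivityCatalog,
    spec: GroupSpec,
    net: nx.Graph,
    config: SimulationConfig,
    leader_config: LeaderConfig,
):
    """Play the multi-group game with leaders and followers.

    Leaders apply the regular update; followers copy same-group leaders in
    reach or fall back per ``leader_config``.  Leaders are assigned once per
    repetition and fixed.  With ``leader_fraction = 1`` the run is
    bit-identical to :func:`distgame.heterogeneity.run_group_simulation`
    under the same seeds.

    Returns
    -------
    (list[Trajectory], GroupedPopulationState, numpy.ndarray)
        Per-group trajectories, the final state of the first repetition and
        its leader flags.
    """
    mg = solve_multigroup(spec, catalog)
    x_stars = [r.x_star for r in mg.groups]
    W = np.vstack([p.w for p in spec.profiles(catalog)])
    M = spec.n_groups
    R = reachability_matrix(net, config.k)
    nbrs = _neighbor_lists(R)
    m = R.shape[0]
    radius = leader_config.search_radius
    if radius == config.k:
        search_nbrs = nbrs
    else:
        search_nbrs = _neighbor_lists(reachability_matrix(net, radius))
    runs = []
    for streams in _rep_seed_sequences(config.seed, config.repetitions):
        labels = assign_groups(m, spec.fractions, streams[1])
        leaders = assign_leaders(m, leader_config.leader_fraction, streams[2])
        init_streams = streams[0].spawn(M)
        X0 = np.empty((m, catalog.n_activities))
        for j in range(M):
            rows = labels == j
            X0[rows] = initialize_population(
                x_stars[j], int(rows.sum()), config.rho, init_streams[j]
            ).strategies
        runs.append(
            _simulate_leader_once(
                X0,
                labels,
                leaders,
                x_stars,
                nbrs,
                search_nbrs,
                W,
                spec.s,
                catalog,
                config,
                leader_config.fallback_policy,
            )
        )
    trajs = []
    for j in range(M):
        per_rep = [(d[:, j], c, None) for d, c, *_ in runs]
        trajs.append(
            Trajectory(
                distances=_mean_trajectory(per_rep),
                converged=all(c for _, c, _ in per_rep),
                generations=max(len(d) for d, _, _ in per_rep) - 1,
            )
        )
    d0, _, X_final, labels_final, leaders_final = runs[0]
    final = GroupedPopulationState(
        strategies=X_final, groups=labels_final, generation=len(d0) - 1
    )
    return trajs, final, leaders_final


def _simulate_leader_once(
    X0, labels, leaders, x_stars, nbrs, search_nbrs, W, s, catalog, config, policy
):
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
            if leaders[i]:
                Y = _group_neighborhood_means(
                    X[nbrs[i]], member_labels[i], M, group_means
                )
                X[i] = _regular_row(X[i], labels[i], Y, W, s, kappa, theta)
            else:
                X[i] = _follower_row(
                    i,
                    X,
                    labels,
                    leaders,
                    search_nbrs[i],
                    nbrs[i],
                    group_means,
                    W,
                    s,
                    catalog,
                    policy,
                )
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
    return np.vstack(distances), converged, X, labels, leaders
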