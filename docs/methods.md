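# Methods

## The distancing game

A population of `m` individuals chooses participation frequencies over `n`
social activities. A strategy is a point on the simplex; `y` denotes the
average strategy of the relevant population (the whole population in the
mean-field game, a network neighborhood in the agent-based game). The
potential risk of activity `i` is `pᵢ(y) = wᵢ σᵢ(yᵢ)` with the logistic
response `σᵢ(y) = 1/(1+exp(−κᵢ(y−θᵢ)))`: an activity becomes riskier the
more popular it is, with rate `κᵢ` and half-risk point `θᵢ`. An individual
of strategy `x` carries risk `π(x, y) = Σᵢ xᵢ pᵢ(y)`, linear in `x`.

`x*` is an equilibrium when no unilateral deviation lowers risk against
`y* = x*`. The KKT characterization is complementarity: `xᵢ*(pᵢ(y*) − λ) = 0`,
`xᵢ* ≥ 0`, `pᵢ(y*) − λ ≥ 0` with `λ = π(x*, y*)`. For an interior
equilibrium all activities equalize at risk `λ` and

```
xᵢ* = σᵢ⁻¹(λ/wᵢ),   Σᵢ σᵢ⁻¹(λ/wᵢ) = 1.
```

Because `pᵢ` depends only on `yᵢ`, the game admits the separable potential
`f(y) = Σᵢ (wᵢ/κᵢ) log(1+exp(κᵢ(yᵢ−θᵢ)))` with `∂f/∂yᵢ = pᵢ(y)`; its
Hessian is diagonal and positive for `wᵢ > 0`, so the interior equilibrium
is the unique strict minimizer of `f` on the simplex and is evolutionarily
stable (it resists small invading strategies).

### Solver

The normalization `g(λ) = Σᵢ σᵢ⁻¹(λ/wᵢ) − 1` is strictly increasing on the
bracket `(0, minᵢ wᵢσᵢ(1))`, inside which every `λ/wᵢ` stays in the range
of `σᵢ`. We root-find with Brent's method at machine precision (`xtol`
1e−16) and renormalize the resulting `x*` onto the simplex; the reported
residual `maxᵢ |wᵢσᵢ(xᵢ*) − λ|` is typically below 1e−15, and the default
acceptance tolerance is 1e−10. If any coordinate of the closed form is
nonpositive the solver raises rather than projecting: the interior formula
simply does not apply, and boundary (corner) equilibria are out of scope.

### Deriving contact and impact factors

Given a reference schedule treated as the equilibrium (all hours positive),
risk equalization `wᵢσᵢ(yᵢ*) = λ` inverts to `wᵢ = λ/σᵢ(yᵢ*)`. The anchor
`λ` is a free scale: the contact factors use `λ = σ₁(y₁*)` (so activity 1
has factor exactly 1), and the impact factors reuse that same `λ` so the
two sets are mutually comparable. Factors are stored at full double
precision; the bundled `casa20` catalog carries the published 4-decimal
values, and tests compare derivations at that printed precision. A shared
`κ = 10`, `θ = 0.5` is used throughout; per-activity values are plumbed
but no shipped result depends on them.

## Small-world networks

Networks are Watts–Strogatz: a degree-`K` ring lattice whose original
right-hand edges are each rewired with probability `b` to a uniformly
chosen non-neighbor. Rewiring moves edges without adding or removing any,
so `|E| = mK/2` and the mean degree is exactly `K`. The generator uses one
seeded RNG stream in node-major, neighbor-minor order; if a candidate set
is empty (near-complete graphs) the edge is kept. A node's k-neighborhood
is its closed k-hop ball (the focal node is included — the mean 1-hop
neighborhood of a `K = 6` network is 7). Neighborhood statistics are
computed by boolean sparse-matrix powers rather than per-node BFS.

## Agent-based dynamics

Each generation every individual observes the average strategy `y` of its
k-neighborhood, the activity risks `pᵢ(y)` and their neighborhood-weighted
average `p̄ = Σᵢ yᵢpᵢ(y)`, and updates each coordinate:

* `pᵢ < p̄` (under-risky): move up — 90% of the gap toward `yᵢ` if below
  it, else 10% of `min(1−xᵢ, xᵢ−yᵢ)` beyond it;
* `pᵢ > p̄` (over-risky): the mirror image downward;
* `|pᵢ − p̄| < 0.01` (near-average): additionally relax halfway toward
  `yᵢ`.

The three blocks apply sequentially to the running value, then the strategy
is clipped at zero and renormalized. The 0.01 band is on the absolute scale
of `p`. The near-average rule is stated here as symmetric motion *toward*
the neighborhood frequency in both branches; a sign-flipped below-average
branch would move the coordinate away from the average and destroy the
fixed point at equilibrium.

**Sweep order.** Generations are sequential (Gauss–Seidel) sweeps in index
order: each observation uses the current population state, including
already-updated lower-indexed neighbors. This choice is load-bearing. With
synchronous snapshots the between-individual dispersion — which is what
fuels the drift of the population mean toward `x*` — collapses geometrically
before the mean has finished moving, and runs freeze at a seed-dependent
offset of order 1e−3. Sequential sweeps keep information flowing through
the network within a generation and the mean distance contracts by roughly
half per generation, passing 1e−4 in about ten generations. The sweep uses
no randomness, so runs remain reproducible; order-dependence is the price.

**Initialization.** Each individual starts from a two-stage draw:
`cᵢ = xᵢ*(1 + U(−ρ, ρ))` per coordinate, then `xᵢ = cᵢ·U(0, 2)`, clipped
and renormalized. Both stages are symmetric about `x*`, so the initial
population mean is unbiased up to Monte-Carlo error. Perturbations up to
`ρ = 0.5` converge in practice; the shipped default is `ρ = 0.2`.

**Convergence and stopping.** A run converges when the population-mean
Euclidean distance `<‖x − x*‖>` to the analytic equilibrium drops below
`tol` (default 1e−4). Runs stop early as failed when the relative
improvement stays below 1e−6 for 10 consecutive generations, or at
`max_generations` (default 100). With `repetitions > 1` (default 5) the
reported trajectory is the per-generation mean over independently seeded
repetitions, padded at each repetition's final value, and convergence
requires every repetition to converge. A master seed spawns per-repetition
child streams, which are further split by purpose (initialization, group
assignment, leader assignment) so that model variants consuming different
subsets still draw identical initial populations.

## Heterogeneous groups

With `M` groups of severities `δ⁽ʲ⁾` (hence factors `w⁽ʲ⁾`), a group-`j`
individual perceives `pᵢ⁽ʲ⁾ = Σₖ s_jk wᵢ⁽ᵏ⁾σᵢ(yᵢ⁽ᵏ⁾)` over the group-wise
neighborhood averages, with own-group weight `s_jj = 1+s` (default
`s = 1`, any positive value; it shifts transients only). The comparison
baseline and the frequency comparisons use the own-group neighborhood
average, and a neighborhood with no members of some group falls back to
that group's population-wide mean. At equilibrium each coupled risk is a
group-constant shift of the others, so every group lands on the
equilibrium it would reach alone and the population strategy is the
fraction-weighted mixture — the closed form the simulation is tested
against. Group labels are assigned by shuffled proportional allocation
(exact counts up to rounding).

Group-restricted neighborhoods are ~`1/M` the size of the full ones, so
multi-group runs plateau around a few 1e−4 at `m = 2000` (a few 1e−3 at
`m = 500`) rather than 1e−4; the decisive check is the 1e−3 per-coordinate
match between converged group means and the closed forms.

## Leaders and followers

A fraction of individuals (exactly `round(fraction·m)`, drawn uniformly at
initialization and fixed) are leaders who update as regular players. A
follower copies the unweighted mean strategy of same-group leaders among
its *closest* neighbors — the direct 1-link neighborhood by default
(`search_radius` configurable). Cross-group copying is excluded. With no
leader in reach the follower either copies the mean of same-group members
of its play neighborhood (`follow-crowd`) or performs the regular update
(`self-decide`). The small default search radius is what differentiates
the policies: searching the whole play neighborhood almost always finds a
leader, making the fallback irrelevant. With 100% leaders the machinery is
inert and trajectories are bitwise equal to the plain multi-group run
under shared seeds.

## Problem sizes and what the tests show

Unit and acceptance tests run the network statistics at the reference size
(m = 2000, 20 seeds) and the simulations at m = 500 with 2 repetitions;
the convergence claims they check (k ≥ 2 converges, k = 1 does not;
ρ ≤ 0.4 converges; group separation; policy ordering) are qualitative and
scale-free, while plateau levels scale like `1/√m`. The synthetic
populations are exchangeable apart from network position and group label:
there is no household structure, no activity-hour constraints, no
homophily in wiring, and the logistic parameters are shared across
activities. Passing tests therefore validate the game-theoretic machinery
and its network dynamics, not the realism of any particular activity
catalog.

## Known limitations

* Only interior equilibria are computed; profiles whose closed form leaves
  the positive orthant raise an error instead of returning a corner
  solution.
* Activities are independent (`pᵢ` depends on `yᵢ` only); cross-activity
  risk coupling is not modeled.
* The agent dynamics are a heuristic replicator-style rule; convergence is
  empirical, not guaranteed, and is genuinely absent for 1-link
  neighborhoods.
* Coupling to epidemic dynamics (severity feeding back on δ) is out of
  scope.
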