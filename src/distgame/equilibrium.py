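"""Equilibrium strategies of the distancing game and their diagnostics.

An interior equilibrium of the single-population game with activity risks
``p_i(y) = w_i sigma_i(y_i)`` equalizes the potential risk across all
activities: ``p_i(y*) = lambda`` for every ``i``.  This gives the closed
form ``x*_i = sigma_i^{-1}(lambda / w_i)``, with the common risk level
``lambda`` fixed by the simplex normalization
``sum_i sigma_i^{-1}(lambda / w_i) = 1``.  Since each summand is strictly
increasing in ``lambda``, the normalization has a unique root that a
bracketed scalar root-finder locates to machine precision.

The game is a potential game: ``p_i`` is the gradient of the separable
potential ``f(y) = sum_i (w_i / kappa_i) log(1 + exp(kappa_i (y_i -
theta_i)))``, whose strict local minimizers on the simplex are exactly the
evolutionarily stable equilibria.  The multi-group extension couples groups
only through an additive, group-constant shift of the risk levels, so each
group's equilibrium solves its own single-group normalization — groups play
"as if alone".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .catalog import (
    ActivityCatalog,
    RiskProfile,
    ValidationError,
    as_strategy,
    blend_risk_factors,
    cost,
    logistic,
    logistic_inverse,
    potential_risk,
)

__all__ = [
    "NoInteriorEquilibriumError",
    "EquilibriumResult",
    "VerificationReport",
    "GroupSpec",
    "MultigroupResult",
    "solve_equilibrium",
    "verify_equilibrium",
    "potential",
    "check_stability",
    "solve_multigroup",
]


class NoInteriorEquilibriumError(RuntimeError):
    """The closed-form solution has a nonpositive coordinate; the interior
    equilibrium formula does not apply to this risk profile."""


@dataclass(frozen=True)
class EquilibriumResult:
    """An interior equilibrium strategy with its common risk level.

    Attributes
    ----------
    x_star : numpy.ndarray
        Equilibrium strategy (all coordinates strictly positive).
    lambda_star : float
        Common potential risk ``p_i(x*) = lambda`` across activities.
    residual : float
        ``max_i |w_i sigma_i(x*_i) - lambda|`` achieved by the solver.
    """

    x_star: np.ndarray
    lambda_star: float
    residual: float

    def hours(self, budget: float = 112.0) -> np.ndarray:
        """Equilibrium weekly active hours ``x* * budget``."""
        return self.x_star * budget


def solve_equilibrium(
    profile: RiskProfile, catalog: ActivityCatalog, tol: float = 1e-10
) -> EquilibriumResult:
    """Solve for the interior equilibrium of the single-population game.

    Finds the root of ``g(lambda) = sum_i sigma_i^{-1}(lambda / w_i) - 1``
    on the bracket ``(0, min_i w_i sigma_i(1))``; on that bracket every
    ``lambda / w_i`` stays inside the range of ``sigma_i`` so the inverse is
    defined, and ``g`` is strictly increasing.

    Raises
    ------
    NoInteriorEquilibriumError
        If the root yields some ``x*_i <= 0`` (or no root exists in the
        bracket): the interior closed form does not apply.
    """
    w = profile.w
    kappa, theta = catalog.kappa, catalog.theta
    if w.shape != kappa.shape:
        raise ValidationError("risk profile and catalog sizes differ")

    def g(lam: float) -> float:
        return float(np.sum(logistic_inverse(lam / w, kappa, theta)) - 1.0)

    hi_cap = float(np.min(w * logistic(1.0, kappa, theta)))
    lo = 1e-9 * float(np.min(w * logistic(1e-9, kappa, theta)))
    hi = hi_cap * (1.0 - 1e-12)
    if g(lo) > 0 or g(hi) < 0:
        raise NoInteriorEquilibriumError(
            "normalization has no root with all x*_i in (0, 1)"
        )
    lam = brentq(g, lo, hi, xtol=1e-16, rtol=8.9e-16)
    x = logistic_inverse(lam / w, kappa, theta)
    if np.any(x <= 0):
        raise NoInteriorEquilibriumError(
            "closed form yields a nonpositive coordinate; equilibrium is not interior"
        )
    # renormalize the last bit of root-finding slack away
    x = x / x.sum()
    residual = float(np.max(np.abs(w * logistic(x, kappa, theta) - lam)))
    if residual > max(tol, 1e-12):
        raise NoInteriorEquilibriumError(
            f"equilibrium residual {residual:.3g} exceeds tolerance {tol:.3g}"
        )
    return EquilibriumResult(x_star=x, lambda_star=float(lam), residual=residual)


@dataclass(frozen=True)
class VerificationReport:
    """Outcome of the complementarity (KKT) check at a candidate strategy.

    The equilibrium conditions with ``lambda = pi(x, x)`` are, for each
    activity: ``x_i >= 0``, ``p_i(x) - lambda >= 0`` and
    ``x_i (p_i(x) - lambda) = 0``.
    """

    is_equilibrium: bool
    lambda_: float
    max_complementarity: float
    min_margin: float

    def __bool__(self) -> bool:
        return self.is_equilibrium


def verify_equilibrium(
    x, profile: RiskProfile, catalog: ActivityCatalog, tol: float = 1e-8
) -> VerificationReport:
    """Check the complementarity conditions at ``x`` (with ``y = x``)."""
    x = as_strategy(x)
    p = potential_risk(x, profile, catalog)
    lam = cost(x, x, profile, catalog)
    slack = p - lam
    comp = float(np.max(np.abs(x * slack)))
    margin = float(np.min(slack))
    ok = comp <= tol and margin >= -tol
    return VerificationReport(
        is_equilibrium=ok, lambda_=lam, max_complementarity=comp, min_margin=margin
    )


def potential(y, profile: RiskProfile, catalog: ActivityCatalog) -> float:
    """Potential function of the game: ``f(y) = sum_i (w_i/kappa_i)
    log(1 + exp(kappa_i (y_i - theta_i)))``, so that ``df/dy_i = p_i(y)``.

    Its strict local minimizers on the simplex are the evolutionarily stable
    equilibria of the game.
    """
    y = np.asarray(y, dtype=float)
    z = catalog.kappa * (y - catalog.theta)
    return float(np.sum(profile.w / catalog.kappa * np.logaddexp(0.0, z)))


def check_stability(
    eq: EquilibriumResult, profile: RiskProfile, catalog: ActivityCatalog
) -> bool:
    """Evolutionary stability of an interior equilibrium.

    The potential's Hessian at ``x*`` is diagonal with entries
    ``w_i sigma_i'(x*_i)``; the equilibrium is evolutionarily stable iff all
    are positive.  Always true for positive risk factors — exposed so that
    generalized profiles can be screened with the same interface.
    """
    sig = logistic(eq.x_star, catalog.kappa, catalog.theta)
    curvature = profile.w * catalog.kappa * sig * (1.0 - sig)
    return bool(np.all(curvature > 0))


@dataclass(frozen=True)
class GroupSpec:
    """Specification of a heterogeneous population of ``M`` groups.

    Parameters
    ----------
    delta : array-like
        Severity per group: shape ``(M,)`` (scalar per group, broadcast over
        activities) or ``(M, n)``.
    fractions : array-like
        Population share of each group; must sum to 1.
    s : float
        Extra own-group coupling weight (an individual weights its own
        group's risk contribution by ``1 + s``).  Must be positive; the
        equilibrium itself does not depend on it.
    """

    delta: np.ndarray
    fractions: np.ndarray
    s: float = 1.0

    def __init__(self, delta, fractions, s: float = 1.0):
        delta = np.atleast_1d(np.asarray(delta, dtype=float))
        fractions = np.asarray(fractions, dtype=float)
        if fractions.ndim != 1 or fractions.size < 1:
            raise ValidationError("fractions must be a nonempty 1-D vector")
        if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
            raise ValidationError("group fractions must be nonnegative and sum to 1")
        if delta.ndim == 1:
            if delta.size != fractions.size:
                raise ValidationError("need one delta per group")
        elif delta.ndim != 2 or delta.shape[0] != fractions.size:
            raise ValidationError("delta must be (M,) or (M, n_activities)")
        if s <= 0:
            raise ValidationError("own-group coupling weight s must be positive")
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "fractions", fractions)
        object.__setattr__(self, "s", float(s))

    @property
    def n_groups(self) -> int:
        return self.fractions.size

    def profiles(self, catalog: ActivityCatalog) -> list[RiskProfile]:
        """Per-group operative risk profiles ``w^(j)``."""
        out = []
        for j in range(self.n_groups):
            d = self.delta[j]
            out.append(blend_risk_factors(catalog.alpha, catalog.beta, d))
        return out

    def coupling_matrix(self) -> np.ndarray:
        """The ``M x M`` weight matrix ``S`` with ``1 + s`` on the diagonal."""
        M = self.n_groups
        return np.ones((M, M)) + self.s * np.eye(M)


@dataclass(frozen=True)
class MultigroupResult:
    """Per-group equilibria and the population-average strategy."""

    groups: tuple
    population: np.ndarray
    eq3_residual: float


def solve_multigroup(
    spec: GroupSpec, catalog: ActivityCatalog, tol: float = 1e-10
) -> MultigroupResult:
    """Solve the multi-group game: each group's equilibrium solves its own
    single-group normalization (groups play "as if alone"); the population
    strategy is the fraction-weighted average.

    Also verifies the coupled risk-equalization consistency: for each group
    ``j``, ``p_i^(j)(y*) = sum_k s_jk w_i^(k) sigma_i(x_i^(k)*)`` must be
    constant over activities — it equals ``sum_k s_jk lambda^(k)``.
    """
    S = spec.coupling_matrix()
    if abs(np.linalg.det(S)) < 1e-12:
        raise RuntimeError("singular group coupling matrix")  # unreachable for s > 0
    results = []
    for prof in spec.profiles(catalog):
        results.append(solve_equilibrium(prof, catalog, tol=tol))
    pop = np.einsum("j,ji->i", spec.fractions, np.array([r.x_star for r in results]))
    # Eq-3 consistency: coupled risks are group-constant over activities
    z = np.array(
        [
            prof.w * catalog.sigma(r.x_star)
            for prof, r in zip(spec.profiles(catalog), results)
        ]
    )  # (M, n): w^(k) sigma(x^(k)*) per activity
    coupled = S @ z  # (M, n): p_i^(j)
    eq3 = float(np.max(np.abs(coupled - coupled.mean(axis=1, keepdims=True))))
    if eq3 > 1e3 * max(tol, 1e-12):
        raise RuntimeError(f"coupled risk equalization violated: {eq3:.3g}")
    return MultigroupResult(groups=tuple(results), population=pop, eq3_residual=eq3)
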