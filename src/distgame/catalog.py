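"""Activity catalog, logistic risk response, and risk-factor derivation.

The distancing game is played over a finite set of ``n`` social activities.
An individual strategy is a probability vector ``x`` over the activities
(participating frequencies); the population (or neighborhood) strategy ``y``
is the average of individual strategies.  Each activity ``i`` carries a
positive risk factor ``w_i`` and the perceived risk of the activity responds
to its popularity through a logistic curve

    sigma_i(y_i) = 1 / (1 + exp(-kappa_i * (y_i - theta_i)))

so the potential distancing risk at activity ``i`` is
``p_i(y) = w_i * sigma_i(y_i)`` and an individual of strategy ``x`` carries
total risk ``pi(x, y) = sum_i x_i p_i(y)``.

Risk factors come in two reference flavors:

* contact factors ``alpha_i`` — derived so that a *complete social
  distancing* reference schedule is the equilibrium of the game;
* impact factors ``beta_i`` — derived so that a *free of social distancing*
  reference schedule is the equilibrium, anchored at the same risk level
  ``lambda`` as the contact-factor derivation.

A severity parameter ``delta_i`` in [0, 1] blends the two into the operative
factor ``w_i = delta_i * alpha_i + (1 - delta_i) * beta_i``.

Weekly schedules are expressed in active hours out of a 112-hour active week
(16 active hours per day); frequencies are hours / 112.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "WEEKLY_ACTIVE_HOURS",
    "SIMPLEX_TOL",
    "ValidationError",
    "DegenerateScheduleError",
    "ActivityCatalog",
    "RiskProfile",
    "Schedule",
    "logistic",
    "logistic_inverse",
    "as_strategy",
    "schedule_to_strategy",
    "strategy_to_schedule",
    "derive_factors",
    "blend_risk_factors",
    "potential_risk",
    "cost",
]

#: Total active hours in a week (16 active hours per day, 7 days).
WEEKLY_ACTIVE_HOURS = 112.0

#: Tolerance on |sum(freq) - 1| for a vector to count as a strategy.
SIMPLEX_TOL = 1e-9


class ValidationError(ValueError):
    """An input violates a model invariant (simplex, range, shape...)."""


class DegenerateScheduleError(ValidationError):
    """A reference schedule has a zero entry; the retrospective factor
    derivation assumes every activity is attended (y_i* > 0)."""


def logistic(y, kappa, theta):
    """Logistic risk response ``sigma(y) = 1 / (1 + exp(-kappa*(y - theta)))``.

    Strictly increasing in ``y``; ``sigma(theta) = 1/2``.  Accepts scalars or
    arrays (broadcast).
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(kappa, dtype=float) * (y - np.asarray(theta, dtype=float))
    out = np.empty_like(z, dtype=float)
    # split by sign for numerical stability
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


def logistic_inverse(p, kappa, theta):
    """Inverse of :func:`logistic`: ``theta - log(1/p - 1) / kappa``.

    Defined for ``p`` strictly inside (0, 1).

    Raises
    ------
    ValidationError
        If any ``p`` lies outside the open interval (0, 1).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValidationError("logistic_inverse requires 0 < p < 1")
    out = np.asarray(theta, dtype=float) - np.log(1.0 / p - 1.0) / np.asarray(
        kappa, dtype=float
    )
    if out.ndim == 0:
        return float(out)
    return out


def as_strategy(freq, tol: float = SIMPLEX_TOL) -> np.ndarray:
    """Validate and return ``freq`` as a strategy (point on the simplex)."""
    x = np.asarray(freq, dtype=float)
    if x.ndim != 1:
        raise ValidationError("a strategy must be a 1-D frequency vector")
    if np.any(x < 0):
        raise ValidationError("strategy frequencies must be nonnegative")
    if abs(x.sum() - 1.0) > tol:
        raise ValidationError(
            f"strategy frequencies must sum to 1 (got {x.sum():.12g})"
        )
    return x


@dataclass(frozen=True)
class ActivityCatalog:
    """A set of social activities with risk parameters.

    Parameters
    ----------
    labels : sequence of str
        Human-readable activity names.
    alpha : array-like
        Contact factors (positive), one per activity.
    beta : array-like
        Impact factors (positive), one per activity.
    kappa : array-like or float
        Logistic rate constants (positive); a scalar is broadcast.
    theta : array-like or float
        Logistic shifts, each in (0, 1); a scalar is broadcast.
    """

    labels: tuple
    alpha: np.ndarray
    beta: np.ndarray
    kappa: np.ndarray
    theta: np.ndarray

    def __init__(self, labels: Sequence[str], alpha, beta, kappa=10.0, theta=0.5):
        labels = tuple(str(s) for s in labels)
        n = len(labels)
        alpha = np.asarray(alpha, dtype=float)
        beta = np.asarray(beta, dtype=float)
        kappa = np.broadcast_to(np.asarray(kappa, dtype=float), (n,)).copy()
        theta = np.broadcast_to(np.asarray(theta, dtype=float), (n,)).copy()
        for name, arr in (("alpha", alpha), ("beta", beta)):
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have one entry per activity")
            if np.any(arr <= 0):
                raise ValidationError(f"{name} factors must be positive")
        if np.any(kappa <= 0):
            raise ValidationError("kappa must be positive")
        if np.any((theta <= 0) | (theta >= 1)):
            raise ValidationError("theta must lie strictly inside (0, 1)")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "kappa", kappa)
        object.__setattr__(self, "theta", theta)

    @property
    def n_activities(self) -> int:
        return len(self.labels)

    def sigma(self, y):
        """Per-activity logistic response evaluated coordinate-wise at ``y``."""
        return logistic(y, self.kappa, self.theta)

    def sigma_inverse(self, p):
        return logistic_inverse(p, self.kappa, self.theta)

    def risk_profile(self, delta) -> "RiskProfile":
        """Blend contact and impact factors with severity ``delta``."""
        return blend_risk_factors(self.alpha, self.beta, delta)


@dataclass(frozen=True)
class RiskProfile:
    """Operative risk factors ``w_i = delta_i*alpha_i + (1-delta_i)*beta_i``."""

    delta: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        if np.any((self.delta < 0) | (self.delta > 1)):
            raise ValidationError("severity delta must lie in [0, 1]")
        if np.any(self.w <= 0):
            raise ValidationError("risk factors w must be positive")


def blend_risk_factors(alpha, beta, delta) -> RiskProfile:
    """Build a :class:`RiskProfile` from contact/impact factors and severity.

    ``delta`` may be a scalar (applied to every activity) or per-activity.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    delta = np.broadcast_to(np.asarray(delta, dtype=float), alpha.shape).copy()
    if alpha.shape != beta.shape:
        raise ValidationError("alpha and beta must have matching lengths")
    if np.any((delta < 0) | (delta > 1)):
        raise ValidationError("severity delta must lie in [0, 1]")
    w = delta * alpha + (1.0 - delta) * beta
    return RiskProfile(delta=delta, w=w)


@dataclass(frozen=True)
class Schedule:
    """Weekly active hours per activity under a fixed active-hour budget."""

    hours: np.ndarray
    budget: float = WEEKLY_ACTIVE_HOURS

    def __init__(self, hours, budget: float = WEEKLY_ACTIVE_HOURS, tol: float = 1e-6):
        hours = np.asarray(hours, dtype=float)
        if hours.ndim != 1:
            raise ValidationError("hours must be a 1-D vector")
        if np.any(hours < 0):
            raise ValidationError("weekly hours must be nonnegative")
        if budget <= 0:
            raise ValidationError("budget must be positive")
        if abs(hours.sum() - budget) > tol:
            raise ValidationError(
                f"hours sum to {hours.sum():g}, expected budget {budget:g}"
            )
        object.__setattr__(self, "hours", hours)
        object.__setattr__(self, "budget", float(budget))

    def to_strategy(self) -> np.ndarray:
        return schedule_to_strategy(self)


def schedule_to_strategy(schedule: Schedule) -> np.ndarray:
    """Convert weekly hours into participating frequencies ``hours / budget``."""
    return as_strategy(schedule.hours / schedule.budget)


def strategy_to_schedule(freq, budget: float = WEEKLY_ACTIVE_HOURS) -> Schedule:
    """Convert a strategy back into weekly hours (``freq * budget``)."""
    freq = as_strategy(freq)
    return Schedule(freq * budget, budget=budget)


def derive_factors(
    reference: Schedule,
    kappa=10.0,
    theta=0.5,
    lambda_anchor="from-first-activity",
) -> np.ndarray:
    """Retrospectively derive risk factors from a reference equilibrium.

    Treat the reference schedule as the game's equilibrium ``y*``.  At an
    interior equilibrium every attended activity carries the same potential
    risk: ``w_i * sigma_i(y_i*) = lambda`` for all ``i``, hence
    ``w_i = lambda / sigma_i(y_i*)``.

    Parameters
    ----------
    reference : Schedule
        Reference weekly schedule; every activity must have positive hours.
    kappa, theta : float or array-like
        Logistic parameters (scalar broadcasts over activities).
    lambda_anchor : float or "from-first-activity"
        The common risk level.  With the default rule the anchor is
        ``sigma_1(y_1*)`` so the first activity's factor is exactly 1; an
        explicit positive float reuses a level from another derivation
        (impact factors reuse the contact-state anchor).

    Returns
    -------
    numpy.ndarray
        Positive risk factors ``w_i``, full double precision.
    """
    y = schedule_to_strategy(reference)
    if np.any(y <= 0):
        raise DegenerateScheduleError(
            "factor derivation needs strictly positive reference frequencies"
        )
    n = y.size
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), (n,))
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (n,))
    sig = logistic(y, kappa, theta)
    if isinstance(lambda_anchor, str):
        if lambda_anchor != "from-first-activity":
            raise ValidationError(f"unknown lambda anchor {lambda_anchor!r}")
        lam = float(sig[0])
    else:
        lam = float(lambda_anchor)
        if lam <= 0:
            raise ValidationError("explicit lambda anchor must be positive")
    return lam / sig


def potential_risk(y, profile: RiskProfile, catalog: ActivityCatalog) -> np.ndarray:
    """Per-activity potential distancing risk ``p_i(y) = w_i sigma_i(y_i)``."""
    return profile.w * catalog.sigma(np.asarray(y, dtype=float))


def cost(x, y, profile: RiskProfile, catalog: ActivityCatalog) -> float:
    """Total distancing risk ``pi(x, y) = sum_i x_i p_i(y)`` (linear in x)."""
    return float(np.asarray(x, dtype=float) @ potential_risk(y, profile, catalog))
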