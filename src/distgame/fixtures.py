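"""Built-in CASA activity catalog and reference schedules.

CASA — "commonly attended social activities" — is a stylized set of 20
activity categories typical of small-town North American daily life, grouped
in five contact-rate levels of four activities each.  The bundled catalog
carries the published contact factors (alpha) and impact factors (beta) at
their printed 4-decimal precision, with a shared logistic response
(kappa = 10, theta = 0.5).

Two reference schedules are bundled:

* ``casa20-complete-schedule`` — complete social distancing: time is
  concentrated on the low-contact activities (14 h/week on each of
  activities 1-4, down to 1 h/week on each of 17-20);
* ``casa20-free-schedule`` — free of social distancing: time follows
  ordinary social and economic life (16 h/week at schools, 20 h/week at
  workplaces, a few hours elsewhere).

Deriving factors from the complete-distancing schedule reproduces the
catalog's alphas; deriving from the free schedule, with the risk-level
anchor kept at the complete-distancing level, reproduces the betas.
"""

from __future__ import annotations

import numpy as np

from .catalog import ActivityCatalog, Schedule

__all__ = [
    "CASA20_LABELS",
    "casa20",
    "casa20_complete_schedule",
    "casa20_free_schedule",
    "CATALOG_FIXTURES",
    "SCHEDULE_FIXTURES",
]

CASA20_LABELS = (
    "reading or watching TV",
    "work at home",
    "hiking",
    "gardening",
    "stay with family",
    "grocery shopping",
    "go to hospitals",
    "visit friends",
    "restaurant/cafeteria dining",
    "go to shopping malls",
    "take buses",
    "go to churches",
    "watch sports",
    "attend concerts",
    "go to schools",
    "go to workplaces",
    "large gathering",
    "go to bars or night clubs",
    "air traveling",
    "go to movie theaters",
)

# Published contact factors, 4-decimal precision.
_CASA20_ALPHA = (
    1.0000, 1.0000, 1.0000, 1.0000,
    1.8483, 1.8483, 1.8483, 1.8483,
    2.4090, 2.4090, 2.4090, 2.4090,
    2.8754, 2.8754, 2.8754, 2.8754,
    3.1418, 3.1418, 3.1418, 3.1418,
)

# Published impact factors, 4-decimal precision.
_CASA20_BETA = (
    2.2052, 2.2052, 2.6318, 2.6318,
    2.2052, 2.6318, 2.6318, 2.2052,
    2.2052, 2.6318, 2.6318, 2.2052,
    2.4090, 2.4090, 0.8402, 0.5948,
    2.0188, 2.0188, 2.4090, 2.4090,
)

# Complete-social-distancing reference schedule, hours/week (112-hour week).
_COMPLETE_HOURS = (14, 14, 14, 14, 7, 7, 7, 7, 4, 4,
                   4, 4, 2, 2, 2, 2, 1, 1, 1, 1)

# Free-of-social-distancing reference schedule, hours/week.
_FREE_HOURS = (5, 5, 3, 3, 5, 3, 3, 5, 5, 3,
               3, 5, 4, 4, 16, 20, 6, 6, 4, 4)


def casa20() -> ActivityCatalog:
    """The 20-activity CASA catalog with published alpha/beta factors."""
    return ActivityCatalog(
        labels=CASA20_LABELS,
        alpha=np.array(_CASA20_ALPHA),
        beta=np.array(_CASA20_BETA),
        kappa=10.0,
        theta=0.5,
    )


def casa20_complete_schedule() -> Schedule:
    """Complete-social-distancing reference schedule (defines the alphas)."""
    return Schedule(np.array(_COMPLETE_HOURS, dtype=float))


def casa20_free_schedule() -> Schedule:
    """Free-of-social-distancing reference schedule (defines the betas)."""
    return Schedule(np.array(_FREE_HOURS, dtype=float))


CATALOG_FIXTURES = {"casa20": casa20}

SCHEDULE_FIXTURES = {
    "casa20-complete-schedule": casa20_complete_schedule,
    "casa20-free-schedule": casa20_free_schedule,
}
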