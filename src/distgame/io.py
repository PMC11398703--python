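"""Serialization: catalogs, schedules, strategy matrices, run reports.

Catalogs are YAML documents; schedules are two-column tab-delimited text
(activity label, hours/week); strategy matrices are tab-delimited text with
an activity-label header and optional leading ``group`` / ``leader``
columns.  All numeric fields round-trip at full double precision.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .catalog import ActivityCatalog, Schedule, ValidationError, WEEKLY_ACTIVE_HOURS
from .fixtures import CATALOG_FIXTURES, SCHEDULE_FIXTURES

__all__ = [
    "load_catalog",
    "write_catalog",
    "load_schedule",
    "write_schedule",
    "write_matrix",
    "read_matrix",
    "RunReport",
]


def load_catalog(source) -> ActivityCatalog:
    """Load an activity catalog from a fixture name or a YAML file.

    Fixture names: ``casa20``.  A YAML catalog is a mapping with an
    ``activities`` list of ``{label, alpha, beta, kappa, theta}`` entries.
    """
    if isinstance(source, str) and source in CATALOG_FIXTURES:
        return CATALOG_FIXTURES[source]()
    if isinstance(source, str) and source in SCHEDULE_FIXTURES:
        raise ValidationError(
            f"{source!r} is a schedule fixture; use load_schedule"
        )
    if not os.path.exists(source):
        raise ValidationError(f"no such catalog file or fixture: {source!r}")
    with open(source) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValidationError(f"malformed catalog document: {exc}") from exc
    try:
        acts = doc["activities"]
        labels = [a["label"] for a in acts]
        alpha = [float(a["alpha"]) for a in acts]
        beta = [float(a["beta"]) for a in acts]
        kappa = [float(a.get("kappa", 10.0)) for a in acts]
        theta = [float(a.get("theta", 0.5)) for a in acts]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed catalog document: missing {exc}") from exc
    return ActivityCatalog(labels, alpha, beta, kappa, theta)


def write_catalog(catalog: ActivityCatalog, path) -> None:
    """Write a catalog as a YAML document (lossless round trip)."""
    doc = {
        "activities": [
            {
                "label": catalog.labels[i],
                "alpha": float(catalog.alpha[i]),
                "beta": float(catalog.beta[i]),
                "kappa": float(catalog.kappa[i]),
                "theta": float(catalog.theta[i]),
            }
            for i in range(catalog.n_activities)
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_schedule(source, budget: float = WEEKLY_ACTIVE_HOURS) -> Schedule:
    """Load a weekly schedule from a fixture name or a delimited-text file.

    Fixture names: ``casa20-complete-schedule``, ``casa20-free-schedule``.
    Files carry two tab-separated columns: activity label, hours/week.
    """
    if isinstance(source, str) and source in SCHEDULE_FIXTURES:
        return SCHEDULE_FIXTURES[source]()
    if not os.path.exists(source):
        raise ValidationError(f"no such schedule file or fixture: {source!r}")
    hours = []
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{source}:{lineno}: expected 'label<TAB>hours', got {line!r}"
                )
            if lineno == 1 and parts[1].strip().lower() in ("hours", "hours/week"):
                continue  # header row
            try:
                hours.append(float(parts[1]))
            except ValueError as exc:
                raise ValidationError(
                    f"{source}:{lineno}: bad hours value {parts[1]!r}"
                ) from exc
    return Schedule(np.array(hours), budget=budget)


def write_schedule(labels, hours, path) -> None:
    """Write a schedule as two-column delimited text with a header."""
    with open(path, "w") as fh:
        fh.write("activity\thours\n")
        for lab, h in zip(labels, hours):
            fh.write(f"{lab}\t{float(h)!r}\n")


def write_matrix(
    strategies,
    labels,
    path,
    groups=None,
    leaders=None,
    hours: bool = False,
    budget: float = WEEKLY_ACTIVE_HOURS,
) -> None:
    """Write a strategy matrix (individuals x activities) as delimited text.

    Optional ``groups`` (1-based in the file) and ``leaders`` (0/1) columns
    precede the per-activity columns.  With ``hours=True`` frequencies are
    written as weekly hours (``freq * budget``).
    """
    X = np.asarray(strategies, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(labels):
        raise ValidationError("strategy matrix shape does not match labels")
    cols = []
    if groups is not None:
        cols.append("group")
    if leaders is not None:
        cols.append("leader")
    header = "\t".join(cols + list(labels))
    out = X * budget if hours else X
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(X.shape[0]):
            row = []
            if groups is not None:
                row.append(str(int(groups[i]) + 1))
            if leaders is not None:
                row.append(str(int(bool(leaders[i]))))
            row += [repr(float(v)) for v in out[i]]
            fh.write("\t".join(row) + "\n")


def read_matrix(path):
    """Read a strategy matrix written by :func:`write_matrix`.

    Returns ``(strategies, labels, groups, leaders)``; ``groups`` (0-based)
    and ``leaders`` are ``None`` when the file has no such columns.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValidationError(f"{path}: empty matrix file")
        cols = header.split("\t")
        has_groups = cols and cols[0] == "group"
        if has_groups:
            cols = cols[1:]
        has_leaders = cols and cols[0] == "leader"
        if has_leaders:
            cols = cols[1:]
        labels = cols
        rows, groups, leaders = [], [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            expect = len(labels) + has_groups + has_leaders
            if len(parts) != expect:
                raise ValidationError(
                    f"{path}:{lineno}: expected {expect} columns, got {len(parts)}"
                )
            if has_groups:
                groups.append(int(parts.pop(0)) - 1)
            if has_leaders:
                leaders.append(bool(int(parts.pop(0))))
            rows.append([float(v) for v in parts])
    X = np.array(rows, dtype=float).reshape(len(rows), len(labels))
    return (
        X,
        labels,
        np.array(groups, dtype=int) if has_groups else None,
        np.array(leaders, dtype=bool) if has_leaders else None,
    )


@dataclass
class RunReport:
    """Structured record of a simulation run.

    Round-trips losslessly through JSON: numeric fields are serialized at
    full double precision.
    """

    config: dict
    trajectories: list
    equilibrium: list
    seeds: list
    wall_clock_seconds: float = 0.0
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "trajectories": [[float(v) for v in t] for t in self.trajectories],
            "equilibrium": [[float(v) for v in e] for e in self.equilibrium],
            "seeds": [int(s) for s in self.seeds],
            "wall_clock_seconds": float(self.wall_clock_seconds),
            "extras": self.extras,
        }
        return json.dumps(payload, indent=2)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "RunReport":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            config=payload["config"],
            trajectories=payload["trajectories"],
            equilibrium=payload["equilibrium"],
            seeds=payload["seeds"],
            wall_clock_seconds=payload.get("wall_clock_seconds", 0.0),
            extras=payload.get("extras", {}),
        )
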