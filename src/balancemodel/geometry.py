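"""Trait-space geometry: phenotype sets, fitness isoclines, optimal loci.

A phenotype set is the curve of trait combinations (x1(u1), x2(R - u1))
achievable at a fixed budget R (fitness-set representation).  Fitness
isoclines are level sets of W in the (x1, x2) plane — straight lines under
additive fitness, downward-convex hyperbolas under multiplicative fitness.
The optimal allocation at each R is the point where its phenotype set
touches the highest reachable isocline; the optimal locus strings those
tangency points together across budgets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .components import DomainError, TradeoffScenario
from .optimize import Allocation, AllocationPath


@dataclass
class Curve:
    """Ordered (x1, x2) polyline with a label and metadata.

    Gaps (e.g. at allocation discontinuities) are encoded as NaN rows in
    ``points`` and listed in ``meta["gaps"]`` — never interpolated across.
    """

    points: np.ndarray  # (m, 2)
    label: str = ""
    meta: dict[str, Any] = field(default_factory=dict)


class CornerAllocationError(ValueError):
    """Tangency check requested at a corner, where it is inapplicable."""


def phenotype_set(scenario: TradeoffScenario, R: float,
                  n_points: int = 256) -> Curve:
    """Achievable trait combinations {(x1(u1), x2(R-u1)) : u1 in [0, R]}."""
    if scenario.n != 2:
        raise NotImplementedError("phenotype sets are drawn for n=2 only")
    if R < 0:
        raise ValueError("R must be nonnegative")
    u1 = np.linspace(0.0, R, 1 if R == 0 else n_points)
    pts = np.column_stack([
        np.atleast_1d(scenario.components[0].evaluate(u1)),
        np.atleast_1d(scenario.components[1].evaluate(R - u1)),
    ])
    return Curve(pts, label=f"phenotype set R={R:g}", meta={"R": float(R)})


def isocline(rule: str, W_level: float, x1_range: tuple[float, float],
             n_points: int = 256) -> Curve:
    """Equal-fitness locus in trait space: x2 = W - x1 or x2 = W / x1."""
    lo, hi = x1_range
    if rule == "multiplicative":
        if W_level <= 0:
            raise ValueError("multiplicative isoclines need W_level > 0")
        if lo <= 0 <= hi or lo <= 0:
            raise DomainError("multiplicative isocline undefined at x1 <= 0")
        x1 = np.linspace(lo, hi, n_points)
        x2 = W_level / x1
    elif rule == "additive":
        x1 = np.linspace(lo, hi, n_points)
        x2 = W_level - x1
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return Curve(np.column_stack([x1, x2]),
                 label=f"isocline W={W_level:g}",
                 meta={"W": float(W_level), "rule": rule})


def optimal_locus(path: AllocationPath) -> Curve:
    """The (x1*, x2*) sequence over R, with NaN breaks at discontinuities."""
    if not path.allocations:
        raise ValueError("empty path")
    pts = [list(a.x[:2]) for a in path.allocations]
    gaps = []
    # insert one NaN row after the grid point preceding each jump bracket
    offsets = 0
    for (rlo, _rhi) in sorted(path.discontinuities):
        i = int(np.searchsorted(path.R_grid, rlo, side="right")) - 1
        j = i + 1 + offsets
        pts.insert(j, [np.nan, np.nan])
        gaps.append(j)
        offsets += 1
    return Curve(np.asarray(pts, dtype=float), label="optimal locus",
                 meta={"gaps": gaps,
                       "R_range": (float(path.R_grid[0]), float(path.R_grid[-1]))})


def tangency_check(scenario: TradeoffScenario, R: float,
                   allocation: Allocation, tol: float = 1e-6) -> bool:
    """True iff the phenotype set is tangent to the W* isocline at the optimum.

    The phenotype-set tangent at u1 is (x1'(u1), -x2'(u2)); the isocline
    tangent at (x1*, x2*) is (1, -1) for additive fitness and
    (1, -x2*/x1*) for multiplicative.  The check compares the normalized
    cross product of the two directions against ``tol``.

    Only applicable at interior optima: raises
    :class:`CornerAllocationError` at a corner (distinct from ``False``).
    """
    if scenario.n != 2:
        raise NotImplementedError("tangency check is defined for n=2 only")
    u1, u2 = float(allocation.u[0]), float(allocation.u[1])
    if not (u1 > 0 and u2 > 0):
        raise CornerAllocationError(
            "tangency is inapplicable at a corner allocation")
    t_set = np.array([scenario.components[0].derivative(u1, 1),
                      -scenario.components[1].derivative(u2, 1)])
    x1s, x2s = float(allocation.x[0]), float(allocation.x[1])
    if scenario.rule == "additive":
        t_iso = np.array([1.0, -1.0])
    else:
        t_iso = np.array([1.0, -x2s / x1s])
    cross = t_set[0] * t_iso[1] - t_set[1] * t_iso[0]
    norm = np.linalg.norm(t_set) * np.linalg.norm(t_iso)
    return bool(abs(cross) / norm < tol)
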