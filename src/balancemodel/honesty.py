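"""Honesty diagnostics for allocation paths.

A signal is honest when optimal signal investment u1*(R) never decreases
with the resource budget R: a receiver can then read quality off signal
size.  This module classifies a computed allocation path as honest or not,
locates violation intervals, and evaluates two analytic conditions on the
viability component x2:

* the *necessary* condition for a breakdown of honesty — the condition-8
  margin m(u2) = x2'' x2 - (x2')^2 turning positive somewhere (equivalently,
  the elasticity S2 increasing with investment);
* the *sufficient* condition for honesty — S2(u2) strictly decreasing over
  the investments the path visits.

A corner prefix (u1* = 0 at low R) does not count against honesty: absent
signals merely mark the lower range of quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import brentq

from .components import ComponentFunction, PreconditionError, UndefinedGradientError
from .optimize import CORNER_TOL, AllocationPath


@dataclass
class HonestyReport:
    """Monotonicity classification of a path and the analytic conditions."""

    honest: bool
    violation_intervals: list[tuple[float, float]]
    x1_monotone: bool
    x1_violation_intervals: list[tuple[float, float]]
    x1_flat: bool  # max - min of x1* below tolerance: uninformative, not dishonest
    corner_prefix: tuple[float, float] | None
    condition8_positive_intervals: list[tuple[float, float]]
    s2_strictly_decreasing: bool
    s2_witness: tuple[float, float] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def as_dict(self) -> dict[str, Any]:
        return {
            "honest": self.honest,
            "violation_intervals": [list(v) for v in self.violation_intervals],
            "x1_monotone": self.x1_monotone,
            "x1_violation_intervals": [list(v) for v in self.x1_violation_intervals],
            "x1_flat": self.x1_flat,
            "corner_prefix": list(self.corner_prefix) if self.corner_prefix else None,
            "condition8_positive_intervals":
                [list(v) for v in self.condition8_positive_intervals],
            "s2_strictly_decreasing": self.s2_strictly_decreasing,
            "s2_witness": list(self.s2_witness) if self.s2_witness else None,
            "meta": self.meta,
        }


def _decreasing_intervals(grid, values, tol):
    """Merge adjacent grid steps where `values` strictly decreases by > tol."""
    dec = np.diff(values) < -tol
    out, start = [], None
    for i, flag in enumerate(dec):
        if flag and start is None:
            start = grid[i]
        elif not flag and start is not None:
            out.append((float(start), float(grid[i])))
            start = None
    if start is not None:
        out.append((float(start), float(grid[-1])))
    return out


def s2_monotonicity(component: ComponentFunction, u_range: tuple[float, float],
                    n_probe: int = 512):
    """Probe whether the elasticity S(u) is strictly decreasing on a range.

    Returns ``(True, None)`` if successive probe values descend with margin
    > 1e-12, else ``(False, (u_a, u_b))`` with a witness pair u_a < u_b
    where S(u_a) <= S(u_b).  A probe check, not a proof.
    """
    lo, hi = u_range
    us = np.linspace(lo, hi, n_probe)
    try:
        s = np.asarray(component.selection_gradient(us))
    except (UndefinedGradientError, ZeroDivisionError) as err:
        raise PreconditionError(
            f"selection gradient undefined on [{lo}, {hi}]: {err}") from err
    bad = np.flatnonzero(np.diff(s) > -1e-12)
    if len(bad):
        i = int(bad[0])
        return False, (float(us[i]), float(us[i + 1]))
    return True, None


def classify_regimes(component: ComponentFunction, u_range: tuple[float, float],
                     n_probe: int = 512,
                     zero_tol: float = 1e-9) -> list[tuple[tuple[float, float], int]]:
    """Partition a range into maximal sign-constant intervals of the margin.

    Each entry is ``((u_lo, u_hi), sign)`` with sign in {-1, 0, +1} for the
    condition-8 margin m(u) = x'' x - (x')^2 on that interval.  Sign changes
    between probe points are located by Brent root bracketing; margins whose
    magnitude stays below ``zero_tol`` relative to (x')^2 count as zero
    (the exponential knife-edge).
    """
    lo, hi = u_range
    us = np.linspace(lo, hi, n_probe)
    m = np.asarray(component.condition8_margin(us))
    scale = np.maximum(np.asarray(component.derivative(us, 1)) ** 2, 1e-300)
    signs = np.where(np.abs(m) <= zero_tol * scale, 0, np.sign(m)).astype(int)

    out = []
    start = us[0]
    cur = signs[0]
    for i in range(1, n_probe):
        if signs[i] == cur:
            continue
        if cur != 0 and signs[i] != 0 and signs[i] == -cur:
            root = brentq(lambda u: component.condition8_margin(u), us[i - 1], us[i],
                          xtol=1e-12)
        else:
            root = 0.5 * (us[i - 1] + us[i])
        out.append(((float(start), float(root)), int(cur)))
        start, cur = root, signs[i]
    out.append(((float(start), float(hi)), int(cur)))
    return out


def honesty_report(path: AllocationPath, scenario=None,
                   tol: float = 1e-6, n_probe: int = 512) -> HonestyReport:
    """Classify a path as honest/dishonest and evaluate the viability conditions.

    Decreases of u1* smaller than ``tol`` (refinement noise) are ignored.
    With a scenario supplied, the condition-8 regimes and S2 monotonicity of
    the viability component are evaluated over the u2 values the path visits.
    """
    if len(path.allocations) < 2:
        raise ValueError("honesty needs a path of at least 2 allocations")
    R = path.R_grid
    u1 = path.u[:, 0]
    x1 = path.x[:, 0]

    violations = _decreasing_intervals(R, u1, tol)
    x1_viol = _decreasing_intervals(R, x1, tol)
    x1_flat = bool(x1.max() - x1.min() < tol)

    corner = None
    if u1[0] <= CORNER_TOL:
        k = int(np.argmax(u1 > CORNER_TOL)) if np.any(u1 > CORNER_TOL) else len(u1) - 1
        corner = (float(R[0]), float(R[max(k - 1, 0)]))

    cond8_pos: list[tuple[float, float]] = []
    s2_dec, witness = False, None
    if scenario is not None and scenario.n >= 2:
        viab = scenario.components[1]
        u2 = path.u[:, 1]
        lo, hi = float(u2.min()), float(u2.max())
        # S2 and the margin need x2, x2' > 0: nudge off a zero at the left edge
        if lo < hi:
            try:
                if viab.evaluate(lo) <= 0.0:
                    lo = lo + 1e-9 * max(1.0, hi)
                regimes = classify_regimes(viab, (lo, hi), n_probe)
                cond8_pos = [iv for iv, s in regimes if s > 0]
                s2_dec, witness = s2_monotonicity(viab, (lo, hi), n_probe)
            except (PreconditionError, UndefinedGradientError):
                pass  # diagnostics unavailable on this range; path verdict stands

    honest = len(violations) == 0
    if s2_dec and not honest:
        # strictly decreasing S2 guarantees honesty; a violation here means
        # the optimizer returned a non-global optimum somewhere
        raise RuntimeError(
            "inconsistent result: S2 strictly decreasing but path shows "
            f"dishonesty at {violations} — solver failure suspected"
        )

    return HonestyReport(
        honest=honest,
        violation_intervals=violations,
        x1_monotone=len(x1_viol) == 0,
        x1_violation_intervals=x1_viol,
        x1_flat=x1_flat,
        corner_prefix=corner,
        condition8_positive_intervals=cond8_pos,
        s2_strictly_decreasing=s2_dec,
        s2_witness=witness,
        meta={"R_min": float(R[0]), "R_max": float(R[-1]), "n_grid": len(R),
              "tol": tol},
    )
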