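"""Constrained allocation: maximize W over the budget simplex u >= 0, sum u = R.

The two-component problem is reduced to one dimension (u1 in [0, R]) and
solved globally: a dense scan brackets every local maximum, each bracket is
polished by bounded scalar minimization, and the endpoints (corner
candidates) are always evaluated.  Single-start local optimization is not
enough here — objectives like the sharp-threshold mating function of the
third worked scenario are multimodal, and the global optimum hops between
branches as R grows, producing genuine discontinuities in u1*(R).

For n > 2 a multistart SLSQP fallback is provided as best-effort; the
brute-force simplex grid serves as an independent oracle for small n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .components import (BalanceModelError, EvaluationError, TradeoffScenario,
                         UndefinedGradientError)

#: Two optima closer than this in W are treated as ties (multiplicity).
TIE_TOL = 1e-9
#: Investments below this are treated as corners (u_i = 0).
CORNER_TOL = 1e-12


def fitness(scenario: TradeoffScenario, u: Sequence[float]) -> float:
    """Combine component values at investments u under the scenario rule."""
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != scenario.n:
        raise ValueError(
            f"expected {scenario.n} investments, got {u.shape[-1]}"
        )
    xs = [c.evaluate(u[..., i]) for i, c in enumerate(scenario.components)]
    if scenario.rule == "additive":
        return sum(xs)
    out = xs[0]
    for x in xs[1:]:
        out = out * x
    return out


@dataclass
class Allocation:
    """Optimal allocation at one budget R, with optimality diagnostics.

    ``gradient_residual`` is the maximum pairwise mismatch of the relevant
    marginal quantity over interior components: elasticities S_i for
    multiplicative fitness, slopes x_i' for additive.  NaN when fewer than
    two components are interior.
    """

    R: float
    u: np.ndarray
    x: np.ndarray
    W: float
    interior_flags: np.ndarray
    gradient_residual: float
    multiplicity: bool = False

    def __post_init__(self):
        assert abs(self.u.sum() - self.R) <= 1e-9, "budget not conserved"
        assert np.all(self.u >= 0.0), "negative investment"


@dataclass
class AllocationPath:
    """Global optima along an increasing grid of budgets R."""

    R_grid: np.ndarray
    allocations: list[Allocation]
    discontinuities: list[tuple[float, float]] = field(default_factory=list)
    corner_segments: list[tuple[float, float]] = field(default_factory=list)

    @property
    def u(self) -> np.ndarray:
        """(len(R_grid), n) array of optimal investments."""
        return np.array([a.u for a in self.allocations])

    @property
    def x(self) -> np.ndarray:
        return np.array([a.x for a in self.allocations])

    @property
    def W(self) -> np.ndarray:
        return np.array([a.W for a in self.allocations])


def _diagnostics(scenario, u):
    """Component values, interior flags and marginal-condition residual at u."""
    xs = np.array([c.evaluate(ui) for c, ui in zip(scenario.components, u)])
    interior = u > CORNER_TOL
    resid = float("nan")
    if interior.sum() >= 2:
        vals = []
        for i in np.flatnonzero(interior):
            c = scenario.components[i]
            try:
                vals.append(
                    c.selection_gradient(u[i])
                    if scenario.rule == "multiplicative"
                    else c.derivative(u[i], 1)
                )
            except UndefinedGradientError:
                vals.append(np.nan)  # x_i = 0 at an interior point: skip
        vals = np.asarray(vals)
        vals = vals[np.isfinite(vals)]
        if len(vals) >= 2:
            resid = float(vals.max() - vals.min())
    return xs, interior, resid


def _finish(scenario, R, u, W, multiplicity=False) -> Allocation:
    u = np.asarray(u, dtype=float).copy()
    u[np.abs(u) < CORNER_TOL] = 0.0
    if u.sum() > 0:
        u *= R / u.sum()  # exact budget conservation
    xs, interior, resid = _diagnostics(scenario, u)
    return Allocation(R=R, u=u, x=xs, W=float(W),
                      interior_flags=interior, gradient_residual=resid,
                      multiplicity=multiplicity)


def _optimize_2(scenario, R, scan_n, refine_xatol):
    c1, c2 = scenario.components[0], scenario.components[1]
    us = np.linspace(0.0, R, scan_n)
    x1 = np.asarray(c1.evaluate(us))
    x2 = np.asarray(c2.evaluate(R - us))
    w = x1 + x2 if scenario.rule == "additive" else x1 * x2
    if not np.all(np.isfinite(w)):
        bad = us[~np.isfinite(w)][0]
        raise EvaluationError(f"non-finite fitness at u1={bad} (R={R})")

    def neg(u1):
        return -(fitness(scenario, [u1, R - u1]))

    # bracket every local maximum of the scan (endpoints included)
    cands = []
    ge_left = np.r_[True, w[1:] >= w[:-1]]
    ge_right = np.r_[w[:-1] >= w[1:], True]
    for i in np.flatnonzero(ge_left & ge_right):
        a = us[max(i - 1, 0)]
        b = us[min(i + 1, scan_n - 1)]
        if b - a <= refine_xatol:
            cands.append((float(w[i]), float(us[i])))
            continue
        res = minimize_scalar(neg, bounds=(a, b), method="bounded",
                              options={"xatol": refine_xatol})
        cands.append((float(-res.fun), float(res.x)))
    cands.append((float(w[0]), 0.0))
    cands.append((float(w[-1]), float(R)))

    w_best = max(c[0] for c in cands)
    near = sorted(u for (wv, u) in cands if wv >= w_best - TIE_TOL)
    u1 = near[0]  # deterministic tie-break: smallest u1
    multiplicity = (near[-1] - near[0]) > 10 * refine_xatol
    return _finish(scenario, R, [u1, R - u1], fitness(scenario, [u1, R - u1]),
                   multiplicity)


def _optimize_n(scenario, R, seed, n_starts):
    n = scenario.n
    rng = np.random.default_rng(seed)
    cons = ({"type": "eq", "fun": lambda u: u.sum() - R},)
    bounds = [(0.0, R)] * n
    starts = [np.full(n, R / n)]
    starts += [R * rng.dirichlet(np.ones(n)) for _ in range(n_starts - 1)]
    for i in range(n):  # corner starts
        e = np.zeros(n)
        e[i] = R
        starts.append(e)
    best_u, best_w = None, -np.inf
    for s in starts:
        res = minimize(lambda u: -fitness(scenario, np.clip(u, 0, None)),
                       s, method="SLSQP", bounds=bounds, constraints=cons,
                       options={"maxiter": 200, "ftol": 1e-12})
        u = np.clip(res.x, 0.0, None)
        if u.sum() > 0:
            u *= R / u.sum()
        wv = fitness(scenario, u)
        if wv > best_w + TIE_TOL or (abs(wv - best_w) <= TIE_TOL and u[0] < best_u[0]):
            best_u, best_w = u, max(wv, best_w)
    return _finish(scenario, R, best_u, best_w)


def optimize_allocation(scenario: TradeoffScenario, R: float, *,
                        scan_n: int = 4096, refine_xatol: float = 1e-10,
                        seed: int = 0, n_starts: int = 16) -> Allocation:
    """Globally maximize fitness over {u >= 0, sum(u) = R}.

    For n = 2 the search is exhaustive (dense scan + bounded refinement in
    every local-maximum bracket); for n > 2, seeded multistart SLSQP.
    Ties within ``TIE_TOL`` in W return the smallest-u1 optimum and flag
    ``multiplicity`` — at a path discontinuity, R at the jump is exactly
    the tie point.
    """
    if R < 0:
        raise ValueError("budget R must be nonnegative")
    if R == 0:
        u = np.zeros(scenario.n)
        return _finish(scenario, 0.0, u, fitness(scenario, u))
    if scenario.n == 2:
        return _optimize_2(scenario, R, scan_n, refine_xatol)
    return _optimize_n(scenario, R, seed, n_starts)


def brute_force_allocation(scenario: TradeoffScenario, R: float,
                           grid_n: int = 10001) -> Allocation:
    """Best point of a uniform simplex grid — the unrefined testing oracle."""
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    if scenario.n == 2:
        us = np.linspace(0.0, R, grid_n)
        x1 = np.asarray(scenario.components[0].evaluate(us))
        x2 = np.asarray(scenario.components[1].evaluate(R - us))
        w = x1 + x2 if scenario.rule == "additive" else x1 * x2
        i = int(np.argmax(w))
        u = np.array([us[i], R - us[i]])
        return _finish(scenario, R, u, float(w[i]))
    if scenario.n == 3 and grid_n <= 600:
        best_u, best_w = None, -np.inf
        for u1 in np.linspace(0, R, grid_n):
            for u2 in np.linspace(0, R - u1, grid_n):
                u = np.array([u1, u2, R - u1 - u2])
                wv = fitness(scenario, u)
                if wv > best_w:
                    best_u, best_w = u, wv
        return _finish(scenario, R, best_u, best_w)
    raise NotImplementedError(
        f"exhaustive gridding not feasible for n={scenario.n}, grid_n={grid_n}"
    )


def allocation_path(scenario: TradeoffScenario, R_grid: Sequence[float], *,
                    scan_n: int = 4096, jump_threshold: float | None = None,
                    **opts) -> AllocationPath:
    """Global optima per budget, with discontinuity and corner annotations."""
    R_grid = np.asarray(R_grid, dtype=float)
    if R_grid.ndim != 1 or len(R_grid) < 2 or np.any(np.diff(R_grid) <= 0):
        raise ValueError("R_grid must be strictly increasing with >= 2 points")
    if np.any(R_grid < 0):
        raise ValueError("budgets must be nonnegative")
    allocs = []
    for R in R_grid:
        try:
            allocs.append(optimize_allocation(scenario, float(R),
                                              scan_n=scan_n, **opts))
        except BalanceModelError as err:
            raise type(err)(f"{err} (at R={R})") from err
    path = AllocationPath(R_grid=R_grid, allocations=allocs)
    path.discontinuities = detect_discontinuities(
        path, scenario=scenario, jump_threshold=jump_threshold, scan_n=scan_n)
    path.corner_segments = _corner_segments(path)
    return path


def _corner_segments(path: AllocationPath) -> list[tuple[float, float]]:
    """Maximal R-intervals on which some component gets zero investment."""
    at_corner = np.array([np.any(a.u <= CORNER_TOL) for a in path.allocations])
    segs, start = [], None
    for R, flag in zip(path.R_grid, at_corner):
        if flag and start is None:
            start = R
        elif not flag and start is not None:
            segs.append((float(start), float(prev)))
            start = None
        prev = R
    if start is not None:
        segs.append((float(start), float(path.R_grid[-1])))
    return segs


def detect_discontinuities(path: AllocationPath, *, scenario=None,
                           jump_threshold: float | None = None,
                           bracket_width: float = 1e-4,
                           scan_n: int = 4096) -> list[tuple[float, float]]:
    """Brackets (R_lo, R_hi) around jumps of the optimal u1.

    A jump is an adjacent-grid step where \\|Δu1*\\| exceeds the threshold
    (default: max(0.05, 10 x median adjacent \\|Δu1*\\|)).  With a scenario
    supplied, each bracket is refined by bisection on R — re-solving the
    allocation at the midpoint and keeping the half that still contains
    the jump — down to ``bracket_width``.
    """
    u1 = path.u[:, 0]
    du = np.abs(np.diff(u1))
    if len(du) == 0:
        return []
    if jump_threshold is None:
        jump_threshold = max(0.05, 10.0 * float(np.median(du)))
    brackets = []
    for i in np.flatnonzero(du > jump_threshold):
        a, b = float(path.R_grid[i]), float(path.R_grid[i + 1])
        ua, ub = u1[i], u1[i + 1]
        if scenario is not None:
            while b - a > bracket_width:
                m = 0.5 * (a + b)
                um = optimize_allocation(scenario, m, scan_n=scan_n).u[0]
                if abs(um - ua) < abs(um - ub):
                    a, ua = m, um
                else:
                    b, ub = m, um
        brackets.append((a, b))
    return brackets


def verify_marginal_conditions(scenario: TradeoffScenario,
                               allocation: Allocation,
                               tol: float = 1e-6) -> dict[str, Any]:
    """First-order optimality diagnostics for an allocation.

    Interior components must equalize their marginal quantity (slopes
    x_i' under additive fitness, elasticities S_i under multiplicative);
    every funded/unfunded pair must satisfy the corner inequality
    (marginal quantity of the funded component) >= (that of the unfunded
    component at 0) - tol.
    """
    u = allocation.u
    interior = np.flatnonzero(allocation.interior_flags)
    corner = np.flatnonzero(~allocation.interior_flags)

    def marginal(i, ui):
        c = scenario.components[i]
        if scenario.rule == "multiplicative":
            try:
                return c.selection_gradient(ui)
            except UndefinedGradientError:
                return np.nan
        return c.derivative(ui, 1)

    m_int = {int(i): marginal(i, u[i]) for i in interior}
    finite = [v for v in m_int.values() if np.isfinite(v)]
    interior_residual = (max(finite) - min(finite)) if len(finite) >= 2 else 0.0

    corner_checks = []
    for j in corner:
        mj0 = marginal(j, 0.0)
        for i in interior:
            mi = m_int[int(i)]
            if np.isfinite(mi) and np.isfinite(mj0):
                corner_checks.append({
                    "funded": int(i), "unfunded": int(j),
                    "margin": float(mi - mj0),
                    "holds": bool(mi >= mj0 - tol),
                })
    return {
        "rule": scenario.rule,
        "interior": [int(i) for i in interior],
        "interior_marginals": {k: float(v) for k, v in m_int.items()},
        "interior_residual": float(interior_residual),
        "interior_ok": bool(interior_residual < tol),
        "corner_checks": corner_checks,
        "corner_ok": all(c["holds"] for c in corner_checks),
        "pass": bool(interior_residual < tol) and all(c["holds"] for c in corner_checks),
    }
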