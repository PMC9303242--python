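"""Fitness-component functions x_i(u_i) and their local diagnostics.

A fitness component is a positive-valued trait (mating success, viability,
fecundity, ...) that increases with the resources u invested in it.  Each
catalog form carries analytic first and second derivatives, from which the
selection gradient (elasticity) S(u) = x'(u)/x(u) and the honesty-breakdown
margin m(u) = x''(u) x(u) - x'(u)^2 are computed.  The sign of m decides
whether S is locally increasing (m > 0, viability "accelerates" strongly
enough to undermine honest signaling) or decreasing (m < 0).

All evaluation functions are vectorized over u (numpy arrays in, arrays
out); scalars in, Python floats out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import erf


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class BalanceModelError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(BalanceModelError):
    """Investment u below the component's domain."""


class EvaluationError(BalanceModelError):
    """A component or fitness evaluation produced a non-finite value."""


class CatalogError(BalanceModelError, KeyError):
    """Unknown catalog form or scenario name."""


class UndefinedGradientError(BalanceModelError):
    """Selection gradient requested where x(u) = 0."""


class PreconditionError(BalanceModelError):
    """A diagnostic's precondition (e.g. x'(u) > 0) does not hold."""


# ---------------------------------------------------------------------------
# catalog forms
# ---------------------------------------------------------------------------
#
# Each form maps (params, u) -> (x, x', x'').  Parameter names are part of
# the public config contract and must stay stable.

def _linear(p: Mapping[str, float], u):
    s = p.get("slope", 1.0)
    c = p.get("intercept", 0.0)
    u = np.asarray(u, dtype=float)
    return c + s * u, np.broadcast_to(np.asarray(s, float), u.shape).copy(), np.zeros_like(u)


def _quadratic(p: Mapping[str, float], u):
    # a*u - b*u^2 (concave for b > 0); Fig. 1 mating success is a=1.5, b=0.7
    a, b = p["a"], p["b"]
    u = np.asarray(u, dtype=float)
    return a * u - b * u**2, a - 2.0 * b * u, np.full_like(u, -2.0 * b)


def _affine_quadratic(p: Mapping[str, float], u):
    # c + a*u - b*u^2; positive intercept c lets zero investment retain
    # some success (Fig. 2 mating: c=0.2, a=1, b=0.5)
    a, b, c = p["a"], p["b"], p["c"]
    u = np.asarray(u, dtype=float)
    return c + a * u - b * u**2, a - 2.0 * b * u, np.full_like(u, -2.0 * b)


def _power_sum(p: Mapping[str, float], u):
    # a*u + b*u^k: accelerating for k > 1 (Fig. 2 viability: u + u^20)
    a = p.get("a", 1.0)
    b = p.get("b", 1.0)
    k = p["k"]
    u = np.asarray(u, dtype=float)
    with np.errstate(over="ignore"):
        x = a * u + b * u**k
        d1 = a + b * k * u ** (k - 1)
        d2 = b * k * (k - 1) * u ** (k - 2)
    return x, d1, d2


def _exp_erf(p: Mapping[str, float], u):
    # exp[a*u + erf(s*(u - m))]: near-flat, then a sharp sigmoidal rise in
    # the exponent around u = m (Fig. 3 mating: a=0.1, s=3, m=3)
    a = p.get("a", 0.1)
    s = p.get("s", 3.0)
    m = p.get("m", 3.0)
    u = np.asarray(u, dtype=float)
    z = s * (u - m)
    g = a * u + erf(z)
    gp = a + s * (2.0 / np.sqrt(np.pi)) * np.exp(-(z**2))
    gpp = -2.0 * z * s**2 * (2.0 / np.sqrt(np.pi)) * np.exp(-(z**2))
    x = np.exp(g)
    return x, gp * x, (gpp + gp**2) * x


def _double_exponential(p: Mapping[str, float], u):
    # exp[a*(1 - exp(-k*u))]: saturating viability with S(u) = a*k*exp(-k*u),
    # strictly decreasing (Fig. 3 viability: a=1, k=1)
    a = p.get("a", 1.0)
    k = p.get("k", 1.0)
    u = np.asarray(u, dtype=float)
    g = a * (1.0 - np.exp(-k * u))
    gp = a * k * np.exp(-k * u)
    gpp = -k * gp
    x = np.exp(g)
    return x, gp * x, (gpp + gp**2) * x


def _exponential(p: Mapping[str, float], u):
    # c*exp(k*u): the knife-edge case with condition-8 margin identically 0
    k = p.get("k", 1.0)
    c = p.get("c", 1.0)
    u = np.asarray(u, dtype=float)
    x = c * np.exp(k * u)
    return x, k * x, k * k * x


_CATALOG = {
    "linear": _linear,
    "quadratic": _quadratic,
    "affine-quadratic": _affine_quadratic,
    "power-sum": _power_sum,
    "exp-erf": _exp_erf,
    "double-exponential": _double_exponential,
    "exponential": _exponential,
}

#: Required / recognised parameter keys per form (for config validation).
CATALOG_PARAMS = {
    "linear": {"slope", "intercept"},
    "quadratic": {"a", "b"},
    "affine-quadratic": {"a", "b", "c"},
    "power-sum": {"a", "b", "k"},
    "exp-erf": {"a", "s", "m"},
    "double-exponential": {"a", "k"},
    "exponential": {"k", "c"},
    "user-tabulated": {"u", "x"},
}


@dataclass(frozen=True)
class ComponentFunction:
    """One fitness component x(u) with analytic (or tabulated) derivatives.

    Parameters
    ----------
    name : str
        Display name, e.g. ``"mating success"``.
    form : str
        A catalog form name (see :data:`CATALOG_PARAMS`) or
        ``"user-tabulated"``.
    params : mapping
        Named real parameters of the form; for ``user-tabulated``, arrays
        ``u`` (strictly increasing) and ``x``.
    domain_min : float
        Lower end of the valid investment range (default 0).
    """

    name: str
    form: str
    params: Mapping[str, Any] = field(default_factory=dict)
    domain_min: float = 0.0

    def __post_init__(self):
        if self.form == "user-tabulated":
            u = np.asarray(self.params["u"], dtype=float)
            x = np.asarray(self.params["x"], dtype=float)
            if u.ndim != 1 or u.size < 2 or np.any(np.diff(u) <= 0):
                raise CatalogError("user-tabulated form needs a strictly increasing u grid")
            object.__setattr__(self, "_spline", CubicSpline(u, x))
        elif self.form not in _CATALOG:
            raise CatalogError(f"unknown component form {self.form!r}")

    # -- evaluation ---------------------------------------------------------

    def _check_domain(self, u):
        if np.any(np.asarray(u) < self.domain_min - 1e-15):
            raise DomainError(
                f"{self.name}: investment below domain minimum {self.domain_min}"
            )

    def __call__(self, u):
        return self.evaluate(u)

    def evaluate(self, u):
        """Return x(u).  Raises :class:`EvaluationError` on non-finite output."""
        self._check_domain(u)
        if self.form == "user-tabulated":
            x = self._spline(np.asarray(u, dtype=float))
        else:
            x = _CATALOG[self.form](self.params, u)[0]
        if not np.all(np.isfinite(x)):
            raise EvaluationError(f"{self.name}: non-finite value at u={u!r}")
        return float(x) if np.ndim(u) == 0 else x

    def derivative(self, u, order: int = 1):
        """Analytic x'(u) or x''(u); central differences for tabulated forms."""
        if order not in (1, 2):
            raise ValueError(f"derivative order must be 1 or 2, got {order}")
        self._check_domain(u)
        if self.form == "user-tabulated":
            d = self._fd(u, order)
        else:
            d = _CATALOG[self.form](self.params, u)[order]
        if not np.all(np.isfinite(d)):
            raise EvaluationError(f"{self.name}: non-finite derivative at u={u!r}")
        return float(d) if np.ndim(u) == 0 else d

    def _fd(self, u, order):
        # central differences; one-sided (shifted stencil) at the domain edge
        u = np.asarray(u, dtype=float)
        h = 1e-6 * np.maximum(1.0, np.abs(u))
        lo = self.domain_min
        base = np.maximum(u, lo + h)  # shift so u-h stays in-domain
        f = self._spline
        if order == 1:
            return (f(base + h) - f(base - h)) / (2.0 * h)
        return (f(base + h) - 2.0 * f(base) + f(base - h)) / h**2

    # -- diagnostics --------------------------------------------------------

    def selection_gradient(self, u):
        """Elasticity S(u) = x'(u)/x(u), the proportional return on investment."""
        x = self.evaluate(u)
        if np.any(np.asarray(x) == 0.0):
            raise UndefinedGradientError(
                f"{self.name}: selection gradient undefined where x(u)=0"
            )
        return self.derivative(u, 1) / x

    def condition8_margin(self, u):
        """Honesty-breakdown margin m(u) = x''(u) x(u) - x'(u)^2.

        For a positive, increasing component, m > 0 iff the elasticity
        S(u) is locally increasing — the necessary condition for honest
        signaling to break down.  m < 0 whenever x is linear or
        decelerating; m is identically 0 for pure exponentials.

        Requires x'(u) > 0 (the component must be increasing at u).
        """
        d1 = self.derivative(u, 1)
        if np.any(np.asarray(d1) <= 0.0):
            raise PreconditionError(
                f"{self.name}: condition-8 margin requires x'(u) > 0"
            )
        x = self.evaluate(u)
        d2 = self.derivative(u, 2)
        return d2 * x - d1 * d1


def make_builtin(form: str, params: Mapping[str, Any] | None = None,
                 name: str | None = None) -> ComponentFunction:
    """Build a catalog component, validating the form name and parameter keys."""
    if form not in CATALOG_PARAMS:
        raise CatalogError(
            f"unknown catalog form {form!r}; available: {sorted(CATALOG_PARAMS)}"
        )
    params = dict(params or {})
    extra = set(params) - CATALOG_PARAMS[form]
    if extra:
        raise CatalogError(f"form {form!r} does not accept parameters {sorted(extra)}")
    return ComponentFunction(name=name or form, form=form, params=params)


@dataclass(frozen=True)
class TradeoffScenario:
    """n >= 2 fitness components combined additively or multiplicatively.

    By convention the first component is the signal / mating-success
    component: honesty is defined on its investment u1.  The second
    component (in the two-component scenarios of interest) is viability.
    """

    components: tuple[ComponentFunction, ...]
    rule: str  # "additive" | "multiplicative"
    name: str = ""
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.components) < 2:
            raise ValueError("a trade-off needs at least two components")
        if self.rule not in ("additive", "multiplicative"):
            raise ValueError(f"rule must be 'additive' or 'multiplicative', got {self.rule!r}")
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def n(self) -> int:
        return len(self.components)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    def check_positivity(self, u_max: float, n_probe: int = 256) -> list[str]:
        """Report components that are not strictly positive on (0, u_max].

        Multiplicative fitness treats components as positive-valued traits;
        violations are reported to the caller, never silently clipped.
        """
        probes = np.linspace(0.0, u_max, n_probe + 1)[1:]
        bad = []
        for c in self.components:
            if np.any(c.evaluate(probes) <= 0.0):
                bad.append(c.name)
        return bad
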