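"""Fitness-component forms: values, derivatives, elasticity, condition-8 margin."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from balancemodel import (CatalogError, ComponentFunction, DomainError,
                          PreconditionError, TradeoffScenario,
                          UndefinedGradientError, make_builtin)

# catalog forms with representative parameters and a working u-range,
# plus the matching sympy expression as an independent derivative oracle
_U = sympy.Symbol("u")
CATALOG_CASES = [
    ("linear", {"slope": 1.3, "intercept": 0.2}, (0.0, 10.0),
     0.2 + 1.3 * _U),
    ("quadratic", {"a": 1.5, "b": 0.7}, (0.0, 1.0),
     1.5 * _U - 0.7 * _U**2),
    ("affine-quadratic", {"a": 1.0, "b": 0.5, "c": 0.2}, (0.0, 1.0),
     0.2 + _U - 0.5 * _U**2),
    ("power-sum", {"a": 1.0, "b": 1.0, "k": 20}, (0.05, 2.0),
     _U + _U**20),
    ("exp-erf", {"a": 0.1, "s": 3.0, "m": 3.0}, (0.0, 6.0),
     sympy.exp(0.1 * _U + sympy.erf(3 * (_U - 3)))),
    ("double-exponential", {"a": 1.0, "k": 1.0}, (0.0, 6.0),
     sympy.exp(1 - sympy.exp(-_U))),
    ("exponential", {"k": 0.8, "c": 1.0}, (0.0, 5.0),
     sympy.exp(0.8 * _U)),
]


@pytest.mark.parametrize("form,params,rng_u,expr",
                         CATALOG_CASES, ids=[c[0] for c in CATALOG_CASES])
def test_derivatives_match_finite_differences(form, params, rng_u, expr):
    """Analytic first/second derivatives agree with central differences of
    evaluate to relative tolerance 1e-5 at 100 random points."""
    c = make_builtin(form, params)
    rng = np.random.default_rng(42)
    lo, hi = rng_u
    us = rng.uniform(lo + 0.01 * (hi - lo), hi - 0.01 * (hi - lo), 100)
    f = c.evaluate
    # step sizes balance truncation against roundoff per difference order
    h1 = 1e-6 * np.maximum(1.0, np.abs(us))
    h2 = 1e-4 * np.maximum(1.0, np.abs(us))
    fd1 = (f(us + h1) - f(us - h1)) / (2 * h1)
    fd2 = (f(us + h2) - 2 * f(us) + f(us - h2)) / h2**2
    scale1 = np.maximum(np.abs(fd1), 1.0)
    scale2 = np.maximum(np.abs(fd2), 1.0)
    assert np.all(np.abs(c.derivative(us, 1) - fd1) / scale1 < 1e-5)
    assert np.all(np.abs(c.derivative(us, 2) - fd2) / scale2 < 1e-5)


@pytest.mark.parametrize("form,params,rng_u,expr",
                         CATALOG_CASES, ids=[c[0] for c in CATALOG_CASES])
def test_derivatives_match_symbolic_oracle(form, params, rng_u, expr):
    """Analytic derivatives agree with sympy differentiation of the same form."""
    c = make_builtin(form, params)
    lo, hi = rng_u
    d1 = sympy.lambdify(_U, sympy.diff(expr, _U), ["scipy", "numpy"])
    d2 = sympy.lambdify(_U, sympy.diff(expr, _U, 2), ["scipy", "numpy"])
    us = np.linspace(lo + 1e-3, hi, 17)
    assert np.allclose(c.derivative(us, 1), d1(us), rtol=1e-10, atol=1e-10)
    assert np.allclose(c.derivative(us, 2), d2(us), rtol=1e-10, atol=1e-10)


def test_printed_form_values(fig1_additive, fig2, fig3):
    """Spot values of the worked-scenario component functions."""
    mating1 = fig1_additive.components[0]
    assert mating1.evaluate(1.0) == pytest.approx(0.8)
    assert mating1.derivative(0.0, 1) == pytest.approx(1.5)
    viab1 = fig1_additive.components[1]
    assert viab1.evaluate(2.5) == 2.5
    assert viab1.derivative(1.7, 2) == 0.0
    # sharply thresholded mating success: nearly flat floor at exp(-1)
    assert fig3.components[0].evaluate(0.0) == pytest.approx(math.exp(math.erf(-9.0)))
    assert round(fig3.components[0].evaluate(0.0), 2) == 0.37
    assert fig3.components[1].evaluate(0.0) == pytest.approx(1.0)
    # strongly accelerating viability
    assert fig2.components[1].derivative(1.0, 2) == pytest.approx(380.0)


def test_selection_gradient_closed_forms(fig3):
    lin = make_builtin("linear", {"slope": 1.0})
    assert lin.selection_gradient(2.0) == pytest.approx(0.5)
    # saturating viability exp[1 - exp(-u)] has elasticity exp(-u)
    viab = fig3.components[1]
    assert viab.selection_gradient(0.0) == pytest.approx(1.0)
    assert viab.selection_gradient(math.log(2.0)) == pytest.approx(0.5)
    with pytest.raises(UndefinedGradientError):
        lin.selection_gradient(0.0)


def test_condition8_margin_values(fig2):
    lin = make_builtin("linear", {"slope": 1.0})
    assert lin.condition8_margin(3.0) == pytest.approx(-1.0)
    # u + u^20 at u=1: m = 380*2 - 21^2
    assert fig2.components[1].condition8_margin(1.0) == pytest.approx(319.0)
    dec = make_builtin("quadratic", {"a": 2.0, "b": 0.5})
    with pytest.raises(PreconditionError):
        dec.condition8_margin(3.0)  # x' = 2 - u <= 0 there


def test_exponential_condition8_neutrality():
    """Pure exponentials sit exactly on the honesty knife edge: m == 0."""
    for k in (0.3, 1.0, 2.5):
        c = make_builtin("exponential", {"k": k})
        us = np.linspace(0.1, 5.0, 20)
        m = np.asarray(c.condition8_margin(us))
        scale = np.asarray(c.derivative(us, 1)) ** 2
        assert np.all(np.abs(m) / scale < 1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(a=st.floats(0.5, 3.0), b=st.floats(0.0, 0.2), c=st.floats(0.1, 2.0),
       u=st.floats(0.01, 2.0))
def test_condition8_negative_for_concave_components(a, b, c, u):
    """With x'' <= 0 and x, x' > 0, the margin is strictly negative:
    linear or decelerating viability can never undermine honesty."""
    comp = make_builtin("affine-quadratic", {"a": a, "b": b, "c": c})
    assert comp.derivative(u, 1) > 0
    assert comp.condition8_margin(u) < 0


def test_user_tabulated_uses_finite_differences():
    us = np.linspace(0.0, 5.0, 81)
    tab = ComponentFunction("tabulated quad", "user-tabulated",
                            {"u": us, "x": 0.3 + 2.0 * us - 0.1 * us**2})
    assert tab.evaluate(1.7) == pytest.approx(0.3 + 3.4 - 0.1 * 1.7**2, rel=1e-8)
    assert tab.derivative(1.7, 1) == pytest.approx(2.0 - 0.2 * 1.7, rel=1e-5)
    # second differences at h = 1e-6 max(1,|u|) are roundoff-limited to ~1e-4
    assert tab.derivative(1.7, 2) == pytest.approx(-0.2, abs=5e-3)
    # one-sided stencil keeps the domain edge evaluable
    assert np.isfinite(tab.derivative(0.0, 1))


def test_argument_and_domain_errors():
    c = make_builtin("linear", {"slope": 1.0})
    with pytest.raises(DomainError):
        c.evaluate(-0.5)
    with pytest.raises(ValueError):
        c.derivative(1.0, order=3)
    with pytest.raises(CatalogError):
        make_builtin("nosuch-form")
    with pytest.raises(CatalogError):
        make_builtin("linear", {"slope": 1.0, "bogus": 2.0})


def test_positivity_violations_are_reported_not_clipped():
    bad = make_builtin("quadratic", {"a": 1.0, "b": 1.0})  # negative past u=1
    good = make_builtin("linear", {"slope": 1.0, "intercept": 0.5})
    scn = TradeoffScenario((bad, good), "multiplicative")
    assert scn.check_positivity(2.0) == ["quadratic"]
    assert scn.check_positivity(0.9) == []
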