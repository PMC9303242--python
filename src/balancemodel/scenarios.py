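"""Built-in worked scenarios and a seeded random-scenario generator.

The built-ins are the three published worked examples of the balance model
(named here after the figures they reproduce) plus a symmetric linear
scenario used for sanity checks:

``fig1_additive`` / ``fig1_multiplicative``
    mating success x1 = 1.5 u1 - 0.7 u1^2, viability x2 = u2, combined
    additively (flat signal, no honesty information) or multiplicatively
    (honest signaling).
``fig2``
    x1 = 0.2 + u1 - 0.5 u1^2, x2 = u2 + u2^20 (strongly accelerating
    viability): multiplicative fitness fails to guarantee honesty.
``fig3``
    x1 = exp[0.1 u1 + erf(3 (u1 - 3))], x2 = exp[1 - exp(-u2)]: honest
    signaling through a corner prefix, a discontinuity and a viability
    plateau.

The random generator builds multiplicative scenarios with a strictly
increasing, strictly positive mating component and a viability component
drawn from a requested curvature class; it backs the property-based tests
of the honesty theory (sufficiency of decreasing S2, necessity of a
condition-8-positive interval for dishonesty).
"""

from __future__ import annotations

from typing import Any, Mapping

import numpy as np
import yaml

from .components import (CatalogError, ComponentFunction, TradeoffScenario,
                         make_builtin)

#: Default working range for component positivity/curvature guarantees.
WORKING_RANGE = (0.0, 10.0)


def _builtin_catalog() -> dict[str, TradeoffScenario]:
    fig1_x1 = make_builtin("quadratic", {"a": 1.5, "b": 0.7}, name="mating success")
    fig1_x2 = make_builtin("linear", {"slope": 1.0}, name="viability")
    fig2_x1 = make_builtin("affine-quadratic", {"a": 1.0, "b": 0.5, "c": 0.2},
                           name="mating success")
    fig2_x2 = make_builtin("power-sum", {"a": 1.0, "b": 1.0, "k": 20},
                           name="viability")
    fig3_x1 = make_builtin("exp-erf", {"a": 0.1, "s": 3.0, "m": 3.0},
                           name="mating success")
    fig3_x2 = make_builtin("double-exponential", {"a": 1.0, "k": 1.0},
                           name="viability")
    sym = make_builtin("linear", {"slope": 1.0})
    return {
        "fig1_additive": TradeoffScenario(
            (fig1_x1, fig1_x2), "additive", name="fig1_additive",
            meta={"recommended_R": (0.0, 1.4)}),
        "fig1_multiplicative": TradeoffScenario(
            (fig1_x1, fig1_x2), "multiplicative", name="fig1_multiplicative",
            meta={"recommended_R": (0.0, 1.4)}),
        "fig2": TradeoffScenario(
            (fig2_x1, fig2_x2), "multiplicative", name="fig2",
            # u2 + u2^20 grows steeply; fitness stays finite but the
            # interesting allocation dynamics live below R = 3
            meta={"recommended_R": (0.0, 3.0)}),
        "fig3": TradeoffScenario(
            (fig3_x1, fig3_x2), "multiplicative", name="fig3",
            meta={"recommended_R": (0.0, 6.0)}),
        "symmetric_linear": TradeoffScenario(
            (ComponentFunction("signal", "linear", {"slope": 1.0}),
             ComponentFunction("viability", "linear", {"slope": 1.0})),
            "multiplicative", name="symmetric_linear",
            meta={"recommended_R": (0.0, 10.0)}),
    }


_SCENARIOS = _builtin_catalog()


def list_scenarios() -> list[str]:
    return sorted(_SCENARIOS)


def load_scenario(name: str) -> TradeoffScenario:
    """Fetch a built-in scenario by name (see module docstring)."""
    try:
        return _SCENARIOS[name]
    except KeyError:
        raise CatalogError(
            f"unknown scenario {name!r}; available: {list_scenarios()}"
        ) from None


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------
#
# The config dialect is YAML (JSON, being a YAML subset, parses too):
#
#   rule: multiplicative
#   components:
#     - {form: quadratic, params: {a: 1.5, b: 0.7}, name: mating success}
#     - {form: linear, params: {slope: 1.0}, name: viability}

def scenario_from_dict(cfg: Mapping[str, Any], name: str = "custom") -> TradeoffScenario:
    if "rule" not in cfg or "components" not in cfg:
        raise CatalogError("scenario config needs 'rule' and 'components'")
    comps = []
    for i, c in enumerate(cfg["components"]):
        if "form" not in c:
            raise CatalogError(f"component {i}: missing 'form'")
        comps.append(make_builtin(c["form"], c.get("params", {}),
                                  name=c.get("name")))
    return TradeoffScenario(tuple(comps), cfg["rule"], name=cfg.get("name", name),
                            meta=dict(cfg.get("meta", {})))


def scenario_from_config(path: str) -> TradeoffScenario:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return scenario_from_dict(cfg)


# ---------------------------------------------------------------------------
# random scenarios
# ---------------------------------------------------------------------------

def random_scenario(seed: int, viability_curvature: str = "decelerating", *,
                    working_range: tuple[float, float] = WORKING_RANGE
                    ) -> TradeoffScenario:
    """Seeded multiplicative scenario for property-based testing.

    The mating component is an increasing concave quadratic with a positive
    intercept, so it is strictly positive and strictly increasing on the
    working range by construction (no clipping).  The viability component
    is drawn from the requested curvature class:

    decelerating
        affine-quadratic with x'' = -2b < 0; its elasticity S is then
        strictly decreasing (honesty guaranteed).
    linear
        positive slope and intercept, x'' = 0; condition-8 margin is
        -slope^2 < 0 everywhere.
    accelerating
        power-sum a*u + b*u^k with k >= 8, x'' > 0 for u > 0.

    The same seed always yields the identical scenario.
    """
    if viability_curvature not in ("decelerating", "linear", "accelerating"):
        raise ValueError(f"unknown curvature class {viability_curvature!r}")
    rng = np.random.default_rng(seed)
    lo, hi = working_range

    # x1: c + a*u - b*u^2 with a - 2*b*hi > 0 so x1' > 0 on the range
    a1 = rng.uniform(0.5, 2.0)
    c1 = rng.uniform(0.1, 1.0)
    b1 = rng.uniform(0.0, 0.9 * a1 / (2.0 * hi))
    x1 = make_builtin("affine-quadratic", {"a": a1, "b": b1, "c": c1},
                      name="mating success")

    if viability_curvature == "decelerating":
        a2 = rng.uniform(0.5, 2.0)
        c2 = rng.uniform(0.1, 1.0)
        b2 = rng.uniform(0.05 * a2 / (2.0 * hi), 0.9 * a2 / (2.0 * hi))
        x2 = make_builtin("affine-quadratic", {"a": a2, "b": b2, "c": c2},
                          name="viability")
    elif viability_curvature == "linear":
        x2 = make_builtin("linear", {"slope": rng.uniform(0.2, 3.0),
                                     "intercept": rng.uniform(0.1, 1.0)},
                          name="viability")
    else:  # accelerating
        k = int(rng.integers(8, 21))
        x2 = make_builtin("power-sum", {"a": rng.uniform(0.5, 1.5),
                                        "b": rng.uniform(0.5, 2.0), "k": k},
                          name="viability")
    return TradeoffScenario(
        (x1, x2), "multiplicative",
        name=f"random-{viability_curvature}-{seed}",
        meta={"seed": int(seed), "curvature": viability_curvature,
              "recommended_R": (lo, min(hi, 3.0) if viability_curvature == "accelerating" else hi)},
    )
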