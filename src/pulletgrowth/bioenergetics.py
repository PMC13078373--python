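"""Bioenergetic traits derived from a fitted monomolecular curve.

Because the fitted curve y(x) maps scaled ME intake to scaled gain, a few
nutritionally meaningful quantities fall out in closed form:

* **Maintenance intake** x0: the unique root of y(x) = 0,
  x0 = ln((a+b)/a) / c (kcal/g BW/day); reported per kg as MEm = 1000·x0.
* **Efficiency of ME use for growth** kg: the gain returned per extra kcal,
  either instantaneous (the slope dy/dx = c·(a+b)·e^(-c·x)) or averaged over
  an intake interval (the chord slope).  By concavity these decline with
  intake, so efficiencies evaluated between successive multiples of
  maintenance (1-2x, 2-3x, ...) decrease — diminishing returns.
* **Net energy for growth** NEg: ME is converted to NE with a fixed factor
  (default 0.62 for balanced layer diets), so the NE cost per gram of gain
  over the 1-4x maintenance range is 0.62 / kg(1-4).

When the fit covariance is available, delta-method standard errors for MEm
and NEg are offered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .monomolecular import MonomolecularParams, predict

DEFAULT_ME_TO_NE_FACTOR = 0.62

EfficiencyMode = Literal["chord", "point"]


@dataclass(frozen=True)
class BioenergeticTraits:
    """MEm, growth efficiencies at 1-4x maintenance, and NEg for one strain."""

    me_maintenance: float            # kcal/kg BW/day
    kg_at: dict[int, float]          # m -> g gain per kcal ME
    kg_overall: float                # average efficiency, 1x to 4x maintenance
    ne_growth: float                 # kcal NE-scale per g gain
    me_to_ne_factor: float
    mode: EfficiencyMode
    se_me_maintenance: float | None = None
    se_ne_growth: float | None = None


def maintenance_intake(params: MonomolecularParams) -> float:
    """Scaled maintenance intake x0 (kcal/g BW/day); 0 when b = 0."""
    if params.b == 0:
        return 0.0
    return math.log((params.a + params.b) / params.a) / params.c


def me_maintenance(params: MonomolecularParams) -> float:
    """ME maintenance requirement, kcal per kg BW per day (1000 x the root)."""
    return 1000.0 * maintenance_intake(params)


def gain_slope(params: MonomolecularParams, x: float) -> float:
    """Instantaneous efficiency dy/dx = c·(a+b)·e^(-c·x) at intake x >= 0."""
    if x < 0:
        raise ValueError("intake cannot be negative")
    return params.c * (params.a + params.b) * math.exp(-params.c * x)


def efficiency_instantaneous(params: MonomolecularParams, multiple: float) -> float:
    """Slope of the gain curve at ``multiple`` times the maintenance intake.

    At multiple = 1 this equals c·a exactly (the exponential cancels against
    the root condition); it decays to 0 as the multiple grows.
    """
    if multiple <= 0:
        raise ValueError(f"maintenance multiple must be positive, got {multiple}")
    return gain_slope(params, multiple * maintenance_intake(params))


def efficiency_average(
    params: MonomolecularParams, m_lo: float, m_hi: float
) -> float:
    """Chord-slope efficiency between m_lo and m_hi times maintenance."""
    if not 0 < m_lo < m_hi:
        raise ValueError(f"need 0 < m_lo < m_hi, got ({m_lo}, {m_hi})")
    x0 = maintenance_intake(params)
    if x0 == 0:
        raise ValueError("maintenance intake is zero (b = 0); chord undefined")
    y_lo = predict(params, m_lo * x0)
    y_hi = predict(params, m_hi * x0)
    return (y_hi - y_lo) / ((m_hi - m_lo) * x0)


def ne_growth(
    params: MonomolecularParams,
    me_to_ne_factor: float = DEFAULT_ME_TO_NE_FACTOR,
) -> float:
    """NE required per g of gain: factor / average efficiency over 1-4x."""
    kg = efficiency_average(params, 1.0, 4.0)
    if kg == 0:
        raise ZeroDivisionError("zero average efficiency")
    return me_to_ne_factor / kg


def derive_traits(
    params: MonomolecularParams,
    mode: EfficiencyMode = "chord",
    me_to_ne_factor: float = DEFAULT_ME_TO_NE_FACTOR,
    with_se: bool = False,
) -> BioenergeticTraits:
    """All traits for one fitted strain.

    ``chord`` (default) evaluates kg(m) as the average efficiency on
    [m, m+1]x maintenance; ``point`` evaluates the instantaneous slope at
    m x maintenance.
    """
    if mode == "chord":
        kg_at = {m: efficiency_average(params, m, m + 1) for m in (1, 2, 3, 4)}
    elif mode == "point":
        kg_at = {m: efficiency_instantaneous(params, m) for m in (1, 2, 3, 4)}
    else:
        raise ValueError(f"unknown efficiency mode {mode!r}")
    se_mem = se_neg = None
    if with_se and params.covariance is not None:
        se_mem = _delta_se(params, me_maintenance)
        se_neg = _delta_se(params, lambda p: ne_growth(p, me_to_ne_factor))
    return BioenergeticTraits(
        me_maintenance=me_maintenance(params),
        kg_at=kg_at,
        kg_overall=efficiency_average(params, 1.0, 4.0),
        ne_growth=ne_growth(params, me_to_ne_factor),
        me_to_ne_factor=me_to_ne_factor,
        mode=mode,
        se_me_maintenance=se_mem,
        se_ne_growth=se_neg,
    )


def _delta_se(params: MonomolecularParams, func) -> float:
    """Delta-method SE of a scalar trait via central differences in (a,b,c)."""
    theta = np.array(params.as_tuple())
    grad = np.empty(3)
    for i in range(3):
        h = 1e-6 * max(abs(theta[i]), 1e-6)
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (
            func(MonomolecularParams(*up)) - func(MonomolecularParams(*dn))
        ) / (2 * h)
    return float(np.sqrt(grad @ params.covariance @ grad))
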