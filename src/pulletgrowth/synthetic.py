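"""Synthetic strain profiles and meta-analysis study sets with known truth.

The generators emulate what a commercial strain guide provides — a weekly
body-weight trajectory starting at a 38 g hatch weight and weekly ME
intakes — but built backwards from a *known* monomolecular curve so every
downstream stage (scaling, fitting, trait derivation, pooling) can be tested
against ground truth.

``generate_scaled`` places intakes on a grid over ``x_range`` (default
0.05-0.45 kcal/g BW/day, spanning roughly 0.5x to 4x a typical maintenance
intake) and draws gains as curve + additive Gaussian noise.
``generate_profile`` then inverts the scaling step: weekly body weights are
accumulated from the generated gains and weekly ME intakes back-solved so
that scaling the profile reproduces the generated (x, y) pairs exactly.
Noise is additive on the gain scale (σ default 0.002 g/g/day), matching the
absolute residual scale seen in real guide fits.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .meta import MetaInput, MetaStudy
from .monomolecular import MonomolecularParams, predict
from .profiles import (
    DAYS_PER_WEEK,
    DEFAULT_HATCH_WEIGHT_G,
    ScaledObservation,
    StrainProfile,
    WeekRecord,
)

DEFAULT_TRUE_PARAMS = (0.10, 0.15, 3.5)
DEFAULT_X_RANGE = (0.05, 0.45)
DEFAULT_NOISE_SD = 0.002


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and layout of one synthetic strain profile."""

    true_params: tuple[float, float, float] = DEFAULT_TRUE_PARAMS
    n_weeks: int = 18
    x_range: tuple[float, float] = DEFAULT_X_RANGE
    noise_sd: float = DEFAULT_NOISE_SD
    hatch_weight_g: float = DEFAULT_HATCH_WEIGHT_G
    seed: int = 0
    strain_name: str = "synthetic"

    def __post_init__(self) -> None:
        a, b, c = self.true_params
        if min(a, b, c) <= 0:
            raise ValueError("true parameters must be positive")
        if self.x_range[0] <= 0 or self.x_range[1] <= self.x_range[0]:
            raise ValueError("x_range must satisfy 0 < x_min < x_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_weeks < 1:
            raise ValueError("need at least one week")

    @property
    def params(self) -> MonomolecularParams:
        return MonomolecularParams(*self.true_params)


def _xy(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(spec.x_range[0], spec.x_range[1], spec.n_weeks)
    y = predict(spec.params, x) + rng.normal(0.0, spec.noise_sd, size=spec.n_weeks)
    return x, np.asarray(y)


def _bw_trajectory(spec: SyntheticSpec, y: np.ndarray) -> np.ndarray:
    """Weekly end weights consistent with the interval-mean scaling rule.

    y = (BW_w − BW_{w−1}) / (7 · (BW_{w−1}+BW_w)/2)  solved for BW_w gives
    BW_w = BW_{w−1} · (1 + 3.5 y) / (1 − 3.5 y).
    """
    h = DAYS_PER_WEEK / 2.0
    if np.any(h * y >= 1.0):
        raise ValueError("gain too large for a feasible weekly trajectory")
    bw = [spec.hatch_weight_g]
    for yi in y:
        bw.append(bw[-1] * (1.0 + h * yi) / (1.0 - h * yi))
    return np.array(bw)  # length n_weeks + 1, bw[0] = hatch


def generate_scaled(spec: SyntheticSpec) -> list[ScaledObservation]:
    """Scaled (x, y) observations drawn around the true curve."""
    x, y = _xy(spec)
    bw = _bw_trajectory(spec, y)
    bw_mean = (bw[:-1] + bw[1:]) / 2.0
    return [
        ScaledObservation(
            week=w + 1, x=float(x[w]), y=float(y[w]),
            bw_mean_g=float(bw_mean[w]), days=DAYS_PER_WEEK,
        )
        for w in range(spec.n_weeks)
    ]


def generate_profile(spec: SyntheticSpec) -> StrainProfile:
    """Strain-guide-style profile whose scaling reproduces generate_scaled."""
    x, y = _xy(spec)
    bw = _bw_trajectory(spec, y)
    bw_mean = (bw[:-1] + bw[1:]) / 2.0
    me = x * bw_mean * DAYS_PER_WEEK
    if np.any(me <= 0):
        raise ValueError("infeasible profile: non-positive weekly ME intake")
    records = tuple(
        WeekRecord(
            week=w + 1, body_weight_g=float(bw[w + 1]),
            me_intake_kcal=float(me[w]), days=DAYS_PER_WEEK,
        )
        for w in range(spec.n_weeks)
    )
    return StrainProfile(
        strain_name=spec.strain_name,
        records=records,
        hatch_weight_g=spec.hatch_weight_g,
    )


def generate_meta_studies(
    k: int,
    mu: float,
    tau2: float,
    se_list: Sequence[float],
    seed: int = 0,
    parameter_name: str = "simulated",
) -> MetaInput:
    """K studies with true effects N(mu, tau2) observed with N(0, se_i²) error."""
    if len(se_list) != k:
        raise ValueError("se_list length must equal k")
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    rng = np.random.default_rng(seed)
    se = np.asarray(se_list, dtype=float)
    theta = rng.normal(mu, np.sqrt(tau2 + se**2))
    studies = tuple(
        MetaStudy(label=f"study_{i + 1}", estimate=float(t), se=float(s))
        for i, (t, s) in enumerate(zip(theta, se))
    )
    return MetaInput(parameter_name=parameter_name, studies=studies)
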