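"""DerSimonian-Laird random-effects meta-analysis of growth parameters.

Each strain's fitted monomolecular parameter (a, b or c) is treated as one
study: an estimate θ_i with standard error se_i.  Pooling across K strains:

* fixed (inverse-variance) weights  w_i = 1/se_i²,
* Cochran's heterogeneity statistic Q = Σ w_i (θ_i − θ̄)² with θ̄ the
  fixed-effect weighted mean, chi-square with K−1 df under homogeneity,
* I² = (Q − (K−1))/Q × 100, truncated at 0 — the percentage of total
  variation attributable to between-strain heterogeneity (anchor points
  25/50/75% read as low/moderate/high),
* the DerSimonian-Laird moment estimator of the between-study variance,
  τ² = max(0, (Q − (K−1)) / (Σw − Σw²/Σw)),
* random-effects weights w*_i = 1/(se_i² + τ²), pooled mean Σw*θ/Σw*,
  pooled SE (Σw*)^(−1/2), 95% CI = pooled ∓ 1.96·SE, and a two-sided z-test
  of the pooled mean against zero.

No small-sample (Knapp-Hartung) adjustment is applied; the confidence
interval is the plain normal one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

Z_95 = 1.96  # normal quantile used for the printed 95% intervals


@dataclass(frozen=True)
class MetaStudy:
    label: str
    estimate: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"standard error must be positive, got {self.se}")


@dataclass(frozen=True)
class MetaInput:
    """Per-strain (estimate, SE) pairs for one monomolecular parameter."""

    parameter_name: str
    studies: tuple[MetaStudy, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))

    @property
    def k(self) -> int:
        return len(self.studies)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        est = np.array([s.estimate for s in self.studies], dtype=float)
        se = np.array([s.se for s in self.studies], dtype=float)
        return est, se


@dataclass(frozen=True)
class MetaResult:
    parameter_name: str
    pooled: float
    se_pooled: float
    ci_low: float
    ci_high: float
    p_value: float
    q: float
    q_df: int
    q_p_value: float
    i_squared: float
    tau_squared: float
    weights_fixed: np.ndarray
    weights_random: np.ndarray
    heterogeneity_label: str


def cochran_q(estimates, se) -> tuple[float, int, float]:
    """Cochran's Q with inverse-variance weights, its df, and chi-square p."""
    est = np.asarray(estimates, dtype=float)
    s = np.asarray(se, dtype=float)
    k = est.size
    if k < 2:
        raise ValueError("need at least two studies for heterogeneity")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    mean = float(np.sum(w * est) / np.sum(w))
    q = float(np.sum(w * (est - mean) ** 2))
    df = k - 1
    return q, df, float(chi2.sf(q, df))


def i_squared(q: float, k: int) -> float:
    """I² heterogeneity percentage, truncated at 0 (and 0 when Q = 0)."""
    if k < 2:
        raise ValueError("need at least two studies")
    if q < 0:
        raise ValueError("Q cannot be negative")
    if q == 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / q * 100.0)


def heterogeneity_label(i2: float) -> str:
    """Nearest of the 25/50/75% anchor points: low / moderate / high."""
    if i2 < 37.5:
        return "low"
    if i2 < 62.5:
        return "moderate"
    return "high"


class DerSimonianLaird(BaseEstimator):
    """Random-effects pooling of per-strain estimates (DL moment estimator).

    ``fit(estimates, se)`` computes the pooled effect and heterogeneity
    statistics; all results are exposed as fitted attributes (``pooled_``,
    ``se_pooled_``, ``ci_low_``, ``ci_high_``, ``p_value_``, ``q_``,
    ``q_p_value_``, ``i_squared_``, ``tau_squared_``, ``weights_fixed_``,
    ``weights_random_``).
    """

    def __init__(self, ci_z: float = Z_95):
        self.ci_z = ci_z

    def fit(self, estimates, se, labels: Sequence[str] | None = None):
        est = np.asarray(estimates, dtype=float).ravel()
        s = np.asarray(se, dtype=float).ravel()
        if est.size != s.size:
            raise ValueError("estimates and se lengths differ")
        k = est.size
        if k < 2:
            raise ValueError("need at least two studies to pool")
        q, df, q_p = cochran_q(est, s)
        w = 1.0 / s**2
        sw = float(np.sum(w))
        denom = sw - float(np.sum(w**2)) / sw
        tau2 = max(0.0, (q - df) / denom)
        w_star = 1.0 / (s**2 + tau2)
        pooled = float(np.sum(w_star * est) / np.sum(w_star))
        se_pooled = float(np.sum(w_star) ** -0.5)

        self.k_ = k
        self.labels_ = list(labels) if labels is not None else [str(i) for i in range(k)]
        self.q_, self.q_df_, self.q_p_value_ = q, df, q_p
        self.tau_squared_ = tau2
        self.i_squared_ = i_squared(q, k)
        self.weights_fixed_ = w
        self.weights_random_ = w_star
        self.pooled_ = pooled
        self.se_pooled_ = se_pooled
        self.ci_low_ = pooled - self.ci_z * se_pooled
        self.ci_high_ = pooled + self.ci_z * se_pooled
        self.p_value_ = float(2.0 * norm.sf(abs(pooled) / se_pooled))
        return self

    def result(self, parameter_name: str = "") -> MetaResult:
        return MetaResult(
            parameter_name=parameter_name,
            pooled=self.pooled_,
            se_pooled=self.se_pooled_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            p_value=self.p_value_,
            q=self.q_,
            q_df=self.q_df_,
            q_p_value=self.q_p_value_,
            i_squared=self.i_squared_,
            tau_squared=self.tau_squared_,
            weights_fixed=self.weights_fixed_,
            weights_random=self.weights_random_,
            heterogeneity_label=heterogeneity_label(self.i_squared_),
        )


def dl_pool(meta_input: MetaInput) -> MetaResult:
    """Functional wrapper: DL random-effects pooling of one MetaInput."""
    est, se = meta_input.arrays()
    labels = [s.label for s in meta_input.studies]
    return (
        DerSimonianLaird()
        .fit(est, se, labels=labels)
        .result(parameter_name=meta_input.parameter_name)
    )


def single_study_result(meta_input: MetaInput) -> MetaResult:
    """K = 1 passthrough: the lone study is the pooled result, τ² = 0."""
    if meta_input.k != 1:
        raise ValueError("passthrough is only for a single study")
    s = meta_input.studies[0]
    return MetaResult(
        parameter_name=meta_input.parameter_name,
        pooled=s.estimate,
        se_pooled=s.se,
        ci_low=s.estimate - Z_95 * s.se,
        ci_high=s.estimate + Z_95 * s.se,
        p_value=float(2.0 * norm.sf(abs(s.estimate) / s.se)),
        q=0.0,
        q_df=0,
        q_p_value=1.0,
        i_squared=0.0,
        tau_squared=0.0,
        weights_fixed=np.array([1.0 / s.se**2]),
        weights_random=np.array([1.0 / s.se**2]),
        heterogeneity_label="low",
    )


def forest_table(result: MetaResult, meta_input: MetaInput) -> pd.DataFrame:
    """Plot-ready forest rows: one per study plus a pooled summary row.

    Per-study confidence limits are ±1.96·SE; the ``weight_pct`` column is
    the study's relative random-effects weight and sums to 100 over the
    studies (the summary row carries no weight).
    """
    rows = []
    total_w = float(np.sum(result.weights_random))
    for study, w in zip(meta_input.studies, result.weights_random):
        rows.append(
            {
                "label": study.label,
                "kind": "study",
                "estimate": study.estimate,
                "ci_low": study.estimate - Z_95 * study.se,
                "ci_high": study.estimate + Z_95 * study.se,
                "weight_pct": 100.0 * float(w) / total_w,
            }
        )
    rows.append(
        {
            "label": "pooled (random effects)",
            "kind": "summary",
            "estimate": result.pooled,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "weight_pct": float("nan"),
        }
    )
    return pd.DataFrame(rows)
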