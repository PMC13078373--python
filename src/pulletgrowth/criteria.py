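"""Goodness-of-fit criteria for comparing growth predictors.

Six statistics computed from an (actual, forecast) pair: R² and adjusted R²,
RMSE, mean absolute deviation (MAD), mean absolute percentage error (MAPE),
AIC and BIC.  Higher adjusted R² is better; for every other criterion lower
is better.

Two conventions here are deliberate and worth noting:

* The AIC is computed as ``n·ln(RSS) + 2p`` while the BIC uses
  ``n·ln(RSS/n) + p·ln(n)``.  The pair is asymmetric (the AIC omits the /n
  inside the log); it is kept as-is because model *ranking* at fixed n is
  unaffected by the n·ln(n) offset, and the conventional
  ``n·ln(RSS/n) + 2p`` form is exported alongside as ``aic_standard``.
* MAD takes absolute deviations, matching its name; the signed mean error is
  exported separately as ``mean_bias``.

MAPE is undefined whenever an actual value is zero; rather than silently
dropping such points it is returned as NaN with ``mape_defined=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class FitCriteria:
    r2: float
    r2_adj: float
    rmse: float
    mad: float
    mape: float
    aic: float
    bic: float
    aic_standard: float
    mean_bias: float
    n_obs: int
    n_params: int
    rss: float
    tss: float
    mape_defined: bool = True

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def criteria(
    actual: Sequence[float], forecast: Sequence[float], n_params: int
) -> FitCriteria:
    """Compute the full criteria suite for one predictor's output.

    ``n_params`` is the number of free parameters p of the predictor (3 for
    the monomolecular curve, 17 for the 1-3-2-1 network); requires n > p.
    """
    A = np.asarray(actual, dtype=float).ravel()
    F = np.asarray(forecast, dtype=float).ravel()
    if A.shape != F.shape:
        raise ValueError("actual and forecast lengths differ")
    n = A.size
    p = int(n_params)
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")

    resid = A - F
    rss = float(resid @ resid)
    tss = float(np.sum((A - A.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    r2_adj = 1.0 - ((n - 1) / (n - p)) * (1.0 - r2) if tss > 0 else float("nan")
    rmse = math.sqrt(rss / (n - p))
    mad = float(np.mean(np.abs(resid)))
    mean_bias = float(np.mean(resid))
    mape_defined = bool(np.all(A != 0))
    mape = (
        float(np.mean(np.abs(resid / A)) * 100.0) if mape_defined else float("nan")
    )
    # log of RSS: perfect fits give -inf, which orders correctly
    log_rss = math.log(rss) if rss > 0 else -math.inf
    log_rss_n = math.log(rss / n) if rss > 0 else -math.inf
    aic = n * log_rss + 2 * p
    bic = n * log_rss_n + p * math.log(n)
    aic_standard = n * log_rss_n + 2 * p
    return FitCriteria(
        r2=r2, r2_adj=r2_adj, rmse=rmse, mad=mad, mape=mape,
        aic=aic, bic=bic, aic_standard=aic_standard, mean_bias=mean_bias,
        n_obs=n, n_params=p, rss=rss, tss=tss, mape_defined=mape_defined,
    )


RANKED_CRITERIA = ("r2_adj", "rmse", "mad", "mape", "aic", "bic")


def rank_models(
    entries: Sequence[FitCriteria] | Mapping[str, FitCriteria],
) -> dict[str, dict[str, float]]:
    """Per-criterion rank of each model (1 = best; ties share the min rank).

    Adjusted R² ranks higher-is-better; every other criterion lower-is-better.
    """
    if isinstance(entries, Mapping):
        labels = list(entries.keys())
        crits = list(entries.values())
    else:
        crits = list(entries)
        labels = [str(i) for i in range(len(crits))]
    if len(crits) < 2:
        raise ValueError("need at least two models to rank")
    out: dict[str, dict[str, float]] = {}
    for name in RANKED_CRITERIA:
        vals = np.array([getattr(c, name) for c in crits], dtype=float)
        if name == "r2_adj":
            vals = -vals
        ranks = rankdata(vals, method="min")
        out[name] = dict(zip(labels, (float(r) for r in ranks)))
    return out
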