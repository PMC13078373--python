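"""Monomolecular (Mitscherlich) growth-response model.

The response of scaled body-weight gain ``y`` to scaled metabolizable-energy
intake ``x`` is modelled by the saturating curve

    y = a - (a + b) * exp(-c * x)

with all three parameters positive: ``a`` is the asymptotic gain at unlimited
intake (y_max), ``-b`` the gain at zero intake (y_min, the fasting weight
loss), and ``c`` a rate constant governing how quickly the response
saturates.  The curve is strictly increasing and concave on x >= 0, which is
what makes the maintenance intake (its unique root) and the diminishing
marginal efficiencies in :mod:`pulletgrowth.bioenergetics` well defined.

Fitting is nonlinear least squares.  Positivity is enforced by optimizing
over (log a, log b, log c) with Levenberg-Marquardt; standard errors are
reported on the natural scale from the Jacobian-based covariance
``s^2 (J'J)^-1`` with ``s^2 = RSS / (n - 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .profiles import ScaledObservation, observations_to_arrays

N_PARAMS = 3


class UnderDeterminedError(ValueError):
    """Too few observations (or too few distinct x) to fit 3 parameters."""


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params: tuple[float, float, float]):
        super().__init__(message)
        self.last_params = last_params


@dataclass(frozen=True)
class MonomolecularParams:
    """Fitted parameters with uncertainty for one strain."""

    a: float
    b: float
    c: float
    se_a: float = float("nan")
    se_b: float = float("nan")
    se_c: float = float("nan")
    covariance: np.ndarray | None = None
    n_obs: int = 0
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b < 0 or self.c <= 0:
            raise ValueError(
                f"parameters must be positive (b may be 0): a={self.a}, b={self.b}, c={self.c}"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


def predict(params: MonomolecularParams | Sequence[float], x) -> np.ndarray | float:
    """Evaluate y = a - (a+b)·exp(-c·x) at intake(s) ``x`` (must be >= 0)."""
    a, b, c = _unpack(params)
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("intake x cannot be negative")
    out = a - (a + b) * np.exp(-c * x_arr)
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def jacobian(params: MonomolecularParams | Sequence[float], x: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the model curve w.r.t. (a, b, c), shape (n, 3)."""
    a, b, c = _unpack(params)
    x = np.asarray(x, dtype=float)
    e = np.exp(-c * x)
    return np.column_stack([1.0 - e, -e, (a + b) * x * e])


def residuals(
    params: MonomolecularParams | Sequence[float],
    observations: Sequence[ScaledObservation],
) -> np.ndarray:
    """Elementwise observed minus predicted gain."""
    x, y = observations_to_arrays(observations)
    return y - predict(params, x)


def _unpack(params) -> tuple[float, float, float]:
    if isinstance(params, MonomolecularParams):
        return params.a, params.b, params.c
    a, b, c = params
    return float(a), float(b), float(c)


def default_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Self-starting values: asymptote just above max(y), b from -min(y),
    c from the log-linear regression ln(a0 - y) = ln(a0 + b) - c·x."""
    a0 = 1.05 * float(np.max(y))
    if a0 <= 0:
        a0 = 1e-3
    b0 = max(1e-4, -float(np.min(y)))
    z = a0 - y
    mask = z > 0
    if mask.sum() >= 2 and np.ptp(x[mask]) > 0:
        slope = np.polyfit(x[mask], np.log(z[mask]), 1)[0]
        c0 = max(1e-3, -float(slope))
    else:
        c0 = 1.0
    return a0, b0, c0


class MonomolecularRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the monomolecular intake-gain curve.

    Parameters
    ----------
    init : tuple of 3 floats, optional
        Starting values (a0, b0, c0).  Defaults to a self-starting heuristic.
    ftol, xtol : float
        Convergence tolerances: relative RSS change and step norm.
    max_iter : int
        Cap on optimizer iterations.

    Attributes
    ----------
    a_, b_, c_ : float
        Point estimates (natural, positive scale).
    se_a_, se_b_, se_c_ : float
        Jacobian-based standard errors.
    covariance_ : ndarray (3, 3)
        Covariance of the estimates, ``s^2 (J'J)^-1``.
    rss_ : float
        Residual sum of squares at the optimum.
    params_ : MonomolecularParams
        All of the above as a value object.
    """

    def __init__(
        self,
        init: tuple[float, float, float] | None = None,
        ftol: float = 1e-12,
        xtol: float = 1e-10,
        max_iter: int = 500,
    ):
        self.init = init
        self.ftol = ftol
        self.xtol = xtol
        self.max_iter = max_iter

    def fit(self, X, y):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("X and y lengths differ")
        n = x.size
        if n < N_PARAMS + 1 or np.unique(x).size < N_PARAMS:
            raise UnderDeterminedError(
                f"need >= {N_PARAMS + 1} observations with >= {N_PARAMS} distinct "
                f"intakes, got n={n} with {np.unique(x).size} distinct"
            )
        if np.ptp(y) == 0:
            raise np.linalg.LinAlgError(
                "constant gain: parameters are not identifiable (singular Jacobian)"
            )

        a0, b0, c0 = self.init if self.init is not None else default_init(x, y)
        if min(a0, b0, c0) <= 0:
            raise ValueError("initial values must be positive")
        theta0 = np.log([a0, b0, c0])

        def resid_log(theta):
            a, b, c = np.exp(theta)
            return y - (a - (a + b) * np.exp(-c * x))

        def jac_log(theta):
            a, b, c = np.exp(theta)
            # chain rule: d r / d log p = (d r / d p) * p
            J = -jacobian((a, b, c), x)
            return J * np.array([a, b, c])

        sol = least_squares(
            resid_log,
            theta0,
            jac=jac_log,
            method="lm",
            ftol=self.ftol,
            xtol=self.xtol,
            gtol=1e-14,
            max_nfev=self.max_iter * 3,
        )
        a, b, c = np.exp(sol.x)
        if not sol.success:
            raise ConvergenceError(
                f"fit did not converge: {sol.message}", (float(a), float(b), float(c))
            )
        rss = float(np.sum(sol.fun**2))

        J = jacobian((a, b, c), x)
        JtJ = J.T @ J
        if np.linalg.cond(JtJ) > 1e12:
            raise np.linalg.LinAlgError("singular Jacobian: data not identifiable")
        s2 = rss / (n - N_PARAMS)
        cov = s2 * np.linalg.inv(JtJ)
        se = np.sqrt(np.diag(cov))

        self.a_, self.b_, self.c_ = float(a), float(b), float(c)
        self.se_a_, self.se_b_, self.se_c_ = (float(s) for s in se)
        self.covariance_ = cov
        self.rss_ = rss
        self.n_obs_ = n
        self.n_iter_ = int(sol.nfev)
        self.params_ = MonomolecularParams(
            a=self.a_, b=self.b_, c=self.c_,
            se_a=self.se_a_, se_b=self.se_b_, se_c=self.se_c_,
            covariance=cov, n_obs=n, rss=rss,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        return predict(self.params_, _as_1d(X))


def fit(
    observations: Sequence[ScaledObservation],
    init: tuple[float, float, float] | None = None,
    **config,
) -> MonomolecularParams:
    """Functional wrapper: fit the curve to scaled observations."""
    x, y = observations_to_arrays(observations)
    return MonomolecularRegressor(init=init, **config).fit(x, y).params_


def _as_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError("X must be 1-d or a single-column 2-d array")
    return x
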