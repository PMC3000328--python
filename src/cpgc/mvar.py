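"""Vector-autoregressive connectivity models.

Two model families over a k-region series X(t):

* plain VAR(p):      X(t) = sum_{n=1..p} A(n) X(t-n) + E(t)
* modified VAR(p):   X(t) = A'(0) X(t) + sum_{n=1..p} A'(n) X(t-n) + E(t)

where A'(0) has a zero diagonal, so only instantaneous *cross*-correlation is
modeled, never autocorrelation. Granger causality read off the lagged
coefficients of the modified model is "correlation-purged" (CPGC): shared
zero-lag variance is absorbed by A'(0) instead of leaking into the lag terms.
Each target region is fit by independent ordinary least squares; the model
order is chosen by BIC on a common effective sample.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .timeseries import SubjectTimeSeries

logger = logging.getLogger(__name__)

COV_JITTER = 1e-10


def _as_array(ts) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(ts, SubjectTimeSeries):
        return ts.data, ts.region_names
    x = np.asarray(ts, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (T, k) matrix")
    return x, None


def min_timepoints(k: int, order: int) -> int:
    """Smallest T admitting a fit: T - p >= k(p + 1) + 5."""
    return k * (order + 1) + 5 + order


class MVAR(BaseEstimator):
    """(Modified) vector autoregression fit by per-target least squares.

    Parameters
    ----------
    order : int or "bic"
        Autoregressive order p >= 1, or "bic" to select it (1..p_max) by the
        Bayesian Information Criterion on a common effective sample.
    p_max : int
        Largest candidate order when ``order="bic"``.
    include_zero_lag : bool
        If True (the modified model), each target is also regressed on the
        *other* regions at lag 0; the self term is never a regressor, so
        diag(A'(0)) is zero by construction. If False, the plain VAR.

    Attributes
    ----------
    order_ : int
        Order actually fitted.
    zero_lag_ : ndarray (k, k)
        A'(0); all-zero matrix for a plain VAR fit.
    lag_coeffs_ : list of p ndarray (k, k)
        A'(1)..A'(p); entry (i, j) multiplies region j's past in region i's
        equation.
    intercepts_ : ndarray (k,)
    residuals_ : ndarray (T - t0, k)
    resid_cov_ : ndarray (k, k)
        Maximum-likelihood residual covariance E'E / N_eff (symmetric PSD).
    bic_values_ : dict[int, float]
        BIC per candidate order (only when order="bic").
    """

    def __init__(self, order: int | str = 1, p_max: int = 5, include_zero_lag: bool = True):
        self.order = order
        self.p_max = p_max
        self.include_zero_lag = include_zero_lag

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        x, names = _as_array(X)
        self.region_names_ = names or [f"R{i + 1}" for i in range(x.shape[1])]
        if self.order == "bic":
            self.bic_values_ = _bic_values(x, self.p_max, self.include_zero_lag, self.region_names_)
            self.order_ = min(self.bic_values_, key=lambda p: (self.bic_values_[p], p))
        else:
            p = int(self.order)
            if p < 1:
                raise ValueError("order must be >= 1")
            self.order_ = p
        self._fit_at(x, self.order_, t0=self.order_)
        return self

    def _fit_at(self, x: np.ndarray, p: int, t0: int) -> None:
        t, k = x.shape
        if t - p < k * (p + 1) + 5:
            raise ValueError(
                f"series too short for order {p}: T={t}, need T >= {min_timepoints(k, p)}"
            )
        n_eff = t - t0
        lag_block = np.column_stack(
            [np.ones(n_eff)] + [x[t0 - n : t - n, :] for n in range(1, p + 1)]
        )
        y_all = x[t0:, :]
        zero_lag = np.zeros((k, k))
        lags = [np.zeros((k, k)) for _ in range(p)]
        intercepts = np.zeros(k)
        resid = np.empty((n_eff, k))
        for i in range(k):
            others = [j for j in range(k) if j != i]
            if self.include_zero_lag:
                design = np.column_stack([lag_block[:, :1], y_all[:, others], lag_block[:, 1:]])
            else:
                design = lag_block
            coef, _, rank, _ = np.linalg.lstsq(design, y_all[:, i], rcond=None)
            if rank < design.shape[1]:
                raise np.linalg.LinAlgError(
                    "singular design matrix for target "
                    f"{self.region_names_[i]!r}: collinear regressors "
                    f"({_collinear_regions(x, self.region_names_)})"
                )
            intercepts[i] = coef[0]
            pos = 1
            if self.include_zero_lag:
                zero_lag[i, others] = coef[pos : pos + k - 1]
                pos += k - 1
            for n in range(p):
                lags[n][i, :] = coef[pos + n * k : pos + (n + 1) * k]
            resid[:, i] = y_all[:, i] - design @ coef
        self.zero_lag_ = zero_lag
        self.lag_coeffs_ = lags
        self.intercepts_ = intercepts
        self.residuals_ = resid
        cov = resid.T @ resid / n_eff
        self.resid_cov_ = (cov + cov.T) / 2.0

    # -- derived matrices --------------------------------------------------

    def causality_matrix(self, absolute: bool = False) -> np.ndarray:
        """Directed influence: entry (i, j) = sum_n a'_ij(n), diagonal zero.

        Computed from a zero-lag-inclusive fit this is the correlation-purged
        Granger causality (CPGC); from a plain VAR fit, the naive GC. With
        ``absolute=True`` the signed sum is replaced by sum_n |a'_ij(n)|.
        """
        self._check_fitted()
        stack = np.stack(self.lag_coeffs_)
        out = np.abs(stack).sum(axis=0) if absolute else stack.sum(axis=0)
        np.fill_diagonal(out, 0.0)
        return out

    def instantaneous_matrix(self) -> np.ndarray:
        """Symmetrized zero-lag coupling (A'(0) + A'(0)^T)/2, zero diagonal."""
        self._check_fitted()
        if not self.include_zero_lag:
            raise ValueError("instantaneous coupling requires a zero-lag (modified VAR) fit")
        out = (self.zero_lag_ + self.zero_lag_.T) / 2.0
        np.fill_diagonal(out, 0.0)
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "lag_coeffs_"):
            raise ValueError("model is not fitted; call fit() first")


def _collinear_regions(x: np.ndarray, names: list[str]) -> str:
    sd = x.std(axis=0)
    const = [names[i] for i in np.flatnonzero(sd == 0)]
    if const:
        return "constant region(s) " + ", ".join(const)
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(x.T)
    pairs = [
        f"{names[i]}~{names[j]}"
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if abs(c[i, j]) > 1.0 - 1e-12
    ]
    return "duplicate pair(s) " + ", ".join(pairs) if pairs else "unidentified collinearity"


def _bic_values(x: np.ndarray, p_max: int, include_zero_lag: bool, names: list[str]) -> dict[int, float]:
    t, k = x.shape
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if t - p_max < k * (p_max + 1) + 5:
        raise ValueError(
            f"series too short for p_max={p_max}: T={t}, need T >= {min_timepoints(k, p_max)}"
        )
    n_eff = t - p_max  # common effective sample across candidate orders
    values: dict[int, float] = {}
    for p in range(1, p_max + 1):
        m = MVAR(order=p, include_zero_lag=include_zero_lag)
        m.region_names_ = names
        m._fit_at(x, p, t0=p_max)
        sign, logdet = np.linalg.slogdet(m.resid_cov_)
        if sign <= 0:
            logger.warning("BIC: residual covariance not PD at p=%d; adding jitter", p)
            sign, logdet = np.linalg.slogdet(m.resid_cov_ + COV_JITTER * np.eye(k))
            if sign <= 0:
                logdet = -np.inf
        n_params = k * (1 + (k - 1 if include_zero_lag else 0) + k * p)
        values[p] = n_eff * logdet + n_params * np.log(n_eff)
    return values


# -- thin functional wrappers -------------------------------------------------


def fit_model(ts, order: int, include_zero_lag: bool = True) -> MVAR:
    """Fit a (modified) VAR of the given order; returns the fitted estimator."""
    return MVAR(order=order, include_zero_lag=include_zero_lag).fit(ts)


def select_order_bic(ts, p_max: int, include_zero_lag: bool = True) -> int:
    """Order in 1..p_max minimizing BIC (ties -> smallest p)."""
    x, names = _as_array(ts)
    values = _bic_values(x, p_max, include_zero_lag, names or [f"R{i+1}" for i in range(x.shape[1])])
    return min(values, key=lambda p: (values[p], p))


def causality_matrix(model: MVAR, absolute: bool = False) -> np.ndarray:
    return model.causality_matrix(absolute=absolute)


def instantaneous_matrix(model: MVAR) -> np.ndarray:
    return model.instantaneous_matrix()


def pearson_matrix(ts) -> np.ndarray:
    """Sample Pearson correlation matrix (k x k, unit diagonal)."""
    x, names = _as_array(ts)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        labels = [names[i] for i in bad] if names else bad.tolist()
        raise ValueError(f"zero-variance region(s): {labels}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.corrcoef(x.T)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r
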