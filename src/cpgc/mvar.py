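"""The modified multivariate autoregressive model and correlation-purged
Granger causality (CPGC).

Model
-----
For k standardized ROI series x_1..x_k stacked as X(t), the model is a
structural VAR with an instantaneous coefficient matrix whose diagonal is
constrained to zero:

    X(t) = A(0) X(t) + A(1) X(t-1) + ... + A(p) X(t-p) + E(t),
    diag(A(0)) = 0.

The off-diagonal entries of A(0) absorb zero-lag (instantaneous)
cross-correlation, so the lagged coefficients A(1)..A(p) are purged of the
leakage of instantaneous correlation into causality estimates — the effect
the hemodynamic blurring of neural activity otherwise produces in fMRI.
Directed causal strength is summarized as

    CPGC_ij = sum_n a_ij(n)^2      (influence of ROI j on ROI i, i != j).

Estimation is per-target-equation least squares with the contemporaneous
cross-regressors included directly.  This matches the model as written and
is deterministic; like any structural-VAR regression it carries a known
simultaneity bias, which is documented rather than corrected.

A naive variant omitting the A(0) terms (``zero_lag=False``) is provided for
testing the purging property only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .defaults import DEFAULTS
from .signal_prep import standardize_array


class FitError(ValueError):
    pass


@dataclass
class MvarModel:
    """Fitted mMVAR: A(0), A(1..p), intercepts, residuals and BIC.

    ``lag_coefs[n-1, i, j]`` is a_ij(n): the coefficient of x_j(t-n) in the
    equation for x_i(t).  ``a0[i, j]`` is the instantaneous coefficient of
    x_j(t); its diagonal is exactly zero (structurally excluded, for
    ``zero_lag=False`` the whole matrix is zero).
    """

    order: int
    a0: np.ndarray            # (k, k), zero diagonal
    lag_coefs: np.ndarray     # (p, k, k)
    intercept: np.ndarray     # (k,)
    residuals: np.ndarray     # (T - p, k)
    resid_cov: np.ndarray     # (k, k)
    bic: float
    zero_lag: bool = True

    @property
    def k(self) -> int:
        return self.a0.shape[0]


def _design(X: np.ndarray, p: int, zero_lag: bool) -> np.ndarray:
    """Regressor matrix over t = p+1..T: [zero-lag cols | lag 1..p cols | 1]."""
    T = X.shape[0]
    parts = []
    if zero_lag:
        parts.append(X[p:])
    for n in range(1, p + 1):
        parts.append(X[p - n:T - n])
    parts.append(np.ones((T - p, 1)))
    return np.concatenate(parts, axis=1)


def _check_standardized(X: np.ndarray) -> bool:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    return bool(np.max(np.abs(mu)) < 1e-6 and np.max(np.abs(sd - 1)) < 1e-4)


def _n_free(k: int, p: int, zero_lag: bool) -> int:
    return (k * (k - 1) if zero_lag else 0) + p * k * k


def fit_mmvar(X: np.ndarray, order: int, zero_lag: bool = True,
              allow_unstandardized: bool = False) -> MvarModel:
    """Least-squares fit of the mMVAR at a fixed order.

    ``X`` must be T x k and standardized (columns mean 0, sample SD 1) unless
    ``allow_unstandardized`` is set.  Each target equation i regresses x_i(t)
    on the other series at lag 0 (when ``zero_lag``) and on all series at
    lags 1..p, plus an intercept that is kept but not counted as a model
    parameter.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise FitError("X must be a T x k matrix")
    T, k = X.shape
    p = int(order)
    if p < 1:
        raise FitError("order must be >= 1")
    if T - p <= k * (p + 1):
        raise FitError(
            f"insufficient time points: need T - p > k(p+1), got T={T}, k={k}, p={p}")
    if not allow_unstandardized and not _check_standardized(X):
        raise FitError(
            "series are not standardized (mean 0, sample SD 1); standardize "
            "first or pass allow_unstandardized=True")

    Z = _design(X, p, zero_lag)
    Y = X[p:]
    m = Z.shape[1]
    a0 = np.zeros((k, k))
    coefs = np.zeros((p, k, k))
    icpt = np.zeros(k)
    resid = np.empty_like(Y)
    for i in range(k):
        if zero_lag:
            cols = np.r_[0:i, i + 1:m]
        else:
            cols = np.arange(m)
        Zi = Z[:, cols]
        if np.linalg.matrix_rank(Zi) < Zi.shape[1]:
            raise FitError(
                f"regressor matrix rank-deficient for target {i} "
                "(duplicated ROI series?)")
        b, *_ = np.linalg.lstsq(Zi, Y[:, i], rcond=None)
        off = 0
        if zero_lag:
            a0[i, :i] = b[:i]
            a0[i, i + 1:] = b[i:k - 1]
            off = k - 1
        coefs[:, i, :] = b[off:off + p * k].reshape(p, k)
        icpt[i] = b[-1]
        resid[:, i] = Y[:, i] - Zi @ b

    Tp = T - p
    cov = resid.T @ resid / Tp
    sign, logdet = np.linalg.slogdet(cov)
    bic = Tp * logdet + _n_free(k, p, zero_lag) * np.log(Tp) if sign > 0 else np.inf
    return MvarModel(p, a0, coefs, icpt, resid, cov, float(bic), zero_lag)


def fit_mmvar_batched(Xb: np.ndarray, order: int, zero_lag: bool = True):
    """Vectorized least squares over a batch of series (n, T, k).

    Solves the per-target normal equations for every batch member at once;
    used for surrogate ensembles where thousands of fits share one shape.
    Returns ``(a0, lag_coefs)`` with shapes (n, k, k) and (n, p, k, k).
    """
    Xb = np.asarray(Xb, dtype=float)
    n, T, k = Xb.shape
    p = int(order)
    rows = T - p
    parts = []
    if zero_lag:
        parts.append(Xb[:, p:, :])
    for lag in range(1, p + 1):
        parts.append(Xb[:, p - lag:T - lag, :])
    parts.append(np.ones((n, rows, 1)))
    Z = np.concatenate(parts, axis=2)               # (n, rows, m)
    Y = Xb[:, p:, :]
    Zt = Z.transpose(0, 2, 1)
    G = Zt @ Z                                      # (n, m, m)
    C = Zt @ Y                                      # (n, m, k)
    m = Z.shape[2]

    a0 = np.zeros((n, k, k))
    coefs = np.zeros((n, p, k, k))
    if zero_lag:
        for i in range(k):
            cols = np.r_[0:i, i + 1:m]
            Gi = G[:, cols[:, None], cols[None, :]]
            ci = C[:, cols, i]
            bi = np.linalg.solve(Gi, ci[..., None])[..., 0]   # (n, m-1)
            a0[:, i, :i] = bi[:, :i]
            a0[:, i, i + 1:] = bi[:, i:k - 1]
            coefs[:, :, i, :] = bi[:, k - 1:k - 1 + p * k].reshape(n, p, k)
    else:
        B = np.linalg.solve(G, C)                   # (n, m, k)
        coefs = B[:, :p * k, :].reshape(n, p, k, k).transpose(0, 1, 3, 2)
    return a0, coefs


def cpgc_from_coefs(lag_coefs: np.ndarray) -> np.ndarray:
    """CPGC_ij = sum over lags of a_ij(n)^2, diagonal zeroed.

    Accepts (p, k, k) or batched (n, p, k, k); sums over the lag axis.
    """
    lag_axis = lag_coefs.ndim - 3
    out = np.square(lag_coefs).sum(axis=lag_axis)
    k = out.shape[-1]
    di = np.arange(k)
    out[..., di, di] = 0.0
    return out


def cpgc_from_model(model: MvarModel, normalize_by_resid: bool = False) -> np.ndarray:
    """Directed causal-strength matrix from a fitted model.

    With ``normalize_by_resid`` each row i is divided by the residual
    variance of its target equation (a monotone variant, default off).
    """
    out = cpgc_from_coefs(model.lag_coefs)
    if normalize_by_resid:
        out = out / np.diag(model.resid_cov)[:, None]
    return out


def instantaneous_corr(model: MvarModel, symmetrize: bool = False) -> np.ndarray:
    """Zero-lag association matrix: A(0) with zero diagonal.

    ``symmetrize`` averages A(0) with its transpose (off by default; the raw
    rows come from different target equations and need not be symmetric).
    """
    out = model.a0.copy()
    np.fill_diagonal(out, 0.0)
    if symmetrize:
        out = 0.5 * (out + out.T)
    return out


def select_order_bic(X: np.ndarray, p_max: int, zero_lag: bool = True,
                     allow_unstandardized: bool = False) -> int:
    """Smallest order minimizing BIC = T' log det(Sigma) + n_free log T'.

    Candidate orders 1..p_max are each fitted on their own effective sample;
    ties break toward the smaller order (strict improvement required).
    """
    if p_max < 1:
        raise FitError("p_max must be >= 1")
    best_p, best_bic = None, np.inf
    for p in range(1, p_max + 1):
        bic = fit_mmvar(X, p, zero_lag=zero_lag,
                        allow_unstandardized=allow_unstandardized).bic
        if bic < best_bic:
            best_p, best_bic = p, bic
    return best_p


class CorrelationPurgedGC(BaseEstimator):
    """Correlation-purged Granger causality estimator for one T x k series.

    Parameters
    ----------
    order : int, default 5
        VAR order p (the study default); ignored when ``select_order``.
    select_order : bool, default False
        Choose the order in 1..max_order by BIC instead.
    max_order : int, default 10
        Upper bound for BIC order selection.
    zero_lag : bool, default True
        Include the instantaneous A(0) terms.  ``False`` gives the naive
        Granger variant used only to demonstrate correlation leakage.
    standardize : bool, default True
        Z-score columns (sample SD) before fitting, as the analysis requires.
    normalize_by_resid : bool, default False
        Divide CPGC rows by target residual variance (monotone variant).

    Attributes (after ``fit``)
    --------------------------
    order_, a0_, lag_coefs_, intercept_, resid_, resid_cov_, bic_,
    cpgc_ (k x k, entry [i, j] = influence of series j on series i),
    instant_corr_, n_features_in_.
    """

    def __init__(self, order: int = DEFAULTS["model_order"],
                 select_order: bool = False, max_order: int = 10,
                 zero_lag: bool = True, standardize: bool = True,
                 normalize_by_resid: bool = False):
        self.order = order
        self.select_order = select_order
        self.max_order = max_order
        self.zero_lag = zero_lag
        self.standardize = standardize
        self.normalize_by_resid = normalize_by_resid

    def fit(self, X, y=None):
        X = np.asarray(getattr(X, "data", X), dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise FitError("X must be T x k with k >= 2")
        if self.standardize:
            X = standardize_array(X)
        p = (select_order_bic(X, self.max_order, self.zero_lag,
                              allow_unstandardized=not self.standardize)
             if self.select_order else int(self.order))
        model = fit_mmvar(X, p, zero_lag=self.zero_lag,
                          allow_unstandardized=not self.standardize)
        self.model_ = model
        self.order_ = model.order
        self.a0_ = model.a0
        self.lag_coefs_ = model.lag_coefs
        self.intercept_ = model.intercept
        self.resid_ = model.residuals
        self.resid_cov_ = model.resid_cov
        self.bic_ = model.bic
        self.cpgc_ = cpgc_from_model(model, self.normalize_by_resid)
        self.instant_corr_ = instantaneous_corr(model)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X=None):
        """Return the fitted CPGC matrix (the estimator's summary output)."""
        if not hasattr(self, "cpgc_"):
            raise FitError("estimator is not fitted")
        return self.cpgc_
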