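"""Spatial lag model (SLM) estimation, prediction and cross-validation.

The model for per-pixel exceedance counts y is

    y = rho * W y + X beta + eps,      eps ~ N(0, sigma^2 I)

where W is a row-standardized spatial weights matrix and rho measures the
average influence of neighbouring pixels on a pixel's own count.  Estimation
is by maximum likelihood with rho concentrated out (Ord 1975 style): for a
candidate rho, beta(rho) and sigma^2(rho) come from OLS of (I - rho W) y on
X, and the concentrated log-likelihood

    L(rho) = -(n/2) [ln(2 pi) + 1] - (n/2) ln sigma^2(rho) + ln|I - rho W|

is maximized by bounded scalar optimization.  The log-determinant uses a
one-off eigenvalue decomposition of W for moderate n (<= 2000) and sparse LU
factorization above that, so no dense n x n matrix is ever formed for large
problems.

Prediction uses the reduced form y_hat = (I - rho W)^-1 X beta, solved
sparsely; this is also how counterfactual NDVI surfaces propagate to
neighbouring pixels' predictions (the spatial multiplier).

The estimator follows scikit-learn conventions (fit/predict, get_params,
trailing-underscore fitted attributes).  A spatial two-stage least-squares
alternative (instruments X, WX, W^2 X) is available via ``method="tsls"``
for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize_scalar
from scipy.sparse.linalg import splu, spsolve
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from .weights import SpatialWeights

__all__ = [
    "SpatialLagRegressor",
    "CVReport",
    "ols_fit",
    "slm_fit_ml",
    "slm_predict",
    "kfold_cv",
    "precompute_w_eigenvalues",
]

_EIG_MAX_N = 2000


def precompute_w_eigenvalues(W: SpatialWeights) -> np.ndarray:
    """Eigenvalues of W (complex), reusable across fits sharing one W."""
    from scipy.linalg import eigvals

    return eigvals(W.matrix.toarray())


def _log_det(rho: float, W: SpatialWeights, eigs: np.ndarray | None) -> float:
    """ln|I - rho W|, via eigenvalues when available, else sparse LU."""
    if eigs is not None:
        # det(I - rho W) = prod(1 - rho lambda_i); complex pairs conjugate,
        # so the sum of logs is real up to rounding
        return float(np.sum(np.log(1.0 - rho * eigs)).real)
    A = (sparse.identity(W.n, format="csc") - rho * W.matrix.tocsc())
    lu = splu(A, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True})
    diagU = lu.U.diagonal()
    if np.any(diagU == 0):
        raise FloatingPointError("singular (I - rho W): non-finite log-determinant")
    return float(np.sum(np.log(np.abs(diagU))))


def ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Ordinary least squares baseline.

    Returns ``(beta, r2, mae)`` computed on the supplied data.  Raises on a
    rank-deficient design.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else float("nan")
    mae = float(np.abs(resid).mean())
    return beta, r2, mae


class SpatialLagRegressor(RegressorMixin, BaseEstimator):
    """Maximum-likelihood spatial lag regression.

    Parameters
    ----------
    rho_bounds : tuple of float
        Search interval for the spatial autoregressive parameter, strictly
        inside the admissible interval (1/lambda_min, 1) for row-standardized
        weights.  Default (-0.99, 0.99); a boundary hit is flagged in
        ``converged_``.
    method : {"ml", "tsls"}
        "ml" (default) concentrated-likelihood maximum likelihood; "tsls"
        spatial two-stage least squares with instruments [X, WX, W^2 X].
    fit_intercept : bool
        Prepend a column of ones to X (default True).  Features are never
        standardized: NDVI and d_w already live in [0, 1], so coefficients
        stay in interpretable days-per-unit-feature units.

    Attributes
    ----------
    coef_ : ndarray
        Slope coefficients (days per unit feature).
    intercept_ : float
        Intercept (0.0 when ``fit_intercept=False``).
    rho_ : float
        Spatial autoregressive parameter.
    sigma2_ : float
        Residual variance (days^2).
    loglik_ : float
        Maximized log-likelihood ("ml" only; NaN for "tsls").
    converged_ : bool
        False when the optimizer stops at a bound of ``rho_bounds``.
    n_ : int
        Sample size.
    """

    def __init__(
        self,
        rho_bounds: tuple[float, float] = (-0.99, 0.99),
        method: str = "ml",
        fit_intercept: bool = True,
    ):
        self.rho_bounds = rho_bounds
        self.method = method
        self.fit_intercept = fit_intercept

    # ------------------------------------------------------------------
    def _design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        W: SpatialWeights,
        w_eigenvalues: np.ndarray | None = None,
    ) -> "SpatialLagRegressor":
        """Fit the model.

        Parameters
        ----------
        X : array-like of shape (n, p)
            Features (without intercept column when ``fit_intercept``).
        y : array-like of shape (n,)
            Exceedance counts (days).
        W : SpatialWeights
            Row-standardized weights aligned with the rows of X.
        w_eigenvalues : ndarray, optional
            Precomputed eigenvalues of W (from
            :func:`precompute_w_eigenvalues`) to share across repeated fits
            with the same weights.
        """
        Xd = self._design(X)
        y = np.asarray(y, dtype=float)
        n, p = Xd.shape
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        if n != W.n:
            raise ValueError("X/y length does not match weights")
        if np.linalg.matrix_rank(Xd) < p:
            raise ValueError("design matrix is rank-deficient")

        if self.method == "tsls":
            self._fit_tsls(Xd, y, W)
        elif self.method == "ml":
            self._fit_ml(Xd, y, W, w_eigenvalues)
        else:
            raise ValueError(f"unknown method {self.method!r}")

        self.n_ = n
        self.n_features_in_ = Xd.shape[1] - int(self.fit_intercept)
        return self

    def _fit_ml(self, X, y, W, eigs) -> None:
        n = X.shape[0]
        if eigs is None and W.n <= _EIG_MAX_N:
            eigs = precompute_w_eigenvalues(W)

        Wy = W.matrix @ y
        # residual-maker applied once: e0 = resid(y|X), e1 = resid(Wy|X)
        b0, *_ = np.linalg.lstsq(X, y, rcond=None)
        b1, *_ = np.linalg.lstsq(X, Wy, rcond=None)
        e0 = y - X @ b0
        e1 = Wy - X @ b1

        lo, hi = self.rho_bounds
        if eigs is not None:
            # keep strictly inside the admissible interval (1/lambda_min, 1)
            lam_min = eigs.real.min()
            if lam_min < 0:
                lo = max(lo, 1.0 / lam_min + 1e-6)

        def neg_conc_loglik(rho: float) -> float:
            e = e0 - rho * e1
            s2 = float(e @ e) / n
            return -(
                -0.5 * n * (np.log(2 * np.pi) + 1.0)
                - 0.5 * n * np.log(s2)
                + _log_det(rho, W, eigs)
            )

        res = minimize_scalar(
            neg_conc_loglik, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        rho = float(res.x)
        tol = 1e-5
        self.converged_ = bool(res.success) and (lo + tol < rho < hi - tol)

        beta = b0 - rho * b1
        e = e0 - rho * e1
        sigma2 = float(e @ e) / n
        self.rho_ = rho
        self.sigma2_ = sigma2
        self.loglik_ = float(-res.fun)
        self._set_coefs(beta)

    def _fit_tsls(self, X, y, W) -> None:
        Wy = W.matrix @ y
        Xs = X[:, 1:] if self.fit_intercept else X
        Q = np.column_stack([X, W.matrix @ Xs, W.matrix @ (W.matrix @ Xs)])
        Z = np.column_stack([X, Wy])
        Zhat = Q @ np.linalg.lstsq(Q, Z, rcond=None)[0]
        theta, *_ = np.linalg.lstsq(Zhat, y, rcond=None)
        resid = y - Z @ theta
        self.rho_ = float(theta[-1])
        self.sigma2_ = float(resid @ resid) / X.shape[0]
        self.loglik_ = float("nan")
        self.converged_ = abs(self.rho_) < 1.0
        self._set_coefs(theta[:-1])

    def _set_coefs(self, beta: np.ndarray) -> None:
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = np.asarray(beta[1:], dtype=float)
        else:
            self.intercept_ = 0.0
            self.coef_ = np.asarray(beta, dtype=float)

    @property
    def beta_(self) -> np.ndarray:
        """Full coefficient vector including the intercept."""
        if self.fit_intercept:
            return np.concatenate([[self.intercept_], self.coef_])
        return self.coef_

    def predict(
        self,
        X: np.ndarray,
        W: SpatialWeights,
        clip: tuple[float, float] | None = None,
    ) -> np.ndarray:
        """Reduced-form prediction: solve (I - rho W) y_hat = X beta.

        ``clip=(lo, hi)`` bounds the result (exposure use clips to
        [0, season_length]); the number of clipped pixels is stored on
        ``last_n_clipped_``.
        """
        Xd = self._design(X)
        if Xd.shape[0] != W.n:
            raise ValueError("X rows do not match weights")
        xb = Xd @ self.beta_
        A = sparse.identity(W.n, format="csc") - self.rho_ * W.matrix.tocsc()
        yhat = spsolve(A, xb)
        if not np.all(np.isfinite(yhat)):
            raise FloatingPointError("singular reduced-form system")
        self.last_n_clipped_ = 0
        if clip is not None:
            out = np.clip(yhat, clip[0], clip[1])
            self.last_n_clipped_ = int((out != yhat).sum())
            yhat = out
        return yhat

    def log_likelihood_ols(self, X: np.ndarray, y: np.ndarray) -> float:
        """Gaussian log-likelihood of the rho = 0 (OLS) submodel."""
        Xd = self._design(X)
        y = np.asarray(y, dtype=float)
        n = Xd.shape[0]
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ beta
        s2 = float(resid @ resid) / n
        return float(-0.5 * n * (np.log(2 * np.pi) + 1.0) - 0.5 * n * np.log(s2))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept_,
            "coef": list(map(float, self.coef_)),
            "rho": self.rho_,
            "sigma2": self.sigma2_,
            "loglik": self.loglik_,
            "converged": self.converged_,
            "n": self.n_,
            "method": self.method,
        }


# ----------------------------------------------------------------------
# thin functional wrappers


def slm_fit_ml(
    X: np.ndarray,
    y: np.ndarray,
    W: SpatialWeights,
    w_eigenvalues: np.ndarray | None = None,
    rho_bounds: tuple[float, float] = (-0.99, 0.99),
) -> SpatialLagRegressor:
    """Fit the SLM by concentrated maximum likelihood (X without intercept)."""
    return SpatialLagRegressor(rho_bounds=rho_bounds).fit(
        X, y, W, w_eigenvalues=w_eigenvalues
    )


def slm_predict(
    model: SpatialLagRegressor,
    X_new: np.ndarray,
    W: SpatialWeights,
    clip: tuple[float, float] | None = None,
) -> np.ndarray:
    return model.predict(X_new, W, clip=clip)


# ----------------------------------------------------------------------
# cross-validation


@dataclass
class CVReport:
    """Per-fold spatial-lag CV results plus fold-averaged coefficients.

    ``mean_beta``/``mean_rho`` are arithmetic means of the per-fold training
    estimates; the scenario engine consumes these fold-averaged coefficients.
    """

    folds: pd.DataFrame  # fold, r2_train, mae_train, r2_test, mae_test, rho + coefs
    mean_beta: np.ndarray  # (intercept, slopes...)
    mean_rho: float

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def to_csv(self, path) -> None:
        self.folds.to_csv(path, index=False)


def _restrict_weights(W: SpatialWeights, idx: np.ndarray) -> SpatialWeights:
    """W restricted to the pixel subset ``idx``, rows re-standardized.

    A training pixel that loses all its neighbours keeps a zero row (no
    spatial term); with k = 8 and realistic fold sizes this is rare.
    """
    sub = W.matrix[np.ix_(idx, idx)].tocsr()
    rs = np.asarray(sub.sum(axis=1)).ravel()
    scale = np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)
    sub = sparse.diags(scale) @ sub
    return SpatialWeights(matrix=sub.tocsr(), k=W.k, ids=W.ids[idx],
                          row_standardized=True)


def _score(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    sse = float(((y_true - y_pred) ** 2).sum())
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    mae = float(np.abs(y_true - y_pred).mean())
    return r2, mae


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    W: SpatialWeights,
    n_folds: int = 5,
    seed: int | None = 0,
    model: SpatialLagRegressor | None = None,
) -> CVReport:
    """k-fold cross-validation of the SLM over pixels.

    Each fold fits on the training pixels with W restricted to the training
    subgraph (rows re-standardized) and predicts *all* pixels by the
    reduced form on the full W with the training coefficients — held-out
    outcomes never enter the prediction.  Scores are reported on the
    training and test partitions; coefficients are averaged over folds.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n = y.size
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    proto = model if model is not None else SpatialLagRegressor()
    p = X.shape[1] + int(proto.fit_intercept)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    betas, rhos = [], []
    for fold, (tr, te) in enumerate(kf.split(X)):
        if len(tr) < p or len(te) < 1:
            raise ValueError("fold smaller than the number of features")
        W_tr = _restrict_weights(W, tr)
        m = proto.__class__(**proto.get_params()).fit(X[tr], y[tr], W_tr)
        yhat_tr = m.predict(X[tr], W_tr)
        yhat_all = m.predict(X, W)
        r2_tr, mae_tr = _score(y[tr], yhat_tr)
        r2_te, mae_te = _score(y[te], yhat_all[te])
        rows.append(
            {"fold": fold, "r2_train": r2_tr, "mae_train": mae_tr,
             "r2_test": r2_te, "mae_test": mae_te, "rho": m.rho_,
             **{f"beta_{j}": b for j, b in enumerate(m.beta_)}}
        )
        betas.append(m.beta_)
        rhos.append(m.rho_)
    folds = pd.DataFrame(rows)
    return CVReport(
        folds=folds,
        mean_beta=np.mean(betas, axis=0),
        mean_rho=float(np.mean(rhos)),
    )
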