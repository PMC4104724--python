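"""NIPALS partial least squares for a binary (0/1-coded) response.

The model regresses disease status ``y`` on the expression of all probes,

    y = sum_i alpha_i x_i + b,

and estimates it through latent variables: NIPALS extracts components one
at a time, each maximizing the covariance between an expression score
``t_k = X w_k`` (``||w_k|| = 1``) and a response score ``u_k``, then
deflates the working matrices,

    X <- X - t (t^T X) / (t^T t),    y <- y - t (t^T y) / (t^T t),

which makes successive score vectors mutually orthogonal. For a single
response the inner iteration converges on the first pass (the first weight
is the normalized covariance vector ``X^T y / ||X^T y||``), so the fit is
deterministic.

Conventions
-----------
* Columns of X are mean-centered, and unit-variance scaled by default
  (``scale=True``); y is mean-centered. Zero-variance columns are dropped
  with a logged list (their indices are in ``dropped_``).
* Each weight vector is sign-fixed so its largest-magnitude entry is
  positive; VIP is sign-invariant, so this only pins down reproducibility.
* Class prediction thresholds the continuous response estimate at 0.5
  (the midpoint of the 0/1 coding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import (
    ConvergenceError,
    InvalidParameterError,
    RankDeficiencyError,
)

logger = logging.getLogger(__name__)

__all__ = ["StandardizedData", "standardize", "PLSNipals", "nipals_fit",
           "pls_predict", "latent_correlations"]

_VAR_TOL = 1e-12


# ---------------------------------------------------------------------------
# standardization (frame boundary: probes x samples -> samples x features)
# ---------------------------------------------------------------------------

@dataclass
class StandardizedData:
    """Centered (and optionally scaled) design matrix with inversion info."""

    X: np.ndarray          # n samples x p kept features
    y: np.ndarray          # centered response, length n
    x_mean: np.ndarray     # per kept feature
    x_scale: np.ndarray    # per kept feature (ones when scaling is off)
    y_mean: float
    kept: np.ndarray       # boolean mask over the input features
    probe_ids: list[str]   # kept probe ids (frame input) or indices
    sample_ids: list[str]


def standardize(expr: pd.DataFrame, pheno: pd.Series,
                scale_columns: bool = True) -> StandardizedData:
    """Standardize a probes x samples frame for PLS fitting.

    Transposes to samples x features, mean-centers every column, scales to
    unit variance when ``scale_columns`` and drops zero-variance probes
    (logged). Requires at least two samples per class.
    """
    y = np.asarray(pheno.reindex(expr.columns), dtype=float)
    if np.isnan(y).any():
        raise InvalidParameterError("phenotype does not cover all expression samples")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n0 < 2 or n1 < 2:
        raise InvalidParameterError(
            f"need >= 2 samples per class, got {n0} controls / {n1} cases")
    X = expr.to_numpy(dtype=float).T
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    kept = sd > _VAR_TOL
    if not kept.any():
        raise InvalidParameterError("every probe has zero variance")
    if not kept.all():
        dropped = [str(p) for p in expr.index[~kept]]
        logger.info("dropped %d zero-variance probe(s): %s",
                    len(dropped), ", ".join(dropped[:20]))
    Xk = X[:, kept] - mean[kept]
    scale = sd[kept] if scale_columns else np.ones(kept.sum())
    Xk = Xk / scale
    return StandardizedData(
        X=Xk, y=y - y.mean(), x_mean=mean[kept], x_scale=scale,
        y_mean=float(y.mean()), kept=kept,
        probe_ids=[str(p) for p in expr.index[kept]],
        sample_ids=[str(s) for s in expr.columns],
    )


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class PLSNipals(RegressorMixin, BaseEstimator):
    """Single-response PLS regression fitted by the NIPALS iteration.

    Parameters
    ----------
    n_components : int
        Number of latent variables ``h``; must satisfy
        ``1 <= h <= min(n_samples - 1, n_features)``.
    scale : bool
        Scale columns of X to unit variance (columns are always centered).
    tol : float
        Convergence tolerance on ``||u - u_prev||`` of the inner iteration.
    max_iter : int
        Iteration cap per component; exceeding it raises
        :class:`~plsde.exceptions.ConvergenceError`.
    threshold : float
        Decision threshold on the continuous response estimate for
        :meth:`predict_binary`.

    Attributes
    ----------
    x_weights_ : ndarray (p_kept, h)
        Unit-norm weight vectors ``w_k``.
    x_scores_ : ndarray (n, h)
        Score vectors ``t_k`` (mutually orthogonal).
    x_loadings_ : ndarray (p_kept, h)
        Loadings ``p_k = X_k^T t_k / (t_k^T t_k)``.
    y_weights_ : ndarray (h,)
        Normalized y-weights ``c_k`` (±1 for a single response).
    y_scores_ : ndarray (n, h)
        Response scores ``u_k``.
    y_loadings_ : ndarray (h,)
        Regression of the working response on ``t_k``.
    x_rotations_ : ndarray (p_kept, h)
        ``W (P^T W)^{-1}``: maps centered/scaled X to scores.
    coef_ : ndarray (p,)
        Regression coefficients on the original feature scale (zeros at
        dropped columns); ``intercept_`` completes the linear model.
    kept_ : ndarray (p,) of bool
        Mask of non-constant columns actually used.
    n_iter_ : list of int
        Inner-iteration count per component.
    """

    def __init__(self, n_components: int = 2, *, scale: bool = True,
                 tol: float = 1e-8, max_iter: int = 500,
                 threshold: float = 0.5):
        self.n_components = n_components
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter
        self.threshold = threshold

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y) -> "PLSNipals":
        X, y = check_X_y(X, y, dtype=float, y_numeric=True)
        n, p = X.shape
        h = int(self.n_components)
        if h < 1:
            raise InvalidParameterError("n_components must be >= 1")
        if h > min(n - 1, p):
            raise InvalidParameterError(
                f"n_components={h} exceeds min(n_samples - 1, n_features) = "
                f"{min(n - 1, p)}")
        if not (self.tol > 0 and self.max_iter >= 1):
            raise InvalidParameterError("tol must be > 0 and max_iter >= 1")

        self.x_mean_full_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        kept = sd > _VAR_TOL
        if not kept.any():
            raise InvalidParameterError("every feature has zero variance")
        if not kept.all():
            logger.info("dropped %d zero-variance feature(s)", int((~kept).sum()))
        self.kept_ = kept
        self.x_mean_ = self.x_mean_full_[kept]
        self.x_scale_ = sd[kept] if self.scale else np.ones(int(kept.sum()))
        self.y_mean_ = float(np.mean(y))

        Xw = (X[:, kept] - self.x_mean_) / self.x_scale_
        yw = np.asarray(y, dtype=float) - self.y_mean_
        self._fit_standardized(Xw, yw, h)

        pk = int(kept.sum())
        coef_kept = self.x_rotations_ @ self.y_loadings_
        coef = np.zeros(p)
        coef[kept] = coef_kept / self.x_scale_
        self.coef_ = coef
        self.intercept_ = self.y_mean_ - float(self.x_mean_full_ @ coef)
        self.n_features_in_ = p
        self.n_components_ = h
        self.n_kept_features_ = pk
        return self

    def _fit_standardized(self, Xw: np.ndarray, yw: np.ndarray, h: int) -> None:
        """NIPALS on an already centered/scaled matrix; mutates copies only."""
        Xw = Xw.copy()
        yw = yw.copy()
        n, pk = Xw.shape
        W = np.empty((pk, h))
        P = np.empty((pk, h))
        T = np.empty((n, h))
        U = np.empty((n, h))
        C = np.empty(h)
        Q = np.empty(h)
        n_iter: list[int] = []
        eps = np.finfo(float).eps

        for k in range(h):
            u0 = yw.copy()
            if float(u0 @ u0) < eps:
                raise RankDeficiencyError(
                    f"response fully explained before component {k + 1}; "
                    f"only {k} component(s) available", n_components_available=k)
            for it in range(1, self.max_iter + 1):
                w = Xw.T @ u0
                nw = float(np.linalg.norm(w))
                if nw < 1e3 * eps:
                    raise RankDeficiencyError(
                        f"working matrix has no covariance with the response at "
                        f"component {k + 1}; only {k} component(s) available",
                        n_components_available=k)
                w /= nw
                t = Xw @ w
                c = float(yw @ t)
                if abs(c) < 1e3 * eps:
                    raise RankDeficiencyError(
                        f"score t_{k + 1} is uncorrelated with the response; "
                        f"only {k} component(s) available",
                        n_components_available=k)
                c_n = c / abs(c)
                u = yw * c_n
                if float(np.linalg.norm(u - u0)) < self.tol:
                    break
                u0 = u
            else:
                raise ConvergenceError(
                    f"NIPALS did not converge for component {k + 1} within "
                    f"{self.max_iter} iterations")
            n_iter.append(it)

            tt = float(t @ t)
            if tt < 1e3 * eps:
                raise RankDeficiencyError(
                    f"score t_{k + 1} is numerically zero; only {k} "
                    f"component(s) available", n_components_available=k)
            # reproducible sign: largest-|.| weight entry positive
            j = int(np.argmax(np.abs(w)))
            if w[j] < 0:
                w, t, c_n, u = -w, -t, -c_n, -u
            p_load = Xw.T @ t / tt
            q = float(yw @ t) / tt
            Xw -= np.outer(t, p_load)
            yw -= t * q
            W[:, k], P[:, k], T[:, k], U[:, k] = w, p_load, t, u
            C[k], Q[k] = c_n, q

        self.x_weights_ = W
        self.x_loadings_ = P
        self.x_scores_ = T
        self.y_scores_ = U
        self.y_weights_ = C
        self.y_loadings_ = Q
        self.x_rotations_ = W @ np.linalg.inv(P.T @ W)
        self.n_iter_ = n_iter

    # -- prediction ---------------------------------------------------------

    def _standardize_new(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise InvalidParameterError(
                f"X has {X.shape[1]} features, model was fitted with "
                f"{self.n_features_in_}")
        return (X[:, self.kept_] - self.x_mean_) / self.x_scale_

    def transform(self, X) -> np.ndarray:
        """Project samples onto the latent variables (scores of new data)."""
        return self._standardize_new(X) @ self.x_rotations_

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        """Continuous response estimate, using the first ``n_components``
        latent variables (all by default)."""
        scores = self.transform(X)
        h = self.n_components_ if n_components is None else int(n_components)
        if not 1 <= h <= self.n_components_:
            raise InvalidParameterError(
                f"n_components must be in [1, {self.n_components_}]")
        return scores[:, :h] @ self.y_loadings_[:h] + self.y_mean_

    def predict_binary(self, X, n_components: int | None = None) -> np.ndarray:
        """Class labels: 1 where the continuous estimate >= ``threshold``."""
        return (self.predict(X, n_components) >= self.threshold).astype(int)


# ---------------------------------------------------------------------------
# frame-level wrappers and diagnostics
# ---------------------------------------------------------------------------

def nipals_fit(data: StandardizedData, h: int, tol: float = 1e-8,
               max_iter: int = 500) -> PLSNipals:
    """Fit :class:`PLSNipals` on already-standardized data.

    The returned model carries the standardization recorded in ``data`` so
    that :meth:`PLSNipals.predict` accepts matrices on the original scale
    (columns ordered as the kept probes).
    """
    n, pk = data.X.shape
    if not 1 <= h <= min(n - 1, pk):
        raise InvalidParameterError(
            f"h={h} outside [1, {min(n - 1, pk)}] for n={n}, p={pk}")
    model = PLSNipals(n_components=h, scale=False, tol=tol, max_iter=max_iter)
    model.kept_ = np.ones(pk, dtype=bool)
    model.x_mean_full_ = data.x_mean
    model.x_mean_ = np.zeros(pk)
    model.x_scale_ = np.ones(pk)
    model.y_mean_ = data.y_mean
    model._fit_standardized(data.X, data.y, h)
    coef_kept = model.x_rotations_ @ model.y_loadings_
    model.coef_ = coef_kept / data.x_scale
    model.intercept_ = data.y_mean - float(data.x_mean @ model.coef_)
    model.n_features_in_ = pk
    model.n_components_ = h
    model.n_kept_features_ = pk
    model.probe_ids_ = list(data.probe_ids)
    # patch standardization so predict() consumes original-scale matrices
    model.x_mean_ = data.x_mean
    model.x_scale_ = data.x_scale
    model.x_mean_full_ = data.x_mean
    return model


def pls_predict(model: PLSNipals, expr_new: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Predict (continuous scores, 0/1 classes) for a probes x samples frame.

    The frame's probes must be a superset of the model's retained probes;
    missing probes are a listed error.
    """
    if not hasattr(model, "probe_ids_"):
        raise InvalidParameterError("model was not fitted through nipals_fit/standardize")
    missing = [p for p in model.probe_ids_ if p not in expr_new.index]
    if missing:
        raise InvalidParameterError(
            f"expression matrix is missing {len(missing)} model probe(s): "
            + ", ".join(missing[:10]))
    X = expr_new.loc[model.probe_ids_].to_numpy(dtype=float).T
    cont = model.predict(X)
    return cont, (cont >= model.threshold).astype(int)


def latent_correlations(model: PLSNipals, y) -> np.ndarray:
    """Squared Pearson correlation of the response with each x-score ``t_k``."""
    check_is_fitted(model, "x_scores_")
    y = np.asarray(y, dtype=float)
    T = model.x_scores_
    if y.shape[0] != T.shape[0]:
        raise InvalidParameterError("y length does not match fitted samples")
    yc = y - y.mean()
    ny = float(np.linalg.norm(yc))
    if ny == 0.0:
        raise InvalidParameterError("response has zero variance")
    out = np.empty(T.shape[1])
    for k in range(T.shape[1]):
        tc = T[:, k] - T[:, k].mean()
        nt = float(np.linalg.norm(tc))
        if nt == 0.0:
            raise InvalidParameterError(f"x-score {k + 1} has zero variance")
        out[k] = (float(yc @ tc) / (ny * nt)) ** 2
    return out
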