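"""Gene selection on top of the PLS fit: VIP scores, cross-validated choice
of the number of latent variables, permutation FDR, and the selected-gene
table with regulation direction.

VIP (variable importance in projection) for probe j over h components is

    VIP_j = sqrt( p * sum_k r2_k * w_kj^2 / sum_k r2_k ),

where ``r2_k = Cor^2(y, t_k)`` is the squared Pearson correlation of the
binary phenotype with the k-th x-score and the weight vectors ``w_k`` are
unit-norm, so that ``sum_j VIP_j^2 = p`` (the number of retained probes).

The permutation FDR for probe i pools null VIPs across all probes and
permutations:

    FDR_i = [ sum_j sum_i' Bool(VIP_{i',j} > VIP_i) / n_perm ] / p

with strict inequality (ties are not exceedances). This pooled estimator is
the default (``method="pooled"``); the conventional exceedance-over-
discoveries estimator is available as ``method="conventional"`` for
comparison only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .exceptions import InvalidParameterError, RankDeficiencyError, ConvergenceError
from .pls import PLSNipals, StandardizedData, latent_correlations, nipals_fit, standardize
from .utils import derive_seed

logger = logging.getLogger(__name__)

__all__ = ["CvCurve", "compute_vip", "cross_val_components", "choose_h_cv",
           "pooled_fdr", "permutation_fdr", "select_genes", "VIPSelector",
           "run_vip_selection"]


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def compute_vip(model: PLSNipals, y) -> np.ndarray:
    """Per-probe VIP over the model's components, weighted by Cor²(y, t_k)."""
    check_is_fitted(model, "x_weights_")
    r2 = latent_correlations(model, y)
    total = float(r2.sum())
    if total <= 0.0:
        raise InvalidParameterError(
            "all squared score-response correlations are zero; VIP undefined")
    W2 = model.x_weights_ ** 2  # columns already unit norm
    p = W2.shape[0]
    return np.sqrt(p * (W2 @ r2) / total)


# ---------------------------------------------------------------------------
# cross-validated choice of h
# ---------------------------------------------------------------------------

@dataclass
class CvCurve:
    """Mean prediction accuracy per candidate number of latent variables."""

    h_values: np.ndarray
    accuracy: np.ndarray
    chosen_h: int
    fold_sizes: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"h": self.h_values, "accuracy": self.accuracy})


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified folds: each class shuffled then dealt round-robin."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_folds:
            raise InvalidParameterError(
                f"class {cls} has {len(idx)} samples, fewer than {n_folds} folds")
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.array(sorted(f)) for f in folds]


def cross_val_components(X, y, h_max: int, n_folds: int = 3, seed: int = 0,
                         scale: bool = True) -> CvCurve:
    """Stratified k-fold accuracy curve over h = 1..h_max.

    Each fold fits one model with ``h_max`` components (components are
    nested, so truncated predictions give every smaller h exactly).
    ``chosen_h`` is the smallest h attaining the maximum mean accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if h_max < 1:
        raise InvalidParameterError("h_max must be >= 1")
    folds = _stratified_folds(y, n_folds, seed)
    correct = np.zeros(h_max)
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        Xtr, ytr = X[train_mask], y[train_mask]
        h_fit = min(h_max, len(ytr) - 1, Xtr.shape[1])
        model = PLSNipals(n_components=h_fit, scale=scale)
        try:
            model.fit(Xtr, ytr)
        except RankDeficiencyError as err:
            if not err.n_components_available:
                raise
            model = PLSNipals(n_components=err.n_components_available,
                              scale=scale).fit(Xtr, ytr)
            h_fit = model.n_components_
        for h in range(1, h_max + 1):
            pred = model.predict_binary(X[test_idx], n_components=min(h, h_fit))
            correct[h - 1] += int(np.sum(pred == y[test_idx]))
    accuracy = correct / n
    chosen = int(np.argmax(accuracy)) + 1  # argmax returns first = smallest h
    return CvCurve(h_values=np.arange(1, h_max + 1), accuracy=accuracy,
                   chosen_h=chosen, fold_sizes=[len(f) for f in folds])


def choose_h_cv(expr: pd.DataFrame, pheno: pd.Series, h_max: int,
                n_folds: int = 3, seed: int = 0,
                scale_columns: bool = True) -> CvCurve:
    """Frame-level wrapper of :func:`cross_val_components` (canonical sample
    order, probes x samples input)."""
    order = sorted(expr.columns)
    X = expr[order].to_numpy(dtype=float).T
    y = pheno.reindex(order).to_numpy(dtype=float)
    return cross_val_components(X, y, h_max, n_folds=n_folds, seed=seed,
                                scale=scale_columns)


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

def pooled_fdr(vip_obs: np.ndarray, vip_null: np.ndarray,
               method: str = "pooled") -> np.ndarray:
    """FDR per probe from observed VIPs and an (n_perm x p) null VIP matrix.

    ``method="pooled"`` divides the pooled strict-exceedance count by
    ``n_perm * p``; ``method="conventional"`` divides the mean per-
    permutation exceedance count by the number of observed discoveries at
    each probe's VIP. Both are clipped to [0, 1]; exact integer counting
    throughout.
    """
    vip_obs = np.asarray(vip_obs, dtype=float)
    vip_null = np.asarray(vip_null, dtype=float)
    if vip_null.ndim != 2 or vip_null.shape[1] != vip_obs.shape[0]:
        raise InvalidParameterError(
            f"null matrix shape {vip_null.shape} does not match "
            f"{vip_obs.shape[0]} probes")
    n_perm, p = vip_null.shape
    pooled = np.sort(vip_null, axis=None)
    # strictly-greater count via right-bisection on the sorted pool
    exceed = pooled.size - np.searchsorted(pooled, vip_obs, side="right")
    if method == "pooled":
        fdr = exceed.astype(float) / (float(n_perm) * float(p))
    elif method == "conventional":
        obs_sorted = np.sort(vip_obs)
        discoveries = p - np.searchsorted(obs_sorted, vip_obs, side="left")
        fdr = (exceed.astype(float) / float(n_perm)) / np.maximum(discoveries, 1)
    else:
        raise InvalidParameterError(f"unknown FDR method {method!r}")
    return np.clip(fdr, 0.0, 1.0)


def _null_vip_matrix(data: StandardizedData, h: int, n_perm: int, seed: int,
                     max_redraw_factor: int = 10) -> tuple[np.ndarray, int]:
    """Null VIPs from label-permuted refits; failed fits are redrawn (counted)."""
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n, p = data.X.shape
    y_orig = data.y + data.y_mean  # original 0/1 labels
    null = np.empty((n_perm, p))
    redraws = 0
    budget = max_redraw_factor * n_perm
    j = 0
    while j < n_perm:
        perm = rng.permutation(n)
        y_perm = y_orig[perm]
        perm_data = StandardizedData(
            X=data.X, y=y_perm - y_perm.mean(), x_mean=data.x_mean,
            x_scale=data.x_scale, y_mean=float(y_perm.mean()), kept=data.kept,
            probe_ids=data.probe_ids, sample_ids=data.sample_ids)
        try:
            model = nipals_fit(perm_data, h)
            null[j] = compute_vip(model, y_perm)
        except (RankDeficiencyError, ConvergenceError, InvalidParameterError):
            redraws += 1
            if redraws > budget:
                raise RankDeficiencyError(
                    f"more than {budget} permutation refits failed at h={h}")
            continue
        j += 1
    if redraws:
        logger.info("redrew %d failed permutation(s)", redraws)
    return null, redraws


def permutation_fdr(expr: pd.DataFrame, pheno: pd.Series, h: int,
                    n_perm: int, seed: int, scale_columns: bool = True,
                    method: str = "pooled") -> pd.Series:
    """Permutation FDR per retained probe for a probes x samples frame.

    Samples are put in canonical (sorted-id) order before any computation,
    so reordering expression columns and phenotype rows jointly leaves the
    result bit-identical.
    """
    order = sorted(expr.columns)
    expr = expr[order]
    data = standardize(expr, pheno.reindex(order), scale_columns=scale_columns)
    model = nipals_fit(data, h)
    vip_obs = compute_vip(model, data.y + data.y_mean)
    null, _ = _null_vip_matrix(data, h, n_perm, seed)
    fdr = pooled_fdr(vip_obs, null, method=method)
    return pd.Series(fdr, index=pd.Index(data.probe_ids, name="probe_id"),
                     name="fdr")


# ---------------------------------------------------------------------------
# the selected-gene table
# ---------------------------------------------------------------------------

def select_genes(expr: pd.DataFrame, pheno: pd.Series, vip: pd.Series,
                 fdr: pd.Series, annotation: pd.Series | None = None,
                 fdr_threshold: float = 0.01) -> pd.DataFrame:
    """Build the per-probe results table.

    ``selected`` is ``fdr < fdr_threshold`` (strict); ``direction`` is
    ``up`` when the case mean exceeds the control mean of the probe's log2
    values, else ``down``. Rows are sorted by ascending FDR then
    descending VIP. Probes absent from ``vip``/``fdr`` (e.g. dropped
    zero-variance probes) appear with NaN scores and ``selected=False``.
    """
    if not 0.0 < fdr_threshold <= 1.0:
        raise InvalidParameterError("fdr_threshold must be in (0, 1]")
    if not vip.index.equals(fdr.index):
        raise InvalidParameterError("vip and fdr must be aligned on the same probes")
    y = pheno.reindex(expr.columns).to_numpy()
    case_mean = expr.loc[:, y == 1].mean(axis=1)
    ctrl_mean = expr.loc[:, y == 0].mean(axis=1)
    table = pd.DataFrame(index=expr.index.astype(str))
    table.index.name = "probe_id"
    table["gene"] = ("" if annotation is None
                     else annotation.reindex(table.index).fillna(""))
    table["vip"] = vip.reindex(table.index)
    table["fdr"] = fdr.reindex(table.index)
    table["selected"] = table["fdr"] < fdr_threshold
    table["selected"] = table["selected"].fillna(False).astype(bool)
    diff = (case_mean - ctrl_mean).reindex(table.index)
    table["direction"] = np.where(diff >= 0, "up", "down")
    table = table.sort_values(["fdr", "vip"], ascending=[True, False],
                              kind="mergesort", na_position="last")
    return table.reset_index()


# ---------------------------------------------------------------------------
# sklearn-style selector
# ---------------------------------------------------------------------------

class VIPSelector(TransformerMixin, BaseEstimator):
    """Feature selector: PLS-VIP scoring with permutation-FDR thresholding.

    Fits a :class:`~plsde.pls.PLSNipals` model (number of latent variables
    chosen by stratified cross-validation unless given), scores every
    feature by VIP, assigns each a pooled permutation FDR and selects
    features with ``fdr < fdr_threshold``.

    Parameters
    ----------
    n_components : int or "cv"
        Number of latent variables, or ``"cv"`` to pick the smallest h
        maximizing mean ``n_folds``-fold accuracy over ``1..h_max``.
    h_max, n_folds : int
        Cross-validation grid and fold count (used when
        ``n_components="cv"``).
    n_perm : int
        Label permutations for the FDR null.
    fdr_threshold : float
        Strict selection cutoff on the permutation FDR.
    fdr_method : {"pooled", "conventional"}
        Pooled estimator (default) or exceedance/discoveries.
    scale : bool
        Unit-variance scaling of features.
    random_state : int
        Seed; fold assignment and permutations derive from it.

    Attributes
    ----------
    model_ : PLSNipals — the fitted latent model (observed labels).
    h_ : int — number of latent variables used.
    cv_curve_ : CvCurve or None — accuracy curve when CV ran.
    vip_ : ndarray (p,) — VIP per feature (NaN at dropped features).
    fdr_ : ndarray (p,) — permutation FDR per feature (NaN at dropped).
    selected_ : ndarray (p,) of bool — ``fdr_ < fdr_threshold``.
    direction_ : ndarray (p,) of str — "up"/"down" by case-control mean.
    n_redrawn_ : int — permutations redrawn after failed refits.
    """

    def __init__(self, n_components: int | str = "cv", *, h_max: int = 8,
                 n_folds: int = 3, n_perm: int = 200,
                 fdr_threshold: float = 0.01, fdr_method: str = "pooled",
                 scale: bool = True, random_state: int = 0):
        self.n_components = n_components
        self.h_max = h_max
        self.n_folds = n_folds
        self.n_perm = n_perm
        self.fdr_threshold = fdr_threshold
        self.fdr_method = fdr_method
        self.scale = scale
        self.random_state = random_state

    def fit(self, X, y) -> "VIPSelector":
        X, y = check_X_y(X, y, dtype=float, y_numeric=True)
        labels = set(np.unique(y))
        if not labels <= {0.0, 1.0} or len(labels) != 2:
            raise InvalidParameterError("y must contain both labels 0 and 1")
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise InvalidParameterError("fdr_threshold must be in (0, 1]")
        base = int(self.random_state)
        if self.n_components == "cv":
            self.cv_curve_ = cross_val_components(
                X, y, h_max=int(self.h_max), n_folds=int(self.n_folds),
                seed=derive_seed(base, 1), scale=self.scale)
            self.h_ = self.cv_curve_.chosen_h
        else:
            self.cv_curve_ = None
            self.h_ = int(self.n_components)

        frame = pd.DataFrame(X.T)  # features x samples, positional labels
        frame.index = frame.index.astype(str)
        frame.columns = [f"S{i:05d}" for i in range(X.shape[0])]
        data = standardize(frame, pd.Series(y, index=frame.columns),
                           scale_columns=self.scale)
        self.model_ = nipals_fit(data, self.h_)
        vip_kept = compute_vip(self.model_, y)
        null, self.n_redrawn_ = _null_vip_matrix(
            data, self.h_, int(self.n_perm), derive_seed(base, 2))
        fdr_kept = pooled_fdr(vip_kept, null, method=self.fdr_method)

        p = X.shape[1]
        self.vip_ = np.full(p, np.nan)
        self.fdr_ = np.full(p, np.nan)
        self.vip_[data.kept] = vip_kept
        self.fdr_[data.kept] = fdr_kept
        with np.errstate(invalid="ignore"):
            self.selected_ = np.where(np.isnan(self.fdr_), False,
                                      self.fdr_ < self.fdr_threshold)
        diff = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        self.direction_ = np.where(diff >= 0, "up", "down")
        self.n_features_in_ = p
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "selected_")
        return self.selected_.astype(bool)

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "selected_")
        X = np.asarray(X, dtype=float)
        return X[:, self.get_support()]


# ---------------------------------------------------------------------------
# frame-level orchestration
# ---------------------------------------------------------------------------

def run_vip_selection(expr: pd.DataFrame, pheno: pd.Series,
                      annotation: pd.Series | None = None, *,
                      h: int | None = None, h_max: int = 8, n_folds: int = 3,
                      n_perm: int = 200, fdr_threshold: float = 0.01,
                      fdr_method: str = "pooled", scale_columns: bool = True,
                      seed: int = 0) -> tuple[pd.DataFrame, CvCurve | None, PLSNipals]:
    """End-to-end probe selection on a probes x samples frame.

    Returns (results table, CV curve or None, fitted model). Samples are
    processed in canonical sorted-id order so the output is invariant to
    input column order.
    """
    order = sorted(expr.columns)
    expr_c = expr[order]
    pheno_c = pheno.reindex(order)

    curve: CvCurve | None = None
    if h is None:
        curve = choose_h_cv(expr_c, pheno_c, h_max=h_max, n_folds=n_folds,
                            seed=derive_seed(seed, 1),
                            scale_columns=scale_columns)
        h = curve.chosen_h
    data = standardize(expr_c, pheno_c, scale_columns=scale_columns)
    model = nipals_fit(data, h)
    vip_kept = compute_vip(model, data.y + data.y_mean)
    null, _ = _null_vip_matrix(data, h, n_perm, derive_seed(seed, 2))
    fdr_kept = pooled_fdr(vip_kept, null, method=fdr_method)
    idx = pd.Index(data.probe_ids, name="probe_id")
    table = select_genes(expr_c, pheno_c,
                         pd.Series(vip_kept, index=idx, name="vip"),
                         pd.Series(fdr_kept, index=idx, name="fdr"),
                         annotation=annotation, fdr_threshold=fdr_threshold)
    return table, curve, model
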