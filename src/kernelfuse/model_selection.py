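"""Hyperparameter selection by cross-validated AUC over a (sigma1, sigma2, gamma) grid.

The tuning algorithm for the weighted LS-SVM: for every combination of the
clinical-kernel bandwidth sigma1, the expression-kernel bandwidth sigma2 and
the regularization gamma, compute leave-one-out (or stratified p-fold)
held-out decision values on the training set, score the pooled held-out
values by AUC, and keep the combination with the highest cross-validated AUC.

Every fold is fully self-contained: gene standardization, the variance
filter, clinical schema ranges / z-scoring and kernel centering are all
recomputed on the fold's training part, so the held-out sample influences
nothing about the model that scores it.  Fold-level preprocessing and Gram
matrices are cached per fold (they do not depend on the grid point), which is
what makes a full-grid LOO affordable; the per-grid-point work is only the
bandwidth-dependent exponentials and one bordered linear solve per fold.

The same machinery tunes the single-view LS-SVMs (one bandwidth + gamma) and
the GEVD / kernel-GEVD score pipelines (bandwidths + the downstream LS-SVM
gamma, searched jointly).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import decision_lssvm, decision_weighted, fit_lssvm, fit_weighted_lssvm
from .dataio import MatrixBundle, VariableSchema, standardize, variance_filter
from .kernels import (
    KernelMatrix,
    KernelParams,
    center_kernel,
    clinical_kernel,
    median_pairwise_distance,
)
from .kgevd import fit_kernel_gevd, project_scores

logger = logging.getLogger("kernelfuse")

METHODS = ("cl_lssvm", "ma_lssvm", "gevd_lssvm", "kgevd_lssvm", "weighted_lssvm")


@dataclass(frozen=True)
class SearchGrid:
    """Cartesian hyperparameter grid and the cross-validation mode.

    ``cv`` is "loo" or a fold count p >= 2 (stratified p-fold).  Sigma lists
    may contain ``None`` where the method has no bandwidth in that slot (e.g.
    the mixed-type clinical kernel, or linear-kernel GEVD).
    """

    sigma1_values: tuple[float | None, ...]
    sigma2_values: tuple[float | None, ...]
    gamma_values: tuple[float, ...]
    cv: str | int = "loo"
    cv_seed: int = 0

    def __post_init__(self) -> None:
        for name, vals in (
            ("sigma1_values", self.sigma1_values),
            ("sigma2_values", self.sigma2_values),
            ("gamma_values", self.gamma_values),
        ):
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(v is not None and not v > 0 for v in vals):
                raise ValueError(f"{name} must be positive")
        if isinstance(self.cv, int) and self.cv < 2:
            raise ValueError("p-fold cv needs p >= 2")


@dataclass
class CVReport:
    """Full grid table of cross-validated AUCs and the selected combination."""

    table: pd.DataFrame  # columns sigma1, sigma2, gamma, cv_auc
    selected: dict  # {"sigma1":…, "sigma2":…, "gamma":…, "cv_auc":…}
    method: str
    cv: str | int = "loo"

    @property
    def best_auc(self) -> float:
        return float(self.selected["cv_auc"])


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # local import keeps module dependencies acyclic
    from .benchmark import auc

    return auc(scores, labels)


# ---------------------------------------------------------------------------
# fold construction with per-fold preprocessing
# ---------------------------------------------------------------------------

@dataclass
class _FoldView:
    """Gram matrices and squared norms of one preprocessed view in one fold."""

    G_tt: np.ndarray
    G_ht: np.ndarray
    sqn_tr: np.ndarray
    sqn_ho: np.ndarray

    def sqdist(self) -> tuple[np.ndarray, np.ndarray]:
        D_tt = np.maximum(self.sqn_tr[:, None] + self.sqn_tr[None, :] - 2.0 * self.G_tt, 0.0)
        D_ht = np.maximum(self.sqn_ho[:, None] + self.sqn_tr[None, :] - 2.0 * self.G_ht, 0.0)
        return D_tt, D_ht


@dataclass
class Fold:
    train_idx: np.ndarray
    heldout_idx: np.ndarray
    y_train: np.ndarray
    y_heldout: np.ndarray
    clin: _FoldView | None  # z-scored clinical (RBF/linear use)
    expr: _FoldView  # standardized + variance-filtered expression
    clin_kernel_tt: np.ndarray | None = None  # mixed-type clinical kernel
    clin_kernel_ht: np.ndarray | None = None


def _view_cache(X_tr: np.ndarray, X_ho: np.ndarray) -> _FoldView:
    return _FoldView(
        G_tt=X_tr @ X_tr.T,
        G_ht=X_ho @ X_tr.T,
        sqn_tr=np.einsum("ij,ij->i", X_tr, X_tr),
        sqn_ho=np.einsum("ij,ij->i", X_ho, X_ho),
    )


def _fold_assignments(y: np.ndarray, cv: str | int, seed: int) -> list[np.ndarray]:
    """Held-out index sets: singletons for LOO, stratified groups for p-fold."""
    n = y.shape[0]
    if cv == "loo":
        return [np.array([i]) for i in range(n)]
    p = int(cv)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    for cls in (-1, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(idx.size) % p
    return [np.flatnonzero(fold_of == f) for f in range(p)]


def build_folds(
    clinical: np.ndarray,
    expression: np.ndarray,
    schema: VariableSchema,
    y: np.ndarray,
    cv: str | int = "loo",
    cv_seed: int = 0,
    clinical_kernel_kind: str = "rbf",
    variance_percentile: float = 10.0,
) -> list[Fold]:
    """Build self-contained cross-validation folds from raw training views.

    All preprocessing (standardization, variance filter, schema ranges) is
    recomputed on each fold's training part.
    """
    clinical = np.asarray(clinical, dtype=float)
    expression = np.asarray(expression, dtype=float)
    y = np.asarray(y)
    n = y.shape[0]
    if n < 4:
        raise ValueError("cross-validation needs at least 4 samples")
    if len(set(np.unique(y).tolist())) < 2:
        raise ValueError("both classes must be present")
    folds: list[Fold] = []
    for ho in _fold_assignments(y, cv, cv_seed):
        tr = np.setdiff1d(np.arange(n), ho)
        y_tr, y_ho = y[tr], y[ho]
        if len(set(np.unique(y_tr).tolist())) < 2:
            logger.warning("fold skipped: training part lost one entire class")
            continue
        # expression: variance-filter on raw fold-train data, then standardize
        # (z-scoring first would flatten every gene variance to 1)
        e_tr = MatrixBundle(expression[tr], [f"g{j}" for j in range(expression.shape[1])],
                            [f"t{i}" for i in range(tr.size)], role="train")
        e_ho = MatrixBundle(expression[ho], e_tr.feature_ids,
                            [f"h{i}" for i in range(ho.size)], role="test")
        if variance_percentile > 0:
            e_tr, e_ho = variance_filter(e_tr, e_ho, percentile=variance_percentile)
        e_tr, e_ho, _ = standardize(e_tr, e_ho)
        fold = Fold(
            train_idx=tr,
            heldout_idx=ho,
            y_train=y_tr,
            y_heldout=y_ho,
            clin=None,
            expr=_view_cache(e_tr.values, e_ho.values),
        )
        if clinical_kernel_kind == "clinical":
            fitted = schema.fit_ranges(clinical[tr])
            fold.clin_kernel_tt = clinical_kernel(clinical[tr], clinical[tr], fitted).values
            fold.clin_kernel_ht = clinical_kernel(
                clinical[ho], clinical[tr], fitted, col_role="train"
            ).values
        else:
            c_tr = MatrixBundle(clinical[tr], list(schema.names),
                                [f"t{i}" for i in range(tr.size)], role="train")
            c_ho = MatrixBundle(clinical[ho], list(schema.names),
                                [f"h{i}" for i in range(ho.size)], role="test")
            c_tr, c_ho, _ = standardize(c_tr, c_ho)
            fold.clin = _view_cache(c_tr.values, c_ho.values)
        folds.append(fold)
    if not folds:
        raise ValueError("all folds degenerate (a class always lost)")
    return folds


def _fold_kernels(
    fold: Fold, view: str, sigma: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """Uncentered (train/train, heldout/train) kernel pair for one fold view."""
    if view == "clinical" and fold.clin_kernel_tt is not None:
        return fold.clin_kernel_tt, fold.clin_kernel_ht
    cache = fold.clin if view == "clinical" else fold.expr
    if sigma is None:  # linear kernel
        return cache.G_tt, cache.G_ht
    D_tt, D_ht = cache.sqdist()
    return np.exp(-D_tt / (2.0 * sigma**2)), np.exp(-D_ht / (2.0 * sigma**2))


def _center_pair(K_tt: np.ndarray, K_ht: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    col = K_tt.mean(axis=0)
    grand = K_tt.mean()
    Kc_tt = K_tt - col[None, :] - col[:, None] + grand
    Kc_ht = K_ht - K_ht.mean(axis=1, keepdims=True) - col[None, :] + grand
    return 0.5 * (Kc_tt + Kc_tt.T), Kc_ht


# ---------------------------------------------------------------------------
# per-method held-out score evaluation
# ---------------------------------------------------------------------------

def _heldout_weighted(
    folds: list[Fold], n: int, sigma1, sigma2, gammas
) -> dict[float, np.ndarray]:
    out = {g: np.full(n, np.nan) for g in gammas}
    for fold in folds:
        K1, K1h = _fold_kernels(fold, "clinical", sigma1)
        K2, K2h = _fold_kernels(fold, "expression", sigma2)
        K1c, K1hc = _center_pair(K1, K1h)
        K2c, K2hc = _center_pair(K2, K2h)
        for g in gammas:
            model = fit_weighted_lssvm(K1c, K2c, fold.y_train, g)
            out[g][fold.heldout_idx] = decision_weighted(model, K1hc, K2hc)
    return out


def _heldout_single_view(
    folds: list[Fold], n: int, view: str, sigma, gammas
) -> dict[float, np.ndarray]:
    out = {g: np.full(n, np.nan) for g in gammas}
    for fold in folds:
        K, Kh = _fold_kernels(fold, view, sigma)
        for g in gammas:
            model = fit_lssvm(K, fold.y_train, g)
            out[g][fold.heldout_idx] = decision_lssvm(model, Kh)
    return out


def _heldout_kgevd(
    folds: list[Fold], n: int, sigma1, sigma2, gammas, n_components=None
) -> dict[float, np.ndarray]:
    out = {g: np.full(n, np.nan) for g in gammas}
    for fold in folds:
        K1, K1h = _fold_kernels(fold, "clinical", sigma1)
        K2, K2h = _fold_kernels(fold, "expression", sigma2)
        K1c, K1hc = _center_pair(K1, K1h)
        K2c, _ = _center_pair(K2, K2h)
        model = fit_kernel_gevd(K1c, K2c, k=n_components)
        S_tr = project_scores(model, K1c)
        S_ho = project_scores(model, K1hc)
        G_tr = S_tr @ S_tr.T
        G_ho = S_ho @ S_tr.T
        for g in gammas:
            clf = fit_lssvm(G_tr, fold.y_train, g)
            out[g][fold.heldout_idx] = decision_lssvm(clf, G_ho)
    return out


def _sigma_pairs(method: str, grid: SearchGrid):
    if method in ("weighted_lssvm", "kgevd_lssvm"):
        return list(itertools.product(grid.sigma1_values, grid.sigma2_values))
    if method == "cl_lssvm":
        return [(s1, None) for s1 in grid.sigma1_values]
    if method == "ma_lssvm":
        return [(None, s2) for s2 in grid.sigma2_values]
    if method == "gevd_lssvm":
        return [(None, None)]
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def loo_scores(
    clinical: np.ndarray,
    expression: np.ndarray,
    schema: VariableSchema,
    y: np.ndarray,
    sigma1: float | None,
    sigma2: float | None,
    gamma: float,
    method: str = "weighted_lssvm",
    cv: str | int = "loo",
    cv_seed: int = 0,
    clinical_kernel_kind: str = "rbf",
    variance_percentile: float = 10.0,
    folds: list[Fold] | None = None,
) -> np.ndarray:
    """Held-out decision values, one per sample, in original sample order.

    For each fold the remaining samples are re-preprocessed and re-kernelized
    from scratch, the model is fitted at (sigma1, sigma2, gamma), and the
    held-out samples are scored through the fold's centered cross kernels.
    Samples of skipped degenerate folds are NaN.
    """
    y = np.asarray(y)
    n = y.shape[0]
    if folds is None:
        folds = build_folds(
            clinical, expression, schema, y, cv=cv, cv_seed=cv_seed,
            clinical_kernel_kind=clinical_kernel_kind,
            variance_percentile=variance_percentile,
        )
    if method == "weighted_lssvm":
        return _heldout_weighted(folds, n, sigma1, sigma2, [gamma])[gamma]
    if method == "cl_lssvm":
        return _heldout_single_view(folds, n, "clinical", sigma1, [gamma])[gamma]
    if method == "ma_lssvm":
        return _heldout_single_view(folds, n, "expression", sigma2, [gamma])[gamma]
    if method in ("kgevd_lssvm", "gevd_lssvm"):
        return _heldout_kgevd(folds, n, sigma1, sigma2, [gamma])[gamma]
    raise ValueError(f"unknown method {method!r}")


def grid_search(
    clinical: np.ndarray,
    expression: np.ndarray,
    schema: VariableSchema,
    y: np.ndarray,
    grid: SearchGrid,
    method: str = "weighted_lssvm",
    clinical_kernel_kind: str = "rbf",
    variance_percentile: float = 10.0,
    folds: list[Fold] | None = None,
) -> CVReport:
    """Cross-validated AUC for every grid combination; deterministic selection.

    The selected row attains the maximal cv AUC; ties are broken toward the
    smallest gamma, then the largest sigma1, then the largest sigma2 (prefer
    smoother, more regularized models).
    """
    y = np.asarray(y)
    n = y.shape[0]
    if folds is None:
        folds = build_folds(
            clinical, expression, schema, y, cv=grid.cv, cv_seed=grid.cv_seed,
            clinical_kernel_kind=clinical_kernel_kind,
            variance_percentile=variance_percentile,
        )
    rows = []
    for s1, s2 in _sigma_pairs(method, grid):
        if method == "weighted_lssvm":
            scores = _heldout_weighted(folds, n, s1, s2, grid.gamma_values)
        elif method == "cl_lssvm":
            scores = _heldout_single_view(folds, n, "clinical", s1, grid.gamma_values)
        elif method == "ma_lssvm":
            scores = _heldout_single_view(folds, n, "expression", s2, grid.gamma_values)
        else:  # gevd_lssvm / kgevd_lssvm
            scores = _heldout_kgevd(folds, n, s1, s2, grid.gamma_values)
        for g in grid.gamma_values:
            sc = scores[g]
            ok = np.isfinite(sc)
            rows.append(
                {
                    "sigma1": s1,
                    "sigma2": s2,
                    "gamma": g,
                    "cv_auc": _auc(sc[ok], y[ok]),
                }
            )
    table = pd.DataFrame(rows)
    best = table["cv_auc"].max()
    cand = table[table["cv_auc"] >= best].copy()
    cand["_s1"] = cand["sigma1"].astype(float).fillna(0.0)
    cand["_s2"] = cand["sigma2"].astype(float).fillna(0.0)
    cand = cand.sort_values(
        by=["gamma", "_s1", "_s2"], ascending=[True, False, False], kind="mergesort"
    )
    sel = cand.iloc[0]
    selected = {
        "sigma1": None if pd.isna(sel["sigma1"]) else float(sel["sigma1"]),
        "sigma2": None if pd.isna(sel["sigma2"]) else float(sel["sigma2"]),
        "gamma": float(sel["gamma"]),
        "cv_auc": float(sel["cv_auc"]),
    }
    return CVReport(table=table, selected=selected, method=method, cv=grid.cv)


def default_grid(
    clinical: np.ndarray,
    expression: np.ndarray,
    schema: VariableSchema,
    clinical_kernel_kind: str = "rbf",
    gamma_values: tuple[float, ...] | None = None,
    sigma_multipliers: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0),
    cv: str | int = "loo",
    cv_seed: int = 0,
    variance_percentile: float = 10.0,
) -> SearchGrid:
    """Bandwidths at multiples of each view's median pairwise distance; gammas 2^-10..2^10.

    Views are preprocessed (z-scoring / standardization + variance filter on
    the data handed in, which should be the training slice) before the median
    distance is measured.
    """
    if gamma_values is None:
        gamma_values = tuple(2.0**k for k in range(-10, 11, 2))
    expr = MatrixBundle(
        np.asarray(expression, dtype=float),
        [f"g{j}" for j in range(expression.shape[1])],
        [f"s{i}" for i in range(expression.shape[0])],
    )
    if variance_percentile > 0:
        expr, _ = variance_filter(expr, percentile=variance_percentile)
    expr, _, _ = standardize(expr)
    med2 = median_pairwise_distance(expr.values)
    sigma2 = tuple(m * med2 for m in sigma_multipliers)
    if clinical_kernel_kind == "clinical":
        sigma1: tuple[float | None, ...] = (None,)
    else:
        clin = MatrixBundle(
            np.asarray(clinical, dtype=float),
            list(schema.names),
            [f"s{i}" for i in range(clinical.shape[0])],
        )
        clin, _, _ = standardize(clin)
        med1 = median_pairwise_distance(clin.values)
        sigma1 = tuple(m * med1 for m in sigma_multipliers)
    return SearchGrid(
        sigma1_values=sigma1, sigma2_values=sigma2, gamma_values=tuple(gamma_values),
        cv=cv, cv_seed=cv_seed,
    )
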