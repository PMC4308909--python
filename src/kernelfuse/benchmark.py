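"""Repeated stratified-holdout benchmark with paired Wilcoxon comparisons.

Protocol: in each repetition, 2/3 of each class is assigned at random to the
training set and the rest to the test set (stratified, so class proportions
are preserved); the same split is shared by every method within a
repetition.  Each method preprocesses with training statistics only, tunes
its hyperparameters by cross-validated AUC on the training set alone, is
refitted at the selected parameters, and is scored by test AUC on its
continuous decision values.  Per-repetition AUCs are summarized as mean(std)
per method, and each method is compared against the weighted LS-SVM with a
two-sided paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .classifiers import decision_lssvm, decision_weighted, fit_lssvm, fit_weighted_lssvm
from .dataio import MatrixBundle, VariableSchema, drop_missing, standardize, variance_filter
from .kernels import center_kernel, clinical_kernel, linear_kernel, rbf_kernel
from .kgevd import kgevd_lssvm
from .model_selection import (
    METHODS,
    SearchGrid,
    build_folds,
    default_grid,
    grid_search,
)
from .synthetic import TwoViewDataset

logger = logging.getLogger("kernelfuse")

REFERENCE_METHOD = "weighted_lssvm"


# ---------------------------------------------------------------------------
# statistics layer
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney form: P(score+ > score-), ties 0.5."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    pos = labels == 1
    neg = labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = scipy.stats.rankdata(scores)  # midranks handle ties exactly
    r_pos = ranks[pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class SplitPlan:
    """One stratified train/test partition."""

    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        inter = np.intersect1d(self.train_idx, self.test_idx)
        if inter.size:
            raise ValueError("train and test indices overlap")


def stratified_split(labels: np.ndarray, fraction: float = 2.0 / 3.0, seed: int = 0) -> SplitPlan:
    """Per class, assign round(fraction * n_class) samples to training at random."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (-1, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        n_train = int(np.rint(fraction * idx.size))
        if n_train < 1 or n_train >= idx.size:
            raise ValueError(
                f"class {cls} too small to appear in both train and test at fraction {fraction}"
            )
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return SplitPlan(
        seed=seed,
        train_idx=np.sort(np.concatenate(train_parts)),
        test_idx=np.sort(np.concatenate(test_parts)),
    )


def _exact_signed_rank_p(ranks2: np.ndarray, w2_plus: int) -> float:
    """Two-sided exact p over all sign assignments, by rank-sum convolution.

    ``ranks2`` are doubled midranks (integers), ``w2_plus`` the doubled
    positive rank sum.  Counts the full distribution of W+ over the 2^n sign
    vectors with a dynamic program, then p = min(1, 2*min(P(W+<=w), P(W+>=w))).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n = ranks2.shape[0]
    denom = 2.0**n
    cdf = counts.cumsum()
    p_le = cdf[w2_plus] / denom
    p_ge = (denom - (cdf[w2_plus - 1] if w2_plus > 0 else 0.0)) / denom
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value for a vs b.

    Zero differences are dropped.  For n <= 25 remaining pairs the exact null
    distribution is computed by enumeration-equivalent convolution (midranks
    for ties); beyond that the normal approximation with tie correction is
    used.  If every difference is zero, p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p-value is 1", stacklevel=2)
        return 1.0
    if d.size < 5:
        raise ValueError("need >= 5 non-zero paired differences")
    ranks = scipy.stats.rankdata(np.abs(d))
    if d.size <= 25:
        ranks2 = np.rint(2.0 * ranks).astype(int)  # doubled midranks are integers
        w2_plus = int(np.rint((ranks2[d > 0]).sum()))
        return _exact_signed_rank_p(ranks2, w2_plus)
    res = scipy.stats.wilcoxon(d, zero_method="wilcox", correction=False, method="approx")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# per-method fit/score at chosen hyperparameters
# ---------------------------------------------------------------------------

@dataclass
class _PreppedSplit:
    """Training-statistics-preprocessed views for one repetition."""

    Xc_tr: np.ndarray  # z-scored clinical (train stats)
    Xc_te: np.ndarray
    Xe_tr: np.ndarray  # standardized + variance-filtered expression
    Xe_te: np.ndarray
    Kc_tt: np.ndarray | None  # mixed-type clinical kernel, if requested
    Kc_te: np.ndarray | None
    y_tr: np.ndarray
    y_te: np.ndarray


def _prepare_split(
    dataset: TwoViewDataset,
    plan: SplitPlan,
    clinical_kernel_kind: str,
    variance_percentile: float,
) -> _PreppedSplit:
    tr, te = plan.train_idx, plan.test_idx
    e_tr = MatrixBundle(dataset.expression[tr], list(dataset.gene_ids),
                        [dataset.sample_ids[i] for i in tr], role="train")
    e_te = MatrixBundle(dataset.expression[te], list(dataset.gene_ids),
                        [dataset.sample_ids[i] for i in te], role="test")
    if variance_percentile > 0:  # filter on raw variances, then standardize
        e_tr, e_te = variance_filter(e_tr, e_te, percentile=variance_percentile)
    e_tr, e_te, _ = standardize(e_tr, e_te)
    c_tr = MatrixBundle(dataset.clinical[tr], dataset.schema.names,
                        [dataset.sample_ids[i] for i in tr], role="train")
    c_te = MatrixBundle(dataset.clinical[te], dataset.schema.names,
                        [dataset.sample_ids[i] for i in te], role="test")
    c_tr_z, c_te_z, _ = standardize(c_tr, c_te)
    Kc_tt = Kc_te = None
    if clinical_kernel_kind == "clinical":
        fitted = dataset.schema.fit_ranges(dataset.clinical[tr])
        Kc_tt = clinical_kernel(dataset.clinical[tr], dataset.clinical[tr], fitted).values
        Kc_te = clinical_kernel(dataset.clinical[te], dataset.clinical[tr], fitted).values
    return _PreppedSplit(
        Xc_tr=c_tr_z.values, Xc_te=c_te_z.values,
        Xe_tr=e_tr.values, Xe_te=e_te.values,
        Kc_tt=Kc_tt, Kc_te=Kc_te,
        y_tr=dataset.labels[tr], y_te=dataset.labels[te],
    )


def _clinical_kernels(prep: _PreppedSplit, sigma1):
    if prep.Kc_tt is not None:
        return prep.Kc_tt, prep.Kc_te
    if sigma1 is None:
        return (linear_kernel(prep.Xc_tr, prep.Xc_tr).values,
                linear_kernel(prep.Xc_te, prep.Xc_tr).values)
    return (rbf_kernel(prep.Xc_tr, prep.Xc_tr, sigma1).values,
            rbf_kernel(prep.Xc_te, prep.Xc_tr, sigma1).values)


def _expression_kernels(prep: _PreppedSplit, sigma2):
    if sigma2 is None:
        return (linear_kernel(prep.Xe_tr, prep.Xe_tr).values,
                linear_kernel(prep.Xe_te, prep.Xe_tr).values)
    return (rbf_kernel(prep.Xe_tr, prep.Xe_tr, sigma2).values,
            rbf_kernel(prep.Xe_te, prep.Xe_tr, sigma2).values)


def _center_pair_arrays(K_tt, K_te):
    col = K_tt.mean(axis=0)
    grand = K_tt.mean()
    Kc = K_tt - col[None, :] - col[:, None] + grand
    Kx = K_te - K_te.mean(axis=1, keepdims=True) - col[None, :] + grand
    return 0.5 * (Kc + Kc.T), Kx


def _fit_score(method: str, prep: _PreppedSplit, params: dict) -> np.ndarray:
    """Fit one method at chosen hyperparameters and score the test samples."""
    s1, s2, g = params.get("sigma1"), params.get("sigma2"), params["gamma"]
    if method == "cl_lssvm":
        K, Kte = _clinical_kernels(prep, s1)
        model = fit_lssvm(K, prep.y_tr, g)
        return decision_lssvm(model, Kte)
    if method == "ma_lssvm":
        K, Kte = _expression_kernels(prep, s2)
        model = fit_lssvm(K, prep.y_tr, g)
        return decision_lssvm(model, Kte)
    if method == "weighted_lssvm":
        K1, K1te = _clinical_kernels(prep, s1)
        K2, K2te = _expression_kernels(prep, s2)
        K1c, K1tec = _center_pair_arrays(K1, K1te)
        K2c, K2tec = _center_pair_arrays(K2, K2te)
        model = fit_weighted_lssvm(K1c, K2c, prep.y_tr, g)
        return decision_weighted(model, K1tec, K2tec)
    if method in ("gevd_lssvm", "kgevd_lssvm"):
        kind = "linear" if method == "gevd_lssvm" else "rbf"
        test_scores, _ = kgevd_lssvm(
            prep.Xc_tr, prep.Xe_tr, prep.Xc_te, prep.Xe_te, prep.y_tr,
            sigma1=s1, sigma2=s2, gamma_lssvm=g, kernel_kind=kind,
        )
        return test_scores
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """Per-repetition test AUCs with summary statistics and paired p-values."""

    auc_table: pd.DataFrame  # repetitions x methods
    split_seeds: list[int]
    selected_params: list[dict]  # per repetition: method -> chosen params
    reference: str = REFERENCE_METHOD

    @property
    def mean(self) -> pd.Series:
        return self.auc_table.mean(axis=0)

    @property
    def std(self) -> pd.Series:
        return self.auc_table.std(axis=0, ddof=1)

    def wilcoxon_vs_reference(self) -> pd.Series:
        """Paired two-sided Wilcoxon p of each method against the reference."""
        if self.auc_table.shape[0] < 2 or self.reference not in self.auc_table:
            return pd.Series(dtype=float)
        ref = self.auc_table[self.reference].to_numpy()
        out = {}
        for m in self.auc_table.columns:
            if m == self.reference:
                continue
            try:
                out[m] = wilcoxon_signed_rank(self.auc_table[m].to_numpy(), ref)
            except ValueError:  # too few non-zero paired differences
                out[m] = np.nan
        return pd.Series(out)

    def summary(self) -> pd.DataFrame:
        pvals = self.wilcoxon_vs_reference()
        return pd.DataFrame(
            {
                "mean_auc": self.mean,
                "std_auc": self.std,
                "p_vs_reference": pvals.reindex(self.auc_table.columns),
            }
        )


def run_benchmark(
    dataset: TwoViewDataset,
    methods: tuple[str, ...] = METHODS,
    n_reps: int = 100,
    seeds: list[int] | None = None,
    grid: SearchGrid | None = None,
    train_fraction: float = 2.0 / 3.0,
    clinical_kernel_kind: str = "rbf",
    variance_percentile: float = 10.0,
    cv: str | int = "loo",
    sigma_multipliers: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0),
    gamma_values: tuple[float, ...] | None = None,
    permute_labels_seed: int | None = None,
    max_failure_fraction: float = 0.1,
) -> BenchmarkResult:
    """Run the repeated stratified-holdout comparison.

    One split per repetition (seeds default to 1..n_reps) is shared by all
    methods.  Unless an explicit ``grid`` is given, each repetition builds its
    bandwidth grid from the training slice (multiples of the median pairwise
    distance per view) and tunes by cross-validated AUC; tuning sees training
    samples only.  ``permute_labels_seed`` permutes the training labels of
    every repetition (null-calibration runs).
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; valid: {METHODS}")
    if seeds is None:
        seeds = list(range(1, n_reps + 1))
    if len(seeds) != n_reps:
        raise ValueError("need one split seed per repetition")
    if np.isnan(dataset.clinical).any():
        from .dataio import MatrixBundle as _MB

        clin = _MB(dataset.clinical, dataset.schema.names, dataset.sample_ids)
        expr = _MB(dataset.expression, dataset.gene_ids, dataset.sample_ids)
        clin, expr, labels = drop_missing(clin, expr, dataset.labels)
        dataset = TwoViewDataset(
            expression=expr.values, clinical=clin.values, schema=dataset.schema,
            labels=labels, sample_ids=clin.sample_ids, gene_ids=dataset.gene_ids,
        )
    perm_rng = (
        np.random.default_rng(permute_labels_seed) if permute_labels_seed is not None else None
    )
    rows: list[dict] = []
    chosen: list[dict] = []
    failures = {m: 0 for m in methods}
    for rep, seed in enumerate(seeds):
        plan = stratified_split(dataset.labels, fraction=train_fraction, seed=seed)
        tr = plan.train_idx
        y_tr = dataset.labels[tr].copy()
        labels_rep = dataset.labels
        if perm_rng is not None:
            y_tr = perm_rng.permutation(y_tr)
            labels_rep = dataset.labels.copy()
            labels_rep[tr] = y_tr
        ds_rep = dataset
        if perm_rng is not None:
            ds_rep = TwoViewDataset(
                expression=dataset.expression, clinical=dataset.clinical,
                schema=dataset.schema, labels=labels_rep,
                sample_ids=dataset.sample_ids, gene_ids=dataset.gene_ids,
            )
        prep = _prepare_split(ds_rep, plan, clinical_kernel_kind, variance_percentile)
        rep_grid = grid
        if rep_grid is None:
            rep_grid = default_grid(
                ds_rep.clinical[tr], ds_rep.expression[tr], ds_rep.schema,
                clinical_kernel_kind=clinical_kernel_kind,
                gamma_values=gamma_values, sigma_multipliers=sigma_multipliers,
                cv=cv, cv_seed=seed, variance_percentile=variance_percentile,
            )
        folds = build_folds(
            ds_rep.clinical[tr], ds_rep.expression[tr], ds_rep.schema, y_tr,
            cv=rep_grid.cv, cv_seed=rep_grid.cv_seed,
            clinical_kernel_kind=clinical_kernel_kind,
            variance_percentile=variance_percentile,
        )
        row: dict = {}
        params_row: dict = {}
        for method in methods:
            try:
                report = grid_search(
                    ds_rep.clinical[tr], ds_rep.expression[tr], ds_rep.schema, y_tr,
                    rep_grid, method=method,
                    clinical_kernel_kind=clinical_kernel_kind,
                    variance_percentile=variance_percentile, folds=folds,
                )
                scores = _fit_score(method, prep, report.selected)
                row[method] = auc(scores, prep.y_te)
                params_row[method] = report.selected
            except (np.linalg.LinAlgError, ValueError) as err:
                failures[method] += 1
                logger.warning("repetition %d: method %s failed: %s", rep, method, err)
                if failures[method] > max_failure_fraction * n_reps:
                    raise RuntimeError(
                        f"method {method} failed on more than "
                        f"{max_failure_fraction:.0%} of repetitions; last error: {err}"
                    ) from err
                row[method] = np.nan
                params_row[method] = None
        rows.append(row)
        chosen.append(params_row)
    table = pd.DataFrame(rows, columns=list(methods))
    return BenchmarkResult(auc_table=table, split_seeds=list(seeds), selected_params=chosen)


def plot_benchmark(result: BenchmarkResult, path: str) -> None:
    """Boxplots of per-repetition test AUCs, one box per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.8 * len(result.auc_table.columns) + 1, 4))
    result.auc_table.boxplot(ax=ax, grid=False)
    ax.set_ylabel("test AUC")
    ax.set_ylim(0, 1.05)
    fig.autofmt_xdate(rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
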