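"""Kernel functions and feature-space centering for the two data views.

Three kernels are provided:

* ``rbf_kernel`` — Gaussian kernel K(x,z) = exp(-||x-z||^2 / (2 sigma^2)),
  the default for both expression and clinical views;
* ``linear_kernel`` — plain inner products, used for the linear GEVD variant
  and for classifiers on projected scores;
* ``clinical_kernel`` — a mixed-type patient similarity that averages
  per-variable scores: range-normalized agreement for continuous and ordinal
  variables, exact match for nominal ones.  Ranges come from the training
  schema so test patients are scored against training statistics.

``center_kernel`` implements feature-space centering of a Gram matrix: for a
training kernel K, the centered matrix is

    Kc_ij = K_ij - mean_r K_ir - mean_r K_jr + mean_rs K_rs,

and a test-vs-train cross kernel is centered with the training column means
and training grand mean only, which is the transformation induced by
subtracting the training feature-space mean from every mapped point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .dataio import VariableSchema

logger = logging.getLogger("kernelfuse")


@dataclass(frozen=True)
class KernelParams:
    kind: str  # rbf | linear | clinical
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "linear", "clinical"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rbf":
            if self.bandwidth is None or not self.bandwidth > 0:
                raise ValueError("rbf kernel requires a positive bandwidth")


@dataclass(frozen=True)
class CenteringStats:
    """Training column means and grand mean used to center cross kernels."""

    col_means: np.ndarray
    grand_mean: float

    def fingerprint(self) -> tuple[int, float, float]:
        return (self.col_means.shape[0], float(self.col_means.sum()), self.grand_mean)


@dataclass
class KernelMatrix:
    """A (possibly centered) Gram matrix with provenance."""

    values: np.ndarray
    view_tag: str = ""
    params: KernelParams | None = None
    centered: bool = False
    row_role: str = "train"
    col_role: str = "train"
    centering: CenteringStats | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("kernel values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kernel matrix contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def is_square_train(self) -> bool:
        return (
            self.row_role == "train"
            and self.col_role == "train"
            and self.values.shape[0] == self.values.shape[1]
        )


def _symmetrize(K: np.ndarray) -> np.ndarray:
    return 0.5 * (K + K.T)


def rbf_kernel(
    X: np.ndarray, Z: np.ndarray, sigma: float, view_tag: str = "", col_role: str = "train"
) -> KernelMatrix:
    """Gaussian kernel matrix K_ij = exp(-||x_i - z_j||^2 / (2 sigma^2))."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"feature dimensions differ: {X.shape[1]} vs {Z.shape[1]}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Z))):
        raise ValueError("rbf_kernel requires finite inputs")
    D2 = cdist(X, Z, metric="sqeuclidean")
    K = np.exp(-D2 / (2.0 * sigma**2))
    same = X is Z or (X.shape == Z.shape and np.array_equal(X, Z))
    if same:
        K = _symmetrize(K)
    return KernelMatrix(
        values=K,
        view_tag=view_tag,
        params=KernelParams("rbf", bandwidth=float(sigma)),
        row_role="train" if same and col_role == "train" else ("test" if not same else "train"),
        col_role=col_role,
    )


def linear_kernel(X: np.ndarray, Z: np.ndarray, view_tag: str = "", col_role: str = "train") -> KernelMatrix:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"feature dimensions differ: {X.shape[1]} vs {Z.shape[1]}")
    K = X @ Z.T
    same = X is Z or (X.shape == Z.shape and np.array_equal(X, Z))
    if same:
        K = _symmetrize(K)
    return KernelMatrix(
        values=K,
        view_tag=view_tag,
        params=KernelParams("linear"),
        row_role="train" if same and col_role == "train" else ("test" if not same else "train"),
        col_role=col_role,
    )


def clinical_kernel(
    X: np.ndarray, Z: np.ndarray, schema: VariableSchema, col_role: str = "train"
) -> KernelMatrix:
    """Mixed-type clinical similarity, averaged over variables.

    Per variable v the similarity of patients x, z is

    * continuous/ordinal: ``(range_v - |x_v - z_v|) / range_v`` clipped to
      [0, 1], with range_v = vmax - vmin observed on training data;
    * nominal: 1 if the categories match (and the category is known to the
      training schema), else 0.

    Variables with zero training range are excluded with a warning.  Ordinal
    variables use their level codes in the continuous formula, i.e. the
    intrinsic ordering is respected and level gaps are treated as equal.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != len(schema) or Z.shape[1] != len(schema):
        raise ValueError("matrix columns must match the schema variables")
    sims = []
    for j, v in enumerate(schema):
        x = X[:, j][:, None]
        z = Z[:, j][None, :]
        if v.kind == "nominal":
            if v.categories is None:
                raise ValueError(f"nominal variable {v.name!r} has no fitted categories")
            cats = np.asarray(v.categories)
            known_x = np.isin(X[:, j], cats)[:, None]
            known_z = np.isin(Z[:, j], cats)[None, :]
            sims.append((x == z) & known_x & known_z)
        else:
            if v.vmin is None or v.vmax is None:
                raise ValueError(f"variable {v.name!r} has no fitted training range")
            rng = v.vmax - v.vmin
            if rng <= 0:
                logger.warning(
                    "clinical_kernel: variable %r has zero training range; excluded", v.name
                )
                continue
            sims.append(np.clip((rng - np.abs(x - z)) / rng, 0.0, 1.0))
    if not sims:
        raise ValueError("no usable clinical variables (all zero-range)")
    K = np.mean([s.astype(float) for s in sims], axis=0)
    same = X.shape == Z.shape and np.array_equal(X, Z)
    if same:
        K = _symmetrize(K)
        K = _ensure_psd(K)
    return KernelMatrix(
        values=K,
        view_tag="clinical",
        params=KernelParams("clinical"),
        row_role="train" if same and col_role == "train" else ("test" if not same else "train"),
        col_role=col_role,
    )


def _ensure_psd(K: np.ndarray, rel_floor: float = 1e-8) -> np.ndarray:
    """Add a minimal diagonal jitter if the smallest eigenvalue is materially negative.

    The mixed-type clinical similarity is PSD in practice but carries no
    general proof; this guard keeps downstream Cholesky/eigen solvers stable.
    """
    n = K.shape[0]
    w_min = float(np.linalg.eigvalsh(K)[0])
    floor = -rel_floor * max(np.trace(K), 1.0) / n
    if w_min < floor:
        logger.warning(
            "clinical kernel not PSD (min eigenvalue %.3e); adding jitter", w_min
        )
        K = K + (-w_min + 1e-12) * np.eye(n)
    return K


def export_kernel_tsv(K: KernelMatrix, path, row_ids=None, col_ids=None) -> None:
    """Write a kernel matrix as a headered TSV (debugging aid)."""
    import pandas as pd

    n, m = K.values.shape
    df = pd.DataFrame(
        K.values,
        index=row_ids or [f"r{i}" for i in range(n)],
        columns=col_ids or [f"c{j}" for j in range(m)],
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def median_pairwise_distance(X: np.ndarray) -> float:
    """Median Euclidean inter-point distance — the usual RBF bandwidth scale."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = cdist(X, X)
    iu = np.triu_indices_from(D, k=1)
    med = float(np.median(D[iu]))
    if not med > 0:
        med = 1.0
    return med


def center_kernel(K_train: KernelMatrix, K_cross: KernelMatrix | None = None) -> KernelMatrix:
    """Center a Gram matrix in feature space using training statistics.

    Without ``K_cross``: returns the centered training kernel
    ``Kc = K - rowmean - colmean + grandmean``.  With ``K_cross`` (test rows x
    train columns, same kernel parameters): returns the cross kernel centered
    with the TRAINING column means and grand mean, i.e.

        Kc(t, i) = K(t, i) - mean_r K(t, r) - mean_r Ktr(i, r) + grand(Ktr).
    """
    if not K_train.is_square_train:
        raise ValueError("K_train must be a square train/train kernel")
    K = K_train.values
    n = K.shape[0]
    col_means = K.mean(axis=0)
    grand = float(K.mean())
    stats = CenteringStats(col_means=col_means, grand_mean=grand)
    if K_cross is None:
        Kc = K - col_means[None, :] - col_means[:, None] + grand
        Kc = _symmetrize(Kc)
        return KernelMatrix(
            values=Kc,
            view_tag=K_train.view_tag,
            params=K_train.params,
            centered=True,
            row_role="train",
            col_role="train",
            centering=stats,
        )
    if K_cross.values.shape[1] != n:
        raise ValueError(
            f"K_cross has {K_cross.values.shape[1]} columns, training kernel has {n}"
        )
    if K_cross.params is not None and K_train.params is not None and K_cross.params != K_train.params:
        raise ValueError("K_cross was computed with different kernel parameters")
    Kx = K_cross.values
    row_means = Kx.mean(axis=1, keepdims=True)
    Kc = Kx - row_means - col_means[None, :] + grand
    return KernelMatrix(
        values=Kc,
        view_tag=K_cross.view_tag,
        params=K_cross.params,
        centered=True,
        row_role="test",
        col_role="train",
        centering=stats,
    )
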