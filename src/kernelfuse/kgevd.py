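"""Kernel GEVD in the dual and the score-projection classification pipeline.

The LS-SVM formulation of kernel GEVD leads, after eliminating the primal
variables, to a generalized eigenproblem on the two centered Gram matrices

    K1c alpha = lambda K2c alpha,

whose eigenvectors alpha are dual directions.  Patient scores are obtained by
projecting a centered clinical kernel onto those directions:

    scores = Kc @ directions        (rows: patients, columns: components)

— the training kernel gives training scores, the centered test-vs-train cross
kernel gives test scores.  ("Projecting the data onto the generalized
eigenvectors" is ambiguous in the primal once feature maps are implicit; the
kernel-times-eigenvector product is the reading that yields per-patient
scores for both training and unseen samples, and it reduces to the explicit
linear projection for linear kernels.)

The linear-GEVD pipeline is the special case of the same code path with
linear kernels on both (standardized) views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import linalg
from .classifiers import decision_lssvm, fit_lssvm
from .kernels import (
    CenteringStats,
    KernelMatrix,
    KernelParams,
    center_kernel,
    linear_kernel,
    rbf_kernel,
)


@dataclass
class KGEVDModel:
    """Top-k dual generalized eigenpairs of the pencil (K1c, K2c + jitter I)."""

    directions: np.ndarray  # N x k
    eigenvalues: np.ndarray  # descending, length k
    kernel1_params: KernelParams | None
    kernel2_params: KernelParams | None
    centering1: CenteringStats | None
    centering2: CenteringStats | None
    jitter_used: float

    @property
    def n_components(self) -> int:
        return self.directions.shape[1]

    @property
    def n_train(self) -> int:
        return self.directions.shape[0]


def fit_kernel_gevd(
    K1c: KernelMatrix | np.ndarray,
    K2c: KernelMatrix | np.ndarray,
    jitter: float | None = None,
    k: int | None = None,
) -> KGEVDModel:
    """Solve the dual kernel-GEVD pencil and retain the leading directions.

    ``k=None`` keeps every eigenvalue above ``1e-8 * max eigenvalue``;
    ``k=0`` is rejected explicitly.
    """
    K1 = K1c.values if isinstance(K1c, KernelMatrix) else np.asarray(K1c, dtype=float)
    K2 = K2c.values if isinstance(K2c, KernelMatrix) else np.asarray(K2c, dtype=float)
    if K1.shape != K2.shape or K1.shape[0] != K1.shape[1]:
        raise ValueError(f"kernels must be square and same size, got {K1.shape}, {K2.shape}")
    if k is not None and k <= 0:
        raise ValueError("number of components k must be a positive count")
    res = linalg.gevd(K1, K2, jitter=jitter)
    w = res.eigenvalues
    if k is None:
        lam_max = max(w.max(), 0.0)
        k_eff = int(np.sum(w > 1e-8 * lam_max))
        if k_eff == 0:
            raise ValueError("no generalized eigenvalue above threshold; pencil is degenerate")
    else:
        k_eff = min(k, w.shape[0])
    return KGEVDModel(
        directions=res.eigenvectors[:, :k_eff],
        eigenvalues=w[:k_eff],
        kernel1_params=K1c.params if isinstance(K1c, KernelMatrix) else None,
        kernel2_params=K2c.params if isinstance(K2c, KernelMatrix) else None,
        centering1=K1c.centering if isinstance(K1c, KernelMatrix) else None,
        centering2=K2c.centering if isinstance(K2c, KernelMatrix) else None,
        jitter_used=res.jitter_used,
    )


def project_scores(model: KGEVDModel, Kc: KernelMatrix | np.ndarray) -> np.ndarray:
    """Project a centered (rows x train) kernel onto the dual directions."""
    K = Kc.values if isinstance(Kc, KernelMatrix) else np.asarray(Kc, dtype=float)
    if K.ndim != 2 or K.shape[1] != model.n_train:
        raise ValueError(
            f"kernel has {K.shape[-1]} columns, model directions expect {model.n_train}"
        )
    return K @ model.directions


def export_scores_tsv(scores: np.ndarray, path, sample_ids=None) -> None:
    """Write a samples x components score matrix as TSV."""
    import pandas as pd

    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    df = pd.DataFrame(
        scores,
        index=sample_ids or [f"s{i}" for i in range(scores.shape[0])],
        columns=[f"component_{j + 1}" for j in range(scores.shape[1])],
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def kgevd_lssvm(
    train_clinical: np.ndarray,
    train_expression: np.ndarray,
    test_clinical: np.ndarray,
    test_expression: np.ndarray,
    y_train: np.ndarray,
    sigma1: float | None = None,
    sigma2: float | None = None,
    gamma_lssvm: float = 1.0,
    kernel_kind: str = "rbf",
    n_components: int | None = None,
    jitter: float | None = None,
    score_kernel: str = "linear",
) -> tuple[np.ndarray, np.ndarray]:
    """GEVD/kernel-GEVD score pipeline ending in an LS-SVM on the scores.

    ``kernel_kind="rbf"`` gives the kernel-GEVD variant (bandwidths sigma1 for
    the clinical view, sigma2 for the expression view); ``"linear"`` gives the
    plain GEVD variant.  Scores of training and test patients are obtained by
    projecting the centered clinical kernels onto the dual directions; an
    LS-SVM (linear kernel on scores by default, RBF behind ``score_kernel``)
    is then fitted on the training scores.

    Returns ``(test_scores, train_scores)`` of the downstream classifier.
    """
    if kernel_kind == "rbf":
        if sigma1 is None or sigma2 is None:
            raise ValueError("rbf kernel GEVD requires sigma1 and sigma2")
        K1 = rbf_kernel(train_clinical, train_clinical, sigma1, view_tag="clinical")
        K2 = rbf_kernel(train_expression, train_expression, sigma2, view_tag="expression")
        K1x = rbf_kernel(test_clinical, train_clinical, sigma1, view_tag="clinical")
    elif kernel_kind == "linear":
        K1 = linear_kernel(train_clinical, train_clinical, view_tag="clinical")
        K2 = linear_kernel(train_expression, train_expression, view_tag="expression")
        K1x = linear_kernel(test_clinical, train_clinical, view_tag="clinical")
    else:
        raise ValueError(f"unknown kernel kind {kernel_kind!r}")
    K1c = center_kernel(K1)
    K2c = center_kernel(K2)
    K1xc = center_kernel(K1, K1x)
    model = fit_kernel_gevd(K1c, K2c, jitter=jitter, k=n_components)
    S_train = project_scores(model, K1c)
    S_test = project_scores(model, K1xc)
    if score_kernel == "linear":
        Ktr = linear_kernel(S_train, S_train)
        Kte = linear_kernel(S_test, S_train)
    elif score_kernel == "rbf":
        from .kernels import median_pairwise_distance

        s = median_pairwise_distance(S_train)
        Ktr = rbf_kernel(S_train, S_train, s)
        Kte = rbf_kernel(S_test, S_train, s)
    else:
        raise ValueError(f"unknown score kernel {score_kernel!r}")
    clf = fit_lssvm(Ktr, y_train, gamma_lssvm)
    return decision_lssvm(clf, Kte), decision_lssvm(clf, Ktr)
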