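"""LS-SVM classifiers in the dual: the single-kernel baseline and the
two-kernel weighted variant.

Both models are exact solutions of a bordered symmetric linear system — the
KKT system of a least-squares SVM.  The baseline classifier solves

    [ 0   y^T          ] [ b    ]   [ 0   ]
    [ y   Omega + I/g  ] [ beta ] = [ 1_N ],    Omega_ij = y_i y_j K(x_i, x_j)

and scores a point x as  f(x) = sum_i beta_i y_i K(x, x_i) + b.

The weighted LS-SVM fuses two views by penalizing the residuals through the
second view's feature-space covariance; in the dual this leaves a system on
the two CENTERED kernel matrices with the labels as regression targets:

    [ 0    1_N^T                 ] [ b     ]   [ 0 ]
    [ 1_N  K1c + (1/g) K2c       ] [ alpha ] = [ y ],

scored as  f(x) = sum_i alpha_i [K1(x, x_i) + (1/g) K2(x, x_i)] + b.  Here
view 1 is the clinical kernel and view 2 the expression kernel acting as the
weighting matrix.  Note the kernel block is NOT label-weighted.

A formulation that places b inside the alpha-weighted sum is degenerate: the
alphas sum to zero (first block row), which would annihilate the bias.  The
standard LS-SVM placement — a single additive b, matching the bias row of
the linear system — is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .kernels import CenteringStats, KernelMatrix, KernelParams


def _solve_bordered(M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve the symmetric indefinite saddle system, with a condition check."""
    try:
        sol = scipy.linalg.solve(M, rhs, assume_a="sym")
    except scipy.linalg.LinAlgError as err:  # pragma: no cover - pathological
        raise np.linalg.LinAlgError(f"singular LS-SVM system: {err}") from err
    residual = np.linalg.norm(M @ sol - rhs)
    scale = np.linalg.norm(rhs) + np.linalg.norm(M) * np.linalg.norm(sol)
    if not np.isfinite(residual) or residual > 1e-6 * max(scale, 1.0):
        cond = np.linalg.cond(M)
        raise np.linalg.LinAlgError(
            f"LS-SVM system solve failed (residual {residual:.3e}, cond {cond:.3e}); "
            "the system is numerically singular — increase gamma or add kernel jitter"
        )
    return sol


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    vals = set(np.unique(y).tolist())
    if not vals <= {-1.0, 1.0}:
        raise ValueError(f"labels must be in {{-1,+1}}, got {sorted(vals)}")
    if len(vals) < 2:
        raise ValueError("both classes must be present")
    return y


@dataclass
class LSSVMModel:
    """Fitted single-kernel LS-SVM: dual coefficients, bias and provenance."""

    beta: np.ndarray
    b: float
    gamma: float
    kernel_params: KernelParams | None
    train_labels: np.ndarray

    @property
    def n_train(self) -> int:
        return self.beta.shape[0]


def fit_lssvm(K: KernelMatrix | np.ndarray, y: np.ndarray, gamma: float) -> LSSVMModel:
    """Fit the LS-SVM dual system on an (uncentered) training kernel."""
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    Kv = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    params = K.params if isinstance(K, KernelMatrix) else None
    y = _check_labels(y)
    n = y.shape[0]
    if Kv.shape != (n, n):
        raise ValueError(f"kernel shape {Kv.shape} does not match {n} labels")
    omega = (y[:, None] * y[None, :]) * Kv
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = y
    M[1:, 0] = y
    M[1:, 1:] = omega + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], np.ones(n)])
    sol = _solve_bordered(M, rhs)
    return LSSVMModel(
        beta=sol[1:], b=float(sol[0]), gamma=float(gamma), kernel_params=params, train_labels=y
    )


def decision_lssvm(model: LSSVMModel, K_test_train: KernelMatrix | np.ndarray) -> np.ndarray:
    """Continuous decision values f(x) = sum_i beta_i y_i K(x, x_i) + b."""
    Kv = (
        K_test_train.values
        if isinstance(K_test_train, KernelMatrix)
        else np.asarray(K_test_train, dtype=float)
    )
    if Kv.ndim != 2 or Kv.shape[1] != model.n_train:
        raise ValueError(
            f"test kernel has {Kv.shape[-1]} columns, model was trained on {model.n_train}"
        )
    return Kv @ (model.beta * model.train_labels) + model.b


@dataclass
class WeightedLSSVMModel:
    """Fitted two-kernel weighted LS-SVM (dual coefficients alpha, bias b)."""

    alpha: np.ndarray
    b: float
    gamma: float
    kernel1_params: KernelParams | None
    kernel2_params: KernelParams | None
    centering1: CenteringStats | None = None
    centering2: CenteringStats | None = None
    train_ids: list[str] | None = None

    @property
    def n_train(self) -> int:
        return self.alpha.shape[0]

    # -- JSON serialization --------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        def params_dict(p: KernelParams | None):
            return None if p is None else {"kind": p.kind, "bandwidth": p.bandwidth}

        def centering_dict(c: CenteringStats | None):
            return (
                None
                if c is None
                else {"col_means": c.col_means.tolist(), "grand_mean": c.grand_mean}
            )

        doc = json.dumps(
            {
                "alpha": self.alpha.tolist(),
                "b": self.b,
                "gamma": self.gamma,
                "kernel1_params": params_dict(self.kernel1_params),
                "kernel2_params": params_dict(self.kernel2_params),
                "centering1": centering_dict(self.centering1),
                "centering2": centering_dict(self.centering2),
                "train_ids": self.train_ids,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "WeightedLSSVMModel":
        text = Path(doc).read_text() if isinstance(doc, Path) else doc
        d = json.loads(text)

        def params(p):
            return None if p is None else KernelParams(p["kind"], p["bandwidth"])

        def centering(c):
            return (
                None
                if c is None
                else CenteringStats(np.asarray(c["col_means"]), c["grand_mean"])
            )

        return cls(
            alpha=np.asarray(d["alpha"], dtype=float),
            b=float(d["b"]),
            gamma=float(d["gamma"]),
            kernel1_params=params(d["kernel1_params"]),
            kernel2_params=params(d["kernel2_params"]),
            centering1=centering(d["centering1"]),
            centering2=centering(d["centering2"]),
            train_ids=d["train_ids"],
        )


def fit_weighted_lssvm(
    K1c: KernelMatrix | np.ndarray,
    K2c: KernelMatrix | np.ndarray,
    y: np.ndarray,
    gamma: float,
    train_ids: list[str] | None = None,
) -> WeightedLSSVMModel:
    """Fit the weighted LS-SVM on two centered training kernels.

    ``K1c`` is the clinical (primary) kernel, ``K2c`` the expression kernel
    whose feature-space covariance weights the residuals; both must be square,
    sample-aligned and centered with training statistics.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    K1 = K1c.values if isinstance(K1c, KernelMatrix) else np.asarray(K1c, dtype=float)
    K2 = K2c.values if isinstance(K2c, KernelMatrix) else np.asarray(K2c, dtype=float)
    for name, K in (("K1c", K1c), ("K2c", K2c)):
        if isinstance(K, KernelMatrix) and not K.centered:
            raise ValueError(f"{name} must be centered with training statistics")
    y = _check_labels(y)
    n = y.shape[0]
    if K1.shape != (n, n) or K2.shape != (n, n):
        raise ValueError("kernels must be square and match the number of labels")
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = 1.0
    M[1:, 0] = 1.0
    M[1:, 1:] = K1 + K2 / gamma
    rhs = np.concatenate([[0.0], y])
    sol = _solve_bordered(M, rhs)
    return WeightedLSSVMModel(
        alpha=sol[1:],
        b=float(sol[0]),
        gamma=float(gamma),
        kernel1_params=K1c.params if isinstance(K1c, KernelMatrix) else None,
        kernel2_params=K2c.params if isinstance(K2c, KernelMatrix) else None,
        centering1=K1c.centering if isinstance(K1c, KernelMatrix) else None,
        centering2=K2c.centering if isinstance(K2c, KernelMatrix) else None,
        train_ids=train_ids,
    )


def decision_weighted(
    model: WeightedLSSVMModel,
    K1_test: KernelMatrix | np.ndarray,
    K2_test: KernelMatrix | np.ndarray,
) -> np.ndarray:
    """Scores f(x) = sum_i alpha_i [K1(x,x_i) + (1/gamma) K2(x,x_i)] + b.

    Test kernels must be centered with the model's training statistics; when
    they carry centering metadata a fingerprint mismatch raises.
    """
    K1 = K1_test.values if isinstance(K1_test, KernelMatrix) else np.asarray(K1_test, dtype=float)
    K2 = K2_test.values if isinstance(K2_test, KernelMatrix) else np.asarray(K2_test, dtype=float)
    if K1.shape != K2.shape or K1.shape[1] != model.n_train:
        raise ValueError(
            f"test kernels must be aligned (rows x {model.n_train}); got {K1.shape} and {K2.shape}"
        )
    for K, own in ((K1_test, model.centering1), (K2_test, model.centering2)):
        if isinstance(K, KernelMatrix) and K.centering is not None and own is not None:
            if K.centering.fingerprint() != own.fingerprint():
                raise ValueError(
                    "test kernel was centered with statistics different from the model's "
                    "training centering"
                )
    return (K1 + K2 / model.gamma) @ model.alpha + model.b


def predict_labels(scores: np.ndarray) -> np.ndarray:
    """sign(score) with sign(0) mapped to +1."""
    return np.where(np.asarray(scores) >= 0, 1, -1)
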