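"""File formats, clinical variable schema, and train/test preprocessing.

Matrices travel as TSV/CSV with sample ids in the first column and feature
ids in the header.  Labels are {-1,+1} (a {0,1} file is mapped on read).
The clinical schema is a JSON document declaring, per variable, whether it is
continuous, ordinal or nominal; observed ranges / category sets are always
(re)computed from training data so that no test statistic leaks into the
mixed-type clinical kernel.

Preprocessing follows the usual leakage-safe protocol for expression data:
samples with missing clinical values are excluded from every view, each gene
is standardized with training mean/sd, and genes whose training variance
falls below a percentile threshold are removed from train and test alike.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("kernelfuse")

VARIABLE_KINDS = ("continuous", "ordinal", "nominal")


@dataclass(frozen=True)
class VariableDef:
    """One clinical variable: its name, measurement kind, and training range.

    ``vmin``/``vmax`` (continuous, ordinal) or ``categories`` (nominal) are
    populated from training data by :meth:`VariableSchema.fit_ranges`.
    """

    name: str
    kind: str
    n_levels: int | None = None
    vmin: float | None = None
    vmax: float | None = None
    categories: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name!r}")


@dataclass(frozen=True)
class VariableSchema:
    variables: tuple[VariableDef, ...]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate clinical variable names in schema")

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def fit_ranges(self, train_values: np.ndarray) -> "VariableSchema":
        """Return a schema with ranges/categories observed in training data."""
        X = np.asarray(train_values, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.variables):
            raise ValueError(
                f"training matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"schema has {len(self.variables)} variables"
            )
        fitted = []
        for j, v in enumerate(self.variables):
            col = X[:, j]
            col = col[np.isfinite(col)]
            if col.size == 0:
                raise ValueError(f"variable {v.name!r} has no observed training values")
            if v.kind == "nominal":
                fitted.append(replace(v, categories=tuple(sorted(set(col.tolist())))))
            else:
                fitted.append(replace(v, vmin=float(col.min()), vmax=float(col.max())))
        return VariableSchema(tuple(fitted))

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> list[dict]:
        out = []
        for v in self.variables:
            d: dict = {"name": v.name, "kind": v.kind}
            if v.n_levels is not None:
                d["n_levels"] = v.n_levels
            if v.vmin is not None:
                d["observed_range"] = [v.vmin, v.vmax]
            if v.categories is not None:
                d["categories"] = list(v.categories)
            out.append(d)
        return out

    @classmethod
    def from_dict(cls, entries: Sequence[dict]) -> "VariableSchema":
        defs = []
        for d in entries:
            rng = d.get("observed_range")
            defs.append(
                VariableDef(
                    name=d["name"],
                    kind=d["kind"],
                    n_levels=d.get("n_levels"),
                    vmin=None if rng is None else float(rng[0]),
                    vmax=None if rng is None else float(rng[1]),
                    categories=None
                    if d.get("categories") is None
                    else tuple(d["categories"]),
                )
            )
        return cls(tuple(defs))


def write_schema(schema: VariableSchema, path: str | Path) -> None:
    Path(path).write_text(json.dumps(schema.to_dict(), indent=2) + "\n")


def read_schema(path: str | Path) -> VariableSchema:
    return VariableSchema.from_dict(json.loads(Path(path).read_text()))


@dataclass
class MatrixBundle:
    """A samples x features matrix with ids and a train/test role tag."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    role: str = "train"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicated sample ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def take_samples(self, idx: np.ndarray) -> "MatrixBundle":
        idx = np.asarray(idx)
        return MatrixBundle(
            values=self.values[idx],
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx.tolist()],
            role=self.role,
        )

    def take_features(self, keep: np.ndarray) -> "MatrixBundle":
        keep = np.asarray(keep)
        return MatrixBundle(
            values=self.values[:, keep],
            feature_ids=[self.feature_ids[i] for i in keep.tolist()],
            sample_ids=list(self.sample_ids),
            role=self.role,
        )


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def write_matrix(bundle: MatrixBundle, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(bundle.values, index=bundle.sample_ids, columns=bundle.feature_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, na_rep="NA")


def read_matrix(path: str | Path, role: str = "train", sep: str | None = None) -> MatrixBundle:
    """Read a TSV/CSV matrix; empty fields and "NA" are treated as missing."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    return MatrixBundle(
        values=df.to_numpy(dtype=float),
        feature_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
        role=role,
    )


def write_labels(labels: np.ndarray, sample_ids: Sequence[str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "label": np.asarray(labels, dtype=int)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read labels; {0,1} coding is mapped to {-1,+1}."""
    df = pd.read_csv(path, sep="\t")
    y = df["label"].to_numpy(dtype=int)
    vals = set(np.unique(y).tolist())
    if vals <= {0, 1}:
        y = np.where(y == 1, 1, -1)
    elif not vals <= {-1, 1}:
        raise ValueError(f"labels must be coded {{-1,+1}} or {{0,1}}, got {sorted(vals)}")
    return y, [str(s) for s in df["sample_id"]]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def drop_missing(
    clinical: MatrixBundle, expression: MatrixBundle, labels: np.ndarray
) -> tuple[MatrixBundle, MatrixBundle, np.ndarray]:
    """Exclude every sample with at least one missing clinical value.

    The exclusion is applied to the clinical view, the expression view and the
    labels alike; sample order is otherwise preserved.
    """
    labels = np.asarray(labels)
    if clinical.n_samples != expression.n_samples or clinical.n_samples != labels.shape[0]:
        raise ValueError("clinical, expression and labels must be sample-aligned")
    keep = ~np.isnan(clinical.values).any(axis=1)
    if not keep.any():
        raise ValueError("all samples have missing clinical values")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("drop_missing: excluded %d of %d samples", n_dropped, keep.size)
    idx = np.flatnonzero(keep)
    return clinical.take_samples(idx), expression.take_samples(idx), labels[idx]


@dataclass(frozen=True)
class StandardizeStats:
    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # boolean mask over the input features


def standardize(
    train: MatrixBundle, test: MatrixBundle | None = None
) -> tuple[MatrixBundle, MatrixBundle | None, StandardizeStats]:
    """Zero-mean/unit-variance per feature, with statistics from training only.

    Zero-variance training features are dropped from both bundles with a
    logged warning.
    """
    if train.values.size == 0:
        raise ValueError("empty training matrix")
    if test is not None and test.feature_ids != train.feature_ids:
        raise ValueError("train and test bundles must share feature ids and order")
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0, ddof=1)
    # relative floor: numerically constant columns have sd at round-off level
    kept = sd > 1e-12 * (np.abs(mean) + 1.0)
    if not kept.all():
        logger.warning(
            "standardize: dropping %d zero-variance training features", int((~kept).sum())
        )
    if not kept.any():
        raise ValueError("all training features have zero variance")
    keep_idx = np.flatnonzero(kept)
    tr = train.take_features(keep_idx)
    tr.values = (tr.values - mean[kept]) / sd[kept]
    te = None
    if test is not None:
        te = test.take_features(keep_idx)
        te.values = (te.values - mean[kept]) / sd[kept]
    return tr, te, StandardizeStats(mean=mean[kept], sd=sd[kept], kept=kept)


def variance_filter(
    train: MatrixBundle, test: MatrixBundle | None = None, percentile: float = 10.0
) -> tuple[MatrixBundle, MatrixBundle | None]:
    """Remove features whose training variance is below the given percentile.

    The threshold is the linear-interpolation sample percentile of the
    training variances; features with variance >= threshold are kept (ties at
    the threshold survive).  The identical feature subset is applied to the
    test bundle.
    """
    if not 0 <= percentile < 100:
        raise ValueError("percentile must lie in [0, 100)")
    if test is not None and test.feature_ids != train.feature_ids:
        raise ValueError("train and test bundles must share feature ids and order")
    variances = train.values.var(axis=0, ddof=1)
    threshold = np.percentile(variances, percentile)
    keep = variances >= threshold
    if not keep.any():
        raise ValueError(f"variance filter at percentile {percentile} removed all features")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "variance_filter: removed %d of %d features below the %gth percentile",
            n_dropped,
            keep.size,
            percentile,
        )
    keep_idx = np.flatnonzero(keep)
    tr = train.take_features(keep_idx)
    te = test.take_features(keep_idx) if test is not None else None
    return tr, te
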