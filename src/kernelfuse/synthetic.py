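"""Synthetic two-view patient cohorts with controllable class signal.

The generator emulates the structure of breast-cancer prognosis cohorts in
which each patient carries a high-dimensional expression profile and a small
mixed-type clinical record with an imbalanced binary outcome:

* expression view — ``n_genes`` continuous features; the first
  ``n_informative_genes`` receive a between-class mean shift of
  ``effect_expression`` standard deviations (residual sd ``noise_sd``);
* clinical view — variables declared continuous, ordinal or nominal.
  Informative continuous variables get a mean shift of ``effect_clinical``
  (unit sd); ordinal variables discretize a shifted latent Gaussian into
  equal-probability levels, preserving the ordering; nominal variables draw
  from class-tilted category probabilities.
* missingness — entries of the clinical view are masked independently at
  ``missing_rate`` (expression is always complete), mirroring the fact that
  clinical records, not arrays, carry missing fields.

One integer seed drives a named root random stream; independent sub-streams
per concern (labels, expression, each clinical variable, missingness) are
spawned deterministically, so datasets are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .dataio import VariableDef, VariableSchema


@dataclass(frozen=True)
class ClinicalVariableSpec:
    name: str
    kind: str  # continuous | ordinal | nominal
    n_levels: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal", "nominal"):
            raise ValueError(f"unknown clinical variable kind {self.kind!r}")
        if self.kind in ("ordinal", "nominal"):
            if self.n_levels is None or self.n_levels < 2:
                raise ValueError(f"{self.kind} variable {self.name!r} needs n_levels >= 2")


DEFAULT_CLINICAL_SPEC: tuple[ClinicalVariableSpec, ...] = (
    ClinicalVariableSpec("age", "continuous"),
    ClinicalVariableSpec("tumor_size", "continuous"),
    ClinicalVariableSpec("tumor_grade", "ordinal", 3),
    ClinicalVariableSpec("nodal_status", "ordinal", 4),
    ClinicalVariableSpec("er_status", "nominal", 2),
    ClinicalVariableSpec("pr_status", "nominal", 2),
    ClinicalVariableSpec("histology", "nominal", 3),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic two-view cohort.

    Defaults mirror a mid-sized breast-cancer cohort: 150 patients, 2000
    genes, 7 mixed-type clinical variables, ~30% event rate, and moderate
    complementary signal in both views.
    """

    n_samples: int = 150
    n_genes: int = 2000
    clinical_spec: tuple[ClinicalVariableSpec, ...] = DEFAULT_CLINICAL_SPEC
    class_fraction: float = 0.3
    effect_expression: float = 0.7
    n_informative_genes: int = 40
    effect_clinical: float = 0.9
    n_informative_clinical: int = 4
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.class_fraction < 1:
            raise ValueError("class_fraction must lie in (0,1)")
        if self.n_informative_genes > self.n_genes:
            raise ValueError("n_informative_genes exceeds n_genes")
        if self.n_informative_clinical > len(self.clinical_spec):
            raise ValueError("n_informative_clinical exceeds the number of clinical variables")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0,1)")
        n_pos = int(np.rint(self.class_fraction * self.n_samples))
        if n_pos < 2 or self.n_samples - n_pos < 2:
            raise ValueError(
                f"degenerate config: class sizes ({n_pos}, {self.n_samples - n_pos}); "
                "each class needs at least 2 samples"
            )


@dataclass
class TwoViewDataset:
    """Paired expression and clinical matrices with labels and a schema."""

    expression: np.ndarray  # n_samples x n_genes
    clinical: np.ndarray  # n_samples x n_vars (float; integer codes for categories, NaN missing)
    schema: VariableSchema
    labels: np.ndarray  # {-1,+1}
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        n = self.expression.shape[0]
        if not (self.clinical.shape[0] == n == self.labels.shape[0] == len(self.sample_ids)):
            raise ValueError("views, labels and ids must share sample order and length")
        if set(np.unique(self.labels)) != {-1, 1}:
            raise ValueError("labels must contain both classes, coded -1/+1")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]


def _ordinal_cutpoints(n_levels: int) -> np.ndarray:
    """Equal-probability thresholds of a standard Gaussian."""
    return norm.ppf(np.arange(1, n_levels) / n_levels)


def generate_two_view(config: SyntheticConfig) -> TwoViewDataset:
    """Generate one reproducible two-view dataset under the given conditions."""
    n = config.n_samples
    root = np.random.SeedSequence(config.seed)
    n_streams = 3 + len(config.clinical_spec)
    streams = [np.random.default_rng(s) for s in root.spawn(n_streams)]
    rng_labels, rng_expr, rng_miss = streams[0], streams[1], streams[2]
    rng_clin = streams[3:]

    # labels: exactly round(class_fraction * n) positives, randomly placed
    n_pos = int(np.rint(config.class_fraction * n))
    labels = np.full(n, -1, dtype=int)
    labels[rng_labels.permutation(n)[:n_pos]] = 1
    pos = labels == 1

    # expression view: informative genes shifted by +-effect/2 * noise_sd
    X = rng_expr.normal(0.0, config.noise_sd, size=(n, config.n_genes))
    shift = 0.5 * config.effect_expression * config.noise_sd
    X[:, : config.n_informative_genes] += np.where(pos, shift, -shift)[:, None]

    # clinical view
    C = np.empty((n, len(config.clinical_spec)))
    for j, (spec, rng) in enumerate(zip(config.clinical_spec, rng_clin)):
        informative = j < config.n_informative_clinical
        eff = config.effect_clinical if informative else 0.0
        if spec.kind == "continuous":
            mu = np.where(pos, 0.5 * eff, -0.5 * eff)
            C[:, j] = rng.normal(mu, 1.0)
        elif spec.kind == "ordinal":
            latent = rng.normal(np.where(pos, 0.5 * eff, -0.5 * eff), 1.0)
            C[:, j] = np.searchsorted(_ordinal_cutpoints(spec.n_levels), latent)
        else:  # nominal: tilt one category up for positives, another for negatives
            L = spec.n_levels
            w_pos = np.ones(L)
            w_neg = np.ones(L)
            w_pos[0] += eff
            w_neg[1 % L] += eff
            p_pos = w_pos / w_pos.sum()
            p_neg = w_neg / w_neg.sum()
            u = rng.random(n)
            C[:, j] = np.where(
                pos,
                np.searchsorted(np.cumsum(p_pos), u, side="right"),
                np.searchsorted(np.cumsum(p_neg), u, side="right"),
            )

    if config.missing_rate > 0:
        mask = rng_miss.random(C.shape) < config.missing_rate
        C[mask] = np.nan

    schema = VariableSchema(
        tuple(
            VariableDef(name=s.name, kind=s.kind, n_levels=s.n_levels)
            for s in config.clinical_spec
        )
    )
    width = len(str(n))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    gene_ids = [f"g{j + 1}" for j in range(config.n_genes)]
    return TwoViewDataset(
        expression=X,
        clinical=C,
        schema=schema,
        labels=labels,
        sample_ids=sample_ids,
        gene_ids=gene_ids,
    )
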