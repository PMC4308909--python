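import numpy as np
import pytest

from kernelfuse import ClinicalVariableSpec, SyntheticConfig, generate_two_view


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-view cohort with signal in both views (session-cached)."""
    cfg = SyntheticConfig(
        n_samples=40,
        n_genes=60,
        class_fraction=0.4,
        effect_expression=1.2,
        n_informative_genes=15,
        effect_clinical=1.2,
        n_informative_clinical=3,
        seed=7,
    )
    return generate_two_view(cfg)


@pytest.fixture(scope="session")
def tiny_spec():
    return (
        ClinicalVariableSpec("age", "continuous"),
        ClinicalVariableSpec("grade", "ordinal", 3),
        ClinicalVariableSpec("er", "nominal", 2),
    )
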