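import numpy as np
import pytest

from igselect import LabelVector, SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def glioma_labels() -> LabelVector:
    """The 26 grade-III / 59 grade-IV cohort split."""
    return LabelVector(["III"] * 26 + ["IV"] * 59)


@pytest.fixture(scope="session")
def small_dataset():
    """Compact planted dataset: 20 nulls, one marginal gene, one XOR pair."""
    return simulate_dataset(
        SimulationSpec(n_per_class=30, m_null=20, marginal_genes=(2.0,), synergy_groups=(0.05,), seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
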