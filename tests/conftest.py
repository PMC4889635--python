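import numpy as np
import pytest

from ghqcat import (
    CATConfig,
    PopulationSpec,
    PrecisionTarget,
    builtin_ghq30,
    draw_thetas,
    sample_responses,
)


@pytest.fixture(scope="session")
def baseline_bank():
    return builtin_ghq30("baseline")


@pytest.fixture(scope="session")
def followup_bank():
    return builtin_ghq30("followup")


@pytest.fixture(scope="session")
def small_population(baseline_bank):
    """150 simulees with θ ~ N(0,1) and their full baseline response matrix."""
    thetas = draw_thetas(PopulationSpec(n=150, seed=42))
    responses = sample_responses(baseline_bank, thetas, seed=42)
    return thetas, responses


@pytest.fixture
def mle_config():
    return CATConfig(
        estimator="MLE",
        selector="UW-FI",
        precision=PrecisionTarget(marginal_reliability=0.80),
    )


def random_pattern(bank, rng, n_items=None):
    """A random (partial) response pattern on a bank."""
    n = n_items or rng.integers(1, len(bank) + 1)
    ids = rng.choice(bank.item_ids, size=n, replace=False)
    return {int(i): int(rng.integers(1, bank.n_categories + 1)) for i in ids}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
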