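import numpy as np
import pytest

from depstack import LexiconSet, ScenarioConfig, generate_feature_table


@pytest.fixture
def toy_lexicons():
    return LexiconSet(
        categories={
            "sad": frozenset({"难过", "伤心"}),
            "negation": frozenset({"不", "没有"}),
            "first_singular": frozenset({"我"}),
        }
    )


@pytest.fixture
def small_table():
    """60-user labeled table with the default planted signal (fast)."""
    return generate_feature_table(
        ScenarioConfig(n_depressed=20, n_control=40), seed=7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
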