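import numpy as np
import pandas as pd
import pytest

from narrsync import synthetic as syn


@pytest.fixture
def small_traits() -> pd.DataFrame:
    """Eight-subject cohort with a fixed, hand-checkable score vector."""
    scores = [16, 17, 18, 18, 19, 20, 38, 40]
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:02d}" for i in range(len(scores))],
            "trait_score": scores,
        }
    )
    table["trait_rank"] = table["trait_score"].rank(method="average")
    return table


@pytest.fixture
def cohort22() -> pd.DataFrame:
    return syn.gen_trait_scores(22, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
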