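import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from matchexplain.synthetic_cohort import (
    CategoricalCovariate,
    ContinuousCovariate,
    GeneratorConfig,
)


@pytest.fixture
def small_config():
    """Tiny two-covariate generator config with a known treatment model."""
    return GeneratorConfig(
        n=200,
        covariates=(
            ContinuousCovariate("age", lo=60, hi=90, mean=75, sd=6, integer=True),
            CategoricalCovariate(
                "site", levels=("a", "b", "c"), probabilities=(0.5, 0.3, 0.2)
            ),
        ),
        treatment_coefficients=(7.5, -0.1, 0.3, -0.2),
        seed=42,
    )


@pytest.fixture
def toy_match_instance():
    """Two treated (A=0.50, B=0.80) and three controls (0.48, 0.79, 0.10)."""
    scores = np.array([0.50, 0.80, 0.48, 0.79, 0.10])
    T = np.array([1, 1, 0, 0, 0])
    return scores, T


def make_stratified_cohort(n=400, seed=0, p_in_young=0.9, p_in_old=0.1,
                           threshold=80):
    """Cohort whose inclusion labels depend only on an age threshold."""
    rng = np.random.default_rng(seed)
    age = rng.integers(65, 95, size=n)
    noise_cat = rng.choice(["x", "y", "z"], size=n)
    noise_num = rng.normal(size=n)
    p = np.where(age <= threshold, p_in_young, p_in_old)
    labels = np.where(rng.random(n) < p, "in", "out")
    cohort = pd.DataFrame(
        {"age": age, "group": noise_cat, "marker": noise_num}
    )
    return cohort, labels
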