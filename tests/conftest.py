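import dataclasses

import numpy as np
import pytest

from devwild import HomogenizationParams, PipelineConfig, StudyWindow, SyntheticConfig
from devwild.trends import TrendParams


@pytest.fixture
def tiny_synth() -> SyntheticConfig:
    """Small synthetic panel sized for fast end-to-end tests."""
    return SyntheticConfig(
        n_countries=10,
        n_populations_per_country=6,
        n_indicators=3,
        indicator_mask_prob=0.0,
        n_regions=3,
        n_orders=6,
        seed=5,
    )


@pytest.fixture
def tiny_config(tiny_synth) -> PipelineConfig:
    return PipelineConfig(
        seed=17,
        synthetic=tiny_synth,
        homogenization=HomogenizationParams(min_populations_per_indicator=5),
        model={"n_chains": 2, "n_iter": 700, "n_burnin": 200},
    )


def linear_series(slope: float, n: int, start: int = 2000, intercept: float = 1.0):
    years = np.arange(start, start + n)
    return years, intercept + slope * (years - start)
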