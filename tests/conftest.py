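import numpy as np
import pytest

import stlcast as sc
from stlcast.residual_model import InformerConfig


@pytest.fixture(scope="session")
def small_series() -> sc.RegularSeries:
    """Three days of synthetic data at 10-minute sampling (432 samples)."""
    return sc.generate(sc.SyntheticSpec(n_samples=432, seed=7))


@pytest.fixture(scope="session")
def tiny_pipeline(small_series) -> sc.Pipeline:
    """A cheaply fitted pipeline for structural checks.

    The training budget is cut to a handful of steps — these tests check
    structure and additivity, not forecast quality.
    """
    cfg = sc.PipelineConfig(
        residual=InformerConfig.reduced(epochs=1, steps_per_epoch=3),
        trend=sc.TrendModelConfig(epochs=1),
        train_stride=8,
    )
    return sc.fit_pipeline(small_series, "temperature", cfg, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
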