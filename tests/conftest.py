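import numpy as np
import pytest

from nanoplan import (
    QualityParams,
    ScoringRegion,
    ensemble_from_quality,
    sample_svs,
)


@pytest.fixture(scope="session")
def region():
    return ScoringRegion()


@pytest.fixture()
def dense_quality():
    """A densely ionizing quality for small deterministic fixtures."""
    return QualityParams(lambda_primary=0.05, cluster_mean=1.0, radial_scale=5.0)


@pytest.fixture()
def small_ensemble(region, dense_quality):
    return ensemble_from_quality(dense_quality, 50, region, rng_seed=11)


@pytest.fixture()
def small_svs(region):
    return sample_svs(region, 500, rng_seed=12)


def make_absolute_probs(rng, width=31):
    """Random absolute ICSD probability vector (exactly normalized)."""
    p = rng.random(width) ** 3
    p[0] += 3.0  # keep a realistic dominant zero bin
    return p / p.sum()
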