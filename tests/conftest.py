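import numpy as np
import pytest

from itlearn import (
    ITPopulationStats,
    StatsConfig,
    generate_population_statistics,
    sample_population,
)


@pytest.fixture(scope="session")
def default_stats():
    """Full-size (64-object, 8-category) statistics at the default config."""
    return generate_population_statistics(seed=1)


@pytest.fixture(scope="session")
def small_stats():
    """Fast 8-object / 2-category statistics for unit tests."""
    cfg = StatsConfig(within_category_corr=(0.9, 0.5), clutter_var_mean=0.25)
    return generate_population_statistics(
        n_objects=8, n_categories=2, seed=7, config=cfg
    )


@pytest.fixture()
def small_pop(small_stats):
    return sample_population(small_stats, n_sites=40, seed=3)


def deterministic_stats(n_objects=2, mean=(2.0, 1.0), kernel=(1.0, 1.0, 1.0)):
    """Zero-covariance, zero-noise statistics: every site equals the mean."""
    return ITPopulationStats(
        n_objects=n_objects,
        n_categories=1,
        object_mean=np.asarray(mean, float),
        object_covariance=np.zeros((n_objects, n_objects)),
        size_kernel_pool=np.asarray([kernel], float),
        clutter_variance_by_object=np.zeros(n_objects),
        repetition_fano=0.0,
    )
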