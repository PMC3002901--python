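import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crhnet.containers import RatioMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from crhnet.synthetic import SyntheticConfig, generate_ratio_matrix


def make_ratio_matrix(values: np.ndarray, time=None, dye=None) -> RatioMatrix:
    """Wrap a plain (genes x samples) array in a RatioMatrix with the
    standard 5-time x 6-replicate dye-swap factor layout (or custom factors)."""
    n_genes, n_samples = values.shape
    if time is None:
        assert n_samples == 30
        time = np.repeat([1.0, 3.0, 6.0, 12.0, 24.0], 6)
    if dye is None:
        dye = np.tile(
            ["treated_cy3"] * 3 + ["treated_cy5"] * 3, n_samples // 6
        )
    samples = pd.DataFrame(
        {"time_h": time, "dye": dye},
        index=[f"s{i:02d}" for i in range(n_samples)],
    )
    genes = [f"g{i:05d}" for i in range(n_genes)]
    return RatioMatrix(pd.DataFrame(values, index=genes, columns=samples.index),
                       samples)


@pytest.fixture(scope="session")
def planted_pool():
    """400-gene pool with 10 planted discriminative genes (design scale)."""
    cfg = SyntheticConfig(n_spots=400, n_de_genes=10, seed=7)
    matrix, truth = generate_ratio_matrix(cfg)
    return matrix, truth


@pytest.fixture(scope="session")
def weak_signal_pool():
    """100 genes, all mildly time-responsive: emulates a preselected pool
    (the regime where the overfitting diagnostic shows its U-shape)."""
    cfg = SyntheticConfig(n_spots=100, n_de_genes=100, de_effect=0.5,
                          noise_sd=0.25, seed=19)
    matrix, truth = generate_ratio_matrix(cfg)
    return matrix, truth


@pytest.fixture(scope="session")
def null_pool():
    """Pure-noise pool: no planted structure at all."""
    cfg = SyntheticConfig(n_spots=400, n_de_genes=0, seed=19)
    matrix, truth = generate_ratio_matrix(cfg)
    return matrix, truth
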