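import numpy as np
import pytest
from hypothesis import settings

from nirproline import GeneratorConfig, SpectrumSet, make_grid

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_grid():
    return make_grid(10000.0, 4000.0, 200)


def make_spectrum_set(values: np.ndarray, grid=None, ids=None) -> SpectrumSet:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if grid is None:
        grid = make_grid(10000.0, 4000.0, values.shape[1])
    if ids is None:
        ids = [f"s{i}" for i in range(values.shape[0])]
    return SpectrumSet(ids, grid, values)


def noiseless_config(n_samples=80, n_points=400, seed=0, **overrides) -> GeneratorConfig:
    """Single-analyte configuration with every corruption source disabled."""
    defaults = dict(
        n_samples=n_samples,
        grid=make_grid(10000.0, 4000.0, n_points),
        analyte_bands=[(7352.0, 120.0, 4.0)],
        interferent_bands=[],
        baseline_slope_sd=0.0,
        baseline_offset_sd=0.0,
        scatter_sd=0.0,
        noise_sd=0.0,
        reference_error_sd=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture
def noiseless_cfg():
    return noiseless_config()
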