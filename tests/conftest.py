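import numpy as np
import pytest

from seedhsi import synthetic_data as sd
from seedhsi.io_hypercube import Hypercube, WavelengthGrid


@pytest.fixture(scope="session")
def small_grid():
    return sd.reduced_grid(32)


@pytest.fixture(scope="session")
def models5():
    """Five well-separated treatment-class spectral models."""
    return sd.make_class_models(5, separation=1.0, rng_seed=0, noise_sigma=0.02)


@pytest.fixture(scope="session")
def models3():
    return sd.make_class_models(3, separation=1.0, rng_seed=0, noise_sigma=0.02)


@pytest.fixture(scope="session")
def dataset5(models5):
    """200 seed chips (40 per class, 16x16x32) plus their pixel matrix."""
    seed_set, pixels, truth = sd.generate_dataset(
        40, models5, chip_hw=(16, 16), rng_seed=0
    )
    return seed_set, pixels, truth


@pytest.fixture(scope="session")
def panel0(models5):
    """One synthetic raw panel with references and ground truth."""
    spec = sd.make_panel_spec(models5, seeds_per_class=2, rows=160, cols=160,
                              grid=sd.reduced_grid(32), rng_seed=0)
    raw, refs, truth = sd.generate_panel(spec, models5)
    return spec, raw, refs, truth


def make_cube(data, start_nm=597.21, step_nm=4.14, **meta):
    data = np.asarray(data, dtype=np.float32)
    grid = WavelengthGrid(start_nm=start_nm, step_nm=step_nm, count=data.shape[2])
    return Hypercube(data=data, grid=grid, meta=meta)
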