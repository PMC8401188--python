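import numpy as np
import pytest

from histofuse import BenchmarkSpec, TextureClassSpec, generate_dataset, make_labels


@pytest.fixture(scope="session")
def small_benchmark_spec() -> BenchmarkSpec:
    """A 3-class, 16x16 texture benchmark small enough for unit tests."""
    labels = make_labels(3)
    specs = [
        TextureClassSpec(labels[0], grating_frequency=3.0,
                         grating_orientation=0.0, blob_density=0.0),
        TextureClassSpec(labels[1], grating_frequency=3.0,
                         grating_orientation=90.0, blob_density=1.5),
        TextureClassSpec(labels[2], grating_frequency=6.0,
                         grating_orientation=45.0, blob_density=3.0),
    ]
    return BenchmarkSpec(class_specs=specs, train_counts=[10, 10, 10],
                         test_counts=[4, 4, 4], patch_size=16, master_seed=7)


@pytest.fixture(scope="session")
def small_datasets(small_benchmark_spec):
    return generate_dataset(small_benchmark_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
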