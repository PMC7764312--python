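import numpy as np
import pytest

from sauseg.io_schema import LabelSchema, LabelVolume, SchemaEntry, Volume3D
from sauseg.phantom import PhantomSpec, TissueSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_schema():
    return LabelSchema([
        SchemaEntry(0, "background"),
        SchemaEntry(1, "blob_left", "left"),
        SchemaEntry(2, "blob_right", "right"),
        SchemaEntry(3, "core"),
    ])


@pytest.fixture
def small_spec(small_schema):
    """32-cube phantom with three structures, deterministic."""
    return PhantomSpec(
        shape=(32, 32, 32),
        tissues=[
            TissueSpec(1, (10.0, 15.5, 15.5), (6.0, 8.0, 8.0), 100.0),
            TissueSpec(2, (22.0, 15.5, 15.5), (6.0, 8.0, 8.0), 150.0),
            TissueSpec(3, (15.5, 15.5, 15.5), (4.0, 4.0, 4.0), 200.0),
        ],
        noise_sd=0.0,
        bias_amplitude=0.0,
        seed=7,
        schema=small_schema,
    )


@pytest.fixture
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture
def random_volume(rng):
    data = rng.normal(100.0, 10.0, size=(16, 16, 16))
    return Volume3D(data, (1.0, 1.0, 1.0))


def labels_from_array(arr, schema, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(np.asarray(arr, dtype=np.int32), schema, spacing)
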