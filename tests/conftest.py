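import numpy as np
import pytest

from ecgforge.records import make_sine_validation_record, make_synthetic_pqrst_record
from ecgforge.render import render_clean_image


@pytest.fixture(scope="session")
def sine_render():
    """Default validation sine (0.5 mV, 1.25 Hz in lead I) rendered once."""
    record = make_sine_validation_record(0, 0.5, 1.25)
    image, manifest = render_clean_image(record)
    return image, manifest


@pytest.fixture(scope="session")
def pqrst_render():
    """A plausible PQRST record rendered once."""
    record = make_synthetic_pqrst_record(60, seed=7)
    image, manifest = render_clean_image(record)
    return record, image, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
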