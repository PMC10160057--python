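import numpy as np
import pytest

from eptrans import ChannelGeometry, SamplingProtocol


@pytest.fixture
def chip_geometry():
    """Default chip: 1.0 x 0.35 mm channel over a 0.1 cm² membrane."""
    return ChannelGeometry(
        width_mm=1.0, height_mm=0.35, length_mm=10.0, membrane_area_cm2=0.1
    )


@pytest.fixture
def default_protocol():
    """200 μL channel, 100 μL aliquot, hourly sampling, fresh-buffer refill."""
    return SamplingProtocol()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
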