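import numpy as np
import pytest

from myosort.actin import (ActinNetwork, _radial_polarity, generate_network,
                           orientation_field)


@pytest.fixture(scope="session")
def mesh_network():
    """Small keratocyte-like meshwork shared across stepping tests."""
    return generate_network(1500, 1500, seed=42)


def make_straight_filament(n_cols=500, n_rows=41, pixel_size=2.4):
    """Single horizontal filament raster with +x polarity."""
    skel = np.zeros((n_rows, n_cols), dtype=bool)
    skel[n_rows // 2, :] = True
    net = ActinNetwork(skeleton=skel, pixel_size=pixel_size,
                       polarity=_radial_polarity(skel.shape))
    net.orientation, net.excluded, _ = orientation_field(skel)
    return net


@pytest.fixture(scope="session")
def straight_filament():
    return make_straight_filament()
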