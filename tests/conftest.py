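import numpy as np
import pytest

from rnahit import (
    HighFidelitySet, Landscape, RateConstants, SequenceSpace,
    calibrate_replication_scale, init_population,
)


@pytest.fixture(scope="session")
def space3():
    return SequenceSpace(3)


@pytest.fixture(scope="session")
def space2():
    return SequenceSpace(2)


@pytest.fixture(scope="session")
def setup3(space3):
    """A small but fully featured core-model configuration on n=3."""
    rng = np.random.default_rng(2024)
    R = HighFidelitySet.random_singleton(3, rng)
    landscape = Landscape.tent_from_terminus(3, 0.01)
    init = init_population(space3, 10, rng, R=R, avoid_R=True)
    a = calibrate_replication_scale(space3, landscape, R, init, target=10.0)
    return {
        "space": space3, "R": R, "landscape": landscape,
        "init": init, "rates": RateConstants(a=a),
    }
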