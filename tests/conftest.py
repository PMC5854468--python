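import numpy as np
import pytest

from mrebalign import ContourScenario, TrajectoryScenario, generate_contour, generate_tracks


@pytest.fixture(scope="session")
def circle_contour():
    return generate_contour(ContourScenario(kind="sphere", radius=1.0, n_vertices=128))


@pytest.fixture(scope="session")
def rod_contour():
    return generate_contour(ContourScenario(kind="rod", width=0.9, length=3.0, n_vertices=256))


@pytest.fixture(scope="session")
def bulged_contour():
    return generate_contour(
        ContourScenario(kind="bulged_sphere", radius=1.0, bulge_width=0.8,
                        neck_depth=0.3, n_vertices=256)
    )


@pytest.fixture(scope="session")
def random_field_tracks():
    return generate_tracks(TrajectoryScenario(kind="random_field", n_tracks=1000, seed=1))
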