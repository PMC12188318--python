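import dataclasses

import numpy as np
import pytest

from livertrack.phantom import PhantomConfig, make_phantom
from livertrack.projector import ConeBeamGeometry


@pytest.fixture(scope="session")
def small_phantom():
    """A coarse phantom used across tests; 24^3 at 8 mm keeps everything fast."""
    cfg = PhantomConfig(grid=24, spacing_mm=8.0, n_surface_nodes=80,
                        n_tumor_points=24, seed=11)
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def desk_geometry():
    return ConeBeamGeometry(gantry_angle_deg=0.0, source_to_axis_mm=400.0,
                            source_to_detector_mm=700.0, detector_cols=64,
                            detector_rows=48, pixel_pitch_mm=6.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
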