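import numpy as np
import pytest

import omagperf as op
from omagperf.flow import compute_flow, scale_to_dynamic_range
from omagperf.segmentation import delineate_disc_margin, prelc_mask, segment_layers


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_complex_volume():
    """Seeded random complex repeated-B-scan volume (ny=6, R=4, nx=8, nz=10)."""
    r = np.random.default_rng(7)
    data = r.standard_normal((6, 4, 8, 10)) + 1j * r.standard_normal((6, 4, 8, 10))
    return op.RepeatedBScanVolume(data=data)


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic scene shared by the imaging-stage tests."""
    spec = op.make_scene(nx=96, ny=96, nz=128, target_vessel_fraction=0.5,
                         delta=1.0, seed=5)
    vol, gt = op.generate_volume(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def scene_products(default_scene):
    """Structural volume, layers, scaled flow and preLC mask for the scene."""
    spec, vol, gt = default_scene
    structural = np.moveaxis(np.abs(vol.data).mean(axis=1), 0, 1)
    layers = delineate_disc_margin(structural, segment_layers(structural))
    flow = scale_to_dynamic_range(compute_flow(vol))
    mask3d = prelc_mask(layers, spec.nz)
    return {"spec": spec, "vol": vol, "gt": gt, "structural": structural,
            "layers": layers, "flow": flow, "mask3d": mask3d}
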