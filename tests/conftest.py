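import numpy as np
import pytest

from prefibril.containers import DensityField
from prefibril.synthetic_data import AssemblyGroundTruth, gen_density_field


@pytest.fixture(scope="session")
def straight_tube_field() -> DensityField:
    """Straight 48 nm, 2.8 nm tube rendered at 0.25 nm voxels, light blur."""
    cl = np.column_stack([np.full(97, 40.0), np.linspace(16.0, 64.0, 97)])
    gt = AssemblyGroundTruth("curvilinear", cl, arc_length=48.0)
    return gen_density_field([gt], (320, 320), 0.25, blur_sd=0.1, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def torus_field_3d() -> DensityField:
    """Noiseless torus, outer 7.5 nm / inner 2.0 nm, 0.25 nm voxels."""
    gt = AssemblyGroundTruth(
        "annulus",
        np.array([[12.0, 12.0, 12.0]]),
        ring_outer_diameter=7.5,
        ring_inner_diameter=2.0,
    )
    return gen_density_field([gt], (96, 96, 96), 0.25, blur_sd=0.0, seed=0)
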