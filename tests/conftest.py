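import numpy as np
import pytest

from graftquant.align import RigidTransform
from graftquant.phantom import PhantomSpec
from graftquant.volio import VolumeImage


@pytest.fixture
def small_spec():
    """A reduced phantom scene (75^3 voxels) for fast unit tests."""
    return PhantomSpec(
        field_of_view=(12.0, 12.0, 12.0),
        slab_thickness=3.0,
        slab_footprint=(8.0, 8.0),
        slab_offset=1.0,
        slab_wedge=(0.8, 1.2),
        cortical_thickness=0.8,
        graft_size=(2.5, 5.0, 5.0),
        screw_radius=0.7,
        screw_length=4.5,
        # the small scene has different tissue fractions, so bone lands
        # mid-window at a lower raw attenuation than in the default scene
        mu_cortical=1000.0,
        mu_trabecular=550.0,
        misalignment=RigidTransform((1.0, -0.8, 0.6), (0.6, -0.5, 0.8)),
        seed=7,
    )


@pytest.fixture
def ball_volume():
    """Noiseless in-band ball (value 450) on background -200, radius 14 voxels."""
    shape = (48, 48, 48)
    idx = np.indices(shape)
    r = np.sqrt(((idx - 23.5) ** 2).sum(axis=0))
    vals = np.where(r < 14, 450.0, -200.0)
    return VolumeImage(vals, (0.16,) * 3, (0, 0, 0), "normalized"), r
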