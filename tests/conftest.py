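"""Shared fixtures: small, fast phantom configurations.

The full study geometry (96x96x160 voxels) is exercised only by the
acceptance-level registration test; everything else runs on a reduced spine
(5 levels, 64x64x56 voxels at 1.25 mm) that keeps the same anatomy.
"""

import numpy as np
import pytest

from spinefuse import PhantomSpec, generate_phantom_pair, make_rigid


SMALL_KW = dict(
    n_levels=5,
    level_height=14.0,
    lesion_levels=(2,),
    grid_xy=64,
    spacing=(1.25, 1.25, 1.25),
)


@pytest.fixture
def small_spec():
    return PhantomSpec(**SMALL_KW, seed=11)


@pytest.fixture
def small_spec_noisefree():
    return PhantomSpec(**SMALL_KW, noise_sd=0.0, seed=11)


@pytest.fixture
def noisefree_pair(small_spec_noisefree):
    """Aligned noise-free pair plus its truth bookkeeping."""
    return generate_phantom_pair(small_spec_noisefree)


def volume_center(spec: PhantomSpec) -> np.ndarray:
    return (np.array(spec.shape) - 1) * np.asarray(spec.spacing) / 2.0


@pytest.fixture
def misaligned_pair(small_spec_noisefree):
    """Noise-free pair with a known small rigid misalignment."""
    center = volume_center(small_spec_noisefree)
    truth_t = make_rigid(3.0, -2.0, 4.0, 1.0, -0.5, 1.5, center)
    spec = small_spec_noisefree.with_transform(truth_t)
    primary, secondary, truth = generate_phantom_pair(spec)
    return primary, secondary, truth, truth_t
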