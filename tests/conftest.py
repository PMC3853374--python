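import numpy as np
import pytest

import periquant as pq


@pytest.fixture
def box_phantom():
    """2 x 3 x 4 cm box at isotropic 0.1 cm spacing, edges on voxel boundaries."""
    spec = pq.PhantomSpec(
        shape=(40, 50, 60),
        spacing=(0.1, 0.1, 0.1),
        shapes=(pq.Box(center=(2.0, 2.5, 3.0), size=(2.0, 3.0, 4.0)),),
    )
    return pq.generate_phantom(spec)


@pytest.fixture
def multi_compartment_phantom():
    """Three disjoint contrast shapes plus a bone-like distractor, 128^3."""
    h = 0.1
    spec = pq.PhantomSpec(
        shape=(128, 128, 128),
        spacing=(h, h, h),
        shapes=(
            pq.Sphere(center=(4.0, 4.0, 6.4), radius=2.5),
            pq.Box(center=(9.0, 9.0, 6.4), size=(3.0, 3.0, 5.0)),
            pq.Ellipsoid(center=(4.0, 9.5, 6.4), semiaxes=(2.0, 1.5, 2.5)),
        ),
        distractors=(pq.Box(center=(11.5, 3.0, 6.4), size=(1.0, 1.0, 8.0)),),
    )
    return spec


def random_label_mask(rng, max_side=32, n_labels=3):
    """A random small labeled mask with random anisotropic spacing."""
    shape = tuple(int(rng.integers(3, max_side + 1)) for _ in range(3))
    labels = rng.integers(0, n_labels + 1, size=shape).astype(np.int32)
    spacing = tuple(float(s) for s in rng.uniform(0.05, 0.6, size=3))
    return pq.CompartmentMask(labels=labels, spacing=spacing)
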