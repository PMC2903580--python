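import numpy as np
import pytest

from lvstrain.fields import DisplacementField
from lvstrain.phantom import PhantomSpec, build_phantom
from lvstrain.experiments import phantom_long_axis


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom(spec):
    return build_phantom(spec)


@pytest.fixture(scope="session")
def phantom_slice(spec):
    """Phantom, its default 1 mm long-axis slice and the long-axis model."""
    return phantom_long_axis(spec)


@pytest.fixture(scope="session")
def interior_points(spec):
    """Random points strictly inside the phantom wall."""

    def sample(n, seed=0, t_margin=0.0):
        rng = np.random.default_rng(seed)
        Z = rng.uniform(1.0, spec.l_len, n)
        r2 = 0.5 * spec.r0 * (1 + Z / spec.l_len)
        r1 = r2 - spec.thickness
        R = rng.uniform(r1 + t_margin, r2 - t_margin)
        phi = rng.uniform(0, 2 * np.pi, n)
        return np.stack([R * np.cos(phi), R * np.sin(phi), Z], axis=-1)

    return sample


def planar_affine_field(A, n=11, spacing=1.0, normal_axis=2):
    """Exact affine motion of a flat slice, as a DisplacementField."""
    ii, jj = np.mgrid[0:n, 0:n]
    half = (n - 1) / 2
    zeros = np.zeros_like(ii, dtype=float)
    cols = [(ii - half) * spacing, (jj - half) * spacing, zeros]
    order = {0: (2, 0, 1), 1: (0, 2, 1), 2: (0, 1, 2)}[normal_axis]
    pos = np.stack([cols[order.index(k)] for k in range(3)], axis=-1)
    normal = np.zeros(3)
    normal[normal_axis] = 1.0
    u = pos @ (np.asarray(A) - np.eye(3)).T
    return DisplacementField(
        ref_positions=pos,
        displacements=u[None],
        mask=np.ones((n, n), bool),
        spacing=spacing,
        slice_normal=normal,
        times=[0.0],
    )


def random_unimodular(rng, scale=0.3, observable=False):
    """Random affine tensor with det 1; ``observable`` zeroes the
    out-of-plane shear couplings (slice normal = third axis)."""
    A = np.eye(3) + scale * rng.standard_normal((3, 3))
    if observable:
        A[0, 2] = A[1, 2] = 0.0
    A = A / np.cbrt(np.linalg.det(A))
    if observable:
        A[0, 2] = A[1, 2] = 0.0
        A /= np.cbrt(np.linalg.det(A))
    return A
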