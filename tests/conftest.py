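"""Shared fixtures: small grids, digitized spheres, a miniature cohort."""

from __future__ import annotations

import numpy as np
import pytest

from oarteval.core import VolumeGrid


def make_grid(values, origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0)) -> VolumeGrid:
    return VolumeGrid(origin=origin, spacing=spacing, values=np.asarray(values))


def sphere_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Digitized sphere: voxel centers within radius (world mm)."""
    sp = np.asarray(spacing, dtype=float)
    ax = [np.arange(n) * s for n, s in zip(shape, sp)]
    cx, cy, cz = center
    r2 = (
        (ax[0][:, None, None] - cx) ** 2
        + (ax[1][None, :, None] - cy) ** 2
        + (ax[2][None, None, :] - cz) ** 2
    )
    return r2 <= radius**2


def random_blob(rng, shape=(24, 24, 24), n_seeds=4, iterations=3) -> np.ndarray:
    """Connected-ish random mask with a few hundred boundary voxels."""
    from scipy import ndimage

    m = np.zeros(shape, dtype=bool)
    idx = rng.integers(4, np.array(shape) - 4, size=(n_seeds, 3))
    m[tuple(idx.T)] = True
    m = ndimage.binary_dilation(m, iterations=iterations)
    noise = rng.random(shape) < 0.2
    m = ndimage.binary_dilation(m) & ~ (noise & ~m)
    return m


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 patients × 2 fractions with dose, generated once per test session."""
    from oarteval.phantom import PhantomConfig, generate_cohort

    config = PhantomConfig(patients=2, fractions=2, master_seed=123)
    sessions, log = generate_cohort(config)
    return config, sessions, log
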