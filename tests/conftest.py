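"""Shared fixtures: small synthetic geometries and tracks."""

import numpy as np
import pytest

from morphotrack import geometry as G


@pytest.fixture(scope="session")
def tissue_small():
    """Coarse-pitch tissue mask, fast enough for unit tests."""
    return G.synthesize_tissue(
        n_cells=8,
        target_eta=10.0,
        seed=11,
        pixel_pitch_um=0.02,
        cell_area_um2=100.0,
    )


@pytest.fixture(scope="session")
def open_geometry():
    """All-extracellular field (free diffusion, no membranes inside)."""
    return G.TissueGeometry(np.ones((500, 500), dtype=np.uint8), 0.01)


def brownian_track(n_frames, d_coeff, dt=0.0117, noise=0.0, seed=0, start=(5.0, 5.0)):
    """A synthetic Brownian track as a tracking.Track object."""
    from morphotrack.tracking import Track

    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2 * d_coeff * dt), size=(n_frames - 1, 2))
    xy = np.concatenate([[start], start + np.cumsum(steps, axis=0)])
    if noise > 0:
        xy = xy + rng.normal(0.0, noise, size=xy.shape)
    return Track(frames=np.arange(n_frames), xy=xy)
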