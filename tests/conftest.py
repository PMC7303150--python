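import numpy as np
import pytest

from stallflow.synthgen import generate_network, generate_players


def paint_tube(volume, p0, p1, radius):
    """Rasterize a solid tube into a (z, y, x) volume (test fixture helper)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in volume.shape], indexing="ij")
    pts = np.stack([zz, yy, xx], -1).astype(float)
    d = p1 - p0
    l2 = float(d @ d)
    t = np.clip(((pts - p0) @ d) / l2, 0, 1) if l2 else np.zeros(pts.shape[:-1])
    dist = np.linalg.norm(pts - (p0 + t[..., None] * d), axis=-1)
    volume[dist <= radius] = 1
    return volume


@pytest.fixture(scope="session")
def y_junction_volume():
    """Three thick tubes meeting at one bifurcation."""
    vol = np.zeros((20, 40, 40), dtype=np.uint8)
    paint_tube(vol, (10, 20, 2), (10, 20, 20), 2)
    paint_tube(vol, (10, 20, 20), (10, 8, 36), 2)
    paint_tube(vol, (10, 20, 20), (10, 32, 36), 2)
    return vol


@pytest.fixture(scope="session")
def small_network():
    return generate_network(3, 60, 0.05, (0.86, 0.05, 0.09), seed=11)


@pytest.fixture(scope="session")
def beta_pool():
    return generate_players(60, (8.0, 2.0), seed=7)
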