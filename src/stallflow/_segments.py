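"""Small shared voxel-geometry helpers."""

from __future__ import annotations

import numpy as np


def lumen_mask_from_points(points_vox, radius_vox: float, shape) -> np.ndarray:
    """Boolean (z, y, x) mask of voxels within ``radius_vox`` of a polyline."""
    pts = np.asarray(points_vox, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    if pts.shape[0] == 0:
        return mask
    segs = [(pts[i], pts[i + 1]) for i in range(len(pts) - 1)] or [(pts[0], pts[0])]
    for p0, p1 in segs:
        lo = np.maximum(np.floor(np.minimum(p0, p1) - radius_vox - 1).astype(int), 0)
        hi = np.minimum(
            np.ceil(np.maximum(p0, p1) + radius_vox + 1).astype(int) + 1,
            np.array(shape),
        )
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        q = np.stack([zz, yy, xx], axis=-1).astype(float)
        d = p1 - p0
        l2 = float(d @ d)
        if l2 == 0:
            dist = np.linalg.norm(q - p0, axis=-1)
        else:
            t = np.clip(((q - p0) @ d) / l2, 0.0, 1.0)
            dist = np.linalg.norm(q - (p0 + t[..., None] * d), axis=-1)
        sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        sub |= dist <= radius_vox
    return mask
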