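"""Rendering of synthetic two-photon imaging data.

Two kinds of images are produced, both with known ground truth:

* :func:`render_stack` — a 4D multi-channel time-lapse stack of a vessel
  network.  The plasma channel mimics an intravascular dye: vessel lumens
  are bright, and unlabeled blood cells appear as dark patches that are
  advected along flowing capillaries and sit still in stalled ones.
  Stalled patches additionally carry cell-type labels: a leukocyte is
  positive in both the rhodamine and hoechst channels, a platelet in
  rhodamine only, and an RBC-only stall in neither.
* :func:`render_linescan` — a space-time image produced by repeatedly
  scanning along a vessel centerline; moving cells trace dark streaks
  whose slope encodes the centerline speed.

Stacks default to 1 µm voxels acquired at 1 frame/s with every capillary
visible for at least 5 consecutive frames, matching the acquisition the
stall definition assumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .._seeds import stream
from .network import VesselGraph

CHANNELS = {"plasma": 0, "rhodamine": 1, "hoechst": 2}


class EmptyFieldError(ValueError):
    """The requested field of view contains no capillary."""


@dataclass
class TimeStack:
    """A 4D multi-channel image stack with physical calibration.

    ``data`` has axes (t, c, z, y, x); voxels are isotropic at ``dz`` µm
    and frames are ``frame_interval`` s apart.  ``origin_um`` is the
    (z, y, x) position, in network coordinates, of voxel (0, 0, 0).
    """

    data: np.ndarray
    dz: float = 1.0
    frame_interval: float = 1.0
    origin_um: tuple = (0.0, 0.0, 0.0)
    channel_map: dict = field(default_factory=lambda: dict(CHANNELS))
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """(t, z, y, x) view of one channel."""
        return self.data[:, self.channel_map[name]]

    def save_tiff(self, path) -> None:
        """Write as a TZCYX multi-page TIFF with calibration metadata."""
        arr = np.moveaxis(self.data, 1, 2)  # (t, c, z, ...) -> (t, z, c, ...)
        tifffile.imwrite(
            path,
            arr.astype(np.float32),
            photometric="minisblack",
            metadata={
                "axes": "TZCYX",
                "dz_um": self.dz,
                "frame_interval_s": self.frame_interval,
                "origin_um": list(self.origin_um),
                "channels": self.channel_map,
            },
        )

    @classmethod
    def load_tiff(cls, path) -> "TimeStack":
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            md = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        data = np.moveaxis(arr, 2, 1)  # TZCYX -> TCZYX
        return cls(
            data=data,
            dz=float(md.get("dz_um", 1.0)),
            frame_interval=float(md.get("frame_interval_s", 1.0)),
            origin_um=tuple(md.get("origin_um", (0.0, 0.0, 0.0))),
            channel_map={k: int(v) for k, v in md.get("channels", CHANNELS).items()},
        )


@dataclass
class RenderedSegment:
    """Ground-truth geometry of one rendered capillary, in voxel coords."""

    edge: tuple
    points_vox: np.ndarray  # (n, 3) float, (z, y, x) voxel coordinates
    radius_um: float
    is_stalled: bool
    stall_cause: str
    speed_um_s: float


def _paint_capsule(volume, p0, p1, radius, value, mode="max", soft=False):
    """Paint a capsule (cylinder with spherical caps) into a (z,y,x) volume.

    ``p0``/``p1`` are voxel-coordinate endpoints; intensity is combined
    with existing content by elementwise maximum (``mode='max'``) or
    overwrite (``mode='set'``).  With ``soft=True`` the boundary voxel
    shell gets partial-volume weighting, so an intensity profile across
    the capsule crosses half maximum at distance ``radius`` exactly.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    pad = radius + (1.5 if soft else 1.0)
    lo = np.maximum(np.floor(np.minimum(p0, p1) - pad).astype(int), 0)
    hi = np.minimum(
        np.ceil(np.maximum(p0, p1) + pad).astype(int) + 1,
        np.array(volume.shape),
    )
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / seg_len2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    sub = volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    if soft:
        w = np.clip(radius + 0.5 - dist, 0.0, 1.0)
        mask = w > 0
        sub[mask] = np.maximum(sub[mask], value * w[mask])
    else:
        mask = dist <= radius
        if mode == "max":
            sub[mask] = np.maximum(sub[mask], value)
        else:
            sub[mask] = value


def _edge_geometry(graph: VesselGraph, edge, origin, dz):
    d = graph.graph.edges[edge]
    p0 = (np.asarray(graph.graph.nodes[edge[0]]["pos"]) - origin) / dz
    p1 = (np.asarray(graph.graph.nodes[edge[1]]["pos"]) - origin) / dz
    return p0, p1, d


def render_stack(
    graph: VesselGraph,
    fov,
    seed: int = 0,
    *,
    n_frames: int = 5,
    frame_interval: float = 1.0,
    dz: float = 1.0,
    origin_um=None,
    lumen_intensity: float = 200.0,
    patch_intensity: float = 30.0,
    cell_intensity: float = 180.0,
    background: float = 12.0,
    cell_background: float = 8.0,
    noise_sd: float = 2.0,
    patch_length_um: float = 6.0,
    flow_jitter: float = 0.05,
) -> TimeStack:
    """Render a vessel graph into a multi-channel time-lapse stack.

    ``fov`` is the (z, y, x) field size in µm; ``origin_um`` defaults to
    the graph bounding-box minimum.  Dark patches (1–3 per capillary,
    ``patch_length_um`` long) are advected by each vessel's ground-truth
    speed; ``flow_jitter`` adds fractional per-frame position noise so
    fast flow does not alias onto apparent stasis.  Raises
    :class:`EmptyFieldError` if no capillary intersects the field.
    """
    fov = np.asarray(fov, float)
    if origin_um is None:
        origin_um, _ = graph.bounding_box()
        origin_um = np.asarray(origin_um, float) - 5.0
    else:
        origin_um = np.asarray(origin_um, float)
    shape = tuple(np.ceil(fov / dz).astype(int))

    def _in_fov(p):
        q = (np.asarray(p) - origin_um) / dz
        return np.all(q >= -1) and np.all(q <= np.array(shape) + 1)

    cap_edges = [
        e
        for e in graph.capillary_edges()
        if _in_fov(graph.graph.nodes[e[0]]["pos"])
        or _in_fov(graph.graph.nodes[e[1]]["pos"])
    ]
    if not cap_edges:
        raise EmptyFieldError(
            f"field of view {tuple(fov)} µm at origin {tuple(origin_um)} "
            "contains no capillary"
        )

    # Static vasculature (plasma channel) painted once.
    plasma_static = np.zeros(shape, dtype=np.float32)
    all_edges = [
        e
        for e in graph.graph.edges
        if _in_fov(graph.graph.nodes[e[0]]["pos"])
        or _in_fov(graph.graph.nodes[e[1]]["pos"])
    ]
    for e in all_edges:
        p0, p1, d = _edge_geometry(graph, e, origin_um, dz)
        _paint_capsule(
            plasma_static, p0, p1, d["radius_um"] / dz, lumen_intensity, soft=True
        )

    rng = stream(seed, "render")
    data = np.empty((n_frames, 3, *shape), dtype=np.float32)

    # Per-capillary patch setup: count, arclength offsets.
    patch_setup = []
    for e in cap_edges:
        p0, p1, d = _edge_geometry(graph, e, origin_um, dz)
        length_vox = float(np.linalg.norm(p1 - p0))
        if length_vox == 0:
            continue
        n_patch = int(rng.integers(1, 4))
        if d["is_stalled"]:
            # keep static patches away from junctions so they stay
            # attributable to this segment
            offs = rng.uniform(0.25, 0.75, size=n_patch) * length_vox
        else:
            offs = rng.uniform(0.0, 1.0, size=n_patch) * length_vox
        patch_setup.append((e, p0, p1, d, length_vox, offs))

    half_len = 0.5 * patch_length_um / dz
    for t in range(n_frames):
        plasma = plasma_static.copy()
        rho = np.zeros(shape, dtype=np.float32)
        hoe = np.zeros(shape, dtype=np.float32)
        for e, p0, p1, d, length_vox, offs in patch_setup:
            u = (p1 - p0) / length_vox
            v_vox = d["speed_um_s"] / dz
            for off in offs:
                if d["is_stalled"]:
                    s = off
                else:
                    step = v_vox * frame_interval
                    s = (off + step * t + rng.normal(0.0, flow_jitter * step)) % length_vox
                a = p0 + u * max(s - half_len, 0.0)
                b = p0 + u * min(s + half_len, length_vox)
                r = d["radius_um"] / dz
                _paint_capsule(plasma, a, b, r * 0.95, patch_intensity, mode="set")
                if d["is_stalled"]:
                    if d["stall_cause"] == "leukocyte":
                        _paint_capsule(rho, a, b, r * 0.95, cell_intensity)
                        _paint_capsule(hoe, a, b, r * 0.95, cell_intensity)
                    elif d["stall_cause"] == "platelet":
                        _paint_capsule(rho, a, b, r * 0.95, cell_intensity)
        data[t, 0] = plasma + background
        data[t, 1] = rho + cell_background
        data[t, 2] = hoe + cell_background
    data += rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)
    np.clip(data, 0.0, None, out=data)

    return TimeStack(
        data=data,
        dz=dz,
        frame_interval=frame_interval,
        origin_um=tuple(origin_um),
        meta={"seed": seed, "n_capillaries": len(cap_edges)},
    )


def rendered_segments(graph: VesselGraph, stack: TimeStack, step_um: float = 1.0):
    """Ground-truth centerlines of each capillary, in stack voxel coords."""
    origin = np.asarray(stack.origin_um, float)
    shape = np.array(stack.data.shape[2:])
    out = []
    for e in graph.capillary_edges():
        p0, p1, d = _edge_geometry(graph, e, origin, stack.dz)
        if np.any(np.maximum(p0, p1) < 0) or np.any(np.minimum(p0, p1) > shape):
            continue
        n = max(int(np.linalg.norm(p1 - p0) * stack.dz / step_um), 2)
        pts = p0 + (p1 - p0) * np.linspace(0, 1, n)[:, None]
        out.append(
            RenderedSegment(
                edge=e,
                points_vox=pts,
                radius_um=d["radius_um"],
                is_stalled=d["is_stalled"],
                stall_cause=d["stall_cause"],
                speed_um_s=d["speed_um_s"],
            )
        )
    return out


def render_single_capillary(
    cause: str,
    seed: int,
    *,
    stalled: bool = True,
    speed_um_s: float = 0.0,
    radius_um: float = 2.5,
    length_um: float = 40.0,
    n_frames: int = 5,
    **kwargs,
):
    """Render one straight capillary in a tight field; returns (stack, segment).

    Convenience wrapper used for per-segment crops (e.g. stall-cause
    classification at scale) without building a whole network.
    """
    import networkx as nx

    g = nx.DiGraph()
    # integer pad keeps the centerline on a voxel center, so axial
    # slices through it see the full vessel diameter
    pad = float(int(np.ceil(3 * radius_um + 4)))
    g.add_node("a", kind="capillary-junction", pos=(pad, pad, 4.0))
    g.add_node("b", kind="capillary-junction", pos=(pad, pad, 4.0 + length_um))
    g.add_edge(
        "a",
        "b",
        kind="capillary",
        radius_um=radius_um,
        length_um=length_um,
        branch_order=1,
        is_stalled=stalled,
        stall_cause=cause if stalled else "none",
        speed_um_s=0.0 if stalled else speed_um_s,
    )
    vg = VesselGraph(g)
    fov = (2 * pad, 2 * pad, length_um + 8.0)
    stack = render_stack(
        vg, fov, seed=seed, n_frames=n_frames, origin_um=(0.0, 0.0, 0.0), **kwargs
    )
    seg = rendered_segments(vg, stack)[0]
    return stack, seg


@dataclass
class LineScan:
    """A space-time image: rows are successive line scans, columns distance."""

    image: np.ndarray  # (n_lines, n_pixels)
    pixel_pitch_um: float
    line_rate_hz: float
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        """TIFF image plus JSON calibration sidecar."""
        path = str(path)
        tifffile.imwrite(path, self.image.astype(np.float32))
        with open(path + ".json", "w") as fh:
            json.dump(
                {
                    "pixel_pitch_um": self.pixel_pitch_um,
                    "line_rate_hz": self.line_rate_hz,
                    **self.meta,
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "LineScan":
        path = str(path)
        img = tifffile.imread(path)
        with open(path + ".json") as fh:
            md = json.load(fh)
        return cls(
            image=img,
            pixel_pitch_um=float(md.pop("pixel_pitch_um")),
            line_rate_hz=float(md.pop("line_rate_hz")),
            meta=md,
        )


def render_linescan(
    speed: float,
    radius: float = 2.0,
    scan_rate: float = 1000.0,
    duration: float = 0.512,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    pixel_pitch_um: float = 1.0,
    n_pixels: int = 128,
    cell_spacing_um: float = 12.0,
    lumen_intensity: float = 200.0,
    cell_depth: float = 160.0,
) -> LineScan:
    """Render a centerline line-scan space-time image for a known speed.

    Dark Gaussian streaks (width tied to ``radius``) move at ``speed``
    µm/s across a bright plasma background.  ``speed=0`` gives vertical
    streaks.  Emits an aliasing warning when a cell would cross the whole
    scan line in less than one line period.
    """
    if speed < 0:
        raise ValueError("speed must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_lines = int(round(duration * scan_rate))
    if speed / (pixel_pitch_um * scan_rate) > n_pixels:
        warnings.warn(
            "speed too high for this scan rate: streak crosses the full "
            "line in under one line period (aliasing)",
            RuntimeWarning,
        )
    rng = stream(seed, "linescan")
    span = n_pixels * pixel_pitch_um
    # Enough cells upstream that the field stays populated for the scan.
    travel = speed * duration
    n_cells = int((travel + span + 4 * cell_spacing_um) / cell_spacing_um)
    if n_cells <= 4000:
        x0 = np.arange(
            -travel - 2 * cell_spacing_um, span + 2 * cell_spacing_um, cell_spacing_um
        )
        x0 = x0 + rng.uniform(-0.4, 0.4, size=x0.size) * cell_spacing_um
    else:
        # aliasing regime: cells cross the field within a line anyway, so
        # a bounded random subset preserves the image statistics
        x0 = rng.uniform(-travel - 2 * cell_spacing_um, span + 2 * cell_spacing_um, 4000)

    t = np.arange(n_lines)[:, None] / scan_rate
    x = np.arange(n_pixels)[None, :] * pixel_pitch_um
    sigma = max(0.8, radius)
    img = np.full((n_lines, n_pixels), lumen_intensity, dtype=np.float64)
    for xc in x0:
        pos = xc + speed * t  # (n_lines, 1)
        img -= cell_depth * np.exp(-((x - pos) ** 2) / (2 * sigma**2))
    np.clip(img, 0.0, None, out=img)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return LineScan(
        image=img,
        pixel_pitch_um=pixel_pitch_um,
        line_rate_hz=scan_rate,
        meta={"true_speed_um_s": speed, "radius_um": radius, "seed": seed},
    )
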