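"""From binary vessel masks to capillary segments and annotation crops.

The pipeline stage between image segmentation and crowd scoring:

1. :func:`mask_surface_vessels` removes large surface vessels / poor-SNR
   regions using a user-supplied binary mask.
2. :func:`extract_centerlines` reduces a binary vessel volume to a
   single-voxel-wide, topology-preserving skeleton.
3. :func:`identify_segments` enumerates capillary segments — skeleton
   paths between bifurcation (or terminal) nodes — after removing short
   spur artifacts and merging adjacent bifurcation voxels into node
   clusters.
4. :func:`make_crop_tasks` cuts an intensity-normalized sub-stack around
   each segment and draws a dilated-centerline outline, producing the
   items served to annotators.

Coordinates are 0-based voxel indices in (z, y, x) order; crop boxes are
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

logger = logging.getLogger(__name__)

_OFFSETS = np.array(
    [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)], dtype=int
)


@dataclass
class CapillarySegment:
    """A capillary: an ordered centerline path between two nodes."""

    id: str
    centerline_vox: np.ndarray  # (n, 3) int voxel coords, ordered
    endpoints: tuple  # node-cluster ids, or None for a free end
    length_um: float
    radius_um: float | None = None
    source_stack_id: str | None = None
    bbox: tuple | None = None  # half-open (z0, z1, y0, y1, x0, x1)


@dataclass
class CropTask:
    """One annotation item: normalized sub-stack plus segment outline."""

    segment_id: str
    substack: np.ndarray  # (t, c, z, y, x), intensities in [0, 1]
    outlines: dict  # z (crop coords) -> (k, 2) array of (y, x) outline voxels
    bbox: tuple  # half-open crop box in source-stack coords
    kind: str = "research"  # 'research' | 'calibration'
    calibration_truth: str | None = None  # 'stalled' | 'flowing' if calibration
    centerline_crop: np.ndarray = None  # centerline in crop coordinates


# --------------------------------------------------------------------------


def mask_surface_vessels(stack, mask: np.ndarray):
    """Zero out masked-away regions (mask 0 = remove, 1 = keep).

    Returns a new stack; the applied-mask provenance is recorded in
    ``stack.meta``.
    """
    mask = np.asarray(mask)
    spatial = stack.data.shape[2:]
    if mask.shape != spatial:
        raise ValueError(
            f"mask shape {mask.shape} does not match stack spatial shape {spatial}"
        )
    out = stack.data * mask[None, None].astype(stack.data.dtype)
    new = type(stack)(
        data=out,
        dz=stack.dz,
        frame_interval=stack.frame_interval,
        origin_um=stack.origin_um,
        channel_map=dict(stack.channel_map),
        meta={**stack.meta, "masked_voxels": int(mask.size - mask.sum())},
    )
    return new


def extract_centerlines(binary: np.ndarray) -> np.ndarray:
    """Topology-preserving 3D thinning of a binary vessel volume.

    A light morphological closing bridges 1-voxel gaps before thinning
    (the classical dilate-then-thin sequence); the result is a boolean
    single-voxel-wide skeleton.
    """
    binary = np.asarray(binary)
    vals = np.unique(binary)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("input volume must be binary (values 0/1)")
    if binary.ndim != 3:
        raise ValueError("expected a 3D volume")
    closed = ndimage.binary_closing(binary.astype(bool), structure=np.ones((3, 3, 3)))
    # closing can clip single-voxel extremities; keep original voxels
    closed |= binary.astype(bool)
    return skeletonize(closed).astype(bool)


# -- skeleton graph machinery ----------------------------------------------


def _adjacency(coords: np.ndarray):
    """26-neighbor adjacency lists over skeleton voxels."""
    index = {tuple(c): i for i, c in enumerate(coords)}
    nbrs = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in _OFFSETS:
            j = index.get(tuple(c + off))
            if j is not None:
                nbrs[i].append(j)
    return nbrs


def _order_path(members: set, nbrs) -> list:
    """Order a degree-<=2 connected voxel set into a path (or cycle)."""
    members = set(members)
    ends = [i for i in members if sum(1 for j in nbrs[i] if j in members) <= 1]
    start = ends[0] if ends else next(iter(members))
    path = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [j for j in nbrs[cur] if j in members and j not in seen]
        if not nxt:
            break
        cur = nxt[0]
        path.append(cur)
        seen.add(cur)
    return path


def _path_length(coords: np.ndarray, path: list, voxel_um: float) -> float:
    if len(path) < 2:
        return 0.0
    pts = coords[path].astype(float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum() * voxel_um)


def identify_segments(
    skeleton: np.ndarray,
    spur_threshold_um: float = 5.0,
    *,
    voxel_um: float = 1.0,
    binary: np.ndarray | None = None,
    node_merge_um: float = 2.0,
    source_stack_id: str | None = None,
) -> list[CapillarySegment]:
    """Enumerate capillary segments from a skeleton volume.

    Nodes are skeleton voxels with >= 3 skeleton neighbors; adjacent node
    voxels (within ``node_merge_um``) are clustered into one bifurcation.
    Terminal branches shorter than ``spur_threshold_um`` that hang off a
    node are treated as centerline artifacts and removed, and nodes left
    with exactly two branches are dissolved so the branches merge.  When
    the originating ``binary`` volume is given, each segment's mean
    radius is read off its distance transform.
    """
    skeleton = np.asarray(skeleton).astype(bool)
    coords = np.argwhere(skeleton)
    if coords.shape[0] == 0:
        return []
    nbrs = _adjacency(coords)
    deg = np.array([len(n) for n in nbrs])

    node_voxels = set(np.flatnonzero(deg >= 3))

    # Cluster node voxels: adjacency plus proximity within node_merge_um.
    cluster_id = {}
    clusters: list[set] = []
    for i in sorted(node_voxels):
        if i in cluster_id:
            continue
        comp = {i}
        queue = [i]
        while queue:
            k = queue.pop()
            for j in nbrs[k]:
                if j in node_voxels and j not in comp:
                    comp.add(j)
                    queue.append(j)
        for k in comp:
            cluster_id[k] = len(clusters)
        clusters.append(comp)
    if len(clusters) > 1 and node_merge_um > 0:
        # merge clusters whose member voxels are within node_merge_um
        centers = [coords[list(c)].astype(float) for c in clusters]
        merged = list(range(len(clusters)))

        def find(a):
            while merged[a] != a:
                merged[a] = merged[merged[a]]
                a = merged[a]
            return a

        for a in range(len(clusters)):
            ta = cKDTree(centers[a])
            for b in range(a + 1, len(clusters)):
                if find(a) == find(b):
                    continue
                d, _ = ta.query(centers[b], k=1)
                if d.min() * voxel_um <= node_merge_um:
                    merged[find(b)] = find(a)
        remap = {}
        new_clusters = []
        for a in range(len(clusters)):
            r = find(a)
            if r not in remap:
                remap[r] = len(new_clusters)
                new_clusters.append(set())
            new_clusters[remap[r]] |= clusters[a]
        clusters = new_clusters
        cluster_id = {i: ci for ci, c in enumerate(clusters) for i in c}

    # Branch components: skeleton minus node voxels.
    branch_members = set(range(len(coords))) - node_voxels
    branches = []  # dict(path=list, ends=(cluster or None, cluster or None))
    seen = set()
    for i in branch_members:
        if i in seen:
            continue
        comp = {i}
        queue = [i]
        while queue:
            k = queue.pop()
            for j in nbrs[k]:
                if j in branch_members and j not in comp:
                    comp.add(j)
                    queue.append(j)
        seen |= comp
        path = _order_path(comp, nbrs)
        end_clusters = []
        for end in (path[0], path[-1]):
            attached = {cluster_id[j] for j in nbrs[end] if j in cluster_id}
            end_clusters.append(min(attached) if attached else None)
        branches.append({"path": path, "ends": tuple(end_clusters)})

    # Spur pruning + dissolution of 2-branch nodes, to a fixed point.
    def attached_counts():
        counts = {ci: [] for ci in range(len(clusters))}
        for bi, br in enumerate(branches):
            for e in br["ends"]:
                if e is not None:
                    counts[e].append(bi)
        return counts

    changed = True
    while changed:
        changed = False
        # remove spurs: terminal branches, attached at exactly one end,
        # shorter than the threshold
        keep = []
        for br in branches:
            e0, e1 = br["ends"]
            is_spur = (
                (e0 is None) != (e1 is None)
                and _path_length(coords, br["path"], voxel_um) < spur_threshold_um
            )
            if is_spur:
                changed = True
            else:
                keep.append(br)
        branches = keep
        # dissolve clusters now touching exactly two branch ends
        counts = attached_counts()
        for ci, bis in counts.items():
            ends_at = [
                (bi, e)
                for bi in set(bis)
                for e, c in enumerate(branches[bi]["ends"])
                if c == ci
            ]
            if len(ends_at) != 2:
                continue
            (b0, e0), (b1, e1) = ends_at
            if b0 == b1:
                continue  # loop closing on one node: keep the node
            cl_path = _order_path(clusters[ci], nbrs)
            p0 = branches[b0]["path"] if e0 == 1 else branches[b0]["path"][::-1]
            p1 = branches[b1]["path"] if e1 == 0 else branches[b1]["path"][::-1]
            # orient the cluster path from p0's end toward p1's start
            if cl_path and np.linalg.norm(
                coords[cl_path[0]] - coords[p0[-1]]
            ) > np.linalg.norm(coords[cl_path[-1]] - coords[p0[-1]]):
                cl_path = cl_path[::-1]
            merged_path = p0 + cl_path + p1
            new_ends = (
                branches[b0]["ends"][0] if e0 == 1 else branches[b0]["ends"][1],
                branches[b1]["ends"][1] if e1 == 0 else branches[b1]["ends"][0],
            )
            newbr = {"path": merged_path, "ends": new_ends}
            for bi in sorted({b0, b1}, reverse=True):
                branches.pop(bi)
            branches.append(newbr)
            changed = True
            break  # cluster indices stale; recompute

    # Emit segments.
    dt = None
    if binary is not None:
        dt = ndimage.distance_transform_edt(np.asarray(binary).astype(bool))
    segments = []
    for si, br in enumerate(branches):
        path = br["path"]
        pts = coords[path]
        radius = float(dt[tuple(pts.T)].mean() * voxel_um) if dt is not None else None
        lo = pts.min(axis=0)
        hi = pts.max(axis=0) + 1
        segments.append(
            CapillarySegment(
                id=f"seg{si:05d}",
                centerline_vox=pts,
                endpoints=br["ends"],
                length_um=_path_length(coords, path, voxel_um),
                radius_um=radius,
                source_stack_id=source_stack_id,
                bbox=(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2]),
            )
        )
    return segments


def segments_to_skeleton(segments, shape) -> np.ndarray:
    """Paint segment centerlines back into a boolean volume."""
    vol = np.zeros(shape, dtype=bool)
    for s in segments:
        vol[tuple(s.centerline_vox.T)] = True
    return vol


# --------------------------------------------------------------------------


def _normalize(sub: np.ndarray) -> np.ndarray:
    lo, hi = float(sub.min()), float(sub.max())
    if hi - lo < 1e-12:
        return np.full_like(sub, 0.5, dtype=np.float32)
    return ((sub - lo) / (hi - lo)).astype(np.float32)


def make_crop_tasks(
    segments,
    stack,
    margin_um: float = 5.0,
    dilation_radius: int = 3,
) -> list[CropTask]:
    """Cut an annotation crop around each segment.

    Each crop is centered on its segment (bbox plus ``margin_um``),
    min-max normalized to span [0, 1] (constant crops map to midscale
    0.5), and carries a per-plane outline: the boundary of the
    centerline dilated by ``dilation_radius`` voxels in-plane
    (``dilation_radius=0`` leaves the centerline trace itself).
    Segments falling outside the stack are skipped with a warning.
    """
    shape = np.array(stack.data.shape[2:])
    margin = int(round(margin_um / stack.dz))
    tasks = []
    for seg in segments:
        pts = np.asarray(seg.centerline_vox)
        lo = pts.min(axis=0) - margin
        hi = pts.max(axis=0) + margin + 1
        if np.any(hi <= 0) or np.any(lo >= shape):
            logger.warning("segment %s lies outside the stack; skipped", seg.id)
            continue
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        sub = stack.data[:, :, lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        sub = _normalize(sub)
        local = pts - lo
        inside = np.all((local >= 0) & (local < (hi - lo)), axis=1)
        local = local[inside]
        outlines = {}
        crop_yx = tuple((hi - lo)[1:])
        for z in np.unique(local[:, 0]):
            plane = np.zeros(crop_yx, dtype=bool)
            zpts = local[local[:, 0] == z]
            plane[zpts[:, 1], zpts[:, 2]] = True
            if dilation_radius > 0:
                yy, xx = np.ogrid[
                    -dilation_radius : dilation_radius + 1,
                    -dilation_radius : dilation_radius + 1,
                ]
                disk = yy**2 + xx**2 <= dilation_radius**2
                dil = ndimage.binary_dilation(plane, structure=disk)
                boundary = dil & ~ndimage.binary_erosion(dil)
            else:
                boundary = plane
            outlines[int(z)] = np.argwhere(boundary)
        tasks.append(
            CropTask(
                segment_id=seg.id,
                substack=sub,
                outlines=outlines,
                bbox=(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2]),
                centerline_crop=local,
            )
        )
    return tasks
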