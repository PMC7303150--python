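"""Centerline extraction, segment identification, crop tasks."""

import numpy as np
import pytest

from stallflow import vesselseg as vs
from stallflow.synthgen import render_single_capillary

from conftest import paint_tube


def oracle_segment_count(skeleton):
    """Independent brute-force count: contract degree-2 chains on the
    voxel graph and count edges between junction/terminal vertices."""
    import networkx as nx

    coords = [tuple(c) for c in np.argwhere(skeleton)]
    cs = set(coords)
    g = nx.Graph()
    g.add_nodes_from(coords)
    for c in coords:
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dz, dy, dx) == (0, 0, 0):
                        continue
                    nb = (c[0] + dz, c[1] + dy, c[2] + dx)
                    if nb in cs:
                        g.add_edge(c, nb)
    junction = {c for c in coords if g.degree(c) >= 3}
    h = g.copy()
    h.remove_nodes_from(junction)
    return sum(1 for comp in nx.connected_components(h) if len(comp) > 0)


class TestMasking:
    def test_identity_mask(self):
        stack, _ = render_single_capillary("none", seed=1, stalled=False, speed_um_s=100)
        out = vs.mask_surface_vessels(stack, np.ones(stack.data.shape[2:], np.uint8))
        assert np.array_equal(out.data, stack.data)

    def test_zero_mask_removes_everything(self):
        stack, _ = render_single_capillary("none", seed=1, stalled=False, speed_um_s=100)
        out = vs.mask_surface_vessels(stack, np.zeros(stack.data.shape[2:], np.uint8))
        assert out.data.max() == 0
        skel = vs.extract_centerlines((out.data[0, 0] > 50).astype(np.uint8))
        assert vs.identify_segments(skel) == []

    def test_masking_out_a_vessel_removes_its_segment(self):
        """Top-planes mask removes a surface vessel from the segment table."""
        vol = np.zeros((24, 30, 40), np.uint8)
        paint_tube(vol, (4, 15, 2), (4, 15, 37), 2)   # 'surface' vessel
        paint_tube(vol, (17, 15, 2), (17, 15, 37), 2)  # deep vessel
        before = vs.identify_segments(vs.extract_centerlines(vol))
        mask = np.ones_like(vol)
        mask[:9] = 0
        after = vs.identify_segments(vs.extract_centerlines(vol * mask))
        assert len(before) == 2
        assert len(after) == 1

    def test_shape_mismatch_names_both_shapes(self):
        stack, _ = render_single_capillary("none", seed=1, stalled=False, speed_um_s=100)
        with pytest.raises(ValueError, match=r"\(1, 1, 1\)"):
            vs.mask_surface_vessels(stack, np.ones((1, 1, 1)))


class TestCenterlines:
    def test_straight_tube_thins_to_line(self):
        vol = np.zeros((20, 20, 40), np.uint8)
        vol[8:13, 8:13, 2:38] = 1  # 5-voxel-thick tube along x
        sk = vs.extract_centerlines(vol)
        xs = np.argwhere(sk)[:, 2]
        assert abs(xs.min() - 2) <= 2 and abs(xs.max() - 37) <= 2
        segs = vs.identify_segments(sk)
        assert len(segs) == 1

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            vs.extract_centerlines(np.full((5, 5, 5), 2.0))

    def test_loop_preserves_one_cycle(self):
        """Thinning a torus keeps exactly one cycle (homotopy)."""
        vol = np.zeros((15, 40, 40), np.uint8)
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in vol.shape], indexing="ij")
        rr = np.sqrt((yy - 20.0) ** 2 + (xx - 20.0) ** 2)
        vol[np.sqrt((rr - 12) ** 2 + (zz - 7.0) ** 2) <= 2.5] = 1
        sk = vs.extract_centerlines(vol)
        coords = np.argwhere(sk)
        nbrs = vs._adjacency(coords)
        edges = sum(len(n) for n in nbrs) // 2
        assert edges - len(coords) + 1 == 1  # E - V + C with C = 1


class TestSegments:
    def test_y_junction_three_segments_one_node(self, y_junction_volume):
        sk = vs.extract_centerlines(y_junction_volume)
        segs = vs.identify_segments(sk)
        assert len(segs) == 3
        assert len(segs) == oracle_segment_count(sk)
        clusters = {e for s in segs for e in s.endpoints if e is not None}
        assert len(clusters) == 1  # all three meet at the same node

    def test_spur_removed_and_residual_branches_merge(self):
        """A short spur off a straight vessel prunes away, leaving 1 segment."""
        vol = np.zeros((20, 30, 40), np.uint8)
        paint_tube(vol, (10, 15, 2), (10, 15, 37), 2)
        paint_tube(vol, (10, 19, 20), (10, 21, 22), 1)  # ~4 µm spur
        sk = vs.extract_centerlines(vol)
        unpruned = vs.identify_segments(sk, spur_threshold_um=0.0)
        pruned = vs.identify_segments(sk, spur_threshold_um=5.0)
        assert len(unpruned) == 3
        assert len(pruned) == 1
        # merged segment spans close to the full vessel
        assert pruned[0].length_um > 28

    def test_empty_skeleton_gives_empty_list(self):
        assert vs.identify_segments(np.zeros((5, 5, 5), bool)) == []

    def test_idempotence_on_pruned_skeleton(self, y_junction_volume):
        sk = vs.extract_centerlines(y_junction_volume)
        segs = vs.identify_segments(sk, spur_threshold_um=5.0)
        sk2 = vs.segments_to_skeleton(segs, y_junction_volume.shape)
        segs2 = vs.identify_segments(sk2, spur_threshold_um=5.0)
        assert len(segs2) == len(segs)
        assert sorted(s.length_um for s in segs2) == pytest.approx(
            sorted(s.length_um for s in segs), abs=3.0
        )

    def test_skeleton_partition_is_conserved(self, y_junction_volume):
        """Segment voxels + node-cluster voxels partition the skeleton."""
        sk = vs.extract_centerlines(y_junction_volume)
        segs = vs.identify_segments(sk, spur_threshold_um=0.0)
        seg_voxels = set()
        for s in segs:
            for v in map(tuple, s.centerline_vox):
                assert v not in seg_voxels, "voxel assigned to two segments"
                seg_voxels.add(v)
        total = int(sk.sum())
        node_voxels = total - len(seg_voxels)
        assert node_voxels >= 0
        # node clusters stay small: within 2% of total length plus a
        # constant per-junction allowance
        assert node_voxels <= 0.02 * total + 9

    def test_radius_from_distance_transform(self):
        vol = np.zeros((20, 20, 40), np.uint8)
        vol[:, :, :] = 0
        paint_tube(vol, (10, 10, 3), (10, 10, 36), 3)
        sk = vs.extract_centerlines(vol)
        segs = vs.identify_segments(sk, binary=vol)
        assert len(segs) == 1
        assert segs[0].radius_um == pytest.approx(3.0, abs=0.8)


class TestCropTasks:
    def _stack_and_segments(self):
        stack, seg = render_single_capillary("none", seed=4, stalled=False, speed_um_s=200)
        binary = (stack.channel("plasma")[0] > 100).astype(np.uint8)
        sk = vs.extract_centerlines(binary)
        segs = vs.identify_segments(sk, binary=binary)
        return stack, segs

    def test_crops_contain_full_centerline_and_are_normalized(self):
        stack, segs = self._stack_and_segments()
        tasks = vs.make_crop_tasks(segs, stack)
        assert len(tasks) == len(segs) > 0
        for task in tasks:
            assert task.substack.min() == pytest.approx(0.0)
            assert task.substack.max() == pytest.approx(1.0)
            # containment: every centerline voxel inside the crop
            z0, z1, y0, y1, x0, x1 = task.bbox
            for s in segs:
                if s.id != task.segment_id:
                    continue
                assert np.all(s.centerline_vox >= [z0, y0, x0])
                assert np.all(s.centerline_vox < [z1, y1, x1])

    def test_outline_encloses_centerline(self):
        stack, segs = self._stack_and_segments()
        (task,) = vs.make_crop_tasks(segs[:1], stack, dilation_radius=3)
        for z in np.unique(task.centerline_crop[:, 0]):
            assert int(z) in task.outlines
            outline = task.outlines[int(z)]
            pts = task.centerline_crop[task.centerline_crop[:, 0] == z][:, 1:]
            # outline voxels surround the centerline: every centerline
            # voxel is strictly inside the outline's bounding box
            assert pts[:, 0].min() > outline[:, 0].min()
            assert pts[:, 0].max() < outline[:, 0].max()
            assert pts[:, 1].min() > outline[:, 1].min()
            assert pts[:, 1].max() < outline[:, 1].max()

    def test_zero_dilation_outline_is_centerline(self):
        stack, segs = self._stack_and_segments()
        (task,) = vs.make_crop_tasks(segs[:1], stack, dilation_radius=0)
        for z in np.unique(task.centerline_crop[:, 0]):
            pts = {tuple(p) for p in task.centerline_crop[task.centerline_crop[:, 0] == z][:, 1:]}
            assert {tuple(p) for p in task.outlines[int(z)]} == pts

    def test_constant_crop_normalizes_to_midscale(self):
        from stallflow.vesselseg import _normalize

        out = _normalize(np.full((2, 3, 4, 4, 4), 7.0))
        assert np.all(out == 0.5)

    def test_out_of_bounds_segment_skipped(self, caplog):
        stack, segs = self._stack_and_segments()
        far = vs.CapillarySegment(
            id="far",
            centerline_vox=segs[0].centerline_vox + 10000,
            endpoints=(None, None),
            length_um=segs[0].length_um,
        )
        tasks = vs.make_crop_tasks([far], stack)
        assert tasks == []
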