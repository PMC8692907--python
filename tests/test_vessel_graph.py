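import numpy as np
import pytest
from skimage.draw import line

from vasoquant.segmentation import VesselMask
from vasoquant.vessel_graph import (
    skeletonize_mask,
    build_graph,
    extract_edges,
    overlay_labels,
)
from vasoquant.phantom import PhantomSpec, generate_phantom
from conftest import bar_mask


def vmask(m, px=5.0):
    return VesselMask(mask=m, pixel_size_um=px, method="truth")


def thick_line(shape, p0, p1, half=2):
    m = np.zeros(shape, dtype=bool)
    rr, cc = line(*p0, *p1)
    for dy in range(-half, half + 1):
        for dx in range(-half, half + 1):
            m[np.clip(rr + dy, 0, shape[0] - 1), np.clip(cc + dx, 0, shape[1] - 1)] = True
    return m


class TestSkeletonize:
    def test_bar_gives_single_midline(self):
        m = bar_mask()  # 5 px wide, 60 px long
        sk = skeletonize_mask(vmask(m))
        assert sk.sum() == pytest.approx(60, abs=8)  # length - O(width)
        ys = np.nonzero(sk)[0]
        assert np.all(np.abs(ys - 30) <= 1)  # on the midline

    def test_empty_mask(self):
        sk = skeletonize_mask(vmask(np.zeros((20, 20), dtype=bool)))
        assert not sk.any()

    def test_component_count_preserved(self, rng):
        from scipy import ndimage

        m = np.zeros((100, 100), dtype=bool)
        m[10:15, 5:95] = True
        m[40:45, 5:95] = True
        m[70:90, 48:53] = True
        sk = skeletonize_mask(vmask(m))
        s8 = np.ones((3, 3))
        assert ndimage.label(sk, s8)[1] == ndimage.label(m, s8)[1]


class TestBuildGraph:
    def test_straight_bar(self):
        m = bar_mask()
        g = build_graph(skeletonize_mask(vmask(m)), vmask(m))
        assert len(g.segments) == 1
        assert len(g.endpoints) == 2
        assert len(g.branch_nodes) == 0

    def test_plus_sign_single_degree4_node(self):
        m = np.zeros((80, 80), dtype=bool)
        m[38:43, 10:70] = True
        m[10:70, 38:43] = True
        g = build_graph(skeletonize_mask(vmask(m)), vmask(m), prune_len_um=0.0)
        from scipy import ndimage

        assert ndimage.label(g.skeleton, np.ones((3, 3)))[1] == 1
        assert len(g.branch_nodes) == 1
        assert g.branch_nodes[0].degree == 4
        assert len(g.segments) == 4

    def test_y_topology(self):
        m = np.zeros((90, 90), dtype=bool)
        for end in [(5, 45), (85, 10), (85, 80)]:
            m |= thick_line((90, 90), (45, 45), end)
        g = build_graph(skeletonize_mask(vmask(m)), vmask(m), prune_len_um=25.0)
        assert len(g.segments) == 3
        assert len(g.branch_nodes) == 1
        assert len(g.endpoints) == 3

    def test_spur_pruned_back_to_bare_bar(self):
        m = bar_mask()
        m_spur = m.copy()
        m_spur[33:36, 40] = True  # 3-px spur, well under 22.5 µm at 5 µm/px
        g_bar = build_graph(skeletonize_mask(vmask(m)), vmask(m))
        g_spur = build_graph(skeletonize_mask(vmask(m_spur)), vmask(m_spur))
        assert len(g_spur.segments) == len(g_bar.segments) == 1
        assert len(g_spur.branch_nodes) == 0
        assert len(g_spur.endpoints) == 2

    def test_pruning_idempotent(self):
        m = thick_line((100, 100), (50, 5), (50, 95)) | thick_line(
            (100, 100), (50, 50), (60, 55), half=0
        )
        vm = vmask(m)
        g1 = build_graph(skeletonize_mask(vm), vm, prune_len_um=40.0)
        # re-derive from the already-pruned skeleton: nothing more to prune
        g2 = build_graph(g1.skeleton, vm, prune_len_um=40.0)
        assert len(g2.segments) == len(g1.segments)
        assert len(g2.nodes) == len(g1.nodes)

    def test_partition_property(self):
        # segment pixels + branch-cluster pixels = skeleton pixels
        m = np.zeros((80, 80), dtype=bool)
        m[38:43, 10:70] = True
        m[10:70, 38:43] = True
        vm = vmask(m)
        g = build_graph(skeletonize_mask(vm), vm, prune_len_um=0.0)
        seg_px = set()
        for s in g.segments:
            seg_px.update(map(tuple, s.path.tolist()))
        node_px = set()
        for n in g.branch_nodes:
            node_px.update(n.pixels)
        assert not seg_px & node_px
        assert len(seg_px) + len(node_px) == g.skeleton.sum()

    def test_disjoint_vessel_count_exact(self):
        spec = PhantomSpec(
            n_vessels=6, layout="parallel", fixed_widths_um=(20.0, 30.0),
            pixel_size_um=5.0, snr=0.0, seed=1,
        )
        img, truth = generate_phantom(spec)
        vm = truth.as_mask()
        g = build_graph(skeletonize_mask(vm), vm)
        assert len(g.metric_segments) == 6

    def test_radii_match_bar_half_width(self):
        m = bar_mask()  # width 5 px at 5 µm/px -> radius 12.5 µm
        vm = vmask(m)
        g = build_graph(skeletonize_mask(vm), vm)
        radii = g.segments[0].radii_um
        mid = radii[5:-5]  # away from end caps
        assert np.all(np.abs(mid - 12.5) <= 5.0)  # within one pixel

    def test_segment_length_is_path_arc_length(self):
        m = bar_mask()
        vm = vmask(m)
        g = build_graph(skeletonize_mask(vm), vm)
        s = g.segments[0]
        steps = np.diff(s.path.astype(float), axis=0)
        expected = np.hypot(steps[:, 0], steps[:, 1]).sum() * 5.0
        assert s.length_um == pytest.approx(expected)

    def test_graph_serializes_to_json(self):
        import json

        m = bar_mask()
        vm = vmask(m)
        g = build_graph(skeletonize_mask(vm), vm)
        payload = json.dumps(g.to_dict())
        assert "segments" in json.loads(payload)

    def test_overlay_label_values(self, bar_vessel_mask):
        g = build_graph(skeletonize_mask(bar_vessel_mask), bar_vessel_mask)
        lab = overlay_labels(g, bar_vessel_mask)
        assert set(np.unique(lab)) <= {0, 1, 2, 3}
        assert (lab == 1).any() and (lab == 2).any()


class TestExtractEdges:
    def test_solid_square_perimeter(self):
        m = np.zeros((10, 10), dtype=bool)
        m[:] = True
        edges = extract_edges(vmask(m))
        assert edges.sum() == 36

    def test_empty(self):
        assert not extract_edges(vmask(np.zeros((5, 5), dtype=bool))).any()

    def test_matches_per_pixel_oracle(self, rng):
        m = rng.random((24, 24)) > 0.6
        edges = extract_edges(vmask(m))
        h, w = m.shape
        for i in range(h):
            for j in range(w):
                if not m[i, j]:
                    assert not edges[i, j]
                    continue
                nbrs = []
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    y, x = i + di, j + dj
                    nbrs.append(m[y, x] if 0 <= y < h and 0 <= x < w else False)
                assert edges[i, j] == (not all(nbrs))
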