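import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

import astrotile as at
from astrotile.graph import NonThinSkeletonError, _square_blocks

from oracles import classify_pixels


def _mask_from_pixels(pixels, shape=(20, 20)):
    m = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        m[r, c] = True
    return m


class TestBinarize:
    def test_strict_inequality_on_zero_threshold(self):
        img = np.zeros((5, 5))
        assert not at.binarize(img, method="fixed", threshold=0).any()

    def test_otsu_separates_bimodal_values(self):
        img = np.full((10, 10), 10.0)
        img[3:6, 3:6] = 200.0
        mask = at.binarize(img, method="otsu")
        assert np.array_equal(mask, img == 200.0)

    def test_otsu_rejects_constant_image(self):
        with pytest.raises(ValueError, match="constant"):
            at.binarize(np.full((4, 4), 7.0), method="otsu")

    def test_fixed_requires_threshold(self):
        with pytest.raises(ValueError):
            at.binarize(np.zeros((3, 3)), method="fixed")

    def test_rendered_culture_mask_equals_labels(self, sparse_culture):
        img, labels = at.render_image(sparse_culture, line_width=1, noise_sd=0.0)
        mask = at.binarize(img, method="fixed", threshold=0)
        assert np.array_equal(mask, labels > 0)


class TestSkeletonize:
    def test_wide_bar_thins_to_single_path(self):
        m = np.zeros((9, 40), dtype=bool)
        m[3:6, 5:35] = True
        s = at.skeletonize_mask(m)
        sg = at.extract_graph(s)
        assert sg.n_edges == 1
        assert sg.node_counts()["endpoint"] == 2
        from scipy import ndimage

        assert ndimage.label(s, np.ones((3, 3)))[1] == 1

    def test_empty_mask_stays_empty(self):
        assert not at.skeletonize_mask(np.zeros((6, 6), dtype=bool)).any()

    def test_plus_sign_yields_one_junction_four_endpoints(self):
        m = np.zeros((31, 31), dtype=bool)
        m[14:17, 3:28] = True
        m[3:28, 14:17] = True
        sg = at.extract_graph(at.skeletonize_mask(m))
        counts = sg.node_counts()
        assert counts["junction"] == 1
        assert counts["endpoint"] == 4
        assert sg.n_edges == 4

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st_h.integers(0, 2**49 - 1))
    def test_idempotence_on_random_masks(self, bits):
        m = np.array([(bits >> i) & 1 for i in range(49)], dtype=bool).reshape(7, 7)
        s1 = at.skeletonize_mask(m)
        s2 = at.skeletonize_mask(s1)
        assert np.array_equal(s1, s2)
        assert not (s1 & ~m).any()  # skeleton subset of mask


class TestExtractGraph:
    def test_straight_path_two_endpoints_one_edge(self):
        m = _mask_from_pixels([(5, c) for c in range(3, 13)])
        sg = at.extract_graph(m)
        assert sg.node_counts()["endpoint"] == 2
        assert sg.n_edges == 1
        (length,) = [d["length"] for _, _, d in sg.graph.edges(data=True)]
        assert length == pytest.approx(9.0)

    def test_diagonal_length_convention(self):
        m = _mask_from_pixels([(i, i) for i in range(2, 12)], shape=(14, 14))
        sg = at.extract_graph(m)
        (length,) = [d["length"] for _, _, d in sg.graph.edges(data=True)]
        assert length == pytest.approx(9 * np.sqrt(2))

    def test_y_shape_matches_hand_enumeration(self):
        # stem: 5 orthogonal steps down to the junction; two diagonal arms
        # of 4 steps each
        j = (10, 10)
        stem = [(10 + i, 10) for i in range(6)]
        arm1 = [(10 - i, 10 - i) for i in range(1, 5)]
        arm2 = [(10 - i, 10 + i) for i in range(1, 5)]
        m = _mask_from_pixels(stem + arm1 + arm2, shape=(20, 20))
        sg = at.extract_graph(m)
        counts = sg.node_counts()
        assert counts["junction"] == 1
        assert counts["endpoint"] == 3
        assert sg.n_edges == 3
        lengths = sorted(d["length"] for _, _, d in sg.graph.edges(data=True))
        assert lengths == pytest.approx(sorted([4 * np.sqrt(2), 4 * np.sqrt(2), 5.0]))
        total = sum(lengths)
        assert total == pytest.approx(5.0 + 8 * np.sqrt(2))

    def test_isolated_pixel_is_single_node_component(self):
        sg = at.extract_graph(_mask_from_pixels([(4, 4)], shape=(8, 8)))
        assert sg.n_nodes == 1
        assert sg.n_edges == 0

    def test_solid_block_rejected(self):
        m = np.zeros((6, 6), dtype=bool)
        m[1:5, 1:5] = True
        with pytest.raises(NonThinSkeletonError):
            at.extract_graph(m)

    def test_ring_becomes_self_loop(self):
        # diamond ring of path pixels: every pixel has exactly 2 neighbours
        pix = [(1, 3), (2, 4), (3, 5), (4, 4), (5, 3), (4, 2), (3, 1), (2, 2)]
        sg = at.extract_graph(_mask_from_pixels(pix, shape=(8, 8)))
        assert sg.n_edges == 1
        (u, v) = list(sg.graph.edges())[0]
        assert u == v
        (length,) = [d["length"] for _, _, d in sg.graph.edges(data=True)]
        assert length == pytest.approx(8 * np.sqrt(2))

    def test_pixel_conservation_on_rendered_culture(self, sparse_culture):
        img, _ = at.render_image(sparse_culture, line_width=3, noise_sd=0.0)
        skel = at.skeletonize_mask(at.binarize(img, method="fixed", threshold=50))
        sg = at.extract_graph(skel)
        node_pix = set()
        for _, d in sg.graph.nodes(data=True):
            node_pix |= set(map(tuple, d["pixels"]))
        interior = []
        for _, _, d in sg.graph.edges(data=True):
            interior += [tuple(map(int, p)) for p in d["points"][1:-1]]
        skel_pix = {tuple(p) for p in np.argwhere(skel)}
        assert node_pix <= skel_pix
        assert set(interior) <= skel_pix
        assert node_pix | set(interior) == skel_pix
        # every interior pixel belongs to exactly one edge
        assert len(interior) == len(set(interior))
        assert not (set(interior) & node_pix)

    def test_counts_match_bruteforce_on_random_masks(self, rng):
        for _ in range(500):
            side = int(rng.integers(4, 8))
            m = rng.random((side, side)) < rng.uniform(0.2, 0.8)
            skel = at.skeletonize_mask(m)
            sg = at.extract_graph(skel)
            oracle = classify_pixels(skel)
            counts = sg.node_counts()
            assert counts["endpoint"] == oracle["endpoints"], skel.astype(int)
            assert counts["junction"] == oracle["junction_clusters"], skel.astype(int)
            assert sg.n_edges == oracle["edges"], skel.astype(int)


class TestAssignCells:
    def test_single_soma_claims_everything(self):
        m = _mask_from_pixels([(5, c) for c in range(3, 13)])
        sg = at.extract_graph(m)
        asg = at.assign_cells(sg, [(5, 3)])
        assert len(asg.unassigned) == 0
        assert asg.cells[0].n_branches == sg.n_edges

    def test_two_components_split_by_membership(self):
        m = _mask_from_pixels(
            [(2, c) for c in range(1, 8)] + [(10, c) for c in range(1, 8)],
            shape=(14, 10),
        )
        sg = at.extract_graph(m)
        asg = at.assign_cells(sg, [(2, 1), (10, 1)])
        assert asg.cells[0].n_branches == 1
        assert asg.cells[1].n_branches == 1
        assert not asg.unassigned

    def test_far_soma_rejected(self):
        sg = at.extract_graph(_mask_from_pixels([(5, c) for c in range(3, 13)]))
        with pytest.raises(ValueError, match="from the skeleton"):
            at.assign_cells(sg, [(15, 3)])

    def test_coincident_somata_rejected(self):
        sg = at.extract_graph(_mask_from_pixels([(5, c) for c in range(3, 13)]))
        with pytest.raises(ValueError, match="same skeleton node"):
            at.assign_cells(sg, [(5, 3), (6, 3)])

    def test_ownership_matches_ground_truth_labels(self, sparse_culture):
        img, labels = at.render_image(sparse_culture, line_width=3, noise_sd=0.0)
        skel = at.skeletonize_mask(at.binarize(img, method="fixed", threshold=50))
        sg = at.extract_graph(skel)
        at.prune_short_terminals(sg, 3.0)
        asg = at.assign_cells(sg, sparse_culture.somata)
        good = total = 0.0
        for cell in asg.cells:
            want = cell.cell_id + 1
            for _, d in cell.branches():
                pix = d["points"].astype(int)
                owners = labels[pix[:, 0], pix[:, 1]]
                frac = np.mean((owners == want) | (owners == at.OVERLAP_LABEL))
                total += d["length"]
                if frac > 0.5:
                    good += d["length"]
        assert good / total >= 0.95
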