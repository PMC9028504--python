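import dataclasses

import numpy as np
import pytest

import astrotile as at
from astrotile.culture import DegenerateGrowthError, PlacementError

from oracles import leaf_delete, make_cell


def _free_params(**kw):
    base = dict(
        n_cells=1,
        field_size=(200, 200),
        soma_min_spacing=20.0,
        primaries_per_cell=5,
        step_length=2.0,
        angle_noise_sd=0.05,
        branch_prob=0.0,
        divergence_angle=1.2,
        avoid_radius=3.0,
        n_candidate_dirs=7,
        n_steps=10,
        repulsion=True,
        self_avoidance=True,
    )
    base.update(kw)
    return at.GrowthParams(**base)


class TestGrowth:
    def test_unbranched_growth_has_exact_lengths(self):
        c = at.generate_culture(_free_params(), seed=3)
        (cell,) = c.cells
        assert cell.n_branches == 5
        for _, d in cell.branches():
            assert d["length"] == pytest.approx(20.0)

    def test_same_seed_is_bit_identical(self, small_params):
        a = at.generate_culture(small_params, 42)
        b = at.generate_culture(small_params, 42)
        assert a.somata == b.somata
        for ca, cb in zip(a.cells, b.cells):
            ea = [d["points"] for _, d in ca.branches()]
            eb = [d["points"] for _, d in cb.branches()]
            assert len(ea) == len(eb)
            for pa, pb in zip(ea, eb):
                assert np.array_equal(pa, pb)

    def test_different_seeds_differ(self, small_params):
        a = at.generate_culture(small_params, 1)
        b = at.generate_culture(small_params, 2)
        assert a.somata != b.somata

    def test_soma_positions_respect_spacing(self, small_culture, small_params):
        pos = np.asarray(small_culture.somata)
        d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= small_params.soma_min_spacing

    def test_cell_roots_coincide_with_somata(self, small_culture):
        for cell, soma in zip(small_culture.cells, small_culture.somata):
            assert cell.soma_pos == pytest.approx(soma)

    def test_placement_failure_names_spacing(self):
        with pytest.raises(PlacementError, match="soma_min_spacing"):
            at.generate_culture(
                _free_params(n_cells=30, soma_min_spacing=150.0), seed=0
            )

    def test_all_tips_stalled_at_step_zero_errors(self):
        # field so small that every candidate is out of bounds
        with pytest.raises(DegenerateGrowthError):
            at.generate_culture(
                _free_params(field_size=(9, 9), soma_min_spacing=1.0, step_length=4.0),
                seed=0,
            )

    def test_repulsion_keeps_cells_apart(self, small_culture, small_params):
        from scipy.spatial import cKDTree

        pix = [c.pixels() for c in small_culture.cells]
        for i in range(len(pix)):
            for j in range(i + 1, len(pix)):
                d, _ = cKDTree(pix[j].astype(float)).query(pix[i].astype(float))
                # continuous clearance minus rasterization rounding
                assert d.min() >= small_params.avoid_radius - np.sqrt(2.0)

    def test_repulsion_lowers_violation_percentage(self):
        base = _free_params(
            n_cells=4,
            field_size=(220, 220),
            soma_min_spacing=70.0,
            branch_prob=0.2,
            angle_noise_sd=0.3,
            n_steps=45,
        )
        wins = 0
        n_pairs = 20
        for seed in range(n_pairs):
            von = at.detect_violations(
                at.generate_culture(base, seed).cells, 1
            ).summary["mean_violation_percentage"]
            voff = at.detect_violations(
                at.generate_culture(
                    dataclasses.replace(base, repulsion=False), seed
                ).cells,
                1,
            ).summary["mean_violation_percentage"]
            wins += von < voff
        from scipy.stats import binomtest

        p = binomtest(wins, n_pairs, 0.5, alternative="greater").pvalue
        assert p < 0.01

    def test_timecourse_snapshots_are_nested(self, small_params):
        snaps = at.generate_timecourse(small_params, 5, [20, 40, 60])
        lengths = [sum(c.total_length for c in snaps[s].cells) for s in (20, 40, 60)]
        assert lengths[0] < lengths[1] < lengths[2]


class TestRetraction:
    def _y_tree(self):
        return make_cell(
            0,
            (10.0, 10.0),
            [
                [(10.0, 10.0), (5.0, 10.0)],
                [(5.0, 10.0), (1.0, 6.0)],
                [(5.0, 10.0), (1.0, 14.0)],
            ],
        )

    def test_zero_probability_is_noop(self, small_culture):
        out = at.apply_retraction(
            small_culture, at.RetractionParams(terminal_prune_prob=0.0, n_rounds=3, exploration=False), 1
        )
        for a, b in zip(small_culture.cells, out.cells):
            assert a.n_branches == b.n_branches
            assert a.total_length == pytest.approx(b.total_length)

    def test_full_prune_matches_leaf_deletion_oracle(self, small_culture):
        for cell in small_culture.cells:
            k = at.branch_orders(cell).max_order
            culture_one = at.SyntheticCulture(
                cells=[cell],
                somata=[cell.soma_pos],
                provenance=small_culture.provenance,
                field_size=small_culture.field_size,
            )
            out = at.apply_retraction(
                culture_one,
                at.RetractionParams(terminal_prune_prob=1.0, n_rounds=k, exploration=False),
                0,
            )
            assert out.cells[0].n_branches == leaf_delete(cell, k) == 0
            assert out.cells[0].graph.number_of_nodes() == 1  # soma only

    def test_single_round_on_y_tree_keeps_stem(self):
        cell = self._y_tree()
        culture = at.SyntheticCulture([cell], [cell.soma_pos], {}, (20, 20))
        out = at.apply_retraction(
            culture, at.RetractionParams(terminal_prune_prob=1.0, n_rounds=1, exploration=False), 0
        )
        assert out.cells[0].n_branches == 1

    def test_exploration_off_never_increases_metrics(self, small_culture):
        out = at.apply_retraction(
            small_culture,
            at.RetractionParams(terminal_prune_prob=0.5, n_rounds=2, exploration=False),
            3,
        )
        for a, b in zip(small_culture.cells, out.cells):
            assert b.n_branches <= a.n_branches
            assert b.total_length <= a.total_length + 1e-9
            assert at.branch_orders(b).max_order <= at.branch_orders(a).max_order


class TestRender:
    def test_single_straight_branch_rasterizes_exactly(self):
        cell = make_cell(0, (5.0, 2.0), [[(5.0, 2.0), (5.0, 11.0)]])
        culture = at.SyntheticCulture([cell], [(5.0, 2.0)], {}, (20, 20))
        img, labels = at.render_image(culture, line_width=1, noise_sd=0.0)
        fg = np.argwhere(img > 0)
        assert {tuple(p) for p in fg} == {(5, c) for c in range(2, 12)}
        assert (labels[img > 0] == 1).all()

    def test_label_pixel_counts_match_ground_truth(self, small_culture):
        _, labels = at.render_image(small_culture, line_width=1, noise_sd=0.0)
        for cell in small_culture.cells:
            own = ((labels == cell.cell_id + 1) | (labels == at.OVERLAP_LABEL)).sum()
            assert own >= len(cell.pixels())  # overlap pixels included
        total = (labels > 0).sum()
        union = {tuple(p) for c in small_culture.cells for p in c.pixels()}
        assert total == len(union) or total <= len(union)

    def test_out_of_field_raises(self):
        cell = make_cell(0, (5.0, 5.0), [[(5.0, 5.0), (5.0, 30.0)]])
        culture = at.SyntheticCulture([cell], [(5.0, 5.0)], {}, (10, 10))
        with pytest.raises(ValueError, match="outside"):
            at.render_image(culture, line_width=1)


class TestMarkerTable:
    def test_identity_target_gives_near_zero_correlations(self):
        t = at.generate_marker_table(2000, target_corr=np.eye(4), seed=1)
        z = np.log(t[list(at.culture.DEFAULT_MARKERS)])
        r = np.corrcoef(z.to_numpy(), rowvar=False)
        off = r[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.06

    def test_target_correlation_recovered_on_gaussian_scores(self):
        t = at.generate_marker_table(2000, seed=2)
        z = np.log(t[list(at.culture.DEFAULT_MARKERS)])
        r = np.corrcoef(z.to_numpy(), rowvar=False)
        assert abs(r[0, 2] - 0.46) < 0.05  # GLAST-GAT3 analogue

    def test_marginals_match_requested_moments(self):
        t = at.generate_marker_table(20000, seed=3)
        x = t["GLAST"].to_numpy()
        assert x.min() > 0
        assert x.mean() == pytest.approx(100.0, rel=0.05)
        assert x.std() / x.mean() == pytest.approx(0.4, rel=0.1)

    def test_same_seed_identical(self):
        a = at.generate_marker_table(50, seed=9)
        b = at.generate_marker_table(50, seed=9)
        assert a.equals(b)

    def test_non_psd_matrix_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            at.generate_marker_table(10, target_corr=bad, markers=list("abc"),
                                     means=[1, 1, 1], cvs=[0.1, 0.1, 0.1])
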