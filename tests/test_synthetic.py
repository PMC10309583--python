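"""Generator determinism, placement statistics and the rendering model."""

import numpy as np
import pandas as pd
import pytest
from conftest import NOISELESS, small_spec

from mitomorph import (
    NeuronSpec,
    RenderConfig,
    generate_cohort,
    generate_neuron,
    render_stack,
)


def unbranched_spec(density=0.5, length_dist=("point", {"value_um": 0.3}), **kw):
    # short rods keep the packing load well below the 1D jamming limit, so
    # realized counts follow the Poisson draw
    kw.setdefault("mito_min_length_um", 0.1)  # geometry-only tests, no floor
    return NeuronSpec(
        max_branch_order=1,
        primary_dendrite_length_um=20.0,
        branch_prob_per_order=(0.0,),
        mito_linear_density_per_um=density,
        mito_length_dist=length_dist,
        **kw,
    )


class TestGenerateNeuron:
    def test_determinism(self):
        a = generate_neuron(small_spec(), seed=7)
        b = generate_neuron(small_spec(), seed=7)
        pd.testing.assert_frame_equal(a.mito_table, b.mito_table)
        assert a.tree.xy == b.tree.xy
        assert a.true_soma_fill_fraction == b.true_soma_fill_fraction

    def test_point_mass_lengths(self):
        g = generate_neuron(
            unbranched_spec(0.2, length_dist=("point", {"value_um": 2.5})), 3
        )
        assert len(g.mito_table) > 0
        assert (g.mito_table["length_um"] == 2.5).all()

    def test_single_order_placement(self):
        g = generate_neuron(unbranched_spec(), seed=7)
        assert (g.mito_table["order"] == 1).all()

    def test_mean_count_matches_poisson_expectation(self):
        """Density 0.5/um on a 20 um dendrite -> mean count within the
        Poisson CI of 10 over 100 seeds."""
        counts = [
            len(generate_neuron(unbranched_spec(), seed=s).mito_table)
            for s in range(100)
        ]
        se = np.sqrt(10.0 / 100)
        assert abs(np.mean(counts) - 10.0) < 3 * se

    def test_counts_conserved_across_branches(self):
        g = generate_neuron(small_spec(), seed=5)
        per_branch = g.mito_table.groupby("branch_id").size().sum()
        assert per_branch == len(g.mito_table)

    def test_scores_within_unit_interval(self):
        g = generate_neuron(small_spec(), seed=9)
        assert g.mito_table["score"].between(0, 1).all()

    def test_invalid_spec_names_field(self):
        with pytest.raises(ValueError, match="soma_mito_fill_fraction"):
            NeuronSpec(soma_mito_fill_fraction=0.0)
        with pytest.raises(ValueError, match="max_branch_order"):
            NeuronSpec(max_branch_order=0)

    def test_density_ratio_reflected_in_counts(self):
        """Group at 0.9/um vs 0.45/um -> ~2-fold mean count difference.

        Thin short rods keep even the dense group below packing saturation.
        """
        thin = dict(
            length_dist=("point", {"value_um": 0.2}),
            mito_diameter_um=0.2,
            mito_min_gap_um=0.15,
        )
        hi = [
            len(generate_neuron(unbranched_spec(0.9, **thin), s).mito_table)
            for s in range(50)
        ]
        lo = [
            len(generate_neuron(unbranched_spec(0.45, **thin), 1000 + s).mito_table)
            for s in range(50)
        ]
        assert np.mean(hi) / np.mean(lo) == pytest.approx(2.0, rel=0.2)


class TestRenderStack:
    def test_render_determinism(self):
        geom = generate_neuron(small_spec(), seed=4)
        s1, _ = render_stack(geom, RenderConfig(seed=4))
        s2, _ = render_stack(geom, RenderConfig(seed=4))
        assert np.array_equal(s1.voxels, s2.voxels)

    def test_noise_free_support_matches_truth(self, noiseless_cell):
        geom, stack, truth = noiseless_cell
        from mitomorph import max_project

        img, _ = max_project(stack, "mito")
        fg = img > 0
        # mito signal support = PSF-dilated ground-truth rods: every truth
        # pixel is lit and nothing lights up far from the truth
        assert (img[truth.mito_mask] > 0).all()
        from scipy import ndimage

        dilated = ndimage.binary_dilation(truth.mito_mask, iterations=6)
        assert not (fg & ~dilated).any()

    def test_background_level_recovered_in_empty_corner(self, noisy_cell):
        geom, stack, truth = noisy_cell
        # single z-plane far from the cell: mean over >= 1000 voxels
        corner = stack.voxels[1, 0, -40:, -40:].astype(float)
        assert corner.size >= 1000
        se = corner.std() / np.sqrt(corner.size)
        # expected local background includes the deliberate x-gradient
        w = stack.voxels.shape[3]
        cols = np.arange(w - 40, w)
        expected = (10.0 + 2.0 * (cols / (w - 1) - 0.5)).mean()
        assert abs(corner.mean() - expected) < max(3 * se, 0.3)

    def test_true_occupancy_matches_analytic_rod_area(self):
        """Noise-free rasterized area agrees with capsule-area arithmetic to
        within rasterization error (2%, aggregated over several cells)."""
        spec = unbranched_spec(0.4, ("point", {"value_um": 2.0}))
        d = spec.mito_diameter_um
        # capsule of tip-to-tip extent 2.0 um and width d
        per_rod = (2.0 - d) * d + np.pi * (d / 2) ** 2
        raster = analytic = 0.0
        for seed in range(5):
            geom = generate_neuron(spec, seed=seed)
            _, truth = render_stack(geom, RenderConfig(seed=seed, **NOISELESS))
            analytic += len(geom.mito_table) * per_rod
            raster += truth.mito_dend_mask.sum() * truth.px_um**2
        assert raster == pytest.approx(analytic, rel=0.02)

    def test_voxel_budget_enforced(self):
        geom = generate_neuron(small_spec(), seed=2)
        with pytest.raises(ValueError, match="budget"):
            render_stack(geom, RenderConfig(max_voxels=1000))


class TestCohort:
    def test_counts_and_determinism(self, tmp_path):
        spec = {"a": small_spec(), "b": small_spec(mito_linear_density_per_um=0.12)}
        cfg = RenderConfig(seed=0)
        man1 = generate_cohort(3, spec, cfg, seed=5, out_dir=tmp_path / "d1")
        man2 = generate_cohort(3, spec, cfg, seed=5, out_dir=tmp_path / "d2")
        assert len(man1) == 6
        assert sorted(man1.group.unique()) == ["a", "b"]
        # byte-identical stacks across reruns with the same master seed
        for cell in man1.cell_id:
            b1 = (tmp_path / "d1" / cell / "stack.tif").read_bytes()
            b2 = (tmp_path / "d2" / cell / "stack.tif").read_bytes()
            assert b1 == b2

    def test_path_collision_rejected(self, tmp_path):
        spec = {"a": small_spec()}
        generate_cohort(1, spec, RenderConfig(), seed=1, out_dir=tmp_path / "d")
        with pytest.raises(FileExistsError):
            generate_cohort(1, spec, RenderConfig(), seed=1, out_dir=tmp_path / "d")

    def test_invalid_cell_count_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_cohort(0, {"a": small_spec()}, RenderConfig(), 1, tmp_path / "x")
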