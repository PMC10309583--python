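"""Background estimation, CTCF and CTMF."""

import numpy as np
import pytest

from mitomorph import (
    BackgroundEstimate,
    RegionOfInterest,
    background_mean,
    ctcf,
    ctmf,
)


def box(x, y, side):
    return RegionOfInterest(
        "box", [[x, y], [x + side, y], [x + side, y + side], [x, y + side]], "background"
    )


PX = 100.0  # nm/px -> a 5x5 um box is 50 px


class TestBackground:
    def test_constant_field(self):
        img = np.full((200, 200), 12.0)
        boxes = [box(10, 10, 50), box(100, 10, 50), box(10, 100, 50)]
        est = background_mean(img, boxes, PX)
        assert est.background_mean == pytest.approx(12.0)

    def test_average_of_three_box_means(self):
        img = np.zeros((200, 200))
        img[10:61, 10:61] = 10.0
        img[10:61, 100:151] = 12.0
        img[100:151, 10:61] = 14.0
        boxes = [box(10, 10, 50), box(100, 10, 50), box(10, 100, 50)]
        est = background_mean(img, boxes, PX)
        assert est.background_mean == pytest.approx(12.0, abs=0.2)

    def test_wrong_cardinality_rejected(self):
        img = np.zeros((100, 100))
        with pytest.raises(ValueError):
            background_mean(img, [box(5, 5, 50)], PX)

    def test_wrong_box_size_rejected(self):
        img = np.zeros((200, 200))
        with pytest.raises(ValueError):
            background_mean(img, [box(5, 5, 20), box(60, 5, 50), box(5, 60, 50)], PX)

    def test_synthetic_background_recovered(self, noisy_cell):
        geom, stack, truth = noisy_cell
        from mitomorph import max_project

        img, px = max_project(stack, "mito")
        est = background_mean(img.astype(float), truth.background_boxes, px)
        # max over 7 z-planes of Poisson+Gaussian noise biases the projection
        # upward relative to the per-plane mean; allow that offset
        assert est.background_mean >= 10.0 - 1.0
        assert est.background_mean <= 10.0 + 8.0


class TestCtcf:
    def bg(self, v):
        return BackgroundEstimate((v, v, v), float(v))

    def test_hand_computed_value(self):
        # integrated density 1000 over 50 px, background 2 -> 1000 - 100
        img = np.zeros((20, 20))
        mask = np.zeros((20, 20), dtype=bool)
        mask[:5, :10] = True
        img[mask] = 20.0
        res = ctcf(img, mask, self.bg(2.0))
        assert res.integrated_density == pytest.approx(1000.0)
        assert res.ctcf == pytest.approx(900.0)

    def test_zero_background_identity(self, rng):
        img = rng.uniform(0, 50, size=(30, 30))
        mask = rng.random((30, 30)) > 0.5
        res = ctcf(img, mask, self.bg(0.0))
        assert res.ctcf == res.integrated_density

    def test_exact_cancellation(self):
        img = np.full((15, 15), 7.5)
        mask = np.ones((15, 15), dtype=bool)
        res = ctcf(img, mask, self.bg(7.5))
        assert res.ctcf == pytest.approx(0.0, abs=1e-9)

    def test_linearity_in_image(self, rng):
        img = rng.uniform(0, 100, size=(25, 25))
        mask = rng.random((25, 25)) > 0.4
        a = 3.7
        r1 = ctcf(img, mask, self.bg(5.0))
        r2 = ctcf(a * img, mask, self.bg(a * 5.0))
        assert r2.ctcf == pytest.approx(a * r1.ctcf)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            ctcf(np.ones((5, 5)), np.zeros((5, 5), dtype=bool), self.bg(0.0))

    def test_negative_flagged_not_clipped(self):
        img = np.full((10, 10), 1.0)
        mask = np.ones((10, 10), dtype=bool)
        res = ctcf(img, mask, self.bg(2.0))
        assert res.ctcf < 0 and res.negative_flag


class TestCtmf:
    def bg(self, v):
        return BackgroundEstimate((v, v, v), float(v))

    def test_uniform_signal_closed_form(self):
        img = np.zeros((40, 40))
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:15, 5:25] = True
        img[mask] = 30.0
        res = ctmf(img, mask, self.bg(0.0), PX)
        # s per px / px-area: 30 / 0.01 um2 per px
        assert res.ctmf == pytest.approx(30.0 / 0.01)

    def test_mask_dilation_invariance_at_uniform_signal(self):
        img = np.zeros((40, 40))
        small = np.zeros((40, 40), dtype=bool)
        small[10:20, 10:20] = True
        big = np.zeros((40, 40), dtype=bool)
        big[5:25, 5:25] = True
        img[big] = 12.0
        r_small = ctmf(img, small, self.bg(0.0), PX)
        r_big = ctmf(img, big, self.bg(0.0), PX)
        assert r_small.ctmf == pytest.approx(r_big.ctmf)

    def test_synthetic_costain_recovery(self):
        """CTMF over the true mitochondrial mask of a noisy rendered co-stain
        channel recovers the generator's expected per-area intensity within
        10%."""
        from conftest import small_spec

        from mitomorph import RenderConfig, generate_neuron, max_project, render_stack

        spec = small_spec(costain_mean_intensity=120.0)
        geom = generate_neuron(spec, seed=21)
        stack, truth = render_stack(geom, RenderConfig(seed=21, include_costain=True))
        img, px = max_project(stack, "costain")
        est = background_mean(img.astype(float), truth.background_boxes, px)
        res = ctmf(img.astype(float), truth.mito_mask, est, px)
        expected = truth.true_costain_mean_px / (px / 1000.0) ** 2
        assert res.ctmf == pytest.approx(expected, rel=0.10)
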