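import numpy as np
import pytest

from contourfill.bcs import (
    BcsConfig,
    BoundaryMask,
    OrientedActivity,
    calibrate_lg_threshold,
    global_boundaries,
    lg_interaction,
    local_boundaries,
)
from contourfill.fcs_pathways import contrast_pathway


@pytest.fixture
def cfg():
    return BcsConfig()


def vertical_step(lo, hi, size=64):
    img = np.full((size, size), lo)
    img[:, size // 2 :] = hi
    return img


class TestLocalBoundaries:
    def test_vertical_step_gives_vertical_ridge(self, cfg):
        lbd = local_boundaries(contrast_pathway(vertical_step(0.0, 1.0)), cfg)
        assert lbd.v.max() > 0
        # ridge sits at the step
        assert abs(int(np.argmax(lbd.v[32])) - 32) <= 2
        # a pure vertical edge creates no horizontal-contour response
        assert lbd.h.max() <= 1e-12

    def test_half_contrast_ridge_strictly_weaker(self, cfg):
        full = local_boundaries(contrast_pathway(vertical_step(0.0, 1.0)), cfg)
        half = local_boundaries(contrast_pathway(vertical_step(0.0, 0.5)), cfg)
        assert 0 < half.v.max() < full.v.max()

    def test_uniform_field_silent(self, cfg):
        lbd = local_boundaries(contrast_pathway(np.full((32, 32), 0.5)), cfg)
        assert lbd.h.max() <= 1e-9 and lbd.v.max() <= 1e-9

    def test_polarity_invariance(self, cfg):
        rng = np.random.default_rng(3)
        img = (rng.random((48, 48)) > 0.5).astype(float)
        a = local_boundaries(contrast_pathway(img), cfg)
        b = local_boundaries(contrast_pathway(1.0 - img), cfg)
        np.testing.assert_allclose(a.h, b.h, atol=1e-12)
        np.testing.assert_allclose(a.v, b.v, atol=1e-12)


class TestGlobalBoundaries:
    def test_gbd_never_below_lbd(self, cfg):
        rng = np.random.default_rng(4)
        img = (rng.random((48, 48)) > 0.5).astype(float)
        lbd = local_boundaries(contrast_pathway(img), cfg)
        gbd = global_boundaries(lbd, cfg)
        assert np.all(gbd.h >= lbd.h - 1e-12)
        assert np.all(gbd.v >= lbd.v - 1e-12)

    def test_all_zero_input_stays_zero(self, cfg):
        z = OrientedActivity(np.zeros((16, 16)), np.zeros((16, 16)))
        gbd = global_boundaries(z, cfg)
        assert gbd.h.max() == 0 and gbd.v.max() == 0

    def test_collinear_facilitation_raises_weak_segment(self, cfg):
        # strong upper segment, weak lower segment of one vertical edge
        img = np.zeros((64, 64))
        img[:32, 32:] = 1.0
        img[32:, 32:] = 0.5
        lbd = local_boundaries(contrast_pathway(img), cfg)
        gbd = global_boundaries(lbd, cfg)
        strong = lbd.v[16, 31:33].max()
        comp_max = lbd.v[:, 30:34].max()  # includes the junction peak
        weak_after = gbd.v[48, 31:33].max()
        # the weak segment is raised to the level of the strongest collinear
        # signal, well above its own local response
        assert weak_after == pytest.approx(comp_max, rel=1e-9)
        assert weak_after >= strong
        # asymmetric facilitation: nothing ever exceeds the strongest signal
        assert gbd.v.max() == pytest.approx(lbd.v.max(), rel=1e-12)

    def test_no_facilitation_beyond_reach(self):
        cfg = BcsConfig(collinear_reach=2, parallel_reach=1)
        img = np.zeros((64, 64))
        img[:24, 32:] = 1.0  # strong edge segment rows 0..24
        img[40:, 32:] = 0.5  # weak segment rows 40.., 16 px away
        lbd = local_boundaries(contrast_pathway(img), cfg)
        gbd = global_boundaries(lbd, cfg)
        # the weak segment keeps its own regional maximum: nothing is
        # imported from the strong segment 16 px away
        sl = np.s_[36:64, 28:36]  # the whole weak contour band
        assert gbd.v[sl].max() == pytest.approx(lbd.v[sl].max(), abs=1e-12)
        assert gbd.v[sl].max() < 0.9 * lbd.v[:24, :].max()


class TestLgInteraction:
    def _oriented(self, value, shape=(8, 8)):
        m = np.full(shape, value)
        return OrientedActivity(h=np.zeros(shape), v=m)

    def test_ratio_one_is_kept(self, cfg):
        lbd = self._oriented(0.8)
        gbd = self._oriented(0.8)
        mask = lg_interaction(lbd, gbd, cfg)
        assert mask.v.all()

    def test_low_ratio_is_erased(self, cfg):
        lbd = self._oriented(0.4)
        gbd = self._oriented(0.8)
        mask = lg_interaction(lbd, gbd, cfg)
        assert not mask.v.any()

    def test_subthreshold_lbd_never_emits(self, cfg):
        lbd = OrientedActivity(h=np.zeros((8, 8)), v=np.full((8, 8), 1e-4))
        lbd.v[0, 0] = 1.0  # sets the scale
        gbd = OrientedActivity(h=lbd.h.copy(), v=lbd.v.copy())
        mask = lg_interaction(lbd, gbd, cfg)
        assert mask.v.sum() == 1  # only the scale-setting site survives

    def test_zero_gbd_guarded(self, cfg):
        z = OrientedActivity(np.zeros((8, 8)), np.zeros((8, 8)))
        mask = lg_interaction(z, z, cfg)
        assert not mask.h.any() and not mask.v.any()


class TestCalibration:
    def test_threshold_sits_in_window(self, cfg):
        ratio = calibrate_lg_threshold(bcs_cfg=cfg)
        assert ratio < cfg.lg_threshold <= 1.0

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError, match="lg_threshold"):
            calibrate_lg_threshold(bcs_cfg=BcsConfig(lg_threshold=0.2))


class TestConfigValidation:
    def test_reach_ordering(self):
        with pytest.raises(ValueError):
            BcsConfig(collinear_reach=3, parallel_reach=5)
        BcsConfig(collinear_reach=1, parallel_reach=1)  # ablation config is legal

    def test_threshold_range(self):
        with pytest.raises(ValueError):
            BcsConfig(lg_threshold=0.0)
        with pytest.raises(ValueError):
            BcsConfig(lg_threshold=1.5)


class TestMaskStructure:
    def test_mask_subset_of_support(self, cfg):
        rng = np.random.default_rng(5)
        img = (rng.random((48, 48)) > 0.5).astype(float)
        lbd = local_boundaries(contrast_pathway(img), cfg)
        gbd = global_boundaries(lbd, cfg)
        mask = lg_interaction(lbd, gbd, cfg)
        scale = max(lbd.h.max(), lbd.v.max())
        assert np.all(lbd.h[mask.h] > cfg.support_eps * scale)
        assert np.all(lbd.v[mask.v] > cfg.support_eps * scale)

    def test_boundary_mask_dtype(self):
        m = BoundaryMask(np.zeros((4, 4)), np.ones((4, 4)))
        assert m.h.dtype == bool and m.v.dtype == bool
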