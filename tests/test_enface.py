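"""En-face projection, Frangi vesselness and binarization."""

import numpy as np
import pytest

from omagperf.enface import binarize_vessels, build_enface_maps, mip_enface, vesselness
from omagperf.flow import FlowVolume


class TestMIP:
    def test_single_slice_slab_equals_that_slice(self, rng):
        flow = rng.random((8, 9, 10)) * 255
        mask = np.zeros((8, 9, 10), bool)
        mask[:, :, 4] = True
        maps = mip_enface(flow, mask)
        np.testing.assert_array_equal(maps.mip, flow[:, :, 4])

    def test_single_impulse(self):
        flow = np.zeros((6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        flow[2, 3, 4] = 77.0
        maps = mip_enface(flow, mask)
        assert maps.mip[2, 3] == 77.0
        assert maps.mip.sum() == 77.0

    def test_matches_loop_oracle_and_dominates(self, rng):
        flow = rng.random((7, 6, 12)) * 255
        mask = rng.random((7, 6, 12)) > 0.3
        maps = mip_enface(flow, mask)
        for i in range(7):
            for j in range(6):
                sel = mask[i, j]
                expected = flow[i, j, sel].max() if sel.any() else 0.0
                assert maps.mip[i, j] == expected
                if sel.any():
                    assert np.all(maps.mip[i, j] >= flow[i, j, sel])

    def test_empty_slab_flagged(self):
        flow = np.full((3, 3, 3), 9.0)
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, :] = True
        maps = mip_enface(flow, mask)
        assert maps.mip[1, 1] == 0.0
        assert maps.empty_slab[1, 1] and not maps.empty_slab[0, 0]

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            mip_enface(np.zeros((3, 3, 3)), np.ones((3, 3, 4), bool))

    def test_unscaled_flow_volume_rejected(self):
        fv = FlowVolume(np.ones((3, 3, 3)), scaled=False)
        with pytest.raises(ValueError, match="scaled"):
            mip_enface(fv, np.ones((3, 3, 3), bool))


def gaussian_ridge(n=96, width=3.0, horizontal=False):
    x = np.arange(n) - n / 2
    profile = np.exp(-x ** 2 / (2 * width ** 2))
    img = np.tile(profile[:, None], (1, n))
    return img.T if horizontal else img


class TestVesselness:
    def test_constant_image_gives_zero(self):
        assert np.all(vesselness(np.full((32, 32), 0.7)) == 0.0)

    def test_scale_selection_tracks_ridge_width(self):
        # with a FIXED structureness cutoff, the centerline response of a
        # Gaussian ridge of width w peaks at the matching analysis scale
        # (analytically sigma = sqrt(2)*w); the adaptive per-scale cutoff
        # would normalise a lone ridge to the same value at every scale
        img = gaussian_ridge(width=3.0)
        n = img.shape[0]
        per_scale = {s: vesselness(img, scales=(s,), c=0.15)[n // 2, n // 2]
                     for s in (1.0, 2.0, 3.0, 4.0, 6.0)}
        best = max(per_scale, key=per_scale.get)
        assert best in (3.0, 4.0)

    def test_centerline_exceeds_off_ridge(self):
        img = gaussian_ridge(width=3.0)
        v = vesselness(img)
        n = img.shape[0]
        assert v[n // 2, n // 2] > v[n // 2 + 12, n // 2]

    def test_axis_aligned_rotation_equivariance(self, rng):
        # with a fixed structureness cutoff the response is exactly
        # equivariant under 90-degree rotation away from the borders (the
        # adaptive cutoff would couple the interior to orientation-
        # dependent boundary values); margin = 3x the largest scale
        img = rng.random((48, 48))
        v = vesselness(img, c=0.2)
        v_rot = vesselness(np.rot90(img), c=0.2)
        m = 12
        np.testing.assert_allclose(v_rot[m:-m, m:-m], np.rot90(v)[m:-m, m:-m],
                                   atol=1e-6)

    def test_additive_constant_invariance(self, rng):
        img = rng.random((32, 32))
        np.testing.assert_allclose(vesselness(img + 0.25), vesselness(img), atol=1e-10)

    def test_empty_scale_list_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            vesselness(np.zeros((8, 8)), scales=())

    @pytest.mark.parametrize("sigma", [1.0, 2.0, 3.0])
    def test_single_scale_matches_library_filter(self, sigma):
        # at one scale the sigma^2 normalisation cancels inside S/c, so the
        # response must equal scikit-image's Frangi filter (an independent
        # implementation of the same formulation) up to its epsilon clamps
        from skimage.filters import frangi

        img = gaussian_ridge(width=2.0) + 0.05 * np.random.default_rng(3).random((96, 96))
        ours = vesselness(img, scales=(sigma,))
        ref = frangi(img, sigmas=[sigma], beta=0.5, gamma=None, black_ridges=False)
        np.testing.assert_allclose(ours, ref, atol=1e-6)


class TestBinarization:
    def test_zero_map_gives_empty_mask(self):
        mask, _ = binarize_vessels(np.zeros((10, 10)))
        assert not mask.any()

    def test_bimodal_otsu_matches_exhaustive_search(self):
        rng = np.random.default_rng(0)
        v = np.where(rng.random((40, 40)) < 0.4, 0.1, 0.9)
        mask, t = binarize_vessels(v, method="otsu")
        # exhaustive between-class-variance maximisation oracle
        candidates = np.linspace(0.0, 1.0, 512)
        best_t, best_var = None, -1.0
        flat = v.ravel()
        for c in candidates:
            lo, hi = flat[flat <= c], flat[flat > c]
            if lo.size == 0 or hi.size == 0:
                continue
            w0, w1 = lo.size / flat.size, hi.size / flat.size
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if var > best_var:
                best_var, best_t = var, c
        assert 0.1 <= t <= 0.9 and 0.1 <= best_t <= 0.9
        np.testing.assert_array_equal(mask, v > best_t)

    def test_fixed_zero_threshold_selects_positive_support(self, rng):
        v = rng.random((12, 12)) * (rng.random((12, 12)) > 0.5)
        mask, _ = binarize_vessels(v, method="fixed", threshold=0.0)
        np.testing.assert_array_equal(mask, v > 0)

    def test_degenerate_otsu_falls_back_with_warning(self):
        v = np.full((8, 8), 0.4)
        with pytest.warns(UserWarning, match="degenerate"):
            mask, t = binarize_vessels(v, method="otsu", threshold=0.5)
        assert t == 0.5 and not mask.any()

    def test_hysteresis_keeps_connected_faint_core(self):
        v = np.zeros((5, 9))
        v[2, 2:7] = [0.5, 0.1, 0.1, 0.1, 0.5]  # faint core between strong ends
        v[0, 0] = 0.1  # isolated faint pixel: excluded
        mask, _ = binarize_vessels(v, method="hysteresis",
                                   threshold=0.15, low_threshold=0.05)
        assert mask[2, 2:7].all()
        assert not mask[0, 0]


def test_default_pipeline_dice_against_ground_truth(scene_products):
    """Vessel mask overlaps the known en-face vasculature (Dice >= 0.7)."""
    maps = build_enface_maps(scene_products["flow"], scene_products["mask3d"],
                             disc_mask=scene_products["layers"].disc_mask)
    gt = scene_products["gt"]
    disc = scene_products["layers"].disc_mask
    inter = (maps.vessel_mask & gt.enface_vessel_mask & disc).sum()
    dice = 2 * inter / ((maps.vessel_mask & disc).sum()
                        + (gt.enface_vessel_mask & disc).sum())
    assert dice >= 0.7
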