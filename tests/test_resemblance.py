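"""Resemblance metric: pairing, differences, fusion, scores, composition."""

import numpy as np
import pytest

from fibersim import (
    PhantomSpec,
    RMConfig,
    bidirectional_pairing,
    compose_rm,
    compute_rm,
    difference_maps,
    fuse,
    generate_phantom_pair,
    score_collective,
    score_coverage,
    score_distance,
    score_orientation,
)
from fibersim.features import FiberMask
from fibersim.io import FeatureMap
from fibersim.resemblance import RM_FEATURES

from conftest import as_collagen, as_elastin, feature_on_mask

E = np.e
CEILING = (0.5 * (1.0 + np.tanh(2.0))) ** 2  # identical-channel RM at C=4


def brute_force_pairing(mask_e, mask_c):
    """O(N^2) oracle: per-pixel minimum distance and argmin coordinates."""
    ep, cp = np.argwhere(mask_e), np.argwhere(mask_c)
    D = np.sqrt(((ep[:, None, :] - cp[None, :, :]) ** 2).sum(-1))
    de = np.full(mask_e.shape, np.nan)
    ie = np.zeros((2,) + mask_e.shape, int)
    for k, (r, c) in enumerate(ep):
        j = int(np.argmin(D[k]))
        de[r, c] = D[k, j]
        ie[:, r, c] = cp[j]
    dc = np.full(mask_c.shape, np.nan)
    ic = np.zeros((2,) + mask_c.shape, int)
    for j, (r, c) in enumerate(cp):
        k = int(np.argmin(D[:, j]))
        dc[r, c] = D[k, j]
        ic[:, r, c] = ep[k]
    return de, dc, ie, ic


def random_mask_pair(rng, shape=(32, 32), p=0.08):
    while True:
        me = rng.random(shape) < p
        mc = rng.random(shape) < p
        if me.any() and mc.any():
            return me, mc


class TestBidirectionalPairing:
    def test_coincident_masks_give_zero_distance_identity_index(self, rng):
        m = rng.random((24, 24)) < 0.2
        m[0, 0] = True
        pr = bidirectional_pairing(as_elastin(m), as_collagen(m), 1.0)
        assert np.nanmax(pr.dist_at_elastin.values) == 0.0
        assert np.nanmax(pr.dist_at_collagen.values) == 0.0
        ir, ic = pr.index_at_elastin
        rr, cc = np.mgrid[0:24, 0:24]
        assert np.array_equal(ir[m], rr[m]) and np.array_equal(ic[m], cc[m])

    def test_asymmetric_three_pixel_configuration(self):
        me = np.zeros((5, 5), bool)
        me[0, 0] = True
        mc = np.zeros((5, 5), bool)
        mc[0, 3] = mc[4, 0] = True
        pr = bidirectional_pairing(as_elastin(me), as_collagen(mc), 1.0)
        assert pr.dist_at_elastin.values[0, 0] == 3.0
        assert tuple(pr.index_at_elastin[:, 0, 0]) == (0, 3)
        assert pr.dist_at_collagen.values[0, 3] == 3.0
        assert pr.dist_at_collagen.values[4, 0] == 4.0
        assert tuple(pr.index_at_collagen[:, 0, 3]) == (0, 0)
        assert tuple(pr.index_at_collagen[:, 4, 0]) == (0, 0)

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            me, mc = random_mask_pair(rng)
            pr = bidirectional_pairing(as_elastin(me), as_collagen(mc), 1.0)
            de, dc, _, _ = brute_force_pairing(me, mc)
            np.testing.assert_allclose(
                pr.dist_at_elastin.values[me], de[me], atol=1e-12
            )
            np.testing.assert_allclose(
                pr.dist_at_collagen.values[mc], dc[mc], atol=1e-12
            )
            # indexed pixel lies on the other mask at the right distance
            ir, ic = pr.index_at_elastin
            assert mc[ir[me], ic[me]].all()
            rr, cc = np.mgrid[0 : me.shape[0], 0 : me.shape[1]]
            d_check = np.hypot(rr - ir, cc - ic)[me]
            np.testing.assert_allclose(pr.dist_at_elastin.values[me], d_check)

    def test_pixel_size_scales_distances(self):
        me = np.zeros((8, 8), bool)
        me[0, 0] = True
        mc = np.zeros((8, 8), bool)
        mc[0, 4] = True
        pr = bidirectional_pairing(as_elastin(me), as_collagen(mc), 0.5)
        assert pr.dist_at_elastin.values[0, 0] == pytest.approx(2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bidirectional_pairing(
                as_elastin(np.zeros((8, 8), bool)),
                as_collagen(np.ones((8, 8), bool)),
                1.0,
            )


class TestDifferenceMaps:
    def test_identical_channels_vanish(self, rng):
        m = rng.random((16, 16)) < 0.3
        m[5, 5] = True
        feat = feature_on_mask("LC", rng.random((16, 16)), m, (0.0, 1.0))
        pr = bidirectional_pairing(as_elastin(m), as_collagen(m), 1.0)
        diff = difference_maps(feat, feat, pr)
        assert np.nanmax(diff.ms_elastin) == 0.0
        assert np.nanmax(diff.ms_collagen) == 0.0

    def test_orientation_wraps_to_complementary_angle(self):
        me = np.zeros((4, 4), bool)
        me[0, 0] = True
        mc = np.zeros((4, 4), bool)
        mc[0, 1] = True
        fe = feature_on_mask("Ori", np.full((4, 4), 10.0), me, (0.0, 180.0))
        fc = feature_on_mask("Ori", np.full((4, 4), 170.0), mc, (0.0, 180.0))
        pr = bidirectional_pairing(as_elastin(me), as_collagen(mc), 1.0)
        diff = difference_maps(fe, fc, pr)
        assert diff.ms_elastin[0, 0] == pytest.approx(20.0)
        assert diff.ms_collagen[0, 1] == pytest.approx(20.0)

    def test_mutual_pair_gives_symmetric_absolute_difference(self):
        me = np.zeros((4, 4), bool)
        me[0, 0] = True
        mc = np.zeros((4, 4), bool)
        mc[0, 1] = True
        fe = feature_on_mask("LC", np.full((4, 4), 0.8), me, (0.0, 1.0))
        fc = feature_on_mask("LC", np.full((4, 4), 0.3), mc, (0.0, 1.0))
        pr = bidirectional_pairing(as_elastin(me), as_collagen(mc), 1.0)
        diff = difference_maps(fe, fc, pr)
        assert diff.ms_elastin[0, 0] == pytest.approx(0.5)
        assert diff.ms_collagen[0, 1] == pytest.approx(0.5)

    def test_distance_pseudo_feature_reuses_pairing(self, rng):
        me, mc = random_mask_pair(rng)
        pr = bidirectional_pairing(as_elastin(me), as_collagen(mc), 1.0)
        diff = difference_maps(None, None, pr)
        np.testing.assert_array_equal(
            diff.ms_elastin[me], pr.dist_at_elastin.values[me]
        )

    def test_feature_name_mismatch_rejected(self, rng):
        m = np.ones((4, 4), bool)
        fa = feature_on_mask("LC", np.zeros((4, 4)), m, (0.0, 1.0))
        fb = feature_on_mask("DV", np.zeros((4, 4)), m, (0.0, 1.0))
        pr = bidirectional_pairing(as_elastin(m), as_collagen(m), 1.0)
        with pytest.raises(ValueError, match="mismatch"):
            difference_maps(fa, fb, pr)


class TestFusion:
    def test_disjoint_masks_keep_each_side(self):
        me = np.zeros((6, 6), bool)
        me[:, :2] = True
        mc = np.zeros((6, 6), bool)
        mc[:, 4:] = True
        diff_e = np.where(me, 0.2, np.nan)
        diff_c = np.where(mc, 0.6, np.nan)
        from fibersim.resemblance import DifferencePair

        fused = fuse(DifferencePair("LC", diff_e, diff_c), as_elastin(me), as_collagen(mc))
        assert np.all(fused[me] == 0.2)
        assert np.all(fused[mc] == 0.6)
        assert np.isnan(fused[~(me | mc)]).all()

    def test_overlap_averages_both_sides(self):
        m = np.ones((4, 4), bool)
        from fibersim.resemblance import DifferencePair

        fused = fuse(
            DifferencePair("LC", np.full((4, 4), 0.2), np.full((4, 4), 0.4)),
            as_elastin(m),
            as_collagen(m),
        )
        np.testing.assert_allclose(fused, 0.3)

    def test_matches_per_pixel_case_analysis_on_random_masks(self):
        rng = np.random.default_rng(3)
        from fibersim.resemblance import DifferencePair

        for _ in range(10):
            me, mc = random_mask_pair(rng, p=0.3)
            a = np.where(me, rng.random(me.shape), np.nan)
            b = np.where(mc, rng.random(mc.shape), np.nan)
            fused = fuse(DifferencePair("DV", a, b), as_elastin(me), as_collagen(mc))
            for r in range(me.shape[0]):
                for c in range(me.shape[1]):
                    if me[r, c] and mc[r, c]:
                        assert fused[r, c] == pytest.approx(0.5 * (a[r, c] + b[r, c]))
                    elif me[r, c]:
                        assert fused[r, c] == a[r, c]
                    elif mc[r, c]:
                        assert fused[r, c] == b[r, c]
                    else:
                        assert np.isnan(fused[r, c])


class TestScores:
    def test_distance_score_closed_form(self):
        duplim = 4.0
        x = np.array([0.0, duplim, duplim / (E - 1.0)])
        s = score_distance(x, duplim).values
        assert s[0] == pytest.approx(1.0, abs=1e-12)
        assert s[1] == pytest.approx(1.0 / E, abs=1e-12)
        assert s[2] == pytest.approx(0.5, abs=1e-12)
        assert np.all(np.diff(score_distance(np.linspace(0, 20, 50), duplim).values) < 0)

    def test_coverage_score_closed_form(self):
        x = np.array([0.0, 1.0, 1.0 / (E - 1.0)])
        s = score_coverage(x).values
        assert s[0] == pytest.approx(1.0, abs=1e-12)
        assert s[1] == pytest.approx(1.0 / E, abs=1e-12)
        assert s[2] == pytest.approx(0.5, abs=1e-12)

    def test_orientation_score_is_cosine(self):
        s = score_orientation(np.array([0.0, 60.0, 90.0])).values
        np.testing.assert_allclose(s, [1.0, 0.5, 0.0], atol=1e-12)

    def test_collective_score_shifted_sigmoid(self):
        s = score_collective(np.array([0.5, 0.0, 1.0])).values
        assert s[0] == pytest.approx(0.5, abs=1e-12)
        assert s[1] == pytest.approx(0.5 * (1.0 + np.tanh(2.0)), abs=1e-12)
        assert s[2] == pytest.approx(0.5 * (1.0 - np.tanh(2.0)), abs=1e-12)

    def test_collective_score_symmetry(self, rng):
        x = rng.random(100)
        s = score_collective(x).values + score_collective(1.0 - x).values
        np.testing.assert_allclose(s, 1.0, atol=1e-12)

    def test_printed_antisymmetric_form_available_for_audit(self):
        cfg = RMConfig(shifted_sigmoid=False)
        s = score_collective(np.array([0.0, 0.5, 1.0]), cfg).values
        np.testing.assert_allclose(
            s, [0.5 * np.tanh(2.0), 0.0, -0.5 * np.tanh(2.0)], atol=1e-12
        )

    def test_degenerate_duplim_raises_without_floor(self):
        with pytest.raises(ValueError, match="Duplim"):
            score_distance(np.array([1.0]), 0.0)
        s = score_distance(np.array([0.0]), 0.0, RMConfig(duplim_floor=2.0))
        assert s.values[0] == pytest.approx(1.0)


class TestComposeRM:
    def _stack(self, rng, mask):
        shape = mask.shape
        scores = {}
        for feat in RM_FEATURES:
            vals = np.where(mask, rng.random(shape), np.nan)
            scores[feat] = FeatureMap(feat, vals, 1.0, (0.0, 1.0))
        return scores

    def test_all_ones_give_one_and_zero_absorbs(self, rng):
        mask = rng.random((8, 8)) < 0.5
        mask[0, 0] = True
        ones = {
            f: FeatureMap(f, np.where(mask, 1.0, np.nan), 1.0, (0.0, 1.0))
            for f in RM_FEATURES
        }
        rm = compose_rm(ones)
        np.testing.assert_allclose(rm.values[mask], 1.0)
        zeroed = dict(ones)
        zeroed["Ori"] = FeatureMap("Ori", np.where(mask, 0.0, np.nan), 1.0, (0.0, 1.0))
        rm0 = compose_rm(zeroed)
        np.testing.assert_allclose(rm0.values[mask], 0.0)

    def test_plain_product_with_unit_weights(self, rng):
        mask = rng.random((8, 8)) < 0.6
        mask[0, 0] = True
        scores = self._stack(rng, mask)
        rm = compose_rm(scores)
        expected = np.ones(mask.shape)
        for f in RM_FEATURES:
            expected *= np.where(mask, scores[f].values, 1.0)
        np.testing.assert_allclose(rm.values[mask], expected[mask])

    def test_zero_weights_give_unit_map(self, rng):
        mask = rng.random((8, 8)) < 0.6
        mask[0, 0] = True
        scores = self._stack(rng, mask)
        cfg = RMConfig(weights={f: 0.0 for f in RM_FEATURES})
        rm = compose_rm(scores, cfg)
        np.testing.assert_allclose(rm.values[mask], 1.0)


class TestFullPipeline:
    def test_identical_channels_hit_the_constant_ceiling(self, identical_phantom):
        stack, _ = compute_rm(identical_phantom.pair)
        vals = stack.rm.defined
        np.testing.assert_allclose(vals, CEILING, atol=1e-9)

    def test_score_maps_and_rm_in_unit_range(self):
        ph = generate_phantom_pair(PhantomSpec(seed=21, coupling_mode="independent"))
        stack, _ = compute_rm(ph.pair)
        for smap in [*stack.scores.values(), stack.rm]:
            vals = smap.defined
            assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_independent_fibers_score_below_coupled(self):
        coupled = generate_phantom_pair(
            PhantomSpec(seed=30, coupling_mode="coupled", coupling_offset=0.5)
        )
        independent = generate_phantom_pair(
            PhantomSpec(seed=30, coupling_mode="independent", n_fibers_per_channel=5)
        )
        rm_c, _ = compute_rm(coupled.pair)
        rm_i, _ = compute_rm(independent.pair)
        assert np.nanmean(rm_i.rm.values) < np.nanmean(rm_c.rm.values)

    @pytest.mark.parametrize(
        "dial, grid",
        [("coupling_offset", [0.0, 2.0, 6.0]), ("coupling_angle_jitter", [0.0, 20.0, 45.0])],
    )
    def test_rm_mean_decreases_with_coupling_perturbation(self, dial, grid):
        means = []
        for value in grid:
            spec = PhantomSpec(
                image_size=128, coupling_mode="coupled", seed=7,
                intensity_noise_sd=0.02, **{dial: value},
            )
            stack, _ = compute_rm(generate_phantom_pair(spec).pair)
            means.append(float(np.nanmean(stack.rm.values)))
        assert means[0] > means[1] > means[2]

    def test_empty_channel_raises_naming_the_channel(self):
        ph = generate_phantom_pair(PhantomSpec(seed=2, intensity_noise_sd=0.0))
        from fibersim.io import ImagePair, IntensityImage

        blank = IntensityImage(np.zeros((128, 128)), ph.pair.pixel_size, "collagen")
        with pytest.raises(ValueError, match="collagen"):
            compute_rm(ImagePair(ph.pair.elastin, blank))

    def test_provenance_records_duplim_and_knobs(self, identical_phantom):
        stack, _ = compute_rm(identical_phantom.pair)
        assert stack.provenance["duplim_um"] == pytest.approx(stack.duplim)
        assert stack.provenance["contrast_coefficient"] == 4.0
        assert stack.provenance["orientation_fusion"] == "wrap-then-fuse"
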