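"""Transform estimation, pairwise compositing, sequences and propagation."""

import math

import numpy as np
import pytest

import spinestitch as ss
from tests.conftest import crop_to_reference


def pairs_from_transform(t: ss.Transform, n=6, seed=0):
    rng = np.random.default_rng(seed)
    b = rng.uniform(10, 200, size=(n, 2))
    a = t.apply(b)
    return ss.PointPairSet(
        points_a=[tuple(p) for p in a], points_b=[tuple(p) for p in b]
    )


class TestEstimateTransform:
    def test_consistent_pairs_recover_translation_exactly(self):
        pairs = pairs_from_transform(ss.Transform(dx=5.0, dy=120.0))
        t = ss.estimate_transform(pairs, "translation")
        assert (t.dx, t.dy) == (5.0, 120.0)
        np.testing.assert_allclose(t.residuals, 0.0, atol=1e-9)

    def test_single_pair_gives_its_displacement(self):
        pairs = ss.PointPairSet(points_a=[(10.0, 130.0)], points_b=[(4.0, 12.0)])
        t = ss.estimate_transform(pairs, "translation")
        assert (t.dx, t.dy) == (6.0, 118.0)

    def test_median_ignores_minority_outlier(self):
        pts_b = [(float(i * 10 + 5), float(i * 7 + 3)) for i in range(9)]
        pts_a = [(x + 0.0, y + 100.0) for x, y in pts_b]
        pts_b.append((60.0, 60.0))
        pts_a.append((110.0, 30.0))  # outlier displaced by (50, -30)
        t = ss.estimate_transform(ss.PointPairSet(pts_a, pts_b), "translation")
        assert (t.dx, t.dy) == (0.0, 100.0)

    def test_similarity_round_trip_within_1e6(self):
        truth = ss.Transform(model="similarity", dx=3.0, dy=-7.0,
                             rotation=math.radians(8.0), scale=1.04)
        t = ss.estimate_transform(pairs_from_transform(truth, n=8), "similarity")
        assert t.dx == pytest.approx(truth.dx, abs=1e-6)
        assert t.dy == pytest.approx(truth.dy, abs=1e-6)
        assert t.rotation == pytest.approx(truth.rotation, abs=1e-6)
        assert t.scale == pytest.approx(truth.scale, abs=1e-6)

    def test_insufficient_pairs_error_names_minimum(self):
        pairs = ss.PointPairSet(points_a=[(0.0, 0.0)], points_b=[(1.0, 1.0)])
        with pytest.raises(ValueError, match="2"):
            ss.estimate_transform(pairs, "similarity")

    def test_transform_inverse_and_compose(self):
        t = ss.Transform(model="similarity", dx=4.0, dy=-2.0,
                         rotation=0.3, scale=1.1)
        pts = np.array([[10.0, 20.0], [-3.0, 7.0]])
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-12)
        ident = t.compose(t.inverse())
        np.testing.assert_allclose([ident.dx, ident.dy, ident.rotation], 0.0, atol=1e-12)


class TestStitchPair:
    def test_identity_stitch_reproduces_input_all_blends(self, phantom):
        img = phantom.pixels[:128, :]
        for blend in ("feather", "average", "overwrite"):
            res = ss.stitch_pair(img, img, ss.Transform(), blend=blend)
            np.testing.assert_allclose(res.canvas.pixels, img, atol=1e-15)
            assert res.overlap_masks[0].all()

    def test_exact_split_reassembles_below_1e6(self, phantom):
        img = phantom.pixels
        a, b = img[:400, :], img[344:, :]
        res = ss.stitch_pair(a, b, ss.Transform(dx=0.0, dy=344.0))
        assert res.canvas.pixels.shape == img.shape
        assert ss.nmse(img, res.canvas.pixels) <= 1e-6

    def test_uncovered_corner_is_background_zero(self):
        a = np.full((50, 50), 0.5)
        b = np.full((50, 50), 0.5)
        res = ss.stitch_pair(a, b, ss.Transform(dx=30.0, dy=30.0))
        assert res.canvas.pixels[-1, 0] == 0.0  # bottom-left: neither source
        assert not res.mask[-1, 0]

    def test_feather_weights_partition_unity_on_flat_input(self):
        ones = np.ones((40, 40))
        res = ss.stitch_pair(ones, ones, ss.Transform(dx=0.0, dy=20.0))
        inside = res.mask
        np.testing.assert_allclose(res.canvas.pixels[inside], 1.0, atol=1e-9)

    def test_empty_overlap_allowed(self):
        a = np.full((30, 30), 0.4)
        res = ss.stitch_pair(a, a, ss.Transform(dx=0.0, dy=60.0))
        assert not res.overlap_masks[0].any()
        assert res.canvas.pixels.shape == (90, 30)

    def test_nonfinite_transform_rejected(self):
        with pytest.raises(ValueError):
            ss.Transform(dx=float("nan"), dy=0.0)


class TestStitchSequence:
    def test_aptp_three_segments_reach_1e3(self, phantom, noisy_segment_set):
        res = ss.stitch_sequence(noisy_segment_set.segments, mode="aptp")[0]
        tr = res.transforms
        for i, (tx, ty) in enumerate(noisy_segment_set.true_offsets):
            dx = tr[i + 1].dx - tr[i].dx
            dy = tr[i + 1].dy - tr[i].dy
            assert abs(dx - tx) <= 0.5 and abs(dy - ty) <= 0.5
        crop = crop_to_reference(res, phantom)
        assert ss.nmse(phantom, crop) <= 1e-3

    def test_mptp_with_exact_pairs_matches_aptp_within_half_pixel(self, phantom):
        segs = ss.split_overlapping(phantom, noise_sd=0.0, seed=3)
        res_a = ss.stitch_sequence(segs.segments, mode="aptp")[0]
        # four exact hand-picked pairs per adjacent pair, from ground truth
        pairs = []
        offset = (0.0, 0.0)
        for (tx, ty) in segs.true_offsets:
            offset = (offset[0] + tx, offset[1] + ty)
            pts_b = [(30.0, 10.0), (200.0, 20.0), (60.0, 40.0), (150.0, 30.0)]
            pts_a = [(x + offset[0], y + offset[1]) for x, y in pts_b]
            pairs.append(ss.PointPairSet(pts_a, pts_b))
        res_m = ss.stitch_sequence(segs.segments, mode="mptp", pairs=pairs)[0]
        for ta, tm in zip(res_a.transforms, res_m.transforms):
            assert abs(ta.dx - tm.dx) <= 0.5
            assert abs(ta.dy - tm.dy) <= 0.5

    def test_mptp_replaying_aptp_pairs_is_pixel_identical(self, noisy_segment_set):
        res_a = ss.stitch_sequence(noisy_segment_set.segments, mode="aptp")[0]
        res_m = ss.stitch_sequence(
            noisy_segment_set.segments, mode="mptp", pairs=res_a.pair_sets
        )[0]
        np.testing.assert_array_equal(res_a.canvas.pixels, res_m.canvas.pixels)

    def test_single_segment_passes_through(self, phantom):
        res = ss.stitch_sequence([phantom])
        assert len(res) == 1
        np.testing.assert_array_equal(res[0].canvas.pixels, phantom.pixels)

    def test_mismatched_slice_counts_rejected(self, phantom):
        s1 = ss.SliceStack([phantom, phantom])
        s2 = ss.SliceStack([phantom])
        with pytest.raises(ValueError):
            ss.stitch_sequence([s1, s2])

    def test_offset_recovery_over_20_jittered_splits(self, phantom):
        # aPTP translation error stays within half a pixel per axis when
        # the overlap is generous and the noise moderate
        failures = []
        for seed in range(20):
            segs = ss.split_overlapping(
                phantom, overlap_px=56, jitter_px=4, noise_sd=0.02, seed=seed
            )
            res = ss.stitch_sequence(segs.segments, mode="aptp")[0]
            tr = res.transforms
            for i, (tx, ty) in enumerate(segs.true_offsets):
                dx = tr[i + 1].dx - tr[i].dx
                dy = tr[i + 1].dy - tr[i].dy
                if abs(dx - tx) > 0.5 or abs(dy - ty) > 0.5:
                    failures.append((seed, i, dx - tx, dy - ty))
        assert not failures, f"offset failures: {failures}"


class TestPropagation:
    @pytest.mark.parametrize("n,expected", [(6, 2), (5, 2), (1, 0), (2, 0)])
    def test_central_slice_index(self, n, expected):
        assert ss.central_slice_index(n) == expected

    def test_transform_applied_unchanged_to_every_slice(self, phantom):
        img = phantom.pixels
        a = ss.SliceStack([ss.ImagePlane(img[:400]) for _ in range(6)])
        b = ss.SliceStack([ss.ImagePlane(img[344:]) for _ in range(6)])
        results = ss.propagate_to_slices(a, b, ss.Transform(dx=0.0, dy=344.0))
        assert len(results) == 6
        for r in results:
            np.testing.assert_array_equal(r.canvas.pixels, results[0].canvas.pixels)
            assert ss.nmse(img, r.canvas.pixels) <= 1e-6

    def test_unequal_slice_counts_rejected(self, phantom):
        a = ss.SliceStack([phantom] * 2)
        b = ss.SliceStack([phantom] * 3)
        with pytest.raises(ValueError):
            ss.propagate_to_slices(a, b, ss.Transform())

    def test_multislice_sequence_estimates_on_central_slice(self, phantom):
        stack = ss.make_phantom_stack(ss.PhantomConfig(seed=5), n_slices=5, slice_noise_sd=0.005)
        segs = ss.split_overlapping(stack, noise_sd=0.005, seed=5)
        results = ss.stitch_sequence(segs.segments, mode="aptp")
        assert len(results) == 5
        # every slice shares the central slice's transforms
        for r in results:
            for t0, t in zip(results[2].transforms, r.transforms):
                assert (t0.dx, t0.dy) == (t.dx, t.dy)


class TestReferenceCrossCheck:
    def test_translation_agrees_with_reference_sift(self, phantom):
        # independent oracle: scikit-image's SIFT on the same segment pair
        # must imply the same inter-segment translation as our chain
        from skimage.feature import SIFT, match_descriptors as sk_match

        segs = ss.split_overlapping(phantom, noise_sd=0.01, seed=2)
        a = segs.segments[0].planes[0].pixels
        b = segs.segments[1].planes[0].pixels
        det_a, det_b = SIFT(), SIFT()
        det_a.detect_and_extract(a)
        det_b.detect_and_extract(b)
        idx = sk_match(det_a.descriptors, det_b.descriptors,
                       max_ratio=0.6, cross_check=True)
        d = det_a.keypoints[idx[:, 0]] - det_b.keypoints[idx[:, 1]]  # (row, col)
        ref_dy = float(np.median(d[:, 0]))
        ref_dx = float(np.median(d[:, 1]))
        pairs = ss.automatic_point_pairs(a, b)
        t = ss.estimate_transform(pairs, "translation")
        assert abs(t.dx - ref_dx) <= 0.5
        assert abs(t.dy - ref_dy) <= 0.5
        tx, ty = segs.true_offsets[0]
        assert abs(ref_dx - tx) <= 0.5 and abs(ref_dy - ty) <= 0.5
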