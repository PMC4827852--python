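"""Extrema detection, sub-pixel localization and keypoint filtering."""

import numpy as np
import pytest

import spinestitch as ss
from tests.conftest import blob_grid, brute_force_extrema, gaussian_blob


def make_dog(levels, base_sigma=1.6):
    """Wrap a list of 2-D arrays as a single-octave DoG pyramid."""
    cfg = ss.ScaleSpaceConfig(base_sigma=base_sigma)
    k = cfg.k
    return ss.DoGPyramid(
        octaves=[[np.asarray(l, dtype=float) for l in levels]],
        level_sigmas=[[base_sigma * k**i for i in range(len(levels))]],
        config=cfg,
    )


def quadratic_cube(shape, peak, offsets, curvature=(0.02, 0.03, 0.04)):
    """Separable concave quadratic over (level, y, x) peaking off-sample.

    The 3-D second-order model is exact for this surface, so localization
    must recover the offsets to machine precision.
    """
    n_l, n_y, n_x = shape
    l0, y0, x0 = offsets
    ll, yy, xx = np.mgrid[0:n_l, 0:n_y, 0:n_x].astype(float)
    cl, cy, cx = curvature
    return (
        peak
        - cl * (ll - l0) ** 2
        - cy * (yy - y0) ** 2
        - cx * (xx - x0) ** 2
    )


def patch_with_hessian(dxx, dyy, dxy, size=7):
    """2-D patch whose central-difference Hessian at the center is exact."""
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xx - c, yy - c
    return 0.5 * dxx * dx**2 + 0.5 * dyy * dy**2 + dxy * dx * dy


class TestDetectExtrema:
    def test_single_planted_maximum_found(self):
        rng = np.random.default_rng(0)
        levels = [rng.normal(0, 1e-4, (8, 8)) for _ in range(3)]
        levels[1][4, 5] = 1.0
        cands = ss.detect_extrema(make_dog(levels))
        assert (0, 1, 4, 5) in cands

    def test_constant_pyramid_yields_nothing(self):
        cands = ss.detect_extrema(make_dog([np.full((8, 8), 0.2)] * 3))
        assert cands == []

    def test_plateau_ties_rejected(self):
        levels = [np.zeros((8, 8)) for _ in range(3)]
        levels[1][3:5, 3:5] = 1.0  # 2x2 plateau: no strict extremum
        assert ss.detect_extrema(make_dog(levels)) == []

    def test_matches_brute_force_on_random_pyramids(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            img = rng.random((48, 48))
            dog = ss.build_dog_pyramid(ss.build_gaussian_pyramid(img))
            assert sorted(ss.detect_extrema(dog)) == sorted(brute_force_extrema(dog))

    def test_gaussian_blob_candidate_near_center_and_scale(self):
        img = gaussian_blob((64, 64), (32, 32), 4.0, 0.8)
        dog = ss.build_dog_pyramid(ss.build_gaussian_pyramid(img))
        cands = ss.detect_extrema(dog)
        probed = [
            (o, l, dog.level_sigmas[o][l])
            for o in range(dog.n_octaves)
            for l in range(1, len(dog.octaves[o]) - 1)
        ]
        best_sigma = min((s for _, _, s in probed), key=lambda s: abs(s - 4.0))
        hits = [
            (o, l, y, x)
            for (o, l, y, x) in cands
            if abs(y * 2**o - 32) <= 1 and abs(x * 2**o - 32) <= 1
        ]
        assert hits, "no candidate near the blob center"
        # the unnormalized DoG biases the extremum one level low, so accept
        # the level nearest the blob scale or its immediate neighbor
        k = dog.config.k
        sigmas = [dog.level_sigmas[o][l] for o, l, _, _ in hits]
        assert any(abs(np.log(s / best_sigma)) <= np.log(k) + 1e-9 for s in sigmas)


class TestLocalization:
    def test_quadratic_offsets_recovered_to_machine_precision(self):
        cube = quadratic_cube((5, 9, 9), 0.2, (2.1, 4.0 - 0.2, 4.0 + 0.3))
        dog = make_dog(list(cube))
        kp = ss.localize_keypoint((0, 2, 4, 4), dog, ss.DetectionConfig())
        assert kp is not None
        assert kp.x == pytest.approx(4.3, abs=1e-6)
        assert kp.y == pytest.approx(3.8, abs=1e-6)
        assert kp.dog_value == pytest.approx(0.2, abs=1e-6)

    def test_symmetric_peak_keeps_sample_position(self):
        cube = quadratic_cube((3, 9, 9), 0.2, (1.0, 4.0, 4.0))
        kp = ss.localize_keypoint((0, 1, 4, 4), make_dog(list(cube)))
        assert kp is not None
        assert (kp.x, kp.y) == (4.0, 4.0)

    def test_low_contrast_extremum_rejected_at_0p03(self):
        cube = quadratic_cube((3, 9, 9), 0.02, (1.0, 4.0, 4.0))
        assert ss.localize_keypoint((0, 1, 4, 4), make_dog(list(cube))) is None
        # the same surface clears a lower threshold
        cfg = ss.DetectionConfig(contrast_threshold=0.01)
        assert ss.localize_keypoint((0, 1, 4, 4), make_dog(list(cube)), cfg) is not None

    def test_interpolated_value_used_for_contrast(self):
        # sample value 0.028 < 0.03 but the interpolated peak is above it
        cube = quadratic_cube((3, 9, 9), 0.0305, (1.0, 4.45, 4.0), curvature=(0.001, 0.05, 0.05))
        kp = ss.localize_keypoint((0, 1, 4, 4), make_dog(list(cube)))
        assert kp is not None
        assert abs(kp.dog_value) >= 0.03

    def test_singular_hessian_rejected(self):
        cube = np.zeros((3, 9, 9))
        assert ss.localize_keypoint((0, 1, 4, 4), make_dog(list(cube))) is None


class TestEdgeResponse:
    def test_isotropic_curvature_accepted(self):
        # equal eigenvalues give the minimum trace^2/det ratio of 4,
        # below the gamma=10 threshold (10+1)^2/10 = 12.1
        dog = make_dog([np.zeros((7, 7)), patch_with_hessian(-0.2, -0.2, 0.0), np.zeros((7, 7))])
        assert ss.edge_response_ok((0, 1, 3, 3), dog)

    def test_saddle_rejected(self):
        dog = make_dog([np.zeros((7, 7)), patch_with_hessian(0.2, -0.2, 0.0), np.zeros((7, 7))])
        assert not ss.edge_response_ok((0, 1, 3, 3), dog)

    def test_eigen_ratio_20_rejected_at_gamma_10(self):
        # ratio (20+1)^2/20 = 22.05 > 12.1
        dog = make_dog([np.zeros((7, 7)), patch_with_hessian(-0.20, -0.01, 0.0), np.zeros((7, 7))])
        assert not ss.edge_response_ok((0, 1, 3, 3), dog)
        # but a laxer gamma admits it: threshold (25+1)^2/25 = 27.04
        assert ss.edge_response_ok((0, 1, 3, 3), dog, ss.DetectionConfig(edge_gamma=25))

    def test_predicate_invariant_to_positive_scaling(self):
        for scale in (0.5, 3.0, 100.0):
            base = patch_with_hessian(-0.07, -0.02, 0.01)
            d1 = make_dog([np.zeros((7, 7)), base, np.zeros((7, 7))])
            d2 = make_dog([np.zeros((7, 7)), base * scale, np.zeros((7, 7))])
            assert ss.edge_response_ok((0, 1, 3, 3), d1) == ss.edge_response_ok((0, 1, 3, 3), d2)


class TestDetectPipeline:
    def test_blank_image_yields_no_keypoints(self):
        assert ss.detect(np.zeros((64, 64))) == []

    def test_blob_grid_keypoints_cover_all_blobs(self):
        img, centers = blob_grid()
        kps = ss.detect(img)
        assert len(kps) >= 9
        for cy, cx in centers:
            d = min(np.hypot(kp.x - cx, kp.y - cy) for kp in kps)
            assert d <= 1.5, f"blob at {(cy, cx)} missed (nearest {d:.2f} px)"

    def test_detection_is_deterministic(self):
        img, _ = blob_grid()
        a = ss.detect(img)
        b = ss.detect(img.copy())
        assert [(k.x, k.y, k.sigma) for k in a] == [(k.x, k.y, k.sigma) for k in b]

    def test_all_keypoints_pass_contrast_and_edge_filters(self, phantom):
        kps = ss.detect(phantom.pixels[:256, :])
        assert kps
        assert all(abs(kp.dog_value) >= 0.03 for kp in kps)

    def test_translation_equivariance_within_tenth_pixel(self):
        img, _ = blob_grid((160, 160))
        shift = (16, 24)  # (dy, dx), integer
        shifted = np.roll(np.roll(img, shift[0], axis=0), shift[1], axis=1)
        kps_a = ss.detect(img)
        kps_b = ss.detect(shifted)
        interior = [
            kp for kp in kps_a
            if 32 < kp.x < 120 and 32 < kp.y < 120
        ]
        assert interior
        for kp in interior:
            d = min(
                np.hypot(kb.x - (kp.x + shift[1]), kb.y - (kp.y + shift[0]))
                for kb in kps_b
            )
            assert d <= 0.1

    def test_raising_contrast_threshold_never_adds_keypoints(self, phantom):
        img = phantom.pixels[:256, :]
        counts = [
            len(ss.detect(img, det_config=ss.DetectionConfig(contrast_threshold=t)))
            for t in (0.02, 0.03, 0.05, 0.08)
        ]
        assert counts == sorted(counts, reverse=True)
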