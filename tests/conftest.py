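"""Shared fixtures: small synthetic images and expensive cached results."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import spinestitch as ss

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


def gaussian_blob(shape, center, sigma, amplitude=1.0):
    """Analytic 2-D Gaussian bump on a zero background."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    return amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2))


def blob_grid(shape=(128, 128), spacing=40, sigma=3.0, amplitude=0.6):
    """3x3 grid of well-separated Gaussian blobs; returns (image, centers)."""
    img = np.zeros(shape)
    centers = []
    for i in range(3):
        for j in range(3):
            cy, cx = 24 + i * spacing, 24 + j * spacing
            img += gaussian_blob(shape, (cy, cx), sigma, amplitude)
            centers.append((cy, cx))
    return img, centers


def brute_force_extrema(dog):
    """Independent exhaustive 26-neighbor scan over a DoG pyramid."""
    out = []
    for o, levels in enumerate(dog.octaves):
        cube = np.stack(levels)
        n_l, n_y, n_x = cube.shape
        for l in range(1, n_l - 1):
            for y in range(1, n_y - 1):
                for x in range(1, n_x - 1):
                    c = cube[l, y, x]
                    neigh = cube[l - 1 : l + 2, y - 1 : y + 2, x - 1 : x + 2].ravel()
                    others = np.delete(neigh, 13)
                    if np.all(c > others) or np.all(c < others):
                        out.append((o, l, y, x))
    return out


@pytest.fixture(scope="session")
def phantom():
    return ss.make_phantom()


@pytest.fixture(scope="session")
def phantom_features(phantom):
    return ss.extract_features(phantom.pixels[:256, :])


@pytest.fixture(scope="session")
def noisy_segment_set(phantom):
    return ss.split_overlapping(phantom, noise_sd=0.01, seed=1)


def crop_to_reference(result: ss.StitchResult, reference: ss.ImagePlane) -> np.ndarray:
    """Express a stitched canvas in the reference (first segment) frame."""
    t0 = result.transforms[0]
    ox, oy = int(round(t0.dx)), int(round(t0.dy))
    crop = result.canvas.pixels[oy : oy + reference.height, ox : ox + reference.width]
    assert crop.shape == reference.pixels.shape, "canvas does not cover the reference"
    return crop
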