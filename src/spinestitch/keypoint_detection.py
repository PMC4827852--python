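"""DoG extrema detection, sub-pixel localization and keypoint filtering.

Candidates are strict extrema over their 26 neighbors in the DoG pyramid
(8 in-plane, 9 in each adjacent scale).  Each candidate is refined with a
second-order Taylor expansion of D(x, y, σ): the offset X̂ solves
∇²D · X̂ = −∇D; the interpolated value D(X̂) = D + ½ ∇Dᵀ X̂ must clear a
contrast threshold (0.03 on [0,1]-normalized images), and edge-like
points are rejected by the principal-curvature ratio test
Tr(H)²/Det(H) ≤ (γ+1)²/γ on the 2-D spatial Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import ImagePlane
from .scale_space import (
    DoGPyramid,
    GaussianPyramid,
    ScaleSpaceConfig,
    build_dog_pyramid,
    build_gaussian_pyramid,
)

__all__ = [
    "DetectionConfig",
    "Keypoint",
    "detect_extrema",
    "localize_keypoint",
    "edge_response_ok",
    "detect",
]


@dataclass
class DetectionConfig:
    """Keypoint filtering thresholds.

    contrast_threshold
        Minimum |D(X̂)| on [0, 1]-normalized images.  Keypoints whose
        interpolated DoG magnitude falls below it are discarded.
    edge_gamma
        Maximum allowed ratio γ of principal curvatures; the curvature
        test accepts iff Tr(H)²/Det(H) ≤ (γ+1)²/γ and Det(H) > 0.
    max_interp_steps / offset_limit
        Refinement is re-centered on the nearest sample and repeated when
        any offset component exceeds offset_limit, up to max_interp_steps
        attempts.
    """

    contrast_threshold: float = 0.03
    edge_gamma: float = 10.0
    max_interp_steps: int = 5
    offset_limit: float = 0.5

    def __post_init__(self) -> None:
        if self.contrast_threshold <= 0:
            raise ValueError("contrast_threshold must be positive")
        if self.edge_gamma < 1:
            raise ValueError("edge_gamma must be >= 1")
        if self.max_interp_steps < 1:
            raise ValueError("max_interp_steps must be >= 1")


@dataclass
class Keypoint:
    """A refined scale-space interest point.

    ``x, y`` are sub-pixel coordinates in input-image pixels, ``sigma``
    the absolute scale.  ``orientation`` is NaN until assigned and
    ``descriptor`` None until computed.
    """

    x: float
    y: float
    sigma: float
    octave: int
    level: int
    dog_value: float
    orientation: float = float("nan")
    descriptor: np.ndarray | None = field(default=None, repr=False)


def detect_extrema(dog: DoGPyramid) -> list[tuple[int, int, int, int]]:
    """Strict 26-neighbor extrema of the DoG pyramid.

    Returns discrete candidates as (octave, level, y, x), drawn only from
    interior levels and at least one pixel away from the spatial border.
    Ties are rejected: a candidate must be strictly above (or below) all
    26 neighbors, so constant regions yield nothing.
    """
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    out: list[tuple[int, int, int, int]] = []
    for o, levels in enumerate(dog.octaves):
        if len(levels) < 3:
            continue
        cube = np.stack(levels)
        nmax = ndimage.maximum_filter(cube, footprint=footprint, mode="constant", cval=np.inf)
        nmin = ndimage.minimum_filter(cube, footprint=footprint, mode="constant", cval=-np.inf)
        is_ext = (cube > nmax) | (cube < nmin)
        is_ext[0] = is_ext[-1] = False
        is_ext[:, 0, :] = is_ext[:, -1, :] = False
        is_ext[:, :, 0] = is_ext[:, :, -1] = False
        for lvl, yy, xx in zip(*np.nonzero(is_ext)):
            out.append((o, int(lvl), int(yy), int(xx)))
    return out


def _gradient_hessian(cube: np.ndarray, l: int, y: int, x: int):
    """Central finite differences of D over (level, y, x) at unit spacing."""
    d = cube
    g = np.array(
        [
            (d[l + 1, y, x] - d[l - 1, y, x]) / 2.0,
            (d[l, y + 1, x] - d[l, y - 1, x]) / 2.0,
            (d[l, y, x + 1] - d[l, y, x - 1]) / 2.0,
        ]
    )
    c = d[l, y, x]
    dss = d[l + 1, y, x] - 2 * c + d[l - 1, y, x]
    dyy = d[l, y + 1, x] - 2 * c + d[l, y - 1, x]
    dxx = d[l, y, x + 1] - 2 * c + d[l, y, x - 1]
    dsy = (d[l + 1, y + 1, x] - d[l + 1, y - 1, x] - d[l - 1, y + 1, x] + d[l - 1, y - 1, x]) / 4.0
    dsx = (d[l + 1, y, x + 1] - d[l + 1, y, x - 1] - d[l - 1, y, x + 1] + d[l - 1, y, x - 1]) / 4.0
    dyx = (d[l, y + 1, x + 1] - d[l, y + 1, x - 1] - d[l, y - 1, x + 1] + d[l, y - 1, x - 1]) / 4.0
    h = np.array([[dss, dsy, dsx], [dsy, dyy, dyx], [dsx, dyx, dxx]])
    return g, h


def localize_keypoint(
    candidate: tuple[int, int, int, int],
    dog: DoGPyramid,
    config: DetectionConfig | None = None,
) -> Keypoint | None:
    """Refine a discrete candidate to sub-pixel position and scale.

    Solves the quadratic model for the offset X̂; if a component exceeds
    ``offset_limit`` the candidate is moved to the nearest sample and
    re-solved, up to ``max_interp_steps`` times.  Returns ``None`` when
    the Hessian is singular, the iteration leaves the pyramid interior,
    or the interpolated contrast |D(X̂)| is below threshold.
    """
    config = config or DetectionConfig()
    o, l, y, x = candidate
    cube = np.stack(dog.octaves[o])
    n_l, n_y, n_x = cube.shape

    offset = None
    for _ in range(config.max_interp_steps):
        if not (1 <= l < n_l - 1 and 1 <= y < n_y - 1 and 1 <= x < n_x - 1):
            return None
        g, h = _gradient_hessian(cube, l, y, x)
        try:
            offset = np.linalg.solve(h, -g)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(offset)):
            return None
        if np.all(np.abs(offset) <= config.offset_limit):
            break
        step = np.clip(np.round(offset), -1, 1).astype(int)
        l += step[0]
        y += step[1]
        x += step[2]
    else:
        return None
    if np.any(np.abs(offset) > config.offset_limit):
        return None

    dog_value = float(cube[l, y, x] + 0.5 * g @ offset)
    if abs(dog_value) < config.contrast_threshold:
        return None

    scale = 2.0**o
    k = dog.config.k
    sigma = dog.level_sigmas[o][l] * k ** float(offset[0])
    return Keypoint(
        x=(x + float(offset[2])) * scale,
        y=(y + float(offset[1])) * scale,
        sigma=sigma,
        octave=o,
        level=l,
        dog_value=dog_value,
    )


def edge_response_ok(
    candidate: tuple[int, int, int, int],
    dog: DoGPyramid,
    config: DetectionConfig | None = None,
) -> bool:
    """Principal-curvature ratio test on the 2-D spatial Hessian.

    Accept iff Det(H) > 0 and Tr(H)²/Det(H) ≤ (γ+1)²/γ.  The ratio is
    invariant to positive scaling of the DoG values.
    """
    config = config or DetectionConfig()
    o, l, y, x = candidate
    d = dog.octaves[o][l]
    if not (1 <= y < d.shape[0] - 1 and 1 <= x < d.shape[1] - 1):
        return False
    c = d[y, x]
    dxx = d[y, x + 1] - 2 * c + d[y, x - 1]
    dyy = d[y + 1, x] - 2 * c + d[y - 1, x]
    dxy = (d[y + 1, x + 1] - d[y + 1, x - 1] - d[y - 1, x + 1] + d[y - 1, x - 1]) / 4.0
    det = dxx * dyy - dxy * dxy
    if det <= 0:
        return False
    tr = dxx + dyy
    g = config.edge_gamma
    return tr * tr / det <= (g + 1.0) ** 2 / g


def detect(
    image: ImagePlane | np.ndarray,
    ss_config: ScaleSpaceConfig | None = None,
    det_config: DetectionConfig | None = None,
    gp: GaussianPyramid | None = None,
) -> list[Keypoint]:
    """Full detection pipeline: DoG extrema → localization → filtering.

    Every returned keypoint passed both the contrast and the edge test.
    Pass a prebuilt ``gp`` to reuse the Gaussian pyramid for the
    descriptor stage.
    """
    ss_config = ss_config or ScaleSpaceConfig()
    det_config = det_config or DetectionConfig()
    if gp is None:
        gp = build_gaussian_pyramid(image, ss_config)
    dog = build_dog_pyramid(gp)
    keypoints = []
    for cand in detect_extrema(dog):
        kp = localize_keypoint(cand, dog, det_config)
        if kp is None:
            continue
        # edge test at the refined integer location
        scale = 2.0**kp.octave
        loc = (kp.octave, kp.level, int(round(kp.y / scale)), int(round(kp.x / scale)))
        if not edge_response_ok(loc, dog, det_config):
            continue
        keypoints.append(kp)
    return keypoints
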