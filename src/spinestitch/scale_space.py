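"""Gaussian scale space and difference-of-Gaussians (DoG) pyramids.

The scale space of an image I is L(x, y, σ) = G(σ) * I, the family of
progressively Gaussian-blurred images; the DoG pyramid is the
level-by-level difference D(x, y, σ) = L(x, y, kσ) − L(x, y, σ) whose
3-D extrema seed keypoint detection.

Levels are organised in octaves: within an octave the blur grows
geometrically by k = 2^(1/s); each new octave halves the resolution.
Absolute blur of level (o, i) is base_sigma · k^i · 2^o.  Incremental
blurs are composed so the realised blur matches that schedule
(σ_inc = sqrt(σ_target² − σ_current²)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import ImagePlane

__all__ = [
    "ScaleSpaceConfig",
    "GaussianPyramid",
    "DoGPyramid",
    "build_gaussian_pyramid",
    "build_dog_pyramid",
]

#: smallest image side processed; deeper octaves are dropped
MIN_OCTAVE_SIZE = 16


@dataclass
class ScaleSpaceConfig:
    """Blur schedule of the pyramid.

    base_sigma
        Blur of the first level of octave 0, in pixels.
    scales_per_octave
        s in k = 2^(1/s).  Each octave carries s + 3 Gaussian levels so
        that every scale in the octave has DoG neighbors above and below.
    n_octaves
        Cap on octave count; ``None`` builds octaves until the image side
        would fall below 16 px.
    assumed_blur
        Blur already present in the input image (pixels); the first
        incremental blur only tops it up to base_sigma.
    """

    base_sigma: float = 1.6
    scales_per_octave: int = 3
    n_octaves: int | None = None
    assumed_blur: float = 0.5

    def __post_init__(self) -> None:
        if self.base_sigma <= 0:
            raise ValueError("base_sigma must be positive")
        if self.scales_per_octave < 1:
            raise ValueError("scales_per_octave must be >= 1")
        if self.n_octaves is not None and self.n_octaves < 1:
            raise ValueError("n_octaves must be >= 1")
        if self.assumed_blur < 0 or self.assumed_blur >= self.base_sigma:
            raise ValueError("assumed_blur must lie in [0, base_sigma)")

    @property
    def k(self) -> float:
        return 2.0 ** (1.0 / self.scales_per_octave)

    @property
    def levels_per_octave(self) -> int:
        return self.scales_per_octave + 3


@dataclass
class GaussianPyramid:
    """Octaves of Gaussian levels plus their absolute blur values."""

    octaves: list[list[np.ndarray]]
    level_sigmas: list[list[float]]
    config: ScaleSpaceConfig

    @property
    def n_octaves(self) -> int:
        return len(self.octaves)


@dataclass
class DoGPyramid:
    """Adjacent-level differences of a Gaussian pyramid.

    ``level_sigmas`` holds the σ of the lower level of each difference.
    """

    octaves: list[list[np.ndarray]]
    level_sigmas: list[list[float]]
    config: ScaleSpaceConfig

    @property
    def n_octaves(self) -> int:
        return len(self.octaves)


def _blur(image: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return image.copy()
    # reflect-at-edge padding preserves constants and avoids dark borders;
    # kernel truncated at 4σ (sub-1e-4 truncation error)
    return ndimage.gaussian_filter(image, sigma, mode="reflect", truncate=4.0)


def build_gaussian_pyramid(
    image: ImagePlane | np.ndarray, config: ScaleSpaceConfig | None = None
) -> GaussianPyramid:
    """Build the Gaussian scale space of a normalized image.

    The input is used at native resolution (no initial upsampling).  The
    next octave starts from the level whose blur is twice the octave
    base, downsampled by taking every other pixel.
    """
    config = config or ScaleSpaceConfig()
    pixels = image.pixels if isinstance(image, ImagePlane) else np.asarray(image, float)
    if min(pixels.shape) < MIN_OCTAVE_SIZE:
        raise ValueError(
            f"image must be at least {MIN_OCTAVE_SIZE} px per axis, got {pixels.shape}"
        )

    s = config.scales_per_octave
    k = config.k
    n_levels = config.levels_per_octave
    # octave-relative blur schedule and incremental blurs between levels
    rel_sigmas = [config.base_sigma * k**i for i in range(n_levels)]
    inc_sigmas = [
        math.sqrt(rel_sigmas[i] ** 2 - rel_sigmas[i - 1] ** 2)
        for i in range(1, n_levels)
    ]

    max_octaves = config.n_octaves if config.n_octaves is not None else 99
    octaves: list[list[np.ndarray]] = []
    level_sigmas: list[list[float]] = []
    base = _blur(
        pixels, math.sqrt(max(config.base_sigma**2 - config.assumed_blur**2, 0.0))
    )
    o = 0
    while o < max_octaves and min(base.shape) >= MIN_OCTAVE_SIZE:
        levels = [base]
        for inc in inc_sigmas:
            levels.append(_blur(levels[-1], inc))
        octaves.append(levels)
        level_sigmas.append([sig * 2.0**o for sig in rel_sigmas])
        # level s has twice the octave's base blur
        base = levels[s][::2, ::2]
        o += 1
    return GaussianPyramid(octaves=octaves, level_sigmas=level_sigmas, config=config)


def build_dog_pyramid(gp: GaussianPyramid) -> DoGPyramid:
    """Element-wise difference of adjacent Gaussian levels, L(kσ) − L(σ)."""
    octaves = []
    sigmas = []
    for levels, sigs in zip(gp.octaves, gp.level_sigmas):
        if len(levels) < 2:
            raise ValueError("each octave needs at least 2 Gaussian levels")
        octaves.append([levels[i + 1] - levels[i] for i in range(len(levels) - 1)])
        sigmas.append(sigs[:-1])
    return DoGPyramid(octaves=octaves, level_sigmas=sigmas, config=gp.config)
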