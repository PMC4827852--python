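"""Gradient orientations and 128-element keypoint descriptors.

Gradients of the Gaussian-smoothed image L come from central differences,
    m(x, y) = sqrt((L(x+1,y) − L(x−1,y))² + (L(x,y+1) − L(x,y−1))²)
    θ(x, y) = atan2(L(x,y+1) − L(x,y−1), L(x+1,y) − L(x−1,y))  in [0, 2π).

Each keypoint receives the dominant orientation(s) of a Gaussian-weighted
(1.5·σ) histogram of gradient orientations in a 3·(1.5·σ) window; every
histogram peak within 80% of the highest spawns its own oriented
keypoint.  The descriptor samples gradients in a support rotated to the
keypoint orientation, distributes Gaussian-weighted magnitudes
trilinearly into a 4×4 grid of 8-bin orientation histograms, and
normalizes the flattened 128-vector (clip at 0.2, renormalize).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .keypoint_detection import Keypoint
from .scale_space import GaussianPyramid

__all__ = [
    "OrientationConfig",
    "GradientField",
    "compute_gradients",
    "assign_orientations",
    "compute_descriptor",
    "GradientCache",
]

#: descriptor geometry: 4×4 spatial cells × 8 orientation bins = 128
N_CELLS = 4
N_ORI_BINS = 8
DESCRIPTOR_CLIP = 0.2
#: samples per spatial cell along each axis (16×16-sample support)
SAMPLES_PER_CELL = 4


@dataclass
class OrientationConfig:
    """Orientation-histogram parameters.

    The window radius is ``window_radius_factor`` times the Gaussian
    weighting scale (``weight_sigma_factor · σ``); peaks within
    ``peak_fraction`` of the highest peak each produce a keypoint.
    """

    hist_bins: int = 36
    window_radius_factor: float = 3.0
    weight_sigma_factor: float = 1.5
    peak_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.hist_bins < 4:
            raise ValueError("hist_bins must be >= 4")
        if not 0 < self.peak_fraction <= 1:
            raise ValueError("peak_fraction must lie in (0, 1]")


@dataclass
class GradientField:
    """Per-pixel gradient magnitude and orientation (radians, [0, 2π))."""

    magnitude: np.ndarray
    orientation: np.ndarray


def compute_gradients(level: np.ndarray) -> GradientField:
    """Central-difference gradient field of one Gaussian level.

    Border pixels use mirrored neighbors.  A zero gradient gets
    orientation 0 by the atan2 convention.
    """
    level = np.asarray(level, dtype=np.float64)
    if level.shape[0] < 3 or level.shape[1] < 3:
        raise ValueError("level must be at least 3x3")
    p = np.pad(level, 1, mode="symmetric")
    dx = p[1:-1, 2:] - p[1:-1, :-2]
    dy = p[2:, 1:-1] - p[:-2, 1:-1]
    magnitude = np.hypot(dx, dy)
    orientation = np.mod(np.arctan2(dy, dx), 2.0 * math.pi)
    return GradientField(magnitude=magnitude, orientation=orientation)


class GradientCache:
    """Lazily computed gradient fields per Gaussian-pyramid level."""

    def __init__(self, gp: GaussianPyramid):
        self.gp = gp
        self._fields: dict[tuple[int, int], GradientField] = {}

    def field(self, octave: int, level: int) -> GradientField:
        key = (octave, level)
        if key not in self._fields:
            self._fields[key] = compute_gradients(self.gp.octaves[octave][level])
        return self._fields[key]

    def nearest_level(self, octave: int, sigma: float) -> int:
        sigs = np.asarray(self.gp.level_sigmas[octave])
        return int(np.argmin(np.abs(sigs - sigma)))


def _keypoint_octave_coords(kp: Keypoint) -> tuple[float, float, float]:
    scale = 2.0**kp.octave
    return kp.x / scale, kp.y / scale, kp.sigma / scale


def assign_orientations(
    kp: Keypoint,
    gp: GaussianPyramid,
    config: OrientationConfig | None = None,
    cache: GradientCache | None = None,
) -> list[Keypoint]:
    """Dominant gradient orientation(s) of a keypoint's neighborhood.

    Builds a ``hist_bins``-bin histogram of gradient orientations within
    a 3·(1.5·σ) window, each sample weighted by its magnitude times a
    Gaussian of scale 1.5·σ.  The highest peak always yields a keypoint;
    any other local peak at ≥ 80% of its height yields an additional one.
    Peak positions are refined by parabolic interpolation.  Returns an
    empty list when the window has no in-image samples.
    """
    config = config or OrientationConfig()
    cache = cache or GradientCache(gp)
    x_o, y_o, sigma_o = _keypoint_octave_coords(kp)
    lvl = cache.nearest_level(kp.octave, kp.sigma)
    grad = cache.field(kp.octave, lvl)
    h, w = grad.magnitude.shape

    sigma_w = config.weight_sigma_factor * sigma_o
    radius = max(1, int(round(config.window_radius_factor * sigma_w)))
    cx, cy = int(round(x_o)), int(round(y_o))
    y0, y1 = max(cy - radius, 0), min(cy + radius + 1, h)
    x0, x1 = max(cx - radius, 0), min(cx + radius + 1, w)
    if y0 >= y1 or x0 >= x1:
        return []

    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - y_o
    dx = xx - x_o
    weight = np.exp(-(dx**2 + dy**2) / (2.0 * sigma_w**2))
    mags = grad.magnitude[y0:y1, x0:x1] * weight
    oris = grad.orientation[y0:y1, x0:x1]

    n = config.hist_bins
    bins = (oris / (2.0 * math.pi) * n).astype(int) % n
    hist = np.bincount(bins.ravel(), weights=mags.ravel(), minlength=n)
    if hist.max() <= 0:
        return []

    peak_floor = config.peak_fraction * hist.max()
    out = []
    best = int(np.argmax(hist))
    for b in range(n):
        left, right = hist[(b - 1) % n], hist[(b + 1) % n]
        if hist[b] < left or hist[b] < right:
            continue
        if b != best and (hist[b] < peak_floor or hist[b] == 0):
            continue
        denom = left - 2.0 * hist[b] + right
        delta = 0.0 if denom == 0 else 0.5 * (left - right) / denom
        theta = ((b + 0.5 + delta) * 2.0 * math.pi / n) % (2.0 * math.pi)
        out.append(replace(kp, orientation=theta, descriptor=None))
    return out


def compute_descriptor(
    kp: Keypoint,
    gp: GaussianPyramid,
    cache: GradientCache | None = None,
) -> np.ndarray:
    """128-element descriptor of an oriented keypoint.

    Pixels in a square support proportional to the keypoint scale are
    rotated into the keypoint frame; their gradient magnitudes, weighted
    by a Gaussian over the support (σ = half the window width), are
    distributed trilinearly into 4×4 spatial cells × 8 orientation bins.
    The flattened histogram is normalized to unit length, clipped at 0.2
    and renormalized.  A patch with no usable gradient yields the
    all-zero (degenerate) descriptor.
    """
    if not np.isfinite(kp.orientation):
        raise ValueError("keypoint orientation must be assigned first")
    cache = cache or GradientCache(gp)
    x_o, y_o, sigma_o = _keypoint_octave_coords(kp)
    lvl = cache.nearest_level(kp.octave, kp.sigma)
    grad = cache.field(kp.octave, lvl)
    h, w = grad.magnitude.shape

    hist, _ = _descriptor_histogram(grad, x_o, y_o, sigma_o, kp.orientation)
    vec = hist.ravel()
    norm = np.linalg.norm(vec)
    if norm <= 0:
        return np.zeros(N_CELLS * N_CELLS * N_ORI_BINS)
    vec = np.minimum(vec / norm, DESCRIPTOR_CLIP)
    norm = np.linalg.norm(vec)
    return vec / norm


def _descriptor_histogram(
    grad: GradientField,
    x_o: float,
    y_o: float,
    sigma_o: float,
    orientation: float,
) -> tuple[np.ndarray, float]:
    """Raw 4×4×8 histogram and the total weighted magnitude deposited.

    Trilinear weights for one sample sum to 1, so samples whose spatial
    cell coordinates are fully interior deposit their whole weighted
    magnitude; support outside the image contributes nothing.
    """
    h, w = grad.magnitude.shape
    cell_px = SAMPLES_PER_CELL * sigma_o  # cell width in pixels
    radius = int(round(cell_px * (N_CELLS + 1) * math.sqrt(2) / 2.0)) + 1
    cx, cy = int(round(x_o)), int(round(y_o))
    y0, y1 = max(cy - radius, 0), min(cy + radius + 1, h)
    x0, x1 = max(cx - radius, 0), min(cx + radius + 1, w)
    hist = np.zeros((N_CELLS + 2, N_CELLS + 2, N_ORI_BINS))
    if y0 >= y1 or x0 >= x1:
        return hist[1:-1, 1:-1], 0.0

    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = (xx - x_o).ravel()
    dy = (yy - y_o).ravel()
    cos_t, sin_t = math.cos(orientation), math.sin(orientation)
    # coordinates in the rotated descriptor frame, in cell units
    u = (cos_t * dx + sin_t * dy) / cell_px
    v = (-sin_t * dx + cos_t * dy) / cell_px
    ubin = u + N_CELLS / 2.0 - 0.5
    vbin = v + N_CELLS / 2.0 - 0.5
    keep = (ubin > -1) & (ubin < N_CELLS) & (vbin > -1) & (vbin < N_CELLS)

    mag = grad.magnitude[y0:y1, x0:x1].ravel()[keep]
    ori = grad.orientation[y0:y1, x0:x1].ravel()[keep]
    ubin, vbin = ubin[keep], vbin[keep]
    u, v = u[keep], v[keep]
    weight_sigma = N_CELLS / 2.0  # half window width, in cell units
    wgt = mag * np.exp(-(u**2 + v**2) / (2.0 * weight_sigma**2))
    obin = ((ori - orientation) % (2.0 * math.pi)) / (2.0 * math.pi) * N_ORI_BINS

    u0 = np.floor(ubin).astype(int)
    v0 = np.floor(vbin).astype(int)
    o0 = np.floor(obin).astype(int)
    fu = ubin - u0
    fv = vbin - v0
    fo = obin - o0
    for du in (0, 1):
        wu = wgt * (fu if du else 1.0 - fu)
        for dv in (0, 1):
            wv = wu * (fv if dv else 1.0 - fv)
            for do in (0, 1):
                wo = wv * (fo if do else 1.0 - fo)
                np.add.at(
                    hist,
                    (v0 + dv + 1, u0 + du + 1, (o0 + do) % N_ORI_BINS),
                    wo,
                )
    return hist[1:-1, 1:-1], float(wgt.sum())
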