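"""Synthetic sagittal spine phantom with known stitching ground truth.

The phantom emulates a sagittal whole-spine view: a column of bright
vertebral bodies separated by darker intervertebral discs, following a
laterally curved midline, with a spinal-canal band behind the column,
over dark background.  Per-pixel intensity jitter inside the structures
stands in for tissue texture and makes each vertebra's neighborhood
distinctive to a feature matcher.

``split_overlapping`` cuts the phantom into vertical bands (head-to-foot
segments, like separate cervical/thoracic/lumbar fields of view) that
share a known overlap band, with optional integer lateral jitter,
per-segment multiplicative gain (coil-sensitivity-like) and additive
Gaussian noise.  The true inter-segment translations are recorded, so
every pipeline stage can be tested against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import ImagePlane, SliceStack

__all__ = [
    "PhantomConfig",
    "SegmentSet",
    "make_phantom",
    "make_phantom_stack",
    "split_overlapping",
]


@dataclass
class PhantomConfig:
    """Geometry and contrast of the spine phantom.

    Intensities are on the [0, 1] scale; ``curvature_amp`` is the
    lateral amplitude (pixels) of the sinusoidal spinal curve;
    ``texture_sd`` the SD of the intra-structure intensity jitter.
    """

    height: int = 700
    width: int = 256
    n_vertebrae: int = 12
    vertebra_intensity: float = 0.85
    disc_intensity: float = 0.45
    cord_intensity: float = 0.35
    background: float = 0.1
    curvature_amp: float = 10.0
    texture_sd: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 128:
            raise ValueError("height must be >= 128")
        for name in ("vertebra_intensity", "disc_intensity", "cord_intensity", "background"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SegmentSet:
    """Overlapping segments cut from one phantom, with ground truth.

    ``true_offsets[i]`` is the translation (dx, dy) mapping segment
    i+1's pixel coordinates into segment i's frame.  With gains = 1 and
    noise_sd = 0, pasting the segments at the true offsets reproduces
    the phantom exactly.
    """

    segments: list[SliceStack]
    true_offsets: list[tuple[int, int]]
    overlap_px: int
    gains: list[float]
    noise_sd: float
    seed: int


def _structure_masks(config: PhantomConfig):
    h, w = config.height, config.width
    yy = np.arange(h)
    midline = w / 2.0 + config.curvature_amp * np.sin(2.0 * np.pi * yy / h)
    xx = np.arange(w)[None, :]
    dist = xx - midline[:, None]

    col_hw = max(8, int(round(w * 0.17)))
    cord_gap = max(2, col_hw // 8)
    cord_w = max(6, col_hw // 3)

    margin = int(round(h * 0.04))
    span = h - 2 * margin
    # vertebral bodies grow head-to-foot (cervical small, lumbar large),
    # which also keeps the column aperiodic
    rel_pitch = np.linspace(0.7, 1.3, config.n_vertebrae)
    pitches = rel_pitch / rel_pitch.sum() * span
    body_frac = 0.75  # rest of each pitch is disc gap
    boundaries = margin + np.concatenate([[0.0], np.cumsum(pitches)])
    in_body = np.zeros(h, dtype=bool)
    in_disc = np.zeros(h, dtype=bool)
    in_span = (yy >= margin) & (yy < h - margin)
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        body_end = lo + body_frac * (hi - lo)
        in_body |= (yy >= lo) & (yy < body_end)
        in_disc |= (yy >= body_end) & (yy < hi)
    in_body &= in_span
    in_disc &= in_span

    column = np.abs(dist) < col_hw
    vertebra = column & in_body[:, None]
    disc = column & in_disc[:, None]
    cord = (dist >= col_hw + cord_gap) & (dist < col_hw + cord_gap + cord_w) & in_span[:, None]
    return vertebra, disc, cord


def make_phantom(config: PhantomConfig | None = None) -> ImagePlane:
    """Deterministic spine phantom for a given config and seed.

    With ``texture_sd > 0`` the structures carry spatially correlated
    intensity jitter (white noise smoothed over ~1.5 px, rescaled to
    ``texture_sd``), emulating marrow and soft-tissue texture at the
    scales a feature detector probes, and each vertebral body gets a
    small random brightness offset of its own — real vertebrae are not
    interchangeable, and this is what makes them distinguishable to a
    descriptor matcher.
    """
    config = config or PhantomConfig()
    vertebra, disc, cord = _structure_masks(config)
    img = np.full((config.height, config.width), config.background)
    img[cord] = config.cord_intensity
    img[disc] = config.disc_intensity
    img[vertebra] = config.vertebra_intensity
    if config.texture_sd > 0:
        from scipy import ndimage

        rng = np.random.default_rng(config.seed)
        # correlated multi-scale texture: tissue heterogeneity shows up both
        # at fine (trabecular) and coarse scales, so smoothed white noise at
        # two correlation lengths is mixed and rescaled to texture_sd
        fine = ndimage.gaussian_filter(rng.normal(0.0, 1.0, img.shape), 1.5, mode="reflect")
        coarse = ndimage.gaussian_filter(rng.normal(0.0, 1.0, img.shape), 4.0, mode="reflect")
        mixed = fine / fine.std() + coarse / coarse.std()
        jitter = mixed / mixed.std() * config.texture_sd
        structures = vertebra | disc | cord
        img[structures] += jitter[structures]
        # per-vertebra brightness offsets (vertebrae are individuals)
        labels, n_lab = ndimage.label(vertebra)
        offsets = rng.normal(0.0, config.texture_sd, n_lab + 1)
        offsets[0] = 0.0
        img += offsets[labels]
        img = np.clip(img, 0.0, 1.0)
    return ImagePlane(img, source_id=f"phantom(seed={config.seed})")


def make_phantom_stack(
    config: PhantomConfig | None = None,
    n_slices: int = 6,
    slice_noise_sd: float = 0.0,
) -> SliceStack:
    """Multi-slice phantom: n copies with optional per-slice noise."""
    config = config or PhantomConfig()
    base = make_phantom(config).pixels
    rng = np.random.default_rng(config.seed + 1)
    planes = []
    for i in range(n_slices):
        p = base.copy()
        if slice_noise_sd > 0:
            p = np.clip(p + rng.normal(0.0, slice_noise_sd, p.shape), 0.0, 1.0)
        planes.append(ImagePlane(p, source_id=f"phantom slice {i}"))
    return SliceStack(planes, segment_label="other")


def split_overlapping(
    phantom: ImagePlane | SliceStack,
    n_segments: int = 3,
    overlap_px: int = 56,
    jitter_px: int = 0,
    gains=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SegmentSet:
    """Cut a phantom into vertical overlapping segments with ground truth.

    Adjacent segments share exactly ``overlap_px`` rows.  ``jitter_px``
    adds a random integer lateral shift (≤ jitter_px per segment) by
    sliding each segment's horizontal crop window, so segment widths are
    reduced by 2·jitter_px.  Gains (per-segment multiplicative factors)
    and seeded per-pixel Gaussian noise are applied after cutting;
    intensities are clipped back to [0, 1].
    """
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    stack = phantom if isinstance(phantom, SliceStack) else SliceStack([phantom])
    h, w = stack.height, stack.width
    if overlap_px < 1:
        raise ValueError("overlap_px must be >= 1")

    total = h + (n_segments - 1) * overlap_px
    base_h = total // n_segments
    extras = total % n_segments
    heights = [base_h + (1 if i < extras else 0) for i in range(n_segments)]
    if min(heights) < 64:
        raise ValueError("overlap too large to tile: segment height < 64 px")
    if min(heights) <= overlap_px:
        raise ValueError("overlap too large to tile: overlap exceeds segment height")

    rng = np.random.default_rng(seed)
    y_starts = [0]
    for i in range(1, n_segments):
        y_starts.append(y_starts[-1] + heights[i - 1] - overlap_px)

    m = int(jitter_px)
    if w - 2 * m < 32:
        raise ValueError("jitter_px too large for the phantom width")
    x_starts = [m + (int(rng.integers(-m, m + 1)) if m > 0 else 0) for _ in range(n_segments)]
    seg_w = w - 2 * m

    if gains is None:
        gain_list = [1.0] * n_segments
    elif np.isscalar(gains):
        gain_list = [float(gains)] * n_segments
    else:
        gain_list = [float(g) for g in gains]
        if len(gain_list) != n_segments:
            raise ValueError("gains must have one entry per segment")

    labels = ["C", "T", "L"] + ["other"] * max(0, n_segments - 3)
    segments = []
    for i in range(n_segments):
        y0, x0 = y_starts[i], x_starts[i]
        planes = []
        for s, plane in enumerate(stack.planes):
            cut = plane.pixels[y0 : y0 + heights[i], x0 : x0 + seg_w].copy()
            cut *= gain_list[i]
            if noise_sd > 0:
                cut += rng.normal(0.0, noise_sd, cut.shape)
            planes.append(ImagePlane(np.clip(cut, 0.0, 1.0), source_id=f"seg{i} slice{s}"))
        segments.append(SliceStack(planes, segment_label=labels[i]))

    true_offsets = [
        (x_starts[i + 1] - x_starts[i], y_starts[i + 1] - y_starts[i])
        for i in range(n_segments - 1)
    ]
    return SegmentSet(
        segments=segments,
        true_offsets=true_offsets,
        overlap_px=overlap_px,
        gains=gain_list,
        noise_sd=noise_sd,
        seed=seed,
    )
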