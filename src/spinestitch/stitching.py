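"""Transform estimation and multi-segment stitching.

Adjacent spine segments (cervical → thoracic → lumbar) are composited
sequentially: the C and T segments are stitched first, then the C-T
mosaic is stitched with the L segment.  The inter-segment transform is
estimated from point correspondences that are either supplied by the
user (manual point-to-point, mPTP) or produced automatically by SIFT
feature matching (aPTP).  For multi-slice stacks the transform is
estimated once, on the most central slice, and applied unchanged to
every slice.

Transform models: pure translation (component-wise median of the
displacement vectors — robust to a minority of mismatches) or a
similarity fit (rotation + isotropic scale + translation, least
squares).  Overlap compositing defaults to feather blending
(distance-to-edge weighted averaging), which hides seam intensity steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .descriptor import OrientationConfig
from .features import extract_features
from .image_io import ImagePlane, SliceStack
from .keypoint_detection import DetectionConfig
from .matching import MatchConfig, match_keypoints
from .scale_space import ScaleSpaceConfig

__all__ = [
    "PointPairSet",
    "Transform",
    "StitchResult",
    "central_slice_index",
    "estimate_transform",
    "automatic_point_pairs",
    "stitch_pair",
    "stitch_sequence",
    "propagate_to_slices",
]


@dataclass
class PointPairSet:
    """Corresponding points in two images' pixel coordinates.

    ``points_a[i]`` in the reference image matches ``points_b[i]`` in the
    image being mapped; ``source`` records whether the pairs were clicked
    (manual) or matched by the detector (automatic).
    """

    points_a: list[tuple[float, float]]
    points_b: list[tuple[float, float]]
    source: str = "manual"

    def __post_init__(self) -> None:
        if len(self.points_a) != len(self.points_b):
            raise ValueError("points_a and points_b must have equal lengths")
        if len(self.points_a) < 1:
            raise ValueError("at least one point pair is required")

    def __len__(self) -> int:
        return len(self.points_a)


@dataclass
class Transform:
    """Mapping from one image's pixel coordinates into a reference frame.

    Applies p ↦ scale · R(rotation) · p + (dx, dy).  The translation
    model keeps rotation 0 and scale 1.
    """

    model: str = "translation"
    dx: float = 0.0
    dy: float = 0.0
    rotation: float = 0.0
    scale: float = 1.0
    residuals: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.model not in ("translation", "similarity"):
            raise ValueError(f"unknown transform model {self.model!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.model == "translation" and (self.rotation != 0.0 or self.scale != 1.0):
            raise ValueError("translation model must keep rotation 0 and scale 1")
        if not all(np.isfinite([self.dx, self.dy, self.rotation, self.scale])):
            raise ValueError("transform parameters must be finite")

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return np.array(
            [
                [self.scale * c, -self.scale * s, self.dx],
                [self.scale * s, self.scale * c, self.dy],
                [0.0, 0.0, 1.0],
            ]
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        m = self.matrix
        out = pts @ m[:2, :2].T + m[:2, 2]
        return out

    def inverse(self) -> "Transform":
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        inv_scale = 1.0 / self.scale
        dx = -inv_scale * (c * self.dx - s * self.dy)
        dy = -inv_scale * (s * self.dx + c * self.dy)
        return Transform(
            model=self.model, dx=dx, dy=dy,
            rotation=-self.rotation if self.model == "similarity" else 0.0,
            scale=inv_scale if self.model == "similarity" else 1.0,
        )

    def compose(self, other: "Transform") -> "Transform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        tx = self.scale * (c * other.dx - s * other.dy) + self.dx
        ty = self.scale * (s * other.dx + c * other.dy) + self.dy
        model = "translation"
        rot = self.rotation + other.rotation
        scale = self.scale * other.scale
        if self.model == "similarity" or other.model == "similarity":
            model = "similarity"
        return Transform(model=model, dx=tx, dy=ty, rotation=rot, scale=scale)


@dataclass
class StitchResult:
    """A composited canvas plus provenance.

    ``transforms[i]`` maps segment i's pixel coordinates into canvas
    coordinates; ``overlap_masks`` holds one boolean map per stitched
    pair, true where both sources contributed; ``mask`` is true wherever
    any segment contributed.  For sequences, ``pair_sets`` records the
    point pairs each step estimated its transform from, expressed in the
    mosaic frame of that step (so they can be replayed as manual input).
    """

    canvas: ImagePlane
    transforms: list[Transform]
    overlap_masks: list[np.ndarray]
    mask: np.ndarray
    pair_sets: list[PointPairSet] = field(default_factory=list)


def central_slice_index(n_slices: int) -> int:
    """0-based index of the most central slice; lower middle for even n."""
    if n_slices < 1:
        raise ValueError("need at least one slice")
    return (n_slices - 1) // 2


def estimate_transform(pairs: PointPairSet, model: str = "translation") -> Transform:
    """Fit the segment-to-reference transform from point pairs.

    translation
        Component-wise median of the displacement vectors a − b; exact
        for consistent pairs and robust to a minority of outliers.
        Needs ≥ 1 pair.
    similarity
        Least-squares rotation + isotropic scale + translation fit.
        Needs ≥ 2 pairs.

    The fitted transform carries per-pair Euclidean ``residuals``.
    """
    a = np.asarray(pairs.points_a, dtype=np.float64)
    b = np.asarray(pairs.points_b, dtype=np.float64)
    if model == "translation":
        if len(pairs) < 1:
            raise ValueError("translation model needs at least 1 pair")
        d = a - b
        t = Transform(model="translation", dx=float(np.median(d[:, 0])), dy=float(np.median(d[:, 1])))
    elif model == "similarity":
        if len(pairs) < 2:
            raise ValueError("similarity model needs at least 2 pairs")
        from skimage.transform import SimilarityTransform

        if hasattr(SimilarityTransform, "from_estimate"):
            st = SimilarityTransform.from_estimate(b, a)
            if not st:
                raise ValueError("degenerate point configuration for similarity fit")
        else:  # scikit-image < 0.26
            st = SimilarityTransform()
            if not st.estimate(b, a):
                raise ValueError("degenerate point configuration for similarity fit")
        t = Transform(
            model="similarity",
            dx=float(st.translation[0]),
            dy=float(st.translation[1]),
            rotation=float(st.rotation),
            scale=float(st.scale),
        )
    else:
        raise ValueError(f"unknown transform model {model!r}")
    t.residuals = np.linalg.norm(t.apply(b) - a, axis=1)
    return t


def automatic_point_pairs(
    plane_a: ImagePlane | np.ndarray,
    plane_b: ImagePlane | np.ndarray,
    ss_config: ScaleSpaceConfig | None = None,
    det_config: DetectionConfig | None = None,
    ori_config: OrientationConfig | None = None,
    match_config: MatchConfig | None = None,
) -> PointPairSet:
    """SIFT-matched point correspondences between two planes (aPTP)."""
    kps_a = extract_features(plane_a, ss_config, det_config, ori_config)
    kps_b = extract_features(plane_b, ss_config, det_config, ori_config)
    if not kps_a or not kps_b:
        raise RuntimeError("no keypoints detected in one of the images")
    matches = match_keypoints(kps_a, kps_b, match_config)
    return PointPairSet(
        points_a=[(kps_a[m.idx_a].x, kps_a[m.idx_a].y) for m in matches],
        points_b=[(kps_b[m.idx_b].x, kps_b[m.idx_b].y) for m in matches],
        source="automatic",
    )


# ---------------------------------------------------------------------------
# compositing
# ---------------------------------------------------------------------------


def _feather_weights(mask: np.ndarray) -> np.ndarray:
    """Distance of each valid pixel to the nearest invalid/outside pixel."""
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    return ndimage.distance_transform_edt(padded)[1:-1, 1:-1]


def _as_array_mask(img) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(img, ImagePlane):
        a = img.pixels
    else:
        a = np.asarray(img, dtype=np.float64)
    return a, np.ones(a.shape, dtype=bool)


def _warp_to_canvas(src: np.ndarray, t_canvas: Transform, shape: tuple[int, int]):
    """Bilinearly resample ``src`` onto a canvas; returns image and mask."""
    h, w = src.shape
    inv = t_canvas.inverse()
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    src_pts = inv.apply(pts)
    xs = src_pts[:, 0].reshape(shape)
    ys = src_pts[:, 1].reshape(shape)
    # epsilon tolerance so a borderline sample (transform off an integer by
    # floating noise) still counts as inside; coordinates are then clamped
    eps = 1e-6
    mask = (xs >= -eps) & (xs <= w - 1 + eps) & (ys >= -eps) & (ys <= h - 1 + eps)
    xs = np.clip(xs, 0, w - 1)
    ys = np.clip(ys, 0, h - 1)
    warped = ndimage.map_coordinates(src, [ys, xs], order=1, mode="constant", cval=0.0)
    warped[~mask] = 0.0
    return warped, mask


def stitch_pair(
    img_a: ImagePlane | np.ndarray,
    img_b: ImagePlane | np.ndarray,
    t: Transform,
    blend: str = "feather",
    mask_a: np.ndarray | None = None,
    mask_b: np.ndarray | None = None,
) -> StitchResult:
    """Composite image b onto image a's frame under transform ``t``.

    The canvas is the bounding box of a and transformed b; pixels covered
    by one source are copied, overlap pixels are combined per ``blend``
    (feather = distance-to-edge weighted average; average; overwrite = b
    wins), and pixels outside both are background 0.  Resampling is
    bilinear.  ``mask_a``/``mask_b`` restrict each source's valid data
    (used when a is itself a mosaic with empty corners).
    """
    if blend not in ("feather", "average", "overwrite"):
        raise ValueError(f"unknown blend mode {blend!r}")
    a, full_a = _as_array_mask(img_a)
    b, full_b = _as_array_mask(img_b)
    mask_a = full_a if mask_a is None else (mask_a & full_a)
    mask_b = full_b if mask_b is None else (mask_b & full_b)

    hb, wb = b.shape
    corners = np.array([[0, 0], [wb - 1, 0], [0, hb - 1], [wb - 1, hb - 1]], float)
    tc = t.apply(corners)
    # snap near-integer bounds so floating noise in the transform does not
    # grow the canvas by a spurious row or column
    x0 = int(math.floor(min(0.0, tc[:, 0].min()) + 1e-6))
    y0 = int(math.floor(min(0.0, tc[:, 1].min()) + 1e-6))
    x1 = int(math.ceil(max(a.shape[1] - 1.0, tc[:, 0].max()) - 1e-6))
    y1 = int(math.ceil(max(a.shape[0] - 1.0, tc[:, 1].max()) - 1e-6))
    shape = (y1 - y0 + 1, x1 - x0 + 1)
    offset = Transform(model="translation", dx=-x0, dy=-y0)

    canvas_a = np.zeros(shape)
    canvas_mask_a = np.zeros(shape, dtype=bool)
    oy, ox = -y0, -x0
    canvas_a[oy : oy + a.shape[0], ox : ox + a.shape[1]] = a
    canvas_mask_a[oy : oy + a.shape[0], ox : ox + a.shape[1]] = mask_a

    t_b = offset.compose(t)
    canvas_b, canvas_mask_b = _warp_to_canvas(b, t_b, shape)
    if not np.all(mask_b):
        wm, _ = _warp_to_canvas(mask_b.astype(np.float64), t_b, shape)
        canvas_mask_b &= wm > 0.999
        canvas_b[~canvas_mask_b] = 0.0

    if blend == "overwrite":
        canvas = np.where(canvas_mask_a, canvas_a, 0.0)
        canvas = np.where(canvas_mask_b, canvas_b, canvas)
    else:
        if blend == "feather":
            w_a = _feather_weights(mask_a)
            canvas_w_a = np.zeros(shape)
            canvas_w_a[oy : oy + a.shape[0], ox : ox + a.shape[1]] = w_a
            canvas_w_b, _ = _warp_to_canvas(_feather_weights(mask_b), t_b, shape)
            canvas_w_b[~canvas_mask_b] = 0.0
            canvas_w_a[~canvas_mask_a] = 0.0
        else:
            canvas_w_a = canvas_mask_a.astype(np.float64)
            canvas_w_b = canvas_mask_b.astype(np.float64)
        den = canvas_w_a + canvas_w_b
        num = canvas_w_a * canvas_a + canvas_w_b * canvas_b
        with np.errstate(invalid="ignore", divide="ignore"):
            canvas = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        # valid pixels whose feather weight warped to 0 (extreme border)
        only = canvas_mask_a & (den == 0)
        canvas[only] = canvas_a[only]
        only = canvas_mask_b & (den == 0) & ~canvas_mask_a
        canvas[only] = canvas_b[only]

    mask = canvas_mask_a | canvas_mask_b
    return StitchResult(
        canvas=ImagePlane(np.clip(canvas, 0.0, 1.0), source_id="stitched"),
        transforms=[offset, t_b],
        overlap_masks=[canvas_mask_a & canvas_mask_b],
        mask=mask,
    )


# ---------------------------------------------------------------------------
# sequences and stacks
# ---------------------------------------------------------------------------


def _as_stack(seg) -> SliceStack:
    if isinstance(seg, SliceStack):
        return seg
    if isinstance(seg, ImagePlane):
        return SliceStack([seg])
    return SliceStack([ImagePlane(np.asarray(seg, dtype=np.float64))])


def stitch_sequence(
    segments,
    mode: str = "aptp",
    pairs: list[PointPairSet] | None = None,
    transforms: list[Transform] | None = None,
    model: str = "translation",
    blend: str = "feather",
    ss_config: ScaleSpaceConfig | None = None,
    det_config: DetectionConfig | None = None,
    ori_config: OrientationConfig | None = None,
    match_config: MatchConfig | None = None,
) -> list[StitchResult]:
    """Sequentially stitch ordered segments; one StitchResult per slice.

    stitch(seg1, seg2) = S12, then stitch(S12, seg3) = S123, and so on.
    Correspondences for each adjacent pair come from SIFT matching on the
    central slice (``aptp``), from user-supplied :class:`PointPairSet`
    objects in the current mosaic's coordinates (``mptp``), or from known
    segment-to-previous-segment transforms (``given``).  The central
    slice's transform is applied unchanged to every slice.

    A single segment is returned unchanged (degenerate case).
    """
    stacks = [_as_stack(s) for s in segments]
    if not stacks:
        raise ValueError("no segments given")
    n_slices = len(stacks[0])
    for st in stacks[1:]:
        if len(st) != n_slices:
            raise ValueError("segments disagree in slice count")
    if mode not in ("aptp", "mptp", "given"):
        raise ValueError(f"unknown stitching mode {mode!r}")
    if mode == "mptp" and (pairs is None or len(pairs) != len(stacks) - 1):
        raise ValueError("mptp mode needs one PointPairSet per adjacent pair")
    if mode == "given" and (transforms is None or len(transforms) != len(stacks) - 1):
        raise ValueError("given mode needs one Transform per adjacent pair")

    central = central_slice_index(n_slices)
    mosaics = [p.pixels.copy() for p in stacks[0].planes]
    masks = [np.ones(m.shape, dtype=bool) for m in mosaics]
    seg_transforms = [Transform()]
    overlap_masks: list[list[np.ndarray]] = [[] for _ in range(n_slices)]

    used_pairs: list[PointPairSet] = []
    for i, seg in enumerate(stacks[1:], start=1):
        if mode == "aptp":
            # correspondences are found between adjacent raw segments (the
            # overlap band lies entirely within both) and lifted into the
            # current mosaic frame, where the transform is estimated
            raw = automatic_point_pairs(
                stacks[i - 1].planes[central].pixels, seg.planes[central].pixels,
                ss_config, det_config, ori_config, match_config,
            )
            lifted = seg_transforms[i - 1].apply(np.asarray(raw.points_a))
            pair_set = PointPairSet(
                points_a=[(float(x), float(y)) for x, y in lifted],
                points_b=raw.points_b,
                source="automatic",
            )
            t = estimate_transform(pair_set, model)
            used_pairs.append(pair_set)
        elif mode == "mptp":
            t = estimate_transform(pairs[i - 1], model)
            used_pairs.append(pairs[i - 1])
        else:
            # given transforms map segment i into segment i-1's frame
            t = seg_transforms[i - 1].compose(transforms[i - 1])

        offset = None
        new_mosaics, new_masks = [], []
        for s in range(n_slices):
            res = stitch_pair(mosaics[s], seg.planes[s].pixels, t, blend,
                              mask_a=masks[s], mask_b=None)
            new_mosaics.append(res.canvas.pixels)
            new_masks.append(res.mask)
            overlap_masks[s].append(res.overlap_masks[0])
            offset = res.transforms[0]  # identical across slices
        mosaics, masks = new_mosaics, new_masks
        # re-express earlier overlap masks and transforms in the new frame
        ox, oy = int(offset.dx), int(offset.dy)
        for s in range(n_slices):
            for j, om in enumerate(overlap_masks[s][:-1]):
                grown = np.zeros(mosaics[s].shape, dtype=bool)
                grown[oy : oy + om.shape[0], ox : ox + om.shape[1]] = om
                overlap_masks[s][j] = grown
        seg_transforms = [offset.compose(tt) for tt in seg_transforms]
        seg_transforms.append(offset.compose(t))

    return [
        StitchResult(
            canvas=ImagePlane(mosaics[s], source_id="stitched"),
            transforms=list(seg_transforms),
            overlap_masks=overlap_masks[s],
            mask=masks[s],
            pair_sets=used_pairs,
        )
        for s in range(n_slices)
    ]


def propagate_to_slices(
    stack_a: SliceStack,
    stack_b: SliceStack,
    central_transform: Transform,
    blend: str = "feather",
) -> list[StitchResult]:
    """Apply the central slice's transform unchanged to every slice pair."""
    if len(stack_a) != len(stack_b):
        raise ValueError("stacks disagree in slice count")
    return [
        stitch_pair(a, b, central_transform, blend)
        for a, b in zip(stack_a.planes, stack_b.planes)
    ]
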