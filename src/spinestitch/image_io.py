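"""Reading, writing and normalizing spine-segment images and slice stacks.

Images are held as :class:`ImagePlane` objects — 2-D float arrays with
intensities min–max normalized to [0, 1] — and grouped per spine segment
(cervical / thoracic / lumbar) into :class:`SliceStack` objects.  DICOM
series, PNG and JPEG are supported on disk; keypoints, matches, point
pairs and transforms round-trip through JSON.

Coordinate convention: 0-based, x = column index, y = row index, pixel
centers at integer coordinates.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ImagePlane",
    "SliceStack",
    "FormatError",
    "GeometryError",
    "normalize_minmax",
    "read_stack",
    "write_stitched",
    "save_point_pairs",
    "load_point_pairs",
    "save_keypoints",
    "load_keypoints",
]


class FormatError(ValueError):
    """Raised for unreadable or unsupported image files."""


class GeometryError(ValueError):
    """Raised when slices of one series disagree in shape."""


@dataclass
class ImagePlane:
    """One 2-D grayscale image with intensities on a [0, 1] scale."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SliceStack:
    """Ordered, co-registered slices of one spine segment.

    All planes must share one shape.  ``segment_label`` is one of
    ``{"C", "T", "L", "other"}``; ``slice_spacing`` (mm) is metadata only.
    """

    planes: list[ImagePlane]
    segment_label: str = "other"
    slice_spacing: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.planes) < 1:
            raise ValueError("a SliceStack needs at least one plane")
        shape = self.planes[0].pixels.shape
        for p in self.planes[1:]:
            if p.pixels.shape != shape:
                raise GeometryError(
                    f"inconsistent slice shapes: {p.pixels.shape} vs {shape}"
                )

    def __len__(self) -> int:
        return len(self.planes)

    @property
    def height(self) -> int:
        return self.planes[0].height

    @property
    def width(self) -> int:
        return self.planes[0].width


def normalize_minmax(arrays: list[np.ndarray]) -> list[np.ndarray]:
    """Min–max normalize a group of arrays jointly to [0, 1].

    The minimum and maximum are taken over the whole group so slices of
    one stack stay mutually consistent.  A zero-range (constant) group
    maps to all zeros.
    """
    lo = min(float(a.min()) for a in arrays)
    hi = max(float(a.max()) for a in arrays)
    rng = hi - lo
    if rng <= 0:
        return [np.zeros_like(np.asarray(a, dtype=np.float64)) for a in arrays]
    return [(np.asarray(a, dtype=np.float64) - lo) / rng for a in arrays]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_RASTER_EXT = {".png", ".jpg", ".jpeg"}


def _read_raster(path: Path) -> np.ndarray:
    from PIL import Image

    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "I", "I;16", "F"):
                im = im.convert("F")
            return np.asarray(im, dtype=np.float64)
    except OSError as exc:  # pragma: no cover - PIL error text varies
        raise FormatError(f"cannot read image {path}: {exc}") from exc


def _dicom_sort_key(ds) -> float:
    """Slice position along the stack normal; Instance Number fallback."""
    try:
        ipp = np.asarray(ds.ImagePositionPatient, dtype=float)
        iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
        normal = np.cross(iop[:3], iop[3:])
        return float(ipp @ normal)
    except Exception:
        return float(getattr(ds, "InstanceNumber", 0))


def _read_dicom_series(path: Path) -> tuple[list[np.ndarray], float]:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception as exc:
            raise FormatError(f"cannot read DICOM file {f}: {exc}") from exc
    if not datasets:
        raise FormatError(f"no DICOM files in {path}")
    datasets.sort(key=_dicom_sort_key)
    arrays = []
    for ds in datasets:
        a = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(a * slope + intercept)
    spacing = float(getattr(datasets[0], "SliceThickness", float("nan")) or "nan")
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise GeometryError("DICOM series mixes frame sizes")
    return arrays, spacing


def read_stack(
    path: str | os.PathLike,
    format_hint: str = "auto",
    segment_label: str = "other",
) -> SliceStack:
    """Read one segment's slices from a DICOM series, directory of PNG/JPEG
    files (ordered lexicographically), or a single raster file.

    Intensities are min–max normalized to [0, 1] per stack.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    spacing = float("nan")
    if path.is_dir():
        entries = sorted(p for p in path.iterdir() if p.is_file())
        if not entries:
            raise FormatError(f"empty directory {path}")
        is_dicom = format_hint == "dicom" or (
            format_hint == "auto"
            and not all(p.suffix.lower() in _RASTER_EXT for p in entries)
        )
        if is_dicom:
            arrays, spacing = _read_dicom_series(path)
        else:
            arrays = [_read_raster(p) for p in entries]
    else:
        if format_hint == "dicom" or (
            format_hint == "auto" and path.suffix.lower() not in _RASTER_EXT
        ):
            import pydicom

            try:
                ds = pydicom.dcmread(path)
            except Exception as exc:
                raise FormatError(f"cannot read {path}: {exc}") from exc
            arrays = [ds.pixel_array.astype(np.float64)]
            spacing = float(getattr(ds, "SliceThickness", float("nan")) or "nan")
        else:
            arrays = [_read_raster(path)]

    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise GeometryError("slices disagree in shape")
    arrays = normalize_minmax(arrays)
    planes = [ImagePlane(a, source_id=str(path)) for a in arrays]
    return SliceStack(planes, segment_label=segment_label, slice_spacing=spacing)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _write_png16(plane: ImagePlane, path: Path) -> None:
    from PIL import Image

    q = np.clip(np.round(plane.pixels * 65535.0), 0, 65535).astype(np.uint16)
    Image.fromarray(q).save(path)


def _write_jpeg(plane: ImagePlane, path: Path) -> None:
    from PIL import Image

    q = np.clip(np.round(plane.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(q, mode="L").save(path, quality=95)


def _write_dicom(plane: ImagePlane, path: Path, index: int) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.InstanceNumber = index + 1
    ds.Rows, ds.Columns = plane.pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    q = np.clip(np.round(plane.pixels * 65535.0), 0, 65535).astype(np.uint16)
    ds.PixelData = q.tobytes()
    ds.save_as(path, enforce_file_format=True)


def write_stitched(stack: SliceStack, path: str | os.PathLike, format: str = "png") -> None:
    """Write a stitched stack as 16-bit PNG, JPEG (lossy), or a DICOM series.

    For a single-slice stack and a raster format, ``path`` is the output
    file; otherwise ``path`` is a directory that receives one numbered
    file per slice.  Lossless formats round-trip within one quantization
    step of the bit depth (1/65535 for 16-bit); JPEG is lossy by nature.
    """
    if not isinstance(stack, SliceStack) or len(stack) == 0:
        raise ValueError("cannot write an empty stack")
    format = format.lower()
    if format not in {"png", "jpeg", "dicom"}:
        raise FormatError(f"unsupported output format {format!r}")
    path = Path(path)
    ext = {"png": ".png", "jpeg": ".jpg", "dicom": ".dcm"}[format]

    single_file = len(stack) == 1 and (path.suffix.lower() in {ext, ".jpeg"} or (
        format != "dicom" and path.suffix.lower() in _RASTER_EXT
    ))
    try:
        if single_file:
            path.parent.mkdir(parents=True, exist_ok=True)
            targets = [path]
        else:
            path.mkdir(parents=True, exist_ok=True)
            targets = [path / f"slice_{i:03d}{ext}" for i in range(len(stack))]
        for i, (plane, target) in enumerate(zip(stack.planes, targets)):
            if format == "png":
                _write_png16(plane, target)
            elif format == "jpeg":
                _write_jpeg(plane, target)
            else:
                _write_dicom(plane, target, i)
    except OSError as exc:
        raise OSError(f"cannot write to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# JSON serialization of pipeline records
# ---------------------------------------------------------------------------


def save_point_pairs(pairs, path: str | os.PathLike) -> None:
    """Write a PointPairSet as a JSON list of {xa, ya, xb, yb} records."""
    records = [
        {"xa": float(a[0]), "ya": float(a[1]), "xb": float(b[0]), "yb": float(b[1])}
        for a, b in zip(pairs.points_a, pairs.points_b)
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def load_point_pairs(path: str | os.PathLike):
    from .stitching import PointPairSet

    records = json.loads(Path(path).read_text())
    pts_a = [(float(r["xa"]), float(r["ya"])) for r in records]
    pts_b = [(float(r["xb"]), float(r["yb"])) for r in records]
    return PointPairSet(points_a=pts_a, points_b=pts_b, source="manual")


def save_keypoints(keypoints, path: str | os.PathLike) -> None:
    records = []
    for kp in keypoints:
        rec = {
            "x": float(kp.x),
            "y": float(kp.y),
            "sigma": float(kp.sigma),
            "orientation": float(kp.orientation),
            "dog_value": float(kp.dog_value),
            "octave": int(kp.octave),
            "level": int(kp.level),
        }
        if kp.descriptor is not None:
            rec["descriptor"] = [float(v) for v in kp.descriptor]
        records.append(rec)
    Path(path).write_text(json.dumps(records))


def load_keypoints(path: str | os.PathLike):
    from .keypoint_detection import Keypoint

    out = []
    for r in json.loads(Path(path).read_text()):
        kp = Keypoint(
            x=r["x"],
            y=r["y"],
            sigma=r["sigma"],
            octave=r.get("octave", 0),
            level=r.get("level", 0),
            dog_value=r.get("dog_value", 0.0),
            orientation=r.get("orientation", float("nan")),
            descriptor=np.asarray(r["descriptor"]) if "descriptor" in r else None,
        )
        out.append(kp)
    return out
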