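"""End-to-end feature extraction: detect, orient and describe keypoints."""

from __future__ import annotations

import numpy as np

from .descriptor import GradientCache, OrientationConfig, assign_orientations, compute_descriptor
from .image_io import ImagePlane
from .keypoint_detection import DetectionConfig, Keypoint, detect
from .scale_space import ScaleSpaceConfig, build_gaussian_pyramid

__all__ = ["extract_features"]


def extract_features(
    image: ImagePlane | np.ndarray,
    ss_config: ScaleSpaceConfig | None = None,
    det_config: DetectionConfig | None = None,
    ori_config: OrientationConfig | None = None,
) -> list[Keypoint]:
    """Detect keypoints and attach orientations and 128-d descriptors.

    A keypoint with several qualifying orientation peaks appears once per
    orientation.  Keypoints with degenerate (all-zero) descriptors are
    dropped; the result is sorted by (y, x, sigma, orientation) for
    determinism.
    """
    ss_config = ss_config or ScaleSpaceConfig()
    gp = build_gaussian_pyramid(image, ss_config)
    cache = GradientCache(gp)
    out: list[Keypoint] = []
    for kp in detect(image, ss_config, det_config, gp=gp):
        for okp in assign_orientations(kp, gp, ori_config, cache=cache):
            desc = compute_descriptor(okp, gp, cache=cache)
            if not desc.any():
                continue
            okp.descriptor = desc
            out.append(okp)
    out.sort(key=lambda k: (k.y, k.x, k.sigma, k.orientation))
    return out
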