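"""Descriptor matching by Euclidean distance.

Two descriptor sets are matched by exhaustive nearest-neighbor search on
the Euclidean distance dis = sqrt(Σ (u_i − v_i)²).  Two optional filters
— Lowe's nearest/second-nearest ratio test and a mutual-consistency
check — suppress the ambiguous matches that raw nearest-distance
matching lets through; both can be disabled to match by nearest distance
alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Match",
    "MatchConfig",
    "InsufficientMatchesError",
    "euclidean_distance",
    "match_descriptors",
    "match_keypoints",
]


class InsufficientMatchesError(RuntimeError):
    """Fewer correspondences survived filtering than ``min_matches``."""


@dataclass
class Match:
    idx_a: int
    idx_b: int
    distance: float
    ratio: float


@dataclass
class MatchConfig:
    """Filtering applied after nearest-neighbor search.

    ratio_threshold
        Maximum nearest/second-nearest distance ratio (1.0 disables).
        Correct overlap matches in same-protocol stitching have far
        smaller ratios than structural lookalikes, so the default is a
        strict 0.7.
    mutual
        Require that A's nearest neighbor in B also picks A back.
    min_matches
        Minimum surviving correspondences for the pair to be usable.
    """

    ratio_threshold: float = 0.7
    mutual: bool = True
    min_matches: int = 4
    max_scale_ratio: float | None = 1.3
    max_orientation_diff: float | None = 0.35

    def __post_init__(self) -> None:
        if not 0 < self.ratio_threshold <= 1:
            raise ValueError("ratio_threshold must lie in (0, 1]")
        if self.min_matches < 1:
            raise ValueError("min_matches must be >= 1")
        if self.max_scale_ratio is not None and self.max_scale_ratio < 1:
            raise ValueError("max_scale_ratio must be >= 1")


def euclidean_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Euclidean distance between two equal-length descriptor vectors."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.sqrt(np.sum((u - v) ** 2)))


def match_descriptors(
    set_a: np.ndarray,
    set_b: np.ndarray,
    config: MatchConfig | None = None,
) -> list[Match]:
    """Match rows of ``set_a`` to their nearest rows in ``set_b``.

    Degenerate (all-zero) descriptors never match.  Distance ties are
    broken by the lower index in B.  Raises
    :class:`InsufficientMatchesError` when fewer than ``min_matches``
    matches survive the ratio and mutual filters.
    """
    config = config or MatchConfig()
    a = np.atleast_2d(np.asarray(set_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(set_b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("descriptor sets must be nonempty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("descriptor dimensionality mismatch")

    valid_a = np.linalg.norm(a, axis=1) > 0
    valid_b = np.linalg.norm(b, axis=1) > 0
    d = cdist(a, b)
    d[~valid_a, :] = np.inf
    d[:, ~valid_b] = np.inf

    nearest_b_of_a = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
    nearest_a_of_b = np.argmin(d, axis=0)

    matches: list[Match] = []
    for i in range(a.shape[0]):
        if not valid_a[i]:
            continue
        j = int(nearest_b_of_a[i])
        d1 = d[i, j]
        if not np.isfinite(d1):
            continue
        if config.mutual and int(nearest_a_of_b[j]) != i:
            continue
        row = d[i].copy()
        row[j] = np.inf
        d2 = float(row.min())
        if np.isfinite(d2) and d2 > 0:
            ratio = d1 / d2
        else:
            ratio = 0.0 if d1 == 0 else float("nan")
        if np.isfinite(ratio) and ratio > config.ratio_threshold:
            continue
        matches.append(Match(idx_a=i, idx_b=j, distance=float(d1), ratio=float(ratio)))

    if len(matches) < config.min_matches:
        raise InsufficientMatchesError(
            f"{len(matches)} matches < min_matches {config.min_matches}"
        )
    return matches


def match_keypoints(kps_a, kps_b, config: MatchConfig | None = None) -> list[Match]:
    """Match two keypoint lists via their descriptors.

    On top of the descriptor filters, matches must be geometrically
    consistent with the near-rigid registration the stitcher fits: the
    two keypoints' scales may differ by at most ``max_scale_ratio`` and
    their orientations by at most ``max_orientation_diff`` radians (set
    either to ``None`` to disable).  Each constraint is checked per
    match in isolation; no consensus over the match set is used.
    """
    config = config or MatchConfig()
    a = np.array([kp.descriptor for kp in kps_a])
    b = np.array([kp.descriptor for kp in kps_b])
    relaxed = MatchConfig(
        ratio_threshold=config.ratio_threshold,
        mutual=config.mutual,
        min_matches=1,
        max_scale_ratio=config.max_scale_ratio,
        max_orientation_diff=config.max_orientation_diff,
    )
    matches = match_descriptors(a, b, relaxed)
    kept = []
    for m in matches:
        ka, kb = kps_a[m.idx_a], kps_b[m.idx_b]
        if config.max_scale_ratio is not None:
            r = ka.sigma / kb.sigma
            if r > config.max_scale_ratio or r < 1.0 / config.max_scale_ratio:
                continue
        if config.max_orientation_diff is not None:
            d = abs(ka.orientation - kb.orientation) % (2.0 * np.pi)
            if min(d, 2.0 * np.pi - d) > config.max_orientation_diff:
                continue
        kept.append(m)
    if len(kept) < config.min_matches:
        raise InsufficientMatchesError(
            f"{len(kept)} matches < min_matches {config.min_matches}"
        )
    return kept
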