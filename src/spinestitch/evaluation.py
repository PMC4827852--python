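"""Agreement statistics between a reference and a test stitched image.

A reference/test pair is summarised by the normalized mean square error
NMSE = Σ(ref − test)² / Σ ref², the Pearson product-moment correlation r
(with its p-value), the coefficient of determination R², and a
Bland–Altman analysis of the paired differences (mean difference, sample
SD, limits of agreement mean ± 1.96·SD, and the fraction of differences
outside the limits).  Comparisons can be restricted to the pixels where
both images carry valid data, so background padding does not inflate
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .image_io import ImagePlane, SliceStack

__all__ = [
    "AgreementReport",
    "nmse",
    "pearson",
    "bland_altman",
    "agreement_report",
    "compare_slicewise",
]


@dataclass
class AgreementReport:
    """Agreement summary for one reference/test pair.

    Intensities are in the images' (arbitrary) units; ``ba_limits`` are
    the Bland–Altman limits of agreement, symmetric about the mean
    difference.
    """

    nmse: float
    pearson_r: float
    p_value: float
    r_squared: float
    ba_mean_diff: float
    ba_sd_diff: float
    ba_limits: tuple[float, float]
    ba_outlier_fraction: float
    n: int


def _pixels(img) -> np.ndarray:
    if isinstance(img, ImagePlane):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def nmse(reference, test) -> float:
    """Normalized mean square error Σ(ref − test)² / Σ ref²."""
    ref = _pixels(reference)
    tst = _pixels(test)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    denom = float(np.sum(ref**2))
    if denom == 0:
        raise ValueError("reference is all zeros; NMSE undefined")
    return float(np.sum((ref - tst) ** 2)) / denom


def pearson(reference, test) -> tuple[float, float, float]:
    """Pearson r, its p-value, and R² of the paired intensities.

    R² is the squared product-moment correlation, i.e. the coefficient
    of determination of the least-squares line through the pairs.
    """
    ref = _pixels(reference).ravel()
    tst = _pixels(test).ravel()
    if ref.size != tst.size:
        raise ValueError("inputs must have equal sizes")
    if ref.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(ref) == 0 or np.var(tst) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(ref, tst)
    return float(r), float(p), float(r * r)


def bland_altman(reference_values, test_values) -> tuple[float, float, tuple[float, float], float]:
    """Bland–Altman statistics of the differences test − reference.

    Returns (mean difference, sample SD, (lower, upper) limits of
    agreement at mean ± 1.96·SD, fraction of differences outside the
    limits).
    """
    ref = np.asarray(reference_values, dtype=np.float64).ravel()
    tst = np.asarray(test_values, dtype=np.float64).ravel()
    if ref.size != tst.size:
        raise ValueError("inputs must have equal lengths")
    if ref.size < 2:
        raise ValueError("need at least 2 paired observations")
    diff = tst - ref
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    outliers = float(np.mean((diff < lo) | (diff > hi)))
    return mean, sd, (lo, hi), outliers


def agreement_report(reference, test, mask: np.ndarray | None = None) -> AgreementReport:
    """Full agreement summary for one image pair.

    ``mask`` restricts the comparison to valid pixels (e.g. the
    intersection of two mosaics' data masks).
    """
    ref = _pixels(reference)
    tst = _pixels(test)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    if mask is not None:
        ref = ref[mask]
        tst = tst[mask]
    r, p, r2 = pearson(ref, tst)
    mean, sd, limits, outliers = bland_altman(ref, tst)
    return AgreementReport(
        nmse=nmse(ref, tst),
        pearson_r=r,
        p_value=p,
        r_squared=r2,
        ba_mean_diff=mean,
        ba_sd_diff=sd,
        ba_limits=limits,
        ba_outlier_fraction=outliers,
        n=int(ref.size),
    )


def compare_slicewise(
    ref_stack: SliceStack, test_stack: SliceStack, mask: np.ndarray | None = None
) -> tuple[list[AgreementReport], AgreementReport | None]:
    """Per-slice pixelwise agreement plus a pooled report.

    The pooled report compares the per-slice mean signal intensities of
    the two stacks (one paired observation per slice); it is ``None``
    when the stack has fewer than 3 slices.
    """
    if len(ref_stack) != len(test_stack):
        raise ValueError("stacks disagree in slice count")
    per_slice = [
        agreement_report(r, t, mask)
        for r, t in zip(ref_stack.planes, test_stack.planes)
    ]
    ref_means = []
    test_means = []
    for r, t in zip(ref_stack.planes, test_stack.planes):
        rp, tp = r.pixels, t.pixels
        if mask is not None:
            rp, tp = rp[mask], tp[mask]
        ref_means.append(float(rp.mean()))
        test_means.append(float(tp.mean()))
    pooled = None
    varies = lambda v: not np.all(np.asarray(v) == v[0])
    if len(ref_means) >= 3 and varies(ref_means) and varies(test_means):
        r, p, r2 = pearson(np.asarray(ref_means), np.asarray(test_means))
        mean, sd, limits, outliers = bland_altman(ref_means, test_means)
        pooled = AgreementReport(
            nmse=nmse(np.asarray(ref_means), np.asarray(test_means)),
            pearson_r=r, p_value=p, r_squared=r2,
            ba_mean_diff=mean, ba_sd_diff=sd, ba_limits=limits,
            ba_outlier_fraction=outliers, n=len(ref_means),
        )
    return per_slice, pooled
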