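"""T2-weighted histogram morphometry.

Tumor intensities are normalized to the mean intensity of the
contralateral kidney, summarized as a probability-density histogram, and
classified into hyperintense (bright, cyst-associated) and hypointense
(dark, necrosis-associated) components using mean +- k*SD thresholds
(k = 3 by default). The percentage of each component is

    % component = 100 * n_component_pixels / n_tumor_pixels

computed with exact rational arithmetic before float conversion.

By default the threshold reference (mean, SD) is the normalized
contralateral-kidney distribution: a tumor's own sample moments cap its
>3 SD tail at ~10% (one-sided Chebyshev), which cannot represent strongly
cystic tumors, whereas the kidney reference measures deviation from
normal-appearing parenchyma. ``reference="tumor"`` or an explicit
``(mean, sd)`` pair are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .containers import ImageVolume, ROISet

__all__ = [
    "HistogramSummary",
    "normalize_to_kidney",
    "kidney_reference",
    "pdf_histogram",
    "classify_extremes",
    "percent_components",
    "analyze_t2w",
]

HYPER, INTERIOR, HYPO = 1, 0, -1


@dataclass
class HistogramSummary:
    """Normalized-intensity histogram plus component classification."""

    values: np.ndarray  # normalized tumor intensities
    bin_edges: np.ndarray
    densities: np.ndarray  # integrates to 1
    ref_mean: float
    ref_sd: float
    k: float
    pct_hyper: float
    pct_hypo: float
    n_hyper: int
    n_hypo: int
    n_total: int
    labels: np.ndarray  # per-voxel: +1 hyper, -1 hypo, 0 interior


def _check_rois(volume: ImageVolume, rois: ROISet) -> None:
    if rois.tumor.shape != volume.data.shape:
        raise ValueError("ROI masks must match the image shape")


def normalize_to_kidney(volume: ImageVolume, rois: ROISet) -> np.ndarray:
    """Tumor voxel intensities divided by the mean kidney intensity.

    Raises if the kidney mean is not positive (a sign of a bad mask or
    corrupted data) — normalization would be meaningless.
    """
    _check_rois(volume, rois)
    kidney_mean = float(volume.data[rois.kidney].mean())
    if kidney_mean <= 0:
        raise ValueError(
            f"kidney mean intensity is {kidney_mean:g}; expected > 0 "
            "(check the kidney mask)")
    return volume.data[rois.tumor] / kidney_mean


def kidney_reference(volume: ImageVolume, rois: ROISet) -> tuple[float, float]:
    """(mean, SD) of the kidney distribution on the normalized scale.

    The normalized kidney mean is exactly 1 by construction; the SD is the
    kidney's coefficient of variation.
    """
    _check_rois(volume, rois)
    kid = volume.data[rois.kidney]
    mean = float(kid.mean())
    if mean <= 0:
        raise ValueError("kidney mean intensity must be positive")
    return 1.0, float(kid.std() / mean)


def pdf_histogram(values: np.ndarray, n_bins: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Probability-density histogram: sum(density * binwidth) == 1."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot histogram an empty sample")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    densities, edges = np.histogram(values, bins=n_bins, density=True)
    return edges, densities


def classify_extremes(values: np.ndarray, ref_mean: float, ref_sd: float,
                      k: float = 3.0) -> np.ndarray:
    """Label each value: +1 above mean + k*SD, -1 below mean - k*SD, else 0.

    Inequalities are strict, so values exactly on a threshold are interior;
    with SD = 0 this degenerates to comparison against the mean itself.
    """
    if ref_sd < 0:
        raise ValueError("reference SD must be non-negative")
    values = np.asarray(values, dtype=float)
    labels = np.zeros(values.shape, dtype=np.int8)
    labels[values > ref_mean + k * ref_sd] = HYPER
    labels[values < ref_mean - k * ref_sd] = HYPO
    return labels


def percent_components(labels: np.ndarray) -> tuple[float, float]:
    """(% hyperintense, % hypointense) as exact rationals cast to float."""
    labels = np.asarray(labels)
    total = int(labels.size)
    if total == 0:
        raise ValueError("no labels to summarize")
    n_hyper = int((labels == HYPER).sum())
    n_hypo = int((labels == HYPO).sum())
    return (float(Fraction(100 * n_hyper, total)),
            float(Fraction(100 * n_hypo, total)))


def analyze_t2w(volume: ImageVolume, rois: ROISet, k: float = 3.0,
                n_bins: int = 100,
                reference: str | tuple[float, float] = "kidney") -> HistogramSummary:
    """Full per-tumor histogram morphometry.

    ``reference`` selects the distribution supplying the threshold mean
    and SD: ``"kidney"`` (default, normalized contralateral kidney),
    ``"tumor"`` (the normalized tumor itself) or an explicit
    ``(mean, sd)`` pair on the normalized scale.
    """
    values = normalize_to_kidney(volume, rois)
    if reference == "kidney":
        ref_mean, ref_sd = kidney_reference(volume, rois)
    elif reference == "tumor":
        ref_mean, ref_sd = float(values.mean()), float(values.std())
    else:
        ref_mean, ref_sd = float(reference[0]), float(reference[1])

    edges, densities = pdf_histogram(values, n_bins)
    labels = classify_extremes(values, ref_mean, ref_sd, k)
    pct_hyper, pct_hypo = percent_components(labels)
    return HistogramSummary(
        values=values, bin_edges=edges, densities=densities,
        ref_mean=ref_mean, ref_sd=ref_sd, k=k,
        pct_hyper=pct_hyper, pct_hypo=pct_hypo,
        n_hyper=int((labels == HYPER).sum()),
        n_hypo=int((labels == HYPO).sum()),
        n_total=int(labels.size), labels=labels)
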