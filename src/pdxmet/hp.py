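"""Hyperpolarized pyruvate/lactate quantification and L/P AUC-ratio maps.

Per voxel of the spectroscopic-imaging grid, metabolite amplitudes are
integrated from magnitude spectra (or taken directly as time-courses),
voxels are gated on SNR > 3 with strictly more than 5 qualifying dynamic
timepoints, and glycolytic conversion is summarized as the ratio of the
lactate to pyruvate areas under the dynamic curves (trapezoidal rule on
the acquired time grid, no extrapolation).
"""

from __future__ import annotations

import numpy as np

from .containers import DynamicMetaboliteGrid, LPRatioResult, VoxelSelection

__all__ = [
    "integrate_peaks",
    "estimate_snr",
    "count_qualifying_timepoints",
    "select_voxels",
    "lp_auc_ratio",
    "lp_map_and_mean",
    "SNR_THRESHOLD",
    "MIN_TIMEPOINTS",
]

SNR_THRESHOLD = 3.0
MIN_TIMEPOINTS = 5  # strictly more than this many qualifying timepoints


def integrate_peaks(spectra: np.ndarray, freq: np.ndarray,
                    windows: dict[str, tuple[float, float]],
                    baseline: bool = True) -> dict[str, np.ndarray]:
    """Integrate magnitude spectra over chemical-shift windows.

    ``spectra`` has the frequency axis last; leading axes (voxels,
    timepoints) are preserved. A linear baseline estimated from the two
    window edges is subtracted (magnitude spectra carry a noise pedestal)
    and negative post-baseline amplitudes are clipped to zero. Windows
    must be mutually disjoint.
    """
    freq = np.asarray(freq, dtype=float)
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[-1] != freq.size:
        raise ValueError("frequency axis must be the last spectra axis")
    spans = sorted(windows.items(), key=lambda kv: kv[1][0])
    for (_, (lo1, hi1)), (_, (lo2, _)) in zip(spans, spans[1:]):
        if hi1 > lo2:
            raise ValueError("chemical-shift windows overlap")

    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in windows.items():
        if hi <= lo:
            raise ValueError(f"window {name!r} has non-positive width")
        sel = (freq >= lo) & (freq <= hi)
        if sel.sum() < 2:
            raise ValueError(f"window {name!r} covers fewer than 2 samples")
        f = freq[sel]
        s = spectra[..., sel]
        if baseline:
            slope = (s[..., -1] - s[..., 0]) / (f[-1] - f[0])
            base = s[..., 0][..., None] + slope[..., None] * (f - f[0])
            s = np.clip(s - base, 0.0, None)
        out[name] = np.trapezoid(s, f, axis=-1)
    return out


def estimate_snr(curve: np.ndarray, noise_sd: float) -> np.ndarray | float:
    """Peak temporal amplitude divided by the noise SD.

    The noise SD must come from a signal-free spectral or temporal
    region; a zero value is rejected rather than guessed.
    """
    if noise_sd <= 0:
        raise ValueError("noise SD must be positive; supply an explicit "
                         "noise-region estimate")
    curve = np.asarray(curve, dtype=float)
    return curve.max(axis=-1) / noise_sd


def count_qualifying_timepoints(curve: np.ndarray, noise_sd: float,
                                threshold: float = SNR_THRESHOLD) -> np.ndarray:
    """Number of timepoints whose amplitude exceeds ``threshold * noise_sd``."""
    if noise_sd <= 0:
        raise ValueError("noise SD must be positive")
    curve = np.asarray(curve, dtype=float)
    return (curve / noise_sd > threshold).sum(axis=-1)


def select_voxels(grid: DynamicMetaboliteGrid,
                  snr_threshold: float = SNR_THRESHOLD,
                  min_timepoints: int = MIN_TIMEPOINTS,
                  channel: str = "pyruvate") -> VoxelSelection:
    """Gate voxels for quantification: SNR > 3 and > 5 dynamic timepoints.

    Both thresholds are strict. ``channel`` selects which metabolite
    time-course supplies the SNR and the qualifying-timepoint count:
    ``"pyruvate"`` (default — the delivered substrate), ``"lactate"``, or
    ``"either"`` (per-timepoint maximum of the two).
    """
    if channel == "pyruvate":
        curve = grid.pyruvate
    elif channel == "lactate":
        curve = grid.lactate
    elif channel == "either":
        curve = np.maximum(grid.pyruvate, grid.lactate)
    else:
        raise ValueError("channel must be 'pyruvate', 'lactate' or 'either'")

    snr = estimate_snr(curve, grid.noise_sd)
    n_tp = count_qualifying_timepoints(curve, grid.noise_sd, snr_threshold)
    selected = (snr > snr_threshold) & (n_tp > min_timepoints)
    return VoxelSelection(snr=snr, n_timepoints=n_tp, selected=selected,
                          snr_threshold=snr_threshold,
                          min_timepoints=min_timepoints, channel=channel)


def lp_auc_ratio(pyruvate: np.ndarray, lactate: np.ndarray,
                 times: np.ndarray) -> float:
    """Trapezoidal AUC(lactate) / AUC(pyruvate) over the acquired times.

    Negative amplitudes (possible after baseline subtraction of noisy
    magnitude data) are clipped to zero first. Returns NaN when the
    pyruvate AUC is non-positive — an undefined, not a zero, ratio.
    """
    times = np.asarray(times, dtype=float)
    pyr = np.clip(np.asarray(pyruvate, dtype=float), 0.0, None)
    lac = np.clip(np.asarray(lactate, dtype=float), 0.0, None)
    if pyr.shape[-1] != times.size or lac.shape[-1] != times.size:
        raise ValueError("curves must align with the time vector")
    auc_p = float(np.trapezoid(pyr, times))
    auc_l = float(np.trapezoid(lac, times))
    if auc_p <= 0:
        return np.nan
    return auc_l / auc_p


def lp_map_and_mean(grid: DynamicMetaboliteGrid, selection: VoxelSelection,
                    tumor_mask: np.ndarray | None = None) -> LPRatioResult:
    """L/P AUC-ratio map over selected (and tumor) voxels, plus their mean.

    Voxels outside the selection/mask, or with zero pyruvate AUC, are NaN
    in the map and excluded from the mean. An empty selected set yields an
    undefined mean with a reason, never zero.
    """
    pyr = np.clip(grid.pyruvate, 0.0, None)
    lac = np.clip(grid.lactate, 0.0, None)
    auc_p = np.trapezoid(pyr, grid.times, axis=-1)
    auc_l = np.trapezoid(lac, grid.times, axis=-1)

    eligible = selection.selected.copy()
    if tumor_mask is not None:
        tumor_mask = np.asarray(tumor_mask) > 0
        if tumor_mask.ndim == 3:
            tumor_mask = tumor_mask[:, :, 0]
        eligible &= tumor_mask

    ratio = np.full(grid.grid_shape, np.nan)
    ok = eligible & (auc_p > 0)
    ratio[ok] = auc_l[ok] / auc_p[ok]

    n = int(ok.sum())
    if n == 0:
        reason = ("no voxels passed SNR/timepoint selection"
                  if not eligible.any() else "pyruvate AUC zero in all voxels")
        return LPRatioResult(ratio=ratio, auc_pyruvate=auc_p, auc_lactate=auc_l,
                             mean_ratio=np.nan, n_voxels=0, reason=reason)
    return LPRatioResult(ratio=ratio, auc_pyruvate=auc_p, auc_lactate=auc_l,
                         mean_ratio=float(ratio[ok].mean()), n_voxels=n)
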