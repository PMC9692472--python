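"""Voxel-wise apparent-diffusion-coefficient mapping with quality control.

The mono-exponential diffusion model ``S_b = S0 * exp(-b * ADC)`` is fit
per voxel by nonlinear least squares on the linear signal scale (the
log-linear solution serves only as the initializer, since the log
transform distorts Rician noise at high b). A voxel passes QC iff its
goodness of fit R^2 exceeds 0.7 and its ADC exceeds 0.1e-3 mm^2/s; tumor
summaries average QC-pass voxels only.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .containers import ADCMap, ADCSummary, DWISeries

__all__ = [
    "resample_roi_to_dwi",
    "fit_monoexp",
    "compute_adc_map",
    "summarize_adc",
    "R2_THRESHOLD",
    "ADC_FLOOR",
]

R2_THRESHOLD = 0.7
ADC_FLOOR = 0.1e-3  # mm^2/s
_MAX_NFEV = 200


def resample_roi_to_dwi(mask: np.ndarray,
                        target_shape: tuple[int, int] = (96, 96)) -> np.ndarray:
    """Nearest-neighbor in-plane resampling of an ROI mask to the DWI matrix.

    Each target voxel samples the source voxel containing its center
    (pixel-center convention over a shared field of view); slices are
    resampled independently. Resampling onto the source grid itself is the
    identity. Raises if the input or resampled mask is empty.
    """
    mask = np.asarray(mask) > 0
    if mask.ndim == 2:
        mask = mask[:, :, None]
        squeeze = True
    else:
        squeeze = False
    if not mask.any():
        raise ValueError("input mask is empty")
    nx_s, ny_s, nz = mask.shape
    nx_t, ny_t = target_shape
    # nearest source index for each target pixel center, grids aligned on a
    # shared FOV; half-even rounding keeps even-index features (e.g. the
    # exact grid center) under integer downsampling factors
    ix = np.clip(np.rint((np.arange(nx_t) + 0.5) * nx_s / nx_t - 0.5).astype(int),
                 0, nx_s - 1)
    iy = np.clip(np.rint((np.arange(ny_t) + 0.5) * ny_s / ny_t - 0.5).astype(int),
                 0, ny_s - 1)
    out = mask[np.ix_(ix, iy, np.arange(nz))]
    if not out.any():
        raise ValueError("ROI vanished after resampling (too small for the target grid)")
    return out[:, :, 0] if squeeze else out


def _r_squared(signal: np.ndarray, model: np.ndarray) -> float:
    ss_res = float(np.sum((signal - model) ** 2))
    ss_tot = float(np.sum((signal - signal.mean()) ** 2))
    if ss_tot <= 1e-12 * float(np.sum(signal**2)):
        # constant data: R^2 is degenerate; a constant is fit perfectly
        return 1.0 if ss_res <= 1e-12 * float(np.sum(signal**2)) else 0.0
    return 1.0 - ss_res / ss_tot


def fit_monoexp(signals: np.ndarray, bvalues: np.ndarray
                ) -> tuple[float, float, float, str]:
    """Fit S0 * exp(-b * ADC) to one voxel's signals.

    Returns ``(s0, adc, r2, status)`` where status is ``"ok"``,
    ``"no-signal"`` (not enough positive finite signals) or
    ``"no-convergence"``. The log-linear slope initializes the nonlinear
    fit; the fit itself minimizes residuals on the linear scale.
    """
    signals = np.asarray(signals, dtype=float)
    bvalues = np.asarray(bvalues, dtype=float)
    if signals.size != bvalues.size:
        raise ValueError("signals and b-values must align")
    finite = np.isfinite(signals)
    if finite.sum() < 2 or (signals[finite] <= 0).all():
        return np.nan, np.nan, np.nan, "no-signal"

    pos = finite & (signals > 0)
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(bvalues[pos], np.log(signals[pos]), 1)
        adc0 = max(-slope, 0.0)
        s0_0 = float(np.exp(intercept))
    else:
        adc0, s0_0 = 1e-3, float(signals[finite].max())

    def residual(p: np.ndarray) -> np.ndarray:
        return p[0] * np.exp(-bvalues[finite] * p[1]) - signals[finite]

    sol = least_squares(residual, np.array([max(s0_0, 1e-12), adc0]),
                        bounds=([0.0, 0.0], [np.inf, 1.0]),
                        max_nfev=_MAX_NFEV, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        return np.nan, np.nan, np.nan, "no-convergence"
    s0, adc = float(sol.x[0]), float(sol.x[1])
    r2 = _r_squared(signals[finite], s0 * np.exp(-bvalues[finite] * adc))
    return s0, adc, r2, "ok"


def compute_adc_map(series: DWISeries, mask: np.ndarray,
                    r2_threshold: float = R2_THRESHOLD,
                    adc_floor: float = ADC_FLOOR) -> ADCMap:
    """Fit every masked voxel and set QC flags; per-voxel failures never
    abort the map, they QC-fail with a reason."""
    mask = np.asarray(mask) > 0
    if mask.shape != series.signal.shape[:3]:
        raise ValueError("mask must match the DWI spatial grid")
    if not mask.any():
        raise ValueError("mask is empty")

    shape = series.signal.shape[:3]
    adc = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    r2 = np.full(shape, np.nan)
    qc_pass = np.zeros(shape, dtype=bool)
    qc_reason = np.full(shape, "outside", dtype=object)

    for idx in zip(*np.nonzero(mask)):
        s0_v, adc_v, r2_v, status = fit_monoexp(series.signal[idx], series.bvalues)
        adc[idx], s0[idx], r2[idx] = adc_v, s0_v, r2_v
        if status != "ok":
            qc_reason[idx] = status
        elif not r2_v > r2_threshold:
            qc_reason[idx] = "low-r2"
        elif not adc_v > adc_floor:
            qc_reason[idx] = "low-adc"
        else:
            qc_reason[idx] = "ok"
            qc_pass[idx] = True

    return ADCMap(adc=adc, s0=s0, r2=r2, qc_pass=qc_pass, qc_reason=qc_reason,
                  r2_threshold=r2_threshold, adc_floor=adc_floor)


def summarize_adc(adc_map: ADCMap, mask: np.ndarray | None = None) -> ADCSummary:
    """Mean ADC over QC-pass voxels (optionally restricted to ``mask``).

    With zero passing voxels the summary is undefined (NaN) with a
    reason — never silently zero.
    """
    considered = adc_map.qc_reason != "outside"
    if mask is not None:
        considered &= np.asarray(mask) > 0
    passing = adc_map.qc_pass & considered
    n_pass = int(passing.sum())
    n_fail = int((considered & ~adc_map.qc_pass).sum())
    if n_pass == 0:
        return ADCSummary(mean_adc=np.nan, n_pass=0, n_fail=n_fail,
                          reason="no QC-pass voxels")
    return ADCSummary(mean_adc=float(adc_map.adc[passing].mean()),
                      n_pass=n_pass, n_fail=n_fail)
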