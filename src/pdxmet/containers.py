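"""In-memory containers shared across the pipeline stages.

These are thin, validated dataclasses around numpy arrays; file I/O lives in
:mod:`pdxmet.io`. Shapes follow the acquisition conventions: image volumes
are 3-D ``(x, y, z)``, diffusion series are 4-D ``(x, y, z, b)``, and the
dynamic metabolic grid is the spectroscopic-imaging matrix ``(x, y, t)`` per
metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageVolume",
    "ROISet",
    "DWISeries",
    "ADCMap",
    "ADCSummary",
    "DynamicMetaboliteGrid",
    "VoxelSelection",
    "LPRatioResult",
]


@dataclass
class ImageVolume:
    """3-D intensity volume with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive numbers (mm)")
        self.spacing = tuple(float(s) for s in self.spacing)


@dataclass
class ROISet:
    """Tumor and contralateral-kidney masks drawn on the same grid.

    Masks must be non-empty, mutually disjoint and shaped like the image
    they annotate (checked against the image at use sites).
    """

    tumor: np.ndarray
    kidney: np.ndarray

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=bool)
        self.kidney = np.asarray(self.kidney, dtype=bool)
        if self.tumor.shape != self.kidney.shape:
            raise ValueError("tumor and kidney masks must share a shape")
        if not self.tumor.any():
            raise ValueError("tumor mask is empty")
        if not self.kidney.any():
            raise ValueError("kidney mask is empty")
        if (self.tumor & self.kidney).any():
            raise ValueError("tumor and kidney masks overlap")


@dataclass
class DWISeries:
    """Multi-b-value diffusion-weighted series, signal in arbitrary units."""

    signal: np.ndarray  # (x, y, z, n_b)
    bvalues: np.ndarray  # s/mm^2
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("DWI signal must be 4-D (x, y, z, b)")
        if self.bvalues.ndim != 1 or self.signal.shape[3] != self.bvalues.size:
            raise ValueError("b-value list must match the 4th signal axis")
        if self.bvalues.size < 2:
            raise ValueError("need at least 2 b-values")
        if (self.bvalues < 0).any():
            raise ValueError("b-values must be non-negative")
        if (np.diff(self.bvalues) <= 0).any():
            raise ValueError("b-values must be strictly increasing")


@dataclass
class ADCMap:
    """Voxel-wise mono-exponential fit results with quality-control flags.

    QC passes iff R^2 exceeds ``r2_threshold`` and ADC exceeds
    ``adc_floor`` (defaults 0.7 and 0.1e-3 mm^2/s).
    """

    adc: np.ndarray  # mm^2/s
    s0: np.ndarray  # a.u.
    r2: np.ndarray
    qc_pass: np.ndarray  # bool
    qc_reason: np.ndarray  # str codes: ok | low-r2 | low-adc | no-signal | no-convergence | outside
    r2_threshold: float = 0.7
    adc_floor: float = 0.1e-3


@dataclass
class ADCSummary:
    """Mean ADC over QC-pass voxels; undefined (NaN) with a reason if none pass."""

    mean_adc: float
    n_pass: int
    n_fail: int
    reason: str = "ok"

    @property
    def defined(self) -> bool:
        return np.isfinite(self.mean_adc)


@dataclass
class DynamicMetaboliteGrid:
    """Per-voxel pyruvate/lactate time-courses on the CSI grid.

    Amplitudes are quantified peak areas (a.u.). ``times`` are the
    acquisition times in seconds after injection start; the default
    protocol samples 15 timepoints every 4.2 s from 10 s.
    """

    pyruvate: np.ndarray  # (nx, ny, nt)
    lactate: np.ndarray  # (nx, ny, nt)
    times: np.ndarray  # (nt,)
    noise_sd: float = 0.0
    spectra: np.ndarray | None = None  # optional (nx, ny, nt, nfreq), magnitude
    freq_ppm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pyruvate = np.asarray(self.pyruvate, dtype=float)
        self.lactate = np.asarray(self.lactate, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.pyruvate.shape != self.lactate.shape:
            raise ValueError("pyruvate and lactate grids must share a shape")
        if self.pyruvate.ndim != 3:
            raise ValueError("dynamic grid must be (x, y, t)")
        if self.pyruvate.shape[2] != self.times.size:
            raise ValueError("time axis must match the times vector")
        if self.times.size >= 2 and (np.diff(self.times) <= 0).any():
            raise ValueError("acquisition times must be strictly increasing")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.pyruvate.shape[:2]


@dataclass
class VoxelSelection:
    """Per-voxel SNR gate for metabolic quantification.

    ``selected`` iff SNR > ``snr_threshold`` and the count of qualifying
    dynamic timepoints is strictly greater than ``min_timepoints``.
    """

    snr: np.ndarray  # (nx, ny)
    n_timepoints: np.ndarray  # (nx, ny) int
    selected: np.ndarray  # bool
    snr_threshold: float = 3.0
    min_timepoints: int = 5
    channel: str = "pyruvate"


@dataclass
class LPRatioResult:
    """Lactate-to-pyruvate AUC ratio map and tumor mean over selected voxels."""

    ratio: np.ndarray  # (nx, ny), NaN where unselected/undefined
    auc_pyruvate: np.ndarray
    auc_lactate: np.ndarray
    mean_ratio: float = field(default=np.nan)
    n_voxels: int = 0
    reason: str = "ok"

    @property
    def defined(self) -> bool:
        return np.isfinite(self.mean_ratio)
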