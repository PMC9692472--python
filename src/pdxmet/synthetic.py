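"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: T2-
weighted anatomical phantoms with cystic/necrotic components, multi-b-value
diffusion series, dynamic hyperpolarized pyruvate/lactate grids on the 8x8
spectroscopic-imaging matrix, steady-state NMR peak tables with prescribed
pool sizes and fractional enrichments, and whole multi-group cohorts laid
out on disk for the end-to-end pipeline.

The generators emulate the study design they are meant to exercise:
orthotopic renal tumors referenced to the contralateral kidney, mono-
exponential diffusion decay with Rician (magnitude) noise, a gamma-variate
pyruvate bolus sampled 15 times every 4.2 s starting 10 s after injection,
and TSP-referenced metabolite quantification of uniformly 13C-labeled
tissue. All randomness flows from a single integer seed through labeled
child streams (see :mod:`pdxmet._rng`), so identical specs give
bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import stream
from .containers import DWISeries, DynamicMetaboliteGrid, ImageVolume, ROISet
from .exchange import simulate_two_site
from .isotopomer import simulate_multiplets

__all__ = [
    "PhantomSpec", "PhantomTruth", "make_t2w_phantom",
    "DWIGroundTruth", "make_dwi_series",
    "ExchangeModelParams", "make_hp_dynamics",
    "NMRGroundTruth", "MetabolitePool", "NMRTables", "make_nmr_tables",
    "GroupSpec", "make_cohort", "default_groups",
    "DEFAULT_BVALUES", "add_noise",
]

DEFAULT_BVALUES = np.array([0.0, 200.0, 400.0, 600.0, 800.0, 1000.0])

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


def _box_mask(shape: tuple[int, int, int], box: Box) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = box
    mask[x0:x1, y0:y1, z0:z1] = True
    return mask


def add_noise(signal: np.ndarray, sd: float, rng: np.random.Generator,
              model: str = "rician") -> np.ndarray:
    """Add measurement noise to a noiseless magnitude signal.

    Rician noise is the magnitude of a complex Gaussian perturbation —
    the correct model for magnitude MR images, upward-biased at low SNR.
    """
    if sd < 0:
        raise ValueError("noise SD must be non-negative")
    if sd == 0:
        return np.asarray(signal, dtype=float).copy()
    signal = np.asarray(signal, dtype=float)
    if model == "rician":
        re = signal + rng.normal(0.0, sd, signal.shape)
        im = rng.normal(0.0, sd, signal.shape)
        return np.hypot(re, im)
    if model == "gaussian":
        return signal + rng.normal(0.0, sd, signal.shape)
    raise ValueError(f"unknown noise model {model!r}")


# --------------------------------------------------------------------------
# T2-weighted anatomical phantom


@dataclass
class PhantomSpec:
    """Geometry and intensity model of the anatomical phantom.

    Tumor voxels are a mixture of three tissue classes: normal tumor,
    cystic (bright) and necrotic (dark). Class intensities are Gaussians;
    the cyst/necrosis means are placed well beyond the +-3 SD
    classification thresholds of the kidney reference so that at zero
    noise the downstream classifier recovers the constructed labels
    exactly. Intensities are in arbitrary units.
    """

    shape: tuple[int, int, int] = (32, 32, 8)
    spacing: tuple[float, float, float] = (0.25, 0.25, 1.0)
    kidney_box: Box = ((3, 13), (6, 26), (2, 7))
    tumor_box: Box = ((18, 28), (6, 26), (2, 7))
    cystic_fraction: float = 0.0
    necrotic_fraction: float = 0.0
    kidney_mean: float = 100.0
    kidney_sd: float = 5.0
    tumor_mean: float = 100.0
    tumor_sd: float = 5.0
    cyst_mean: float = 160.0
    cyst_sd: float = 5.0
    necrosis_mean: float = 40.0
    necrosis_sd: float = 5.0
    background_mean: float = 15.0
    background_sd: float = 3.0
    noise_sd: float = 0.0
    noise_model: str = "rician"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.cystic_fraction <= 1.0
                and 0.0 <= self.necrotic_fraction <= 1.0):
            raise ValueError("class fractions must lie in [0, 1]")
        if self.cystic_fraction + self.necrotic_fraction > 1.0:
            raise ValueError("cystic + necrotic fraction exceeds 1")
        for name in ("kidney_sd", "tumor_sd", "cyst_sd", "necrosis_sd",
                     "background_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kidney_mean <= 0:
            raise ValueError("kidney mean must be positive")
        kid = _box_mask(self.shape, self.kidney_box)
        tum = _box_mask(self.shape, self.tumor_box)
        if not kid.any() or not tum.any():
            raise ValueError("kidney/tumor boxes must be non-empty")
        if (kid & tum).any():
            raise ValueError("kidney and tumor masks overlap")
        # separation guidance: extreme-class means should clear the
        # mean +- 3 SD thresholds by >= 4 reference SDs for exact recovery
        hyper_thr = self.kidney_mean + 3.0 * self.kidney_sd
        hypo_thr = self.kidney_mean - 3.0 * self.kidney_sd
        if self.cystic_fraction > 0 and self.cyst_mean < hyper_thr + 4 * self.kidney_sd:
            warnings.warn("cyst mean within 4 reference SDs of the hyper "
                          "threshold; zero-noise recovery may be inexact")
        if self.necrotic_fraction > 0 and self.necrosis_mean > hypo_thr - 4 * self.kidney_sd:
            warnings.warn("necrosis mean within 4 reference SDs of the hypo "
                          "threshold; zero-noise recovery may be inexact")


@dataclass
class PhantomTruth:
    """Constructed tissue class per tumor voxel.

    ``labels`` is an int8 volume: -1 outside the tumor, 0 normal tumor,
    1 cystic, 2 necrotic.
    """

    labels: np.ndarray
    n_cystic: int
    n_necrotic: int
    n_tumor: int

    @property
    def pct_cystic(self) -> float:
        return 100.0 * self.n_cystic / self.n_tumor

    @property
    def pct_necrotic(self) -> float:
        return 100.0 * self.n_necrotic / self.n_tumor


def make_t2w_phantom(spec: PhantomSpec) -> tuple[ImageVolume, ROISet, PhantomTruth]:
    """Generate a T2-weighted phantom with kidney/tumor ROIs and truth labels.

    Exact counts of cystic and necrotic voxels are assigned
    (``round(fraction * n_tumor)``), their positions drawn without
    replacement from the tumor mask.
    """
    spec.validate()
    rng_assign = stream(spec.seed, "t2w-assign")
    rng_draw = stream(spec.seed, "t2w-draw")
    rng_noise = stream(spec.seed, "t2w-noise")

    kidney = _box_mask(spec.shape, spec.kidney_box)
    tumor = _box_mask(spec.shape, spec.tumor_box)
    n_tumor = int(tumor.sum())
    n_cyst = int(round(spec.cystic_fraction * n_tumor))
    n_necr = int(round(spec.necrotic_fraction * n_tumor))

    labels = np.full(spec.shape, -1, dtype=np.int8)
    labels[tumor] = 0
    tumor_idx = np.flatnonzero(tumor.ravel())
    chosen = rng_assign.choice(tumor_idx, size=n_cyst + n_necr, replace=False)
    flat_labels = labels.ravel()
    flat_labels[chosen[:n_cyst]] = 1
    flat_labels[chosen[n_cyst:]] = 2
    labels = flat_labels.reshape(spec.shape)

    data = spec.background_mean + spec.background_sd * rng_draw.standard_normal(spec.shape)
    data[kidney] = spec.kidney_mean + spec.kidney_sd * rng_draw.standard_normal(int(kidney.sum()))
    for code, mean, sd in ((0, spec.tumor_mean, spec.tumor_sd),
                           (1, spec.cyst_mean, spec.cyst_sd),
                           (2, spec.necrosis_mean, spec.necrosis_sd)):
        sel = labels == code
        data[sel] = mean + sd * rng_draw.standard_normal(int(sel.sum()))

    data = add_noise(data, spec.noise_sd, rng_noise, spec.noise_model)
    volume = ImageVolume(data, spec.spacing)
    rois = ROISet(tumor=tumor, kidney=kidney)
    truth = PhantomTruth(labels=labels, n_cystic=n_cyst, n_necrotic=n_necr,
                         n_tumor=n_tumor)
    return volume, rois, truth


# --------------------------------------------------------------------------
# Diffusion-weighted series


@dataclass
class DWIGroundTruth:
    """Per-voxel mono-exponential diffusion ground truth.

    Noiseless signal at b is ``S0 * exp(-b * ADC)``; ADC in mm^2/s.
    """

    adc: np.ndarray  # (x, y, z), mm^2/s
    s0: np.ndarray  # (x, y, z), a.u.
    bvalues: np.ndarray = field(default_factory=lambda: DEFAULT_BVALUES.copy())
    noise_model: str = "rician"
    noise_sd: float = 0.0
    spacing: tuple[float, float, float] = (0.33, 0.33, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.adc = np.atleast_3d(np.asarray(self.adc, dtype=float))
        self.s0 = np.atleast_3d(np.asarray(self.s0, dtype=float))
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if self.adc.shape != self.s0.shape:
            raise ValueError("ADC and S0 grids must share a shape")
        if (self.adc < 0).any():
            raise ValueError("true ADC must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.bvalues.size < 2 or (np.diff(self.bvalues) <= 0).any():
            raise ValueError("b-values must be strictly increasing, >= 2 of them")
        if self.bvalues[0] != 0:
            raise ValueError("b-value list must include b = 0")
        if (self.bvalues < 0).any():
            raise ValueError("b-values must be non-negative")


def make_dwi_series(truth: DWIGroundTruth) -> DWISeries:
    """Forward-simulate the diffusion series from voxelwise (S0, ADC)."""
    rng = stream(truth.seed, "dwi-noise")
    signal = truth.s0[..., None] * np.exp(-truth.bvalues[None, None, None, :]
                                          * truth.adc[..., None])
    signal = add_noise(signal, truth.noise_sd, rng, truth.noise_model)
    return DWISeries(signal=signal, bvalues=truth.bvalues.copy(),
                     spacing=truth.spacing)


# --------------------------------------------------------------------------
# Hyperpolarized dynamics


@dataclass
class ExchangeModelParams:
    """Acquisition and exchange parameters for the dynamic 13C grid.

    Defaults follow the acquisition protocol the pipeline targets: an 8x8
    spectroscopic matrix, 15 timepoints every 4.2 s starting 10 s after
    injection, 10 degree excitations. T1 defaults (43 s pyruvate, 33 s
    lactate) are typical in-vivo values at 3 T. The bolus is a
    gamma-variate (shape 3, scale 1.5 s) starting at injection; a delta
    bolus is retained for closed-form checks.
    """

    kpl: np.ndarray | float = 0.02  # s^-1, scalar or (nx, ny)
    grid_shape: tuple[int, int] = (8, 8)
    t1_pyruvate: float = 43.0
    t1_lactate: float = 33.0
    flip_deg: float = 10.0
    n_timepoints: int = 15
    tr: float = 4.2
    start_time: float = 10.0
    bolus: str = "gamma"
    bolus_arrival: float = 0.0
    bolus_shape: float = 3.0
    bolus_scale: float = 1.5
    bolus_amplitude: np.ndarray | float = 100.0  # a.u., scalar or (nx, ny)
    noise_sd: float = 0.0
    make_spectra: bool = False
    linewidth_ppm: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if np.any(np.asarray(self.kpl) < 0):
            raise ValueError("kPL must be non-negative")
        if self.t1_pyruvate <= 0 or self.t1_lactate <= 0:
            raise ValueError("T1 values must be positive")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.tr * np.arange(self.n_timepoints)


# 13C chemical shifts (ppm) used for optional spectral synthesis
PYRUVATE_PPM = 171.0
LACTATE_PPM = 183.2
SPECTRAL_AXIS_PPM = (160.0, 195.0, 512)


def _lorentzian(ppm: np.ndarray, center: float, area: float,
                fwhm: float) -> np.ndarray:
    hwhm = fwhm / 2.0
    return area / np.pi * hwhm / ((ppm - center) ** 2 + hwhm**2)


def make_hp_dynamics(params: ExchangeModelParams) -> DynamicMetaboliteGrid:
    """Simulate the dynamic pyruvate/lactate grid via two-site exchange.

    Per voxel the driven linear system of :mod:`pdxmet.exchange` is
    sampled at the acquisition times; additive Gaussian amplitude noise
    models quantification noise on the peak areas. Optionally Lorentzian
    magnitude spectra are synthesized per timepoint.
    """
    params.validate()
    nx, ny = params.grid_shape
    kpl = np.broadcast_to(np.asarray(params.kpl, dtype=float), (nx, ny)).copy()
    amp = np.broadcast_to(np.asarray(params.bolus_amplitude, dtype=float),
                          (nx, ny)).copy()
    times = params.times

    pyr, lac = simulate_two_site(
        times, kpl, params.t1_pyruvate, params.t1_lactate,
        flip_deg=params.flip_deg, tr=params.tr, bolus=params.bolus,
        bolus_arrival=params.bolus_arrival, bolus_shape=params.bolus_shape,
        bolus_scale=params.bolus_scale, bolus_amplitude=1.0)
    pyr = pyr * amp[..., None]
    lac = lac * amp[..., None]

    rng = stream(params.seed, "hp-noise")
    if params.noise_sd > 0:
        pyr = pyr + rng.normal(0.0, params.noise_sd, pyr.shape)
        lac = lac + rng.normal(0.0, params.noise_sd, lac.shape)

    spectra = freq = None
    if params.make_spectra:
        lo, hi, n = SPECTRAL_AXIS_PPM
        freq = np.linspace(lo, hi, n)
        spectra = (_lorentzian(freq, PYRUVATE_PPM, 1.0, params.linewidth_ppm)
                   * np.clip(pyr, 0, None)[..., None]
                   + _lorentzian(freq, LACTATE_PPM, 1.0, params.linewidth_ppm)
                   * np.clip(lac, 0, None)[..., None])
        if params.noise_sd > 0:
            spectra = np.abs(spectra + rng.normal(
                0.0, params.noise_sd / 50.0, spectra.shape))

    return DynamicMetaboliteGrid(pyruvate=pyr, lactate=lac, times=times,
                                 noise_sd=params.noise_sd, spectra=spectra,
                                 freq_ppm=freq)


# --------------------------------------------------------------------------
# NMR tables


@dataclass
class MetabolitePool:
    """True pool size (nmol/mg tissue), fractional enrichment and the
    proton multiplicity of the quantified 1-D resonance."""

    pool: float
    fe: float
    protons: int

    def validate(self, name: str) -> None:
        if self.pool < 0:
            raise ValueError(f"{name}: pool size must be non-negative")
        if not 0.0 <= self.fe <= 1.0:
            raise ValueError(f"{name}: FE must lie in [0, 1]")
        if self.protons <= 0:
            raise ValueError(f"{name}: proton multiplicity must be positive")


def _default_panel() -> dict[str, MetabolitePool]:
    # plausible wet-tissue pools (nmol/mg) for a glycolytic renal tumor
    return {
        "lactate": MetabolitePool(25.0, 0.35, 3),
        "alanine": MetabolitePool(3.5, 0.30, 3),
        "glutamate": MetabolitePool(8.0, 0.10, 2),
        "glucose": MetabolitePool(4.0, 0.45, 1),
        "taurine": MetabolitePool(12.0, 0.0, 4),
        "creatine": MetabolitePool(7.0, 0.0, 3),
        "choline": MetabolitePool(1.5, 0.0, 9),
        "glycerophosphocholine": MetabolitePool(2.5, 0.0, 9),
        "phosphoethanolamine": MetabolitePool(3.0, 0.0, 2),
        "myo-inositol": MetabolitePool(5.0, 0.0, 1),
        "atp": MetabolitePool(2.0, 0.0, 1),
    }


@dataclass
class NMRGroundTruth:
    """Ground truth behind the synthetic NMR peak tables.

    The labeling scenario (``f_pdh``, ``y_pc``, ``y_s``) drives the
    glutamate multiplet table through the isotopomer forward model of
    :mod:`pdxmet.isotopomer` — the single source of truth for multiplet
    patterns. TSP is the internal concentration standard (9 protons).
    """

    metabolites: dict[str, MetabolitePool] = field(default_factory=_default_panel)
    tsp_conc_mm: float = 0.5  # mM in the NMR sample
    tsp_volume_ml: float = 0.6
    tsp_protons: int = 9
    tissue_mass_mg: float = 50.0
    tsp_area: float = 1000.0
    area_noise_cv: float = 0.0
    f_pdh: float = 0.5
    y_pc: float = 0.5
    y_s: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name, m in self.metabolites.items():
            m.validate(name)
        if self.tsp_area <= 0:
            raise ValueError("TSP area must be positive")
        if self.tissue_mass_mg <= 0 or self.tsp_volume_ml <= 0 or self.tsp_conc_mm <= 0:
            raise ValueError("TSP amount and tissue mass must be positive")
        if self.area_noise_cv < 0:
            raise ValueError("noise CV must be non-negative")

    @property
    def tsp_amount_nmol(self) -> float:
        return self.tsp_conc_mm * self.tsp_volume_ml * 1000.0  # mM * mL -> nmol


@dataclass
class NMRTables:
    """Synthetic peak tables: 1-D areas, HSQC labeled concentrations and
    glutamate multiplet fractions."""

    peaks_1d: pd.DataFrame  # metabolite, area, protons (incl. TSP row)
    hsqc: pd.DataFrame  # metabolite, labeled_nmol_mg
    multiplets: pd.DataFrame  # carbon, component, fraction


def make_nmr_tables(truth: NMRGroundTruth) -> NMRTables:
    """Forward-generate the three NMR tables from the ground truth.

    1-D areas are proportional to pool x proton multiplicity referenced to
    the TSP area; HSQC entries are labeled concentrations (pool x FE);
    multiplet fractions come from the isotopomer forward model. Noise is
    multiplicative with the given CV; noisy multiplet fractions are
    re-normalized per carbon, as relative peak volumes are in practice.
    """
    truth.validate()
    rng = stream(truth.seed, "nmr-noise")

    def jitter(x: float) -> float:
        if truth.area_noise_cv == 0:
            return x
        return float(x * (1.0 + truth.area_noise_cv * rng.standard_normal()))

    rows = [{"metabolite": "TSP", "area": truth.tsp_area,
             "protons": truth.tsp_protons}]
    hsqc_rows = []
    for name, m in truth.metabolites.items():
        area = (truth.tsp_area * (m.pool * truth.tissue_mass_mg / truth.tsp_amount_nmol)
                * (m.protons / truth.tsp_protons))
        rows.append({"metabolite": name, "area": max(jitter(area), 0.0),
                     "protons": m.protons})
        hsqc_rows.append({"metabolite": name,
                          "labeled_nmol_mg": max(jitter(m.pool * m.fe), 0.0)})

    mult = simulate_multiplets(truth.f_pdh, truth.y_pc, truth.y_s)
    mdf = mult.to_frame()
    if truth.area_noise_cv > 0:
        noisy = np.clip(mdf["fraction"].to_numpy()
                        * (1.0 + truth.area_noise_cv
                           * rng.standard_normal(len(mdf))), 0.0, None)
        mdf["fraction"] = noisy
        for carbon, sub in mdf.groupby("carbon"):
            s = sub["fraction"].sum()
            if s > 0:
                mdf.loc[sub.index, "fraction"] = sub["fraction"] / s

    return NMRTables(peaks_1d=pd.DataFrame(rows),
                     hsqc=pd.DataFrame(hsqc_rows), multiplets=mdf)


# --------------------------------------------------------------------------
# Cohort generation


@dataclass
class GroupSpec:
    """Per-group parameter distributions for cohort simulation.

    Defaults describe a moderately glycolytic, homogeneous tumor line;
    per-tumor values are drawn around the group means.
    """

    name: str = "groupA"
    n_tumors: int = 3
    cystic_fraction: float = 0.02
    necrotic_fraction: float = 0.005
    adc: float = 1.2e-3  # mm^2/s
    adc_sd: float = 0.05e-3
    kpl_mean: float = 0.02  # s^-1
    kpl_sd: float = 0.004
    growth_rate: float = 0.03  # cc/day
    f_pdh: float = 0.5
    y_pc: float = 0.0
    y_s: float = 0.0
    lactate_fe: float = 0.35
    t2w_noise_sd: float = 2.0
    dwi_noise_sd: float = 20.0  # with S0=1000: SNR 50
    hp_noise_sd: float = 1.0
    nmr_noise_cv: float = 0.03


def default_groups() -> list[GroupSpec]:
    return [
        GroupSpec(name="lineA", n_tumors=3, kpl_mean=0.02, adc=1.2e-3,
                  cystic_fraction=0.02, growth_rate=0.02),
        GroupSpec(name="lineB", n_tumors=3, kpl_mean=0.06, adc=1.5e-3,
                  cystic_fraction=0.10, growth_rate=0.05),
    ]


# DWI simulation geometry for cohorts: small grid, tumor sub-box
_DWI_SHAPE = (24, 24, 2)
_DWI_TUMOR_BOX: Box = ((6, 18), (6, 18), (0, 2))
# HP grid: tumor occupies the central 4x4 block of the 8x8 matrix
_HP_TUMOR = np.zeros((8, 8), dtype=bool)
_HP_TUMOR[2:6, 2:6] = True


def make_cohort(groups: list[GroupSpec] | None, out_dir: str | Path,
                seed: int = 0) -> pd.DataFrame:
    """Generate a cohort directory of synthetic tumors with a truth manifest.

    Layout::

        out_dir/
          manifest.csv        one row of true parameters per tumor
          config.yaml         generation parameters echoed back
          <group>_<k>/
            t2w.nii, tumor_mask.nii, kidney_mask.nii
            dwi.nii, dwi.bvals.json, dwi_mask.nii
            hp_dynamics.nii, hp_dynamics.timing.json, hp_mask.nii
            nmr_peaks1d.csv, nmr_hsqc.csv, nmr_multiplets.csv
            volumes.csv       tumor volume (cc) vs day, for growth rate
    """
    from . import io as _io

    if groups is None:
        groups = default_groups()
    if len(groups) < 1:
        raise ValueError("need at least one group")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = []
    tumor_index = 0
    for group in groups:
        for k in range(group.n_tumors):
            rng = stream(seed, "cohort-params", tumor_index)
            tid = f"{group.name}_{k}"
            tdir = out_dir / tid
            tdir.mkdir(exist_ok=True)

            kpl = max(float(rng.normal(group.kpl_mean, group.kpl_sd)), 1e-4)
            adc = max(float(rng.normal(group.adc, group.adc_sd)), 1e-4 * 1e-3)

            # anatomical phantom
            pspec = PhantomSpec(cystic_fraction=group.cystic_fraction,
                                necrotic_fraction=group.necrotic_fraction,
                                noise_sd=group.t2w_noise_sd,
                                seed=seed * 1000 + tumor_index)
            vol, rois, truth = make_t2w_phantom(pspec)
            _io.save_volume(tdir / "t2w.nii", vol.data, vol.spacing)
            _io.save_mask(tdir / "tumor_mask.nii", rois.tumor, vol.spacing)
            _io.save_mask(tdir / "kidney_mask.nii", rois.kidney, vol.spacing)

            # diffusion series
            dwi_mask = _box_mask(_DWI_SHAPE, _DWI_TUMOR_BOX)
            adc_grid = np.full(_DWI_SHAPE, 0.8e-3)
            adc_grid[dwi_mask] = adc
            dtruth = DWIGroundTruth(adc=adc_grid,
                                    s0=np.full(_DWI_SHAPE, 1000.0),
                                    noise_sd=group.dwi_noise_sd,
                                    seed=seed * 1000 + tumor_index)
            series = make_dwi_series(dtruth)
            _io.save_dwi(tdir / "dwi.nii", series)
            _io.save_mask(tdir / "dwi_mask.nii", dwi_mask, series.spacing)

            # hyperpolarized dynamics
            kpl_grid = np.where(_HP_TUMOR, kpl, 0.002)
            amp_grid = np.where(_HP_TUMOR, 100.0, 30.0)
            hparams = ExchangeModelParams(kpl=kpl_grid,
                                          bolus_amplitude=amp_grid,
                                          noise_sd=group.hp_noise_sd,
                                          seed=seed * 1000 + tumor_index)
            grid = make_hp_dynamics(hparams)
            _io.save_dynamic_grid(tdir / "hp_dynamics.nii", grid)
            _io.save_mask(tdir / "hp_mask.nii",
                          _HP_TUMOR[:, :, None].astype(np.uint8))

            # NMR tables
            panel = _default_panel()
            panel["lactate"].fe = group.lactate_fe
            ntruth = NMRGroundTruth(metabolites=panel,
                                    area_noise_cv=group.nmr_noise_cv,
                                    f_pdh=group.f_pdh, y_pc=group.y_pc,
                                    y_s=group.y_s,
                                    seed=seed * 1000 + tumor_index)
            tables = make_nmr_tables(ntruth)
            tables.peaks_1d.to_csv(tdir / "nmr_peaks1d.csv", index=False)
            tables.hsqc.to_csv(tdir / "nmr_hsqc.csv", index=False)
            tables.multiplets.to_csv(tdir / "nmr_multiplets.csv", index=False)
            _io.write_json(tdir / "nmr_reference.json",
                           {"tsp_amount_nmol": ntruth.tsp_amount_nmol,
                            "tissue_mass_mg": ntruth.tissue_mass_mg,
                            "tsp_protons": ntruth.tsp_protons})

            # growth curve: last 3 measurements exactly linear at the
            # tumor's rate (drawn around the group mean), earlier points
            # sub-linear
            days = np.array([0.0, 4.0, 8.0, 11.0, 14.0])
            rate = max(float(rng.normal(group.growth_rate,
                                        0.15 * group.growth_rate)), 1e-3)
            v_final = 0.8
            vols = v_final + rate * (days - days[-1])
            vols[0] *= 0.85
            vols[1] *= 0.92
            vols = np.maximum(vols, 0.05)
            pd.DataFrame({"day": days, "volume_cc": vols}).to_csv(
                tdir / "volumes.csv", index=False)

            manifest.append({
                "tumor_id": tid, "group": group.name,
                "true_cystic_fraction": group.cystic_fraction,
                "true_necrotic_fraction": group.necrotic_fraction,
                "true_adc_mm2_s": adc, "true_kpl_s": kpl,
                "true_growth_rate_cc_day": rate,
                "true_lactate_fe": group.lactate_fe,
                "true_f_pdh": group.f_pdh, "true_y_pc": group.y_pc,
                "true_y_s": group.y_s,
            })
            tumor_index += 1

    mdf = pd.DataFrame(manifest)
    mdf.to_csv(out_dir / "manifest.csv", index=False)
    _io.write_yaml(out_dir / "config.yaml",
                   {"seed": seed, "groups": [asdict(g) for g in groups]})
    return mdf
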