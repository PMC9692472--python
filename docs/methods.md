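# Methods

This note documents the models implemented in `pdxmet`, their defaults,
the synthetic data used to validate them, and the numerical choices a
maintainer would want to know. Nothing here asserts an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## T2-weighted histogram morphometry

Tumor voxel intensities are divided by the mean intensity of the
contralateral-kidney ROI, which removes inter-subject scanner scaling and
makes tumors comparable (the normalized kidney mean is exactly 1 by
construction). The normalized values are summarized as a probability
density histogram (area 1; 100 bins over the observed range by default)
and classified with strict thresholds at mean ± k·SD, k = 3 by default:

- hyperintense ⇔ value > μ + k·σ (bright, cyst-associated)
- hypointense ⇔ value < μ − k·σ (dark, necrosis-associated)

Percentages are exact rationals 100·count/total, converted to float last.

**Reference distribution.** The threshold (μ, σ) defaults to the
*normalized kidney* distribution rather than the tumor's own moments. The
choice matters: with tumor-based moments, the mass beyond 3 sample SDs is
capped near 10% by the one-sided Chebyshev bound, so a strongly cystic
tumor (tens of percent bright voxels) could never be reported as such.
The kidney reference instead measures deviation from normal-appearing
parenchyma. `reference="tumor"` and explicit `(mean, sd)` remain
available. Values exactly on a threshold are interior (strict
inequalities); with σ = 0 the rule degenerates to comparison against the
mean, which is what makes zero-noise phantom recovery exact.

## ADC mapping

Model: `S_b = S₀·exp(−b·ADC)`. The fit is nonlinear least squares on the
linear signal scale, because log-transforming magnitude (Rician) data
biases high-b points; the log-linear slope is used only to initialize.
Optimizer: bounded `scipy.optimize.least_squares` (S₀ ≥ 0,
0 ≤ ADC ≤ 1 mm²/s), at most 200 function evaluations; non-convergence
QC-fails the voxel with reason `no-convergence`. R² = 1 − SSres/SStot on
the same scale; for constant signals (SStot ≈ 0) R² is defined as 1 when
the residual is at floating-point level, since a constant is fit
perfectly by ADC = 0 — such voxels then fail the ADC floor, not R².

QC: pass ⇔ R² > 0.7 and ADC > 0.1×10⁻³ mm²/s (both configurable;
relaxing either is monotone in the pass count). Default b-values are
{0, 200, 400, 600, 800, 1000} s/mm² — declared defaults, configurable;
with only 2 b-values R² is degenerate (always 1) and the CLI warns below 3.

ROI transfer to the DWI grid (default 96×96 in-plane) is nearest-neighbor
on a shared field of view: each target pixel samples the source pixel
nearest its center, with half-even rounding of the aligned coordinate so
that a feature on an even source index (e.g. the exact grid center)
survives integer downsampling. An ROI that vanishes after resampling is
an error, not an empty result.

## Hyperpolarized pyruvate–lactate exchange

Forward model (simulator): the driven linear two-site system

    dP/dt = u(t) − (1/T1P + kPL + ρ)·P
    dL/dt = kPL·P − (1/T1L + ρ)·L

with ρ = −ln(cos θ)/TR the per-excitation flip-angle loss converted to a
continuous rate, applied to both pools; keeping the loss continuous keeps
the system linear and analytically checkable. Defaults follow the
acquisition the pipeline targets: 8×8 grid, 15 timepoints every
TR = 4.2 s starting 10 s after injection, θ = 10°; T1P = 43 s,
T1L = 33 s (typical in-vivo values at 3 T). The bolus is a gamma-variate
(shape 3, scale 1.5 s, arriving at injection); a delta bolus is retained
because it has a closed form: with no flip loss and an unbounded window,
AUC(L)/AUC(P) → kPL·T1L. Bolus amplitude is in arbitrary units — dose is
not modeled. Amplitude noise is additive Gaussian (quantified peak areas,
not raw magnitude images); negative amplitudes are clipped to zero at
quantification.

Quantification: spectra, when used, are integrated over disjoint
chemical-shift windows after subtracting a linear baseline spanned by the
window edges (magnitude spectra carry a noise pedestal). SNR is defined —
the acquisition convention leaves it open — as peak temporal amplitude ÷
noise SD, with the noise SD taken from a signal-free region and required
explicitly (never guessed from zero). Voxel selection: SNR > 3 *and*
strictly more than 5 qualifying timepoints (amplitude/noise > 3), both
counted on the pyruvate channel by default (`lactate` and `either` are
config options). The L/P AUC ratio is trapezoidal on the acquired time
grid with no extrapolation; AUC(P) = 0 yields an undefined (NaN) ratio
excluded from means, never zero.

Note on the closed-form check: at kPL = 0.1 s⁻¹ the pyruvate decay
time-constant is ≈ 8 s, so trapezoidal quadrature at the 4.2 s protocol
spacing alone misses ~2.7% of AUC(P); the kPL·T1L limit is therefore
verified on 1 s sampling, where quadrature error is ~0.1%.

## NMR quantification and fractional enrichment

Absolute concentration from a 1-D peak area, TSP (9 protons) internal
standard:

    conc [nmol/mg] = (area/area_TSP) · (9/protons) · n_TSP[nmol] / mass[mg]

This proton-count-and-mass normalization is standard internal-standard
practice, stated explicitly so results are auditable. Relative
concentrations (RU) are plain volume ratios to TSP with no proton
correction. FE = labeled(HSQC)/total; values above 1.02 are flagged (not
clipped) as physically impossible beyond noise allowance; total = 0 gives
an undefined FE. No natural-abundance ¹³C correction is applied by
default, matching the plain ratio definition.

## TCA isotopomer model

A deliberately transparent turn-iteration model of label flow from
uniformly ¹³C-labeled glucose into glutamate, with three inflows relative
to citrate-synthase flux (=1):

- PDH: [1,2-¹³C]acetyl-CoA, labeled with probability `f_pdh` (the
  remainder of the acetyl pool enters unlabeled);
- PC (`y_pc`): [1,2,3-¹³C]oxaloacetate from carboxylation of the same
  pyruvate pool (CO₂ unlabeled), so `f_pdh` is the single pyruvate-pool
  enrichment shared by both routes — keeping the parameter count
  identifiable from 12 multiplet fractions;
- Y_S (`y_s`): unlabeled anaplerosis at succinyl-CoA.

Atom mapping per turn: acetyl C2→glutamate C4, acetyl C1→C5; OAA
C2/C3/C4→glutamate C3/C2/C1; OAA C1 leaves as CO₂ at isocitrate
dehydrogenase and glutamate C1 at α-ketoglutarate dehydrogenase; the
symmetric succinate intermediate is orientation-averaged (50/50).
Anaplerotic inflows are balanced by isotope-blind efflux from the OAA
pool. The full 16-state OAA isotopomer distribution is iterated to a
fixed point (max change < 1e-8, error after 500 turns; `n_turns=k` gives
the truncated k-turn pattern for first-turn analyses). Glutamate, in fast
exchange with α-ketoglutarate, reports per-carbon multiplets: for each of
C2/C3/C4 the singlet/doublet/doublet-of-doublets fractions are the
conditional probabilities of the neighbor labeling given the observed
carbon is labeled; an unlabeled carbon carries all-zero fractions.

This is a simplified stand-in for full legacy isotopomer-analysis codes:
pyruvate-kinase recycling, natural abundance, and multiple substrate
pools are not modeled, and its fidelity target is self-consistency
(recovery of its own simulations), not numerical agreement with any
particular software.

**Fitting and model selection.** Candidate models: PDH-only (k=1),
PDH+PC (k=2), PDH+PC+Y_S (k=3). Bounded least squares on the 12 multiplet
fractions with 5 seeded multi-starts (first at 0.5, others uniform in the
bounds) to avoid local minima; ties broken by lower SSR then fewer
parameters. Metrics per fit: SSR; AICc = n·ln(SSR/n) + 2k +
2k(k+1)/(n−k−1) (undefined with reason when n ≤ k+1; SSR floored at the
smallest positive double so a perfect fit gives a large negative, finite
score); Ln(Residual) = ln(SSR); and ADp, the Anderson–Darling normality
p-value of the residuals (NaN for degenerate, zero-variance residual
vectors). The lowest-AICc model is selected and flagged when ADp < 0.05
(structured residuals).

## Cohort statistics

Growth rate is the OLS slope of the last 3 tumor volumes against time
(cc/day); fewer than 3 measurements are refused. Imaging metrics are
compared across lines by one-way ANOVA with Tukey's post-hoc test and
reported as mean ± SD; metabolic assays use Welch's unequal-variance
t-test or two-way (metabolite × group) ANOVA and report mean ± SE — the
error-bar convention is recorded in the output schema. Significance is
fixed at p < 0.05 with no correction beyond Tukey. The wrappers delegate
to scipy/statsmodels; tests pin them against hand-computed textbook
formulas and a null-simulation type-I error of ~5%.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analysis
assumes: Gaussian tissue-class intensities referenced to the kidney,
mono-exponential diffusion decay under Rician (magnitude) noise,
two-site-exchange dynamics under a gamma-variate bolus, and
TSP-referenced peak tables driven by the same isotopomer forward model
the fitting stage uses. Phantom geometry is simple boxes (kidney and
tumor of 1000 voxels each on a 32×32×8 grid); cyst/necrosis class means
default to ≥ 4 reference SDs beyond the ±3 SD thresholds so that
zero-noise classification recovers the constructed labels exactly (a
warning fires if a user-supplied spec violates the separation). Cohort
defaults describe two lines of 3 tumors differing in cystic fraction
(2% vs 10%), ADC (1.2 vs 1.5×10⁻³ mm²/s), kPL (0.02 vs 0.06 s⁻¹) and
growth rate, with measurement noise at realistic SNR (DWI SNR 50, HP
amplitude noise 1% of bolus units, 3% NMR area CV).

It does **not** emulate k-space/coil physics, pulse-sequence fidelity,
spatial anatomy, partial-volume effects, motion, B0/B1 inhomogeneity, or
spectral overlap, so passing tests demonstrate correctness of the
quantification chain under its stated noise models — not robustness to
real-acquisition artifacts. Problem sizes in the tests (1000-voxel
tumors, 1000-voxel noise studies, 50-replicate selection studies,
6-tumor cohorts) were chosen as the package's own desk-scale validation
conditions.

## Determinism

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` child streams (`pdxmet._rng.stream`), keyed
by a CRC32 of a purpose label plus an item index, so adding a consumer
never perturbs existing streams. Outputs avoid wall-clock metadata
(uncompressed `.nii`, sorted JSON/YAML), making the full
simulate→analyze→report chain byte-reproducible for a fixed seed.
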