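# Methods

## Kinetic model

One tissue voxel exchanges hyperpolarized urea between a vascular pool of
volume fraction `vb` and an extravascular/extracellular pool of fraction
`vee`, with first-order transfer constant `kve` (s⁻¹). The EES
concentration obeys

    dCe/dt = (kve / ve) Cb(t) − α Ce(t),    α = kve/ve + 1/T1,

whose solution between any two times is the decayed initial condition
plus an exponential-kernel convolution of the vascular input. The signal
is the volume-weighted compartment sum; the cellular fraction
`vc = 1 − vb − vee` carries no signal because urea does not cross most
cell membranes on the experiment's timescale (erythrocytes excepted,
which is also why no hematocrit correction is applied to `vb`). The
three model variants differ only in which volume fractions are free:
all three (`I`), vascular term dropped (`II`, extracellular fraction
`vec`), or cellular term dropped (`III`, `vev = 1 − vb`). Model II is
Model I at `vb = 0` and Model III is Model I at `vee = 1 − vb`; both
identities are enforced by tests.

Assumptions carried throughout: T1 of urea is known and fixed (20 s
default) and spatially uniform; the flip angle is exact and uniform;
transverse magnetization is fully spoiled between excitations; the
observation is taken at the pulse instant (TE decay is not modeled);
blood within a voxel is completely replenished over one TR, so prior
excitations never deplete the vascular term.

## Sampling model

Snapshot spoiled-GRE: `floor(duration/TR)` excitations at constant flip
angle, the first coinciding with bolus onset (zero initial signal). Each
pulse reads out `sin(flip)` of the longitudinal signal and multiplies
the extravascular pool by `cos(flip)`, which is carried forward as the
initial condition of the next inter-pulse interval. The forward
operator precomputes the vascular input on every interval's quadrature
grid, making one forward evaluation a matrix–vector product plus a
scalar recursion — this is what keeps Monte-Carlo studies with tens of
thousands of fits inside seconds-to-minutes.

Noise is zero-mean additive Gaussian on the real-valued signal, applied
after simulation; no magnitude rectification is performed (fitting
noisy negative samples as-is). A stated "reference SNR" always means:
the noise SD is the peak of the *default* noise-free curve divided by
that SNR, calibrated once per study and held fixed while parameters are
varied, so that differing conditions are compared at equal absolute
noise.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| kve | 0.02 s⁻¹ | trans-capillary transfer rate |
| vb | 0.09 | blood volume fraction |
| vee | 0.30 | EES volume fraction |
| T1 | 20 s | urea longitudinal relaxation |
| TR / flip / duration | 1 s / 20° / 60 s | snapshot acquisition |
| VIF shape / timescale | 2.5 / 2.5 s | gamma-variate bolus, peak at 6.25 s |
| VIF onset / amplitude | 0 s / 1 | bolus arrival, arbitrary units |

The physiological defaults are representative of small-animal solid
tumors. The gamma-variate's shape and timescale are a plausible choice
for a murine tail-vein bolus (the bolus peaks ~6 s after arrival); they
are exposed in configuration precisely because bolus geometry varies
between setups and several published Monte-Carlo statistics are
sensitive to it. Concentrations and signals are in arbitrary units —
only rate constants and dimensionless fractions/ratios are
interpretable.

## Numerical choices

* **Convolution quadrature.** The inter-pulse convolution
  `∫ Cb(τ) e^{−α(t−τ)} dτ` is integrated by exponential product
  integration: the input is taken piecewise-linear on a uniform 0.01-s
  grid and the exponential kernel is integrated exactly on each cell.
  Plain trapezoid at the same step loses ~0.5% accuracy when washout is
  fast (α ≈ 25 s⁻¹ at the corner of the supported parameter ranges);
  the product rule is exact in α and keeps the error below 1e−6
  relative across the ranges (verified against adaptive ODE
  integration). The step is configurable (`FitOptions.quad_step`).
* **Optimizer.** `scipy.optimize.least_squares`, trust-region
  reflective, with box bounds kve ∈ [0, 1] s⁻¹, volume fractions ∈
  [0, 1], VIF scale ∈ [0.01, 100]; initial guess kve = 0.05 s⁻¹,
  vb = 0.1, vee/vec = 0.3, scale = 1; ftol = xtol = 1e−10. Model I's
  simplex constraint `vb + vee ≤ 1` is kept by a soft penalty residual
  (zero inside the simplex), leaving the problem smooth for the
  trust-region step. Non-convergence is reported on the results object,
  never raised, and non-converged fits are retained in aggregate
  statistics (a convergence-rate column is reported alongside).
* **Degenerate inputs.** `ve = 0` with `kve > 0` is rejected (transfer
  rate undefined); `ve = 0` with `kve = 0` decays with T1 only. A flip
  angle of 0° yields an all-zero curve. Sample counts use
  `floor(duration/TR)` with a 1e−9 guard against floating-point edge
  cases.

## Fitting modes and identifiability

With the VIF known exactly ("accurate VIF") all model parameters are
identifiable from noise-free data and recovered to ≤1e−4 relative.
With the VIF amplitude as an extra fitted parameter, the model family
is exactly invariant under `(scale·s, kve/s, vb/s, ve/s)` for Models I
and II, so only the ratios `kve/ve` (and `kve/vb` where applicable)
remain point-identifiable; estimate dispersion along the flat ridge is
then a property of the optimizer path, not of the data. Model III's
`vev = 1 − vb` coupling formally breaks the symmetry but leaves a long,
shallow valley with much the same practical effect. This is the
package's reading of why fitted-scale coefficients of variation are
larger and more method-dependent than accurate-VIF ones, and why the
ratio is the quantity to report from VIF-scale fits.

`voxelwise_fit` (where the fitted scale is mandatory, since a measured
VIF shape has arbitrary amplitude) pins the gauge deterministically by a
two-stage fit: stage one fixes scale = 1, stage two releases the scale
starting from the stage-one solution. A voxel whose true input
amplitude matches the measured VIF therefore keeps scale = 1 and
recovers the generating parameters; the gauge-invariant ratio maps are
unaffected by the choice. The curve-level API (`DynamicUreaModel`,
`run_noise_study`) deliberately keeps the conventional single-stage
scheme so its Monte-Carlo statistics reflect standard practice.

A measured VIF shape is used nonparametrically, interpolated to the
quadrature grid. The default interpolant is monotone cubic (PCHIP):
linear interpolation of a 1-s-sampled bolus leaves ~1% kve bias in
noise-free voxelwise recovery, an order of magnitude above the rest of
the numerical error budget; PCHIP brings it below 0.1%. Linear remains
available (`FitOptions.vif_interp`).

## Monte-Carlo studies

All noisy data are generated from Model I at the defaults. Per
repetition, one fresh Gaussian noise realization is shared across all
models and fitting modes (paired comparisons); RNG streams are spawned
from a master seed, making every study bit-reproducible. Accuracy is
the signed mean error in percent; reproducibility is the coefficient of
variation (sample SD, n−1 denominator, over the mean) in percent. The
studies use 100 repetitions per condition by default; the acquisition
sweep's published-figure-scale grid (15 log-spaced TRs × 30 flip
angles) is configurable, and tests exercise reduced grids since each
grid point costs n_reps fits.

## Synthetic phantom

`generate_phantom` builds a 16×16×1×60 dynamic series: one voxel
carries the gamma-variate bolus (the "blood" voxel used as measured-VIF
shape), a tumor block follows Model I under the same snapshot sampling,
background is noise-only; everything is multiplied by a configurable
receive-sensitivity map and Gaussian noise is added at a stated tumor
peak SNR (default 13, representative of small-animal HP urea imaging;
`peak_snr=None` gives the noise-free phantom used by exactness tests).
The phantom emulates the structure the voxelwise pipeline needs —
bolus-shaped input voxel, kinetically homogeneous tissue region,
sensitivity-induced VIF/tissue amplitude mismatch — and deliberately
omits features of real data: no partial-volume mixing by default (a
brightness knob exists), no spatial parameter heterogeneity within the
tumor, no motion, no EPI reconstruction artifacts, no B1 variation, and
real-valued (not magnitude-rectified) noise. Passing phantom tests
therefore demonstrates correctness of the estimation machinery, not
robustness to in-vivo confounds.

## Known limitations

* T1 and flip angle are treated as known; miscalibration of either
  biases kve (not studied here).
* VIF timing is assumed exact (first excitation at bolus onset); onset
  error propagates directly into transfer-rate estimates.
* The Gaussian-noise model ignores the Rician floor of magnitude
  images, relevant at low SNR.
* Single-T1, two-site exchange; no intravascular bolus-dispersion
  modeling, no variable flip-angle schedules, no SSFP/FSE acquisition
  variants.
* Monte-Carlo dispersion statistics under a fitted VIF scale depend on
  optimizer internals (see identifiability above) and on the bolus
  shape; comparisons across implementations should expect
  tens-of-percent-level differences in those CoVs even when the
  accurate-VIF statistics agree closely.
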