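# hpurea

Pharmacokinetic modeling of dynamic hyperpolarized (HP) ¹³C-urea MRI.

Hyperpolarized ¹³C urea is a non-renewable perfusion agent: its signal
decays with T₁ and is consumed by every RF excitation, so the familiar
DCE-MRI machinery cannot be applied directly. `hpurea` implements three
nested compartmental models of urea exchange between blood and tissue
under snapshot spoiled-gradient-echo sampling, estimates their parameters
from dynamic signal curves by bounded trust-region least squares, runs
Monte-Carlo studies of acquisition settings, model misspecification and
noise, and maps the kinetic parameters voxelwise over dynamic image
series. It is aimed at researchers developing quantitative perfusion and
permeability readouts from preclinical HP urea (and similar HP agent)
experiments.

## The models

A voxel is fed by a vascular input function (VIF) C_b(t), modeled as a
gamma-variate bolus or taken nonparametrically from a measured blood
voxel. Labeled spins extravasate into the extravascular/extracellular
space (EES) at rate constant k_ve (s⁻¹) and are lost to washout and T₁
decay, with aggregate rate α = k_ve/v_e + 1/T₁:

    dC_e/dt = (k_ve / v_e) · C_b(t) − α · C_e(t)

The longitudinal signal is the volume-weighted sum of compartments
(urea does not enter cells appreciably, so the cellular fraction v_c is
signal-free; no hematocrit correction, since erythrocytes are permeable
to urea):

* **Model I** (extended-Tofts-like): M_z ∝ v_b·C_b(t) + v_ee·C_e(t),
  three parameters (k_ve, v_b, v_ee).
* **Model II** (Tofts-like): vascular signal neglected (v_b = 0), two
  parameters (k_ve, v_ec).
* **Model III**: cellular space neglected (v_ev = 1 − v_b), two
  parameters (k_ve, v_b).

Sampling is discrete: one image per excitation at interval TR with
constant flip angle θ. Each pulse yields sin θ times the longitudinal
signal and leaves cos θ of the extravascular magnetization behind; blood
is assumed fully replaced between pulses, so the VIF is never attenuated.
Between pulses the EES concentration is propagated in closed form, with
the vascular convolution integral evaluated by exponential product
integration on a 0.01-s grid.

Because HP signal has no absolute scale, jointly fitting a VIF amplitude
scale makes individual parameters identifiable only up to the rescaling
(scale·s, k_ve/s, v_b/s, v_e/s); the ratios k_ve/v_e and k_ve/v_b are the
gauge-invariant observables. This matters in vivo, where the VIF is
measured with a different receive-coil sensitivity than the tissue.

## Worked example

```python
import hpurea as h

curve = h.simulate_dynamic_signal(h.PhysioParams(), h.AcquisitionParams(),
                                  h.VIFParams(), "I")
noisy = h.add_noise(curve, h.calibrate_noise_sigma(25.0), seed=7)
model = h.DynamicUreaModel(noisy, "I", h.AcquisitionParams(), h.VIFParams())
print(model.fit().summary())
```

```
Dynamic HP-urea kinetic fit (Model I)
==============================================
n samples                       60
converged                     True
func evaluations                 8
residual norm (SSR)     0.00016092
----------------------------------------------
kve               0.026429  s^-1
vb                0.078702
vee                0.21577
----------------------------------------------
kve/ve             0.12249  s^-1
kve/vb             0.33581  s^-1
```

The defaults are the study conditions throughout: k_ve = 0.02 s⁻¹,
v_b = 0.09, v_ee = 0.30, T₁ = 20 s, TR = 1 s, flip 20°, 60-s
acquisition, gamma-variate bolus peaking at 6.25 s. This one noisy
realization at peak SNR 25 recovers k_ve within ~30% — single-fit
dispersion of exactly the size the Monte-Carlo studies quantify
(Model I k_ve coefficient of variation ≈ 11–18% at this SNR, depending
on whether the VIF amplitude is known or fitted).

Higher-level drivers: `run_acquisition_sweep` (TR × flip-angle recovery
maps), `run_sensitivity_sweep` (noise-free misspecification bias of
Models II/III on Model-I data), `run_noise_study` (accuracy/CoV across
reference SNRs for all models, with accurate vs fitted VIF amplitude),
and `voxelwise_fit`/`generate_phantom` for image-domain mapping. The
same drivers are exposed as a CLI:

```bash
hpurea simulate --snr 25 --seed 3 --out out/
hpurea noise-study --reps 100 --seed 1 --out out/
hpurea voxelfit --series series.nii.gz --mask mask.nii.gz --vif-voxel 2 2 0 --out maps/
```

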