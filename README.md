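# petkin

Kinetic mapping for dynamic PET by non-parametric residue modelling, with a
full simulation framework for studying when it pays to pool the data from
multiple tracer injections acquired in one imaging session.

## The problem

Dynamic PET studies that inject more than one tracer dose — a water bolus
followed by an FDG infusion in flow–metabolism imaging, or repeated water
boluses in activation studies — can be analysed *separately*, one injection
window at a time, or *combined*, fitting the concatenated time course with
coefficients shared across windows. `petkin` implements:

* **NPRM (non-parametric residue mapping)** — voxel-level kinetics from a
  linear model. The image is segmented into kinetically homogeneous
  segments; each segment mean is modelled as a piecewise-linear, monotone
  non-increasing residue `R(t)` convolved with the arterial input
  `C_p(t − Δ)` (or as a scaled injection-site signal, or a non-decreasing
  distribution function), all by constrained weighted least squares with a
  grid search on the delay `Δ`. The modelled curves (sub-TACs), plus the
  input curve itself (spike residue) and its running integral (constant
  residue, the Patlak element), form a basis pruned by cross-validated
  backwards elimination. Every voxel curve `z_i` is then fitted as a
  non-negative combination `z_i ≈ X α_i` (NNLS), and the voxel residue
  `R_i = Σ_k α_ik R_k` is decomposed into vascular, in-distribution and
  retained parts, giving `V_B`, `V_D`, `K_D = R_D(0)`, `K_i = R_E(0)`,
  `K_1 = K_D + K_i`, extraction `K_i/K_1` and `MTT = V_D/K_D + Δ̄`.
* **Scanning simulators** — a fast 1-D Poisson deconvolution model
  (circular `|ν|^−β` blurring kernel, attenuation, dose-scaled Poisson
  counts; exact Fourier "FBP" inversion and positivity-constrained Poisson
  ML by damped IRLS) and a 2-D attenuated parallel-beam Radon model
  (128×128 image, 183×181 sinogram, filtered backprojection). With
  `β = 1.35` the dose dependence of the 1-D reconstruction error matches
  2-D PET, so replication-heavy experiments stay cheap.
* **Evaluation** — the normalised squared-error functional over injection
  windows, combined/separate MSE summaries and percent improvement, the
  Gaussian theory ratio `MSE_C/MSE_j = σ_j^−2 / Σ_k σ_k^−2` (equal to `1/J`
  for replicate injections), meta-regressions of scaled MSE on design
  covariates, the dose-decay exponent of reconstruction error, and the
  dose-equivalence of an MSE improvement.
* **Phantoms** — mixture sources `λ(x,t) = Σ_k α_k(x) μ_k(t)` built from
  tissue-class coefficient profiles and one-compartment (water) or
  irreversible two-compartment (FDG) kinetics, gamma-variate bolus and
  2-minute-infusion input functions, seven dose levels (0.3–3.2), seven
  water:FDG count ratios (16:1–64:1) and repeat designs with J ∈ {2,4,6,8}.

## Worked example

```python
from petkin.schedule import build_frame_schedule, H2O_FRAMING
from petkin.evaluation import theory_mse_ratio, dose_equivalence
from petkin.phantom import make_study
from petkin.experiments import run_improvement_study

sched = build_frame_schedule(H2O_FRAMING)
print(f"water protocol: {sched.n_frames} frames over {sched.total_duration_s/60:.2f} min")
print(f"theoretical MSE ratio, 4 replicate injections: {theory_mse_ratio([1.0]*4):.2f}")
print(f"dose equivalent of a 10% MSE gain at exponent 0.42: "
      f"{dose_equivalence(0.10, 0.42):.1f}%")
design = make_study("repeat_h2o", dose=1.0, ratio_or_j=2, n_replicates=20, seed=7)
s = run_improvement_study(design)["summary"]
print(f"repeat-water study, J=2, 20 replicates: "
      f"MSE_C={s.mse_combined:.4f}, MSE_S={s.mse_separate:.4f}, "
      f"improvement={s.percent_improvement:.1f}% +/- {s.percent_improvement_stderr:.1f}")
```

prints

```
water protocol: 57 frames over 8.75 min
theoretical MSE ratio, 4 replicate injections: 0.25
dose equivalent of a 10% MSE gain at exponent 0.42: 25.5%
repeat-water study, J=2, 20 replicates: MSE_C=0.0023, MSE_S=0.0043, improvement=81.9% +/- 8.0
```

The first three lines are closed-form facts: the clinical water framing
expands to 57 frames totalling 8.75 minutes; pooling J identical injections
divides the estimator MSE by J; and with reconstruction error decaying as
dose^−0.42, a 10% MSE gain from combined analysis is worth about a 25%
dose increase. The last line is a Monte-Carlo result: on a simulated
two-injection repeat-water study the combined fit roughly halves the
normalised source error, and the improvement grows approximately in
proportion to J − 1 as more injections are pooled.

A command-line interface mirrors the library:

```bash
petkin experiment repeat-h2o --injections 2,4,6,8 --replicates 50 --seed 0 --out sweep.csv
petkin evaluate --replicates 100 --seed 0 --out dose.csv   # prints gamma_tau
petkin report --table sweep.csv --design-kind repeat
```

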