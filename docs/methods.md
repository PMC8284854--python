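# Methods

This note records the models implemented in `petkin`, their assumptions,
the defaults that matter, and the design choices made where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Residue model and kinetic summaries

Tracer–tissue interaction is assumed linear and time-invariant, so a tissue
curve is the convolution of the arterial input `C_p` with a residue
function `R(t)`: the amount of tracer still resident `t` minutes after an
idealised unit bolus. Indicator-dilution theory makes `R` non-negative and
monotone non-increasing; we represent it non-parametrically as a piecewise
linear function on a knot grid and extend it beyond its last knot at the
terminal (retained) level.

Over a scan window `[0, T_E]` the residue splits additively into

* a vascular part `R_B(t) = R(t) − R(T_B)` on `[0, T_B]`, zero after, where
  `T_B` bounds large-vessel transit (default 15 s, configurable);
* a retained part `R_E(t) = R(T_E)`;
* the in-distribution remainder `R_D = R − R_B − R_E`.

Summaries: `V_B = ∫R_B`, `V_D = ∫R_D` (exact trapezoid on the knots),
`K_D = R_D(0)`, `K_i = R_E(0)`, `K_1 = K_D + K_i`, extraction `K_i/K_1`,
and `MTT = V_D/K_D + Δ` by the central volume theorem. All but MTT and
extraction are linear in `R`. When `K_D = 0` the MTT is reported as an
undefined flag (`None`/NaN), never as infinity, so parametric maps stay
finite; extraction is likewise undefined for an all-zero residue.

Reference compartmental forms: the one-compartment flow model
`R = K_1 e^{−k_2 t}` and the irreversible two-compartment form
`R = K_1[(k_2/(k_2+k_3)) e^{−(k_2+k_3)t} + k_3/(k_2+k_3)]` are sampled onto
knot grids dense enough that the piecewise-linear error stays below 0.2% of
`K_1` (contract: 0.5%). The two-exponential model TAC
`η(t) = f_b C_p(t−Δ) + Σ_m A_m ∫ e^{−λ_m(t−s)} C_p(s−Δ) ds` is fitted by
variable projection: amplitudes by NNLS, rates by Nelder–Mead on the log
scale from several starts, delay by grid search.

### Numerical quadrature

PET frames record integrated counts, so model curves are **frame-averaged**,
not sampled at mid-frame. Convolutions are evaluated on a fine uniform grid
(0.1 s for single curves, 0.25 s inside the sub-TAC design matrices, a
deliberate speed/accuracy trade documented by the convolution unit tests)
with a trapezoid endpoint correction, then averaged over each frame
interval. The delay grid is −10 s to +30 s in 2 s steps by default.

## The NPRM pipeline

1. **Segmentation.** Recursive binary splitting of the voxel set: the
   segment whose members deviate most from proportionality (mean
   correlation distance of L1-normalised curves to the segment mean) is
   split by Ward-linkage clustering until a target count or the
   proportionality tolerance is reached. Ward is used for the binary split
   because average linkage on correlation distance tends to peel single
   outliers rather than separate tissue classes. An optional
   `metric_curves` argument lets the caller cluster on denoised features
   (the experiment drivers use duration-weighted temporal rebinning, eight
   bins per injection window) while means and SDs always come from the
   data. Segment SDs are stored as the standard error of the segment mean
   (`sd/√n`), floored at 1% of the segment peak per member voxel, so
   weights stay finite without erasing the frame-weighting structure of
   large segments.
2. **Sub-TAC modelling.** Each segment mean is fitted, per injection
   window, as (a) a residue convolution, (b) a scaled injection-site
   signal, or (c) a non-decreasing distribution function convolved with the
   input. Monotone constraints are encoded by writing the residue as a
   non-negative combination of unit "drop" elements plus a constant (ramps
   for the distribution case), so every candidate delay is a weighted NNLS
   problem. One knot is pinned at `T_B` so vascular spikes can complete
   exactly at the decomposition boundary. By default a single
   tissue-arrival delay is grid-searched jointly across windows: a sharp
   early bolus anchors the delay for injections (slow infusions) that
   cannot resolve it; per-window delays remain available. The residue model
   is kept unless an alternative lowers the weighted SSE by more than 10%.
3. **Basis selection.** Candidates are the modelled segment curves plus,
   per injection, the input curve (spike residue) and its running integral
   (Patlak element). Backwards elimination removes, at each step, the
   column whose removal gives the lowest cross-validated error, stopping
   when the best removal would exceed the best score seen by more than 2%.
   The CV folds are interleaved subsets of the *frame* axis (fit on the
   remaining frames, score on the held-out frames, per segment): with only
   a handful of segments, folding over segments would never credit a column
   for fitting its own segment and prunes tissue-specific columns.
4. **Voxel fitting and mapping.** Each voxel curve is fitted by NNLS
   (optionally weighted; the experiment drivers weight frames by the
   inverse of the reconstruction variance proxy
   `counts/(scale·duration)²`). The voxel residue is the coefficient-
   weighted sum of the residue-carrying columns — non-parametric residues
   and Patlak elements (a Patlak column is the curve of a unit constant
   residue and therefore contributes to `K_i`). Spike/injection-site
   columns contribute their coefficient (times the column's input scale) to
   `V_B`. The voxel delay is the flow-weighted mean of column delays,
   `Δ̄ = Σ α_k K_{Dk} Δ_k / Σ α_k K_{Dk}`.

## Scanning models

**1-D Poisson deconvolution.** The source on a 128-bin circle is blurred by
a kernel with Fourier coefficients `|ν|^−β` (DC kept at 1 so total activity
is preserved; default `β = 1.35`), multiplied by a positive attenuation
profile (default: smooth bump in [0.5, 1]), scaled so the expected total
counts over the study equal the dose `τ`, and Poisson sampled per frame.
Per-frame expectations are proportional to frame activity × duration; in
multi-tracer studies each injection window gets its own scale so the count
split follows the prescribed dose ratio (`r:1` gives water `r/(r+1)` of the
total). The kernel's spectral tail rings slightly negative where the source
vanishes, so phantoms carry a low soft-tissue background and the drivers
clip expectations at zero before sampling; the projection itself is kept
exact so that direct Fourier inversion is an exact round trip on noiseless
data (verified to 1e−10). ML reconstruction solves the
positivity-constrained Poisson problem by damped IRLS: each iteration
solves the local weighted least-squares problem (weights `1/max(μ̂, ε)`) by
NNLS with a halving line search that keeps the deviance non-increasing;
stationarity along the scaling direction makes the forward-projected total
match the observed counts at convergence. Post-reconstruction smoothing is
a circular Gaussian; the study-wide bandwidth is chosen on the total-uptake
image, either against the known truth (simulation) or by the replicate-pair
criterion `mean ‖smooth(z_a,h) − z_b‖²`, whose expectation differs from the
MSE only by an h-independent constant.

**2-D attenuated Radon.** 128×128 image on the unit square; padding the
image by one zero row/column makes the parallel-beam projection grid
exactly 183 radial bins × 181 angles over [0, π). Attenuation acts
multiplicatively along each line of response through a fixed attenuation
sinogram `exp(−Radon(μ))`, as appropriate for coincidence detection.
Reconstruction is attenuation-corrected FBP (ramp filter, optional Hann
window, Gaussian post-smoothing). Only FBP is provided in 2-D; the 1-D
model carries the ML comparisons.

## Synthetic data

The mixture source is `λ(x,t) = Σ_k α_k(x) μ_k(t)`. Coefficient profiles
are continuous trapezoids ("ramp" profiles; Gaussian bumps available).
Continuity matters: piecewise-linear profiles have a polynomial spectral
tail (`|s_ν|² ~ ν^{−4}`), which together with `β = 1.35` places the
optimal-bandwidth reconstruction MSE in the `τ^{−0.42}`-type decay regime;
flat-top step profiles or analytic bumps move the exponent out of that
regime. Component curves are surrogates: one-compartment water kinetics and
irreversible two-compartment FDG kinetics with parameters spanning spleen,
tumour, myocardium, normal breast, liver and a blood pool (water `K_1`
0.12–0.85 mL/mL/min; FDG flux via `k_3`), and a brain-like set for repeat
studies with `K_1 ∈ [0.22, 0.85]` and `K_1/k_2 ∈ [0.7, 1.0]`. They emulate
the qualitative shapes of patient-fitted curves, not any particular
patient, so simulated improvement percentages are comparable in structure
but not cell-by-cell with clinical tables. Input functions are
gamma-variate boluses (peak 30 s after injection, small slow recirculation
tail) and, for FDG, the same shape convolved with a 2-minute rectangular
infusion. Tracer from each injection is confined to its acquisition window
(windows partition the schedule), consistent with short-lived tracers and
the negligible-spillover regime the combined/separate comparison assumes.

The absolute count scale is set by `REFERENCE_TOTAL_COUNTS = 2e6` expected
events for a dose-1.0 study, chosen so the relative SD at the peak
voxel-frame of a reconstructed water study falls in the 10–50% band typical
of clinical dynamic PET (checked by a calibration test). Doses are
multiples {0.3, 0.5, 0.7, 1, 1.5, 2.2, 3.2} of this reference.

## Experiments and problem sizes

* **Dose exponent.** Seven doses × 100 replicates of the total-uptake scan;
  per dose, the Gaussian bandwidth minimising the replicate-averaged MSE
  against truth is selected from a 13-point grid and the minimised MSE
  regressed on log dose.
* **Improvement studies.** FBP at a fixed bandwidth of 1.5 bins (a single
  study-wide bandwidth, the package's stated practice; per-injection
  bandwidths exist but are off by default). 50 replicates per design cell;
  combined and separate NNLS fits against the known-truth basis; the
  squared-error functional weights each window by `1/(D_j λ̄_j²)` with
  `λ̄_j` the spatio-temporal maximum of the true source in the window (99th
  percentile optional) and averages over voxels so values are comparable
  across grids.
* **Sub-TAC robustness.** Each replicate simulates a 24-slice × 128-bin
  volume (slices share the phantom geometry), so segments pool 100+ voxels
  — the regime in which segment-mean modelling is meaningful; a single
  128-bin axis leaves segment means too noisy for the comparison to be
  informative. The full pipeline (segmentation on rebinned slice-averaged
  curves, sub-TAC modelling, CV pruning) runs per replicate; kinetic maps
  of the first slice from the estimated basis are compared with those from
  the known-truth basis. Scored: water `K_D`, `V_D`, FDG `K_i`. The
  estimated basis costs roughly 10–20% extra RMSE at this scale; `V_D` is
  the most sensitive because it integrates the weakly identified late tail
  of the non-parametric residue.
* **Local-error scaling.** Seven doses × 20 replicates, FDG-injection maps
  against per-voxel RMS reconstruction and modelling error. The regression
  is restricted to variance-dominated voxels (replicate |bias| below the
  replicate SD, truth above 5% of its maximum): the scaling law is an
  asymptotic variance statement and partial-volume edge voxels, which are
  bias-dominated, do not follow it.

## Known limitations

* The 1-D scanner's reconstruction noise is spatially near-stationary,
  unlike clinical tomographs where variance tracks local activity; the
  local-error analysis therefore leans on dose variation for its leverage.
* No plasma metabolite correction, no AIF dispersion beyond the fitted
  delay, no randoms/scatter/deadtime, no detector blurring beyond the
  kernel, and no 2-D ML or 3-D geometry.
* Improvement percentages from the surrogate phantoms are larger than those
  reported for patient-derived sources; the qualitative structure
  (improvement growing ∝ J − 1, growing with dose ratio, combined never
  worse, dose-decay exponent near 0.42) is the reproducible content.
* Bladder-style accumulation signals are handled only through the
  distribution-function sub-TAC kind; there is no anatomical masking.
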