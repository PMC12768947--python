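# Methods

## Problem and scope

`pahsers` is a synthetic, fully reproducible implementation of a machine-learning
analysis chain for multiplexed SERS (surface-enhanced Raman scattering) detection of
five polycyclic aromatic hydrocarbon (PAH) water pollutants: pyrene (PY),
triphenylene (TP), nitro-pyrene (NP), benzo[a]pyrene (BAP) and anthracene (ANT).
The chain is:

1. simulate labeled mixture spectra by scaled addition of reference spectra;
2. train a 1D CNN multilabel **classifier** (which targets are present) and a 1D CNN
   **regressor** (how much each contributes, plus a normalization term);
3. threshold classifier scores by the geometric mean of sensitivity and specificity;
4. convert regressor outputs to concentrations through per-target calibration curves;
5. evaluate with per-target/micro/macro classification metrics, ROC-AUC,
   RMSE_spectrum and RMSE_conc.

No experimental spectra ship with the package; the synthetic-data generator is a
first-class, tested component that emulates the documented qualitative structure of
the real measurements.

## Spectral model

All spectra live on a uniform wavenumber grid. The spectral width w = 660 is fixed
by the evaluation definitions; the range 400–2000 cm⁻¹ is a package choice that
brackets every band referenced in the target descriptions (including 1241 cm⁻¹ and
~1400 cm⁻¹). Reference bands are Lorentzian with a default FWHM of 12 cm⁻¹, a
typical SERS line width; line shapes and all centers other than PY's 1241 cm⁻¹ ring
C=C band are conventions, not literature assignments. The library is constrained by
qualitative audits enforced in tests:

* ANT has exactly 3 resolvable bands and the weakest concentration response;
* BAP has 8 resolvable bands;
* every NP band lies within one FWHM of some other target's band (no unique peaks);
* PY, NP and ANT all have bands within ±10 cm⁻¹ of 1240 and 1400 cm⁻¹;
* all pairwise cosine similarities are < 0.95 (the targets remain distinguishable).

The water blank is a broad low-order polynomial hump (amplitude 0.05 of the unit
signal scale for drinking water; the river preset is about twice as strong with a
different tilt) plus optional Gaussian noise.

## Concentration response

Per-target peak height follows a Hill/Langmuir saturation h(c) = h_max·c/(K+c),
monotone and invertible — a deliberate substitute for an unspecified-degree
polynomial fit, because polynomials are not monotone outside their fit range and
cannot be safely inverted. K values (0.28–0.35 μM) place the 10 nM–1 μM calibration
range at roughly 3–75% of saturation; ANT's h_max (0.45) is about half the others',
making it the faintest target. The calibration module can also fit a quadratic in
log10(concentration) (`form="poly_log"`), with monotonicity over the data range
enforced at fit time.

## Mixture simulation and labels

A training sample is M = Σᵢ aᵢ·Rᵢ + blank (+ shift + noise) with aᵢ = ℓᵢ·S:

* contributions ℓᵢ: each target zeroed independently with probability 0.2; survivors
  get a Dirichlet draw mapped onto the simplex slice with every entry ≥ 0.01, so
  contributions sum to 1 with a hard 1%-of-total floor. All-zero draws are kept as
  blank-class samples.
* total signal scale S: log-uniform over [0.1, 10] (two decades), so the models see
  varied signal-to-background ratios. The distribution is a package choice.
* augmentation: integer grid shifts uniform in ±2 points (edge-value extension) and
  Gaussian noise with sd 1% of the spectrum maximum. Both are package defaults,
  config-exposed.
* the network consumes M/max(M); the label carries ℓ, the presence pattern, and the
  normalization factor **z = max(M)/S**. This definition makes the conversion chain
  exact: (ℓᵢ/z)·max(M) = aᵢ, i.e. dividing a contribution by z and scaling by the
  unnormalized maximum recovers the absolute height applied to reference i.

Dataset sizes default to 10,000 (training), 2,000 (validation) and 6,000
(optimization/architecture search).

## Networks and training

Both models are 3 convolutional blocks + 1 dense layer, implemented in numpy with
hand-written backpropagation (convolution via column matrices, max pooling, ReLU,
inverted dropout, Adam). Defaults: filters 8/16/32, kernel 9, max-pool 2, dense 64,
dropout 0.2, learning rate 1e-3, batch 64, up to 15 epochs with early stopping
(patience 4, best-validation weights restored). The filter counts and epoch budget
are sized so the full default pipeline trains in minutes on a single CPU; the random
architecture search (`search_architecture`, seeded, small discrete space) exists to
re-tune them. The classifier head is 5 independent sigmoids trained with multilabel
binary cross-entropy; the regressor head is 6 unconstrained linear outputs trained
with MSE (non-negativity is enforced downstream at concentration conversion, not in
the head).

Reproducibility: every stochastic stage (simulation, initialization, shuffling,
dropout, search) is seeded; repeat-run equality is asserted at 1e-4 relative
tolerance rather than bitwise, which is the honest contract across BLAS builds.

## Decisions and quantification

Per-target thresholds maximize √(sensitivity·specificity) over candidate cutoffs at
midpoints between adjacent sorted unique validation scores (plus the two boundary
candidates); a score equal to the threshold counts as positive, and ties break
toward the lower threshold. Thresholds are fitted on validation scores only.

Quantification: heightᵢ = max(ℓ̂ᵢ,0)/ẑ · raw_max, then conc = curve⁻¹(height), with
a floor of 0 μM. Heights at or below the blank-equivalent level report 0; heights
above the calibrated maximum are inverted analytically (Hill) and capped at 10× the
calibrated range, flagged as extrapolation. ẑ below 1e-6 is a hard error rather than
a silent division.

LOD is the smallest concentration whose predicted height reaches snr·blank_sd
(default S/N = 3.5), found by inverting the calibration curve.

## Evaluation conventions

* Metrics with zero denominators are reported as `None` and excluded from macro
  averages with a warning — never coerced to 0 or 1.
* Micro averages pool the five per-target confusion matrices; ROC micro pools all
  (score, truth) pairs; macro averages per-target values.
* RMSE_spectrum = √(Σᵢₖ(ŷᵢₖ−yᵢₖ)²/(n·w)) is computed on max-normalized spectra (the
  model's operating scale); the predicted spectrum is the scaled addition of
  references from the predicted labels, divided by raw_max. The actual spectrum
  includes the water background while the reconstruction does not, so even perfect
  labels leave a small background-sized residual.
* RMSE_conc = √(Σᵢⱼ(ĉᵢⱼ−cᵢⱼ)²/(n·m)) in μM over m = 5 targets.
* Because whether "accuracy" means per-call or exact-pattern accuracy is ambiguous,
  both subset accuracy (all five calls right) and per-call accuracy are reported.

## Benchmark design

Four synthetic test sets mirror a 2×2 design — {drinking, river} background ×
{full, sparse} mixtures — with 10/10/10/9 = 39 samples. Full sets contain all five
targets at rotations of the 5:2:1:1:1 ratio at 1 μM total (so concentrations span
0.1–0.5 μM); sparse sets contain exactly 2 of 5 targets at 0.5 μM each. River-set
samples use the stronger river background although references and training data use
the drinking-water blank, deliberately stressing background mismatch.

## What the simulation does and does not show

The generator reproduces: overlapping band structure, saturating concentration
response, varying signal-to-background ratio, wavenumber drift, additive noise, and
a background-mismatch condition. It does not model: multiplicative/heteroscedastic
SERS noise, nanoparticle batch variation, matrix effects from real river water,
cosmic-ray spikes, or wavenumber-dependent instrument response. Passing benchmarks
therefore demonstrates the correctness and internal consistency of the analysis
chain under its own generative assumptions — not field performance on real samples.

## Numerical choices and degenerate inputs

* Savitzky–Golay smoothing: span 5, degree 3, `mode="interp"` (in-window polynomial
  edge fits, no padding). Baseline subtraction uses a degree-1 SG filter with a
  window defaulting to ~n/3 (221 points): a 5-point degree-1 baseline would subtract
  the narrow peaks themselves, so the wide window is the package default and the
  span is an explicit parameter.
* Max normalization refuses all-nonpositive spectra; composing an all-blank sample
  with a zero background is an error rather than a 0/0.
* Hill calibration fits constrain h_max above the largest observed height so the
  inverse exists on the data range; fits verify inverse(round-trip) to 1e-6.
* Max pooling drops a trailing remainder (660 → 330 → 165 → 82 with pool 2).

## Known limitations

* The numpy CNN is CPU-only and modest; it is sized for the benchmark, not for
  large-scale reuse.
* The regressor's z output is scale-dependent on the generator's S distribution;
  applying the trained model to spectra whose absolute scale convention differs
  requires re-simulation or re-training.
* Sparse test sets at 0.5 μM sit in the flatter part of the Hill curves, where
  height errors amplify into concentration errors — visible as higher RMSE_conc on
  sparse sets.
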