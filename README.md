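# pahsers

Machine-learning analysis of multiplexed SERS spectra for detecting and
quantifying five polycyclic aromatic hydrocarbon (PAH) water pollutants —
pyrene (PY), triphenylene (TP), nitro-pyrene (NP), benzo[a]pyrene (BAP) and
anthracene (ANT) — built as a fully synthetic, reproducible benchmark.

PAHs are carcinogenic combustion by-products that contaminate drinking and
river water at nanomolar levels. Surface-enhanced Raman scattering (SERS)
can sense them in solution, but their Raman bands overlap heavily (PY, NP
and ANT all share structure near 1240 and 1400 cm⁻¹, and NP has no unique
band at all), so single-peak readout fails on mixtures. This package
implements the unmixing-by-learning approach:

1. **Simulate** labeled mixture spectra by scaled addition of unit-max
   reference spectra: M = Σᵢ ℓᵢ·S·Rᵢ + blank (+ shift + noise), with
   contributions ℓᵢ summing to 1, each target zeroed with 20% probability
   and nonzero contributions floored at 1% of total signal.
2. **Train** two 1D CNNs (3 conv layers + 1 dense, written in numpy) on the
   max-normalized spectra: a multilabel **classifier** (5 sigmoid outputs,
   one per target) and a **regressor** (6 outputs: ℓ₁…ℓ₅ and the
   normalization factor z = max(M)/S).
3. **Decide and quantify**: per-target thresholds maximize
   √(sensitivity·specificity) on validation scores; concentrations come
   from heightᵢ = ℓ̂ᵢ/ẑ · max(M) inverted through a per-target Hill
   calibration curve h(c) = h_max·c/(K+c), floored at 0 μM.
4. **Evaluate** with per-target/micro/macro precision, sensitivity,
   specificity, NPV and f1, ROC-AUC, and two figures of merit:
   RMSE_spectrum = √(Σᵢₖ(ŷᵢₖ−yᵢₖ)²/(n·w)) over w = 660 spectral points, and
   RMSE_conc = √(Σᵢⱼ(ĉᵢⱼ−cᵢⱼ)²/(n·m)) in μM over m = 5 targets.

The benchmark's four test sets mirror a 2×2 design — {drinking, river}
water background × {all-5-targets at varied ratios, 2-of-5 at equal
concentrations} — 39 samples total. See `docs/methods.md` for the full
model description, defaults and limitations.

## Worked example

```python
import numpy as np
from pahsers import (
    PipelineConfig, TARGETS, ratio_to_concentrations,
    simulate_measured_spectrum, max_normalize,
    contributions_to_concentrations, estimate_lod,
)
from pahsers.pipeline import build_library, fit_calibration_curves
from pahsers.references import DEFAULT_RESPONSE_MODELS, NoiseConfig

refs = build_library(PipelineConfig())
curves = fit_calibration_curves(refs)

# a 1 uM total mixture at the 5:2:1:1:1 ratio
concs = ratio_to_concentrations(1.0, (5, 2, 1, 1, 1))
print({t: float(c) for t, c in zip(TARGETS, concs)})

# simulate its measured spectrum (1% noise, drinking-water background)
cfg = NoiseConfig(noise_sd=0.01, max_shift=0, background_scale=0.05, seed=0)
spec = simulate_measured_spectrum(dict(zip(TARGETS, concs)),
                                  DEFAULT_RESPONSE_MODELS, refs, cfg)
normed, raw_max = max_normalize(spec)
print(f"raw spectrum maximum: {raw_max:.3f}")

# quantify from the ground-truth 6-label (what a perfect regressor would emit)
heights = np.array([DEFAULT_RESPONSE_MODELS[t].height(c)
                    for t, c in zip(TARGETS, concs)])
labels = np.append(heights / heights.sum(), raw_max / heights.sum())
result = contributions_to_concentrations(labels, raw_max, curves)
print({t: round(c, 3) for t, c in result.as_dict().items()})

# limit of detection for pyrene at S/N = 3.5 over a 1% blank noise floor
print(f"PY LOD: {estimate_lod(curves['PY'], blank_sd=0.01) * 1000:.1f} nM")
```

prints

```
{'PY': 0.5, 'TP': 0.2, 'NP': 0.1, 'BAP': 0.1, 'ANT': 0.1}
raw spectrum maximum: 0.835
{'PY': 0.5, 'TP': 0.2, 'NP': 0.1, 'BAP': 0.1, 'ANT': 0.1}
PY LOD: 10.9 nM
```

The 1 μM total splits exactly 0.5/0.2/0.1/0.1/0.1 μM across the five
targets; feeding the true labels through the quantification chain recovers
those concentrations (the chain is exact on noiseless labels), and the PY
calibration curve puts the detection limit near 11 nM for a 1% noise floor
at S/N = 3.5.

## Command line

```
pahsers simulate --seed 1 --out-dir run/data --force
pahsers train    --seed 1 --data-dir run/data --out-dir run/models
pahsers evaluate --seed 1 --data-dir run/data --model-dir run/models --out-dir run/reports
pahsers demo     --seed 1 --out-dir run-demo        # small end-to-end run
```

`evaluate` writes `evaluation.json`, a `summary.csv` metric table and a
per-sample `concentrations.csv`. On the default configuration (n = 10,000
training / 2,000 validation, seed 1) the classifier reaches micro f1 = 1.00
and micro/macro ROC-AUC = 1.00 on the four synthetic test sets, and the
regressor reaches RMSE_spectrum = 9.6×10⁻² and RMSE_conc = 6.1×10⁻² μM
combined — the river-background and sparse sets are hardest, exactly as the
background-mismatch and Hill-saturation arguments predict.

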