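# nirgaf

Near-infrared (NIR) spectroscopy is a fast, non-destructive way to classify
agricultural products — distinguishing wheat-kernel cultivars from their
reflectance spectra, or detecting internal browning in pears from transmitted
Vis-NIR light. Classical chemometric classifiers such as PLS-DA work on the
1-D spectrum directly and are sensitive to scatter effects and noise.
`nirgaf` implements an image-based alternative: each spectrum is encoded as a
2-D **Gramian angular field** (GAF) image and classified by a small
convolutional network with a **coordinate-attention** (CA) module, alongside
the classical baselines, under one shared evaluation protocol.

The package is for chemometricians and ML practitioners who want to compare
shallow, ensemble and deep classifiers on tabular spectral data — their own
CSVs or the built-in synthetic generator.

## Method

Given a spectrum `X = {x_1..x_n}`, the encoding is

1. min–max scaling, `x̃_i = (x_i − min X) / (max X − min X) ∈ [0, 1]`;
2. piecewise aggregate approximation (PAA) down to N = 64 points;
3. polar transform `θ_i = arccos x̃_i`, `r_i = i/N`;
4. the Gramian matrices
   `GASF[i,j] = cos(θ_i + θ_j)`, `GADF[i,j] = sin(θ_i − θ_j)`,
   mapped affinely from [−1, 1] to [0, 1] grayscale.

The GADF has an exactly zero main diagonal and is antisymmetric; the GASF
diagonal equals `2x̃² − 1`, so the original sequence is recoverable from it.
Off-diagonal pixels carry pairwise difference/sum information between all
wavelength positions, which a convolution kernel can read as *long-range*
spectral structure inside a small receptive field.

Models (all behind one `fit`/`predict` interface):

* **PLS-DA** — NIPALS PLS2 regression onto one-hot labels, naive-max decision
  rule, component count (1–15) by leave-one-out CV;
* **Random forest** — Gini-criterion ensemble, grid search over
  {50..300 step 50} trees × {10,30,50,70,90} depth by stratified 5-fold CV;
* **CNN / CACNN** — a fixed VGG-style stack
  (Conv 3×3×32 → [CA] → 3×3×32 → pool → 3×3×64 → pool → 3×3×128 → pool →
  global-max-pool → Dense 128 → softmax), trained with Adam at lr 5·10⁻⁴
  halved every 200 iterations (600 total), dropout 0.25 — implemented
  entirely in NumPy with manual backpropagation.

Preprocessing conditions: none, Savitzky–Golay first derivative, SNV, MSC,
and wavelet shrinkage (`db8`, per-level soft threshold at 0.1·max|detail|).
Evaluation reports Accuracy / RP / RN (%) as mean ± sample SD over 10
repeated stratified 2:1 splits. Robustness is probed by additive Gaussian
noise at a stated SNR (dB), `SNR = 10·log10(Ps/Pn)`, and interpretation by
Grad-CAM heatmaps with the ratio-of-attention (fraction of pixels above a
threshold) and the confidence index (max softmax probability).

## Worked example

```python
import numpy as np
from nirgaf import (ModelRecipe, PreprocessSpec, TrainConfig,
                    generate, benchmark_presets, repeated_split_eval)

cfg = benchmark_presets()["wheat-like"]   # two-class, two affected bands
cfg.seed = 0
ds = generate(cfg)                          # 200 spectra, 256 points

plsda = ModelRecipe(model="plsda", preprocess=PreprocessSpec(method="snv"))
report = repeated_split_eval(ds, plsda, n_repeats=10, base_seed=0)
s = report.summary()
print(f"{plsda.name}: {s['accuracy_mean']:.2f} +/- {s['accuracy_sd']:.2f}")
```

prints

```
snv-plsda: 100.00 +/- 0.00
```

i.e. with a strong two-band class effect the SNV-preprocessed PLS-DA
separates the classes perfectly on every one of the 10 random test splits.
The same protocol with the image-based attention network,

```python
recipe = ModelRecipe(model="cacnn", encoding="gadf",
                     model_params={"config": TrainConfig(total_iterations=140,
                                                         batch_size=16)})
```

reaches ≥ 95 % mean accuracy with a desk-scale training budget. The
command-line interface wires the same pieces together:

```bash
nirgaf simulate --preset wheat-like --seed 0 --out runs/sim
nirgaf encode   --data runs/sim/spectra.csv --kind gadf --out runs/enc --png
nirgaf evaluate --preset wheat-like --model plsda --out runs/eval
nirgaf robustness --preset wheat-like --model plsda --model rf --out runs/rob
```

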