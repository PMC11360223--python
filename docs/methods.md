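# Methods

## Pipeline overview

`nirgaf` treats a classification experiment as a *recipe*: a preprocessing
condition, an encoding (raw spectra or a Gramian angular field image), and a
model, evaluated under a repeated random-split protocol. Every piece of
state a recipe acquires (the MSC reference spectrum, model weights, selected
hyperparameters) is fitted inside a single run on that run's training split
only, so sweeps over recipes cannot leak information between cells or into
the test split.

## Gramian angular field encoding

A spectrum is min–max scaled per spectrum (not per dataset): the polar
angle `θ_i = arccos x̃_i` needs `x̃ ∈ [0, 1]`, and per-spectrum scaling makes
the encoding invariant to each sample's own offset and gain. Downsampling
to the 64-point image resolution uses piecewise aggregate approximation with
segment boundaries at `round(j·p/m)`, so segment sizes differ by at most one
point and the global mean is conserved when `m | p`. Both Gramian fields are
computed in their matrix-product form (`GADF = s'x − x's` with
`s = √(1−x̃²)`), which makes the zero diagonal and antisymmetry of the GADF
*exact* in floating point rather than merely approximate; the elementwise
trigonometric definition is kept in the test suite as an independent oracle.
Images are mapped from [−1, 1] to [0, 1] by a fixed affine map so pixel
semantics are comparable across samples; the GADF diagonal therefore sits at
exactly 0.5. Spectra shorter than the image size are rejected unless linear
interpolation is explicitly enabled. The numeric array is the authoritative
representation; PNG export (8-bit, `round(255·v)`) is for inspection only.

## Preprocessing

Five conditions: `none`, Savitzky–Golay first derivative (default window 15,
polyorder 2 — a common chemometrics choice, both configurable), SNV
(per-spectrum centering to sample SD 1), MSC (per-spectrum OLS regression on
the training-mean reference, then `(x − a)/b`), and wavelet shrinkage. The
wavelet condition uses the discrete `db8` basis with multilevel
decomposition (depth `floor(log2(p/filter_length))`, capped at 5) and
per-level soft thresholding at `0.1 × max|detail|`; a scalar noise-threshold
fraction combined with a Daubechies basis only makes sense as shrinkage, so
that is what is implemented. The MSC reference is frozen on the training
split and reused for test data to avoid leakage.

## Models

**PLS-DA.** NIPALS PLS2 with deflation, responses as K one-hot columns,
regression coefficients `B = W(PᵀW)⁻¹Qᵀ`, and the naive-max decision rule
(ties to the lowest class index, which is deterministic and logged in the
class order). Component count is selected by leave-one-out CV over 1–15;
each fold fits once at the maximal rank and evaluates all candidate counts
from that single fit, which makes LOOCV affordable (an `n ≤ 2000` guard
remains). Ties select the smallest count. The implementation is checked
against an independent PLS regression implementation in the test suite.

**Random forest.** Gini-criterion CART ensemble delegated to a well-tested
library implementation behind the package's interface; the Gini impurity
function itself is exposed directly. The grid is 6 tree counts
({50..300 step 50}) × 5 depths ({10, 30, 50, 70, 90} — a step of 20 from 10
cannot reach 100, so 100 is excluded), scored by stratified 5-fold CV
accuracy with ties resolved toward fewer trees, then shallower depth.

**CNN / CACNN.** The fixed architecture is the shallow VGG-style stack
documented in `deepnet.py`; "same" padding and stride-1 convolutions are
forced by the required intermediate shapes (64×64 preserved through the
conv layers, 8×8×128 after the third pool, 128 features after global max
pooling). The network is implemented directly in NumPy — 3×3 convolutions
as nine shifted channel-mixing matrix products, manual backward passes
verified against central finite differences — so no deep-learning framework
is required and Grad-CAM has direct access to intermediate gradients. The
coordinate-attention module pools each channel along both spatial axes,
squeezes the concatenated profiles through a shared 1×1 transform to
`max(C/r, 8)` channels (ReLU; reduction r = 8 by default, the original
design convention), expands back per direction and gates the input
multiplicatively through sigmoids. A `pin_gates` hook forces both gates to
one, making the CACNN forward pass exactly equal a weight-matched CNN — the
architectural-equivalence oracle used in the tests. Training uses Adam
(field default; the optimizer is configurable in principle via
`TrainConfig`) with initial learning rate 5·10⁻⁴ halved every 200
iterations, 600 iterations total, dropout 0.25 after the first dense layer,
and categorical cross-entropy. "Iterations" are optimizer steps: full-batch
when `n ≤ 512` and no batch size is given, otherwise mini-batches (default
32); the choice is explicit in `TrainConfig` and recorded in training
history. A non-finite loss aborts with a diagnostic rather than continuing.

## Evaluation protocol

Stratified 2:1 splits with train size `round(2n/3)` (ties upward — this
reproduces both 400 → 267/133 and 495 → 330/165). Stratification uses the
largest-remainder method, keeping per-class train frequencies within one
sample of the global proportions and guaranteeing both parts contain every
class; it is on by default so RP/RN are defined on every split, with a flag
to disable. Metrics are Accuracy, RP and RN in percent from the
misclassification counts; aggregation over the 10 repeats (seeds
`base_seed .. base_seed+9`) uses the sample standard deviation (n−1), the
convention validated by reproducing a published five-value summary row
exactly. The preprocessing sweep additionally reports, per model, the
cross-method SD of the five per-method mean accuracies — a stability
measure of the model under preprocessing choice.

## Noise robustness

Additive Gaussian noise at a stated SNR in dB with signal power defined as
the mean squared value of the clean spectrum (the standard signal-power
convention; variance-based power would change levels by a spectrum-dependent
offset). Noise is drawn per sample with per-sample power so the nominal SNR
is uniform across samples, and corruption is applied to the raw spectra
*before* preprocessing. The default grid {10, 20, 30, ∞} dB is configurable
and always reported alongside results.

## Interpretation

Grad-CAM weights each channel of a chosen conv layer (default the deepest,
`conv4`, using its rectified activations) by the spatial mean of the
target-logit gradient, rectifies the weighted sum, upsamples bilinearly to
64×64 and min–max normalizes. An all-zero attribution returns an all-zero
map with a warning — under global max pooling gradients are spatially
sparse and genuinely zero attributions can occur. The ratio of attention is
the fraction of pixels strictly above a threshold; the threshold has no
canonical value and is a required, logged parameter (0.5 by default on the
normalized map). The confidence index is the maximum softmax probability.

## Synthetic data generator

Each spectrum is `(1 + s_i)·Σ_k A_k(class)·Gauss(c_k, w_k) + baseline + ε`
with per-sample multiplicative scatter `s_i ~ N(0, 0.05²)` and additive
noise `ε ~ N(0, 0.01²)` absorbance units — the minimal structure under which
SNV/MSC do something meaningful and the GADF carries spatially localized
class signal. Two presets mirror the two benchmark situations: `wheat-like`
(870–1700 nm, class effect +0.12 on two of four peaks, near 975 and
1360 nm) and `pear-like` (370–1160 nm, class B attenuated on all peaks, most
strongly at 700 nm, so one class dominates pointwise). Defaults are 100
samples per class and 256 points — enough for the image encoding while
keeping deep-model training desk-fast. The generator does **not** emulate
wavelength drift, correlated detector noise, instrument transfer effects or
real absorption-band physics; passing tests demonstrate that the pipeline
recovers a planted, linearly separable class signal and degrades gracefully
under additive noise, not that it attains any particular accuracy on real
instruments.

One caveat the tests make explicit: with the class effect zeroed, repeated
splits of a *single* finite dataset are correlated, so "chance level" has a
wider band than the naive per-run binomial error; the null check therefore
uses three across-split SDs around 50 %.

## Desk-scale problem sizes

End-to-end checks run the full protocol at deliberately modest sizes chosen
once as part of the package's own test design: the wheat-like preset at
100/class; CACNN budgets of 140 training iterations (mini-batches of 16) for
the recovery check and 60 for the robustness grid; 10 repeats for recovery
and 3 per (model, SNR) cell for robustness, with the forest evaluated at a
single (100 trees, depth 30) grid cell there. At these sizes all models
saturate on the planted signal, which is what the checks assert.

## Known limitations

* The NumPy network trains on CPU only; it is sized for 64×64 single-channel
  inputs and the fixed architecture, not as a general DL framework.
* LOOCV component selection refits the training set once per left-out
  sample; for `n` in the thousands use a fixed component count.
* GASF encoding is provided for completeness; the modeling defaults use
  GADF throughout.
* Multi-class (>2) inputs are accepted by the models, but RP/RN are defined
  only for binary problems.
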