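# Methods

## Problem and model

The package classifies a 5-sequence 3D MRI volume of a pediatric brain
tumor (CE-T1WI, T1WI, T2WI, FLAIR, ADC, in that fixed channel order, plus a
binary tumor mask) as low grade (WHO I/II) or high grade (WHO III/IV). The
classifier is a hybrid CNN/Transformer:

- **CAEFF stem.** One convolutional path per sequence (3×3×3, stride
  `stem_stride`, `stem_channels` filters). The T1WI path is standard
  convolution followed by squeeze-and-excitation channel attention
  (global average pool → bottleneck MLP of width C/reduction with ReLU →
  sigmoid → channel rescale). Every other path is a *soft-routed* pair:
  a per-channel gate `g_c = σ(affine(pooled channel means))` blends a
  standard convolution with a DSGC, `g_c·std + (1−g_c)·dsgc`.
  Hard routing ("important channels use standard convolution") is
  non-differentiable; the convex blend preserves gradient flow and recovers
  hard routing exactly at the gate endpoints — an optional inference mode
  thresholds the gates at `gate_threshold` (default 0.5). Path outputs are
  concatenated.
- **MSFE stages.** Each stage multiplies the feature map channel-wise by
  gating-network weights (pooled context → affine → sigmoid), then applies
  DSGC with stride 2. DSGC = depthwise 3×3×3 convolution (padding 1)
  followed by a 1×1×1 pointwise convolution grouped by gcd(C_in, C_out).
- **Transformer.** Each spatial position of the final feature map becomes a
  token by linear projection to `embed_dim`; a learnable CLS token is
  prepended and learnable positional embeddings added. Encoder blocks are
  *pre-norm* (LayerNorm before attention and before the MLP) with residual
  connections; attention is standard scaled dot-product multi-head with an
  output projection; the MLP uses exact (erf) GELU.
- **Head.** linear(E→E) → LayerNorm → linear(E→E/2) → linear(→1) on the
  CLS state; sigmoid of the logit is P(high grade). The loss is
  BCE-with-logits; the optimiser is Adam (β = 0.9/0.999, no weight decay;
  the source material names only the loss and schedule, not the optimiser);
  the learning rate follows cosine annealing
  `lr(e) = base_lr·(1 + cos(πe/E))/2` to zero.

### Presets

| preset | input (D,H,W) | stem | MSFE | embed | depth | heads | params |
|--------|---------------|------|------|-------|-------|-------|--------|
| desk   | 16×64×64      | 8    | 24, 32 (stride 2 each) | 96 | 2 | 4 | 185 087 |
| paper  | 16×64×64      | 16   | 64, 128 | 768 | 8 | 12 | ~57.8 M |

The "paper" preset reproduces the originally printed dims (channel
dimension 768, 12 heads so head size 64, 8 encoder layers). Those dims are
**internally inconsistent** with the originally reported 1.82 M-parameter /
28.5 G-FLOP totals — eight encoder layers at width 768 alone exceed 1.82 M
parameters, and the input size was never stated — so the preset is shipped
verbatim and documented rather than silently "fixed", and those totals are
not targets. The desk preset is the configuration every test trains; its
stage strides take the 16×64×64 input to a 2×8×8 token grid (128 tokens +
CLS), which is what makes 1-CPU numpy training practical.

Unstated architecture choices made here, once: one CAEFF stage then two
MSFE stages; SE reduction 16 by default (4 in the desk preset, which has
only 8 stem channels); "second channel" = T1WI at index 1 of the canonical
order; initialisation truncated-normal σ = 0.02 for projections/embeddings
and Kaiming-normal for convolutions, all driven by one seed.

## Numerical core

There is no deep-learning framework in the dependency set. `cvit3d._nn`
implements a reverse-mode autodiff Tensor on numpy with fused primitives
(grouped 3D convolution via strided-view im2col, layer norm, softmax,
BCE-with-logits) and an Adam optimiser. Every fused backward pass is
validated against central finite differences in `tests/test_nn.py`; the
multi-head attention and DSGC forward passes are additionally checked
against independent scalar-loop oracles. All randomness flows through
explicitly passed `numpy.random.Generator`s, so seeded runs are
bit-reproducible on a fixed platform.

## Complexity accounting

`cvit3d.complexity` computes exact integer multiply counts:
output extents `floor((in + 2P − K)/S) + 1` per axis; dense convolution
`K₁K₂K₃·C_in·C_out·V`; DSGC `K₁K₂K₃·C_in·V + V·C_out·C_in/gcd(C_in,C_out)`;
reduction ratio `1/C_out + 1/(gcd·K³)` (= 1 + 1/K³, i.e. *no* saving, when
C_out = 1). Convention: multiplies only — additions, biases and softmax are
ignored; a `multiply_add=True` toggle doubles counts for comparison with
MAC-based profilers. Attention rows count the QKV/output projections and
the two attention matmuls. The per-layer parameter table is analytic and
asserted equal to the instantiated network's trainable-parameter total.

## Statistics

- AUC: rank form with midranks for ties (tie handling was unspecified;
  midranks make the statistic equal the pairwise wins + half-ties count,
  which the tests verify exhaustively). Single-class input is an error,
  not a silent number.
- Confusion metrics from a score threshold of 0.5 by default (the original
  confusion matrix's threshold is unstated). Zero-denominator metrics are
  reported as NaN with a warning, never as 0.
- DeLong: fast structural-components form; the variance of ΔAUC uses
  per-positive and per-negative component covariances. Degenerate variance
  → z = 0, p = 1. Calibration is tested: null rejection rate at α = 0.05
  within [0.03, 0.07] over 1000 simulations.
- Cohort tables: Pearson chi-square *without* Yates correction by default
  (flag available); Welch unequal-variance t-test with Satterthwaite df
  ("independent samples t-test" left the variance assumption open).
  Percentages round to one decimal.

## Radiomics selection

First-order features (mean, population variance, skewness, kurtosis,
energy, 32-bin entropy, 10th/90th percentiles, voxel count, volume) per
sequence inside the mask; constant regions report skewness/kurtosis 0 with
a warning. The univariate screen dichotomizes each continuous feature at
its median and runs a 2×2 Pearson chi-square against the grade — the exact
null rejection rate of this screen at α = 0.05, n = 200 is 0.066 (margins
fixed by the median split), within the tested α ± 0.02 band; an ANOVA
screen is available behind a flag. LASSO: L1-penalised logistic regression,
features standardized internally, λ grid of 100 log-spaced points from
λ_max (the smallest λ that zeroes every coefficient) down 4 decades, 5-fold
CV minimising binomial deviance, λ.min rule. `screen_and_select` runs the
screen first so the selected set is a subset of the chi-square pass set by
construction. Feature names follow `<sequence>_<filter>_<class>_<name>` so
selections can be tallied per sequence of origin.

## The phantom generator's stated world

`generate_phantom` draws a shared ellipsoid tumor on the model grid and
builds the five channels from it: CE-T1WI rim enhancement (stronger for
HG), mildly hypointense T1WI, hyperintense T2WI with HG-only smooth
heterogeneity texture and a bright necrotic core, FLAIR with a peritumoral
edema band, and ADC whose in-tumor mean is **lower for HG than LG by
construction** — the HG−LG gap defaults to 1.0 noise SD (noise σ = 0.1
arbitrary units on a background of 1.0). HG boundaries are smoothed with
σ_b = 1.5 voxels against 0.5 for LG (infiltrative vs sharp borders); the
label mask stays the exact ellipsoid indicator. Cohort tables draw
grade-conditional covariates (gender, location, type, necrosis, edema,
Ki-67, age) with probabilities mirroring the reference cohort's printed
proportions (n = 340, 142 LG / 198 HG), including the near-deterministic
Ki-67/grade coupling.

What the phantoms do **not** emulate: anatomy, scanner/protocol effects,
bias fields, registration error, or class overlap — the grade contrasts are
planted and therefore recoverable. A green training test establishes that
the optimisation pipeline can fit effects the generator encoded; it says
nothing about clinical discrimination.

Splitting: the reference 237/51/52 split of 340 is not reproducible by any
standard rounding (0.70·340 = 238), and a strict per-class
`round(ratio·n_class)` rule breaks the balanced-100 → 70/15/15 case
(round(7.5) per class gives 16 validation subjects). `stratified_split`
therefore rounds the *global* val/test sizes and apportions them across
classes by largest remainder (ties to the smaller class label), which keeps
every split's class prevalence within one subject of the global prevalence.

## Preprocessing stand-ins

Bias correction and inter-sequence registration are upstream
responsibilities; mismatched grids/affines are refused, never silently
registered. WhiteStripe intensity normalization (which models the
white-matter intensity mode) is replaced by a documented stand-in: a
z-score against the mean/SD inside the modal-intensity window (histogram
mode ± 5 % of the intensity range); the returned parameters flag the
substitution, and the map is affine-invariant and idempotent. For
*network input conditioning* the training pipeline defaults to a plain
per-channel z-score (`preprocess_batch`): the network has no input
normalization layers, and modal-window-normalized phantoms (lesion
intensities tens of window-SDs from zero) destabilise the short desk-scale
schedules, while z-scored inputs train cleanly. Resampling uses trilinear
interpolation for intensities and nearest-neighbour for masks, output
extent ceil(extent_mm/spacing), origin preserved.

## Training harness

Adam + cosine annealing + BCE-with-logits, defaults epochs = 100,
batch = 16, base_lr = 1e-4 (the reference schedule). The 30-epoch overfit
smoke test uses base_lr = 1e-3 — a rate appropriate to its shorter
schedule; no learning rate was specified for that test. The best
checkpoint by validation AUC is retained (final state when no validation
set is given); the run log records per-epoch loss, learning rate (asserted
equal to the closed-form cosine) and metrics. NaN loss aborts with a
diagnostic. Interpretability export writes per-channel SE weights, gate
values and GN weights (JSON) plus the head-averaged final-layer CLS
attention row, normalised over the token grid and trilinearly resampled to
the input grid (NIfTI).

## Known limitations

- The attention/projection initialisation (σ = 0.02) attenuates the
  token→CLS pathway, so very short training runs on very small datasets
  (≲ 50 subjects, ≲ 25 epochs) can sit at chance before breaking through;
  the tested 60-phantom / 30-epoch configuration trains reliably.
- The "paper" preset's parameter/FLOP totals deliberately do not match the
  originally printed 1.82 M / 28.5 G (see Presets above).
- The radiomics extractor is first-order only; texture (GLCM/GLRLM),
  shape and wavelet families are out of scope.
- Pure-numpy training is ~2 s per 16-volume step at desk scale on one CPU;
  the package is a reference implementation, not a performance tool.
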