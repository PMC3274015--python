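# Methods

This note records the model, the tunable parameters, and the numerical
conventions the implementation commits to, so results are interpretable
and reproducible without reading the source.

## 1. Problem and pipeline

Eight repetitive leg motions (class 1 = standing still) are to be
recognized from two single-axis rate-gyro channels, one above and one
below the knee. The pipeline is:

```
two-channel rate segment (2 × 1600 samples)
  → level-i DWT per channel → sub-band statistics → feature vector
  → min–max normalization to [0, 1]
  → MLP n1:n2:n3 (log-sigmoid hidden, linear output)
  → max-selection over the 8 outputs → class label
```

### Sensor and acquisition model (`gyrowave.synthetic`)

| Parameter | Default | Unit | Notes |
|---|---|---|---|
| `rate_max` | 90 | deg/s | full-scale input, symmetric |
| `v_zero` | 2.5 | V | zero-rate output |
| `v_min`, `v_max` | 0.5, 4.5 | V | output saturates at these rails |
| `adc_bits` | 8 | bits | mid-tread quantizer over `adc_range` |
| `adc_range` | (0, 5) | V | step = 5/255 V; code = ⌊v/step + 0.5⌋ |
| `fs_raw` | 2668 | Hz | ADC sampling rate |
| `downsample_factor` | 20 | — | keep-every-20th decimation → 133.4 Hz |

The rate→voltage map is affine, `v = v_zero + r · (v_max − v_zero)/rate_max`,
clipped to the rails. After quantization the reconstructed rate can exceed
±90 deg/s by up to half a quantization step in rate units (≈ 0.44 deg/s);
dataset invariants use that bound, not a hard ±90.

### Recording protocol

Default: 8 motions × 8 intervals of 72 s × 6 segments of 1,600 samples
(12 s at 133.4 Hz) × 2 channels = 768 single-channel segments, paired into
384 two-channel patterns. One third of patterns (stratified by class, so
16 per class) trains the network; the remaining 256 are held out.

### Synthetic motion generator — what it does and does not emulate

The generator produces quasi-periodic burst trains: a repetition period
drawn once per recording from U(5, 7) s (10–14 repetitions per 72 s
interval), Hann-envelope bursts with class- and channel-specific amplitude
and harmonic content, per-repetition amplitude jitter (truncated Gaussian,
relative sd `amp_jitter` = 0.10, clipped at ±2.5 σ), and additive white
Gaussian noise with σ = max(`noise_floor` = 0.5 deg/s, amplitude ·
10^(−`snr_db`/20)); default `snr_db` = 20 dB. Class 1 is noise only.
Two class pairs (4/5 and 2/8) are constructed with deliberately similar
amplitudes and spectra so that confusions concentrate where energy
features are genuinely ambiguous; classes 2 and 8 are below-knee dominant.

It does **not** emulate gait biomechanics, sensor drift/bias instability,
cross-axis sensitivity, mounting variability, inter-subject variation, or
non-stationary cadence. Accuracy figures obtained on this data validate
the *pipeline implementation*, not clinical performance on real subjects.

## 2. Wavelet analysis (`gyrowave.wavelets`)

* **Catalogue** (75 wavelets): Haar; Daubechies 2–32; Symlets 2–8;
  Coiflets 1–5; biorthogonal and reverse-biorthogonal orders
  {1.1, 1.3, 1.5, 2.2, 2.4, 2.6, 2.8, 3.1, 3.3, 3.5, 3.7, 3.9, 4.4, 5.5,
  6.8}; discrete Meyer.
* **Boundary handling**: periodized convolution (`mode="periodization"`),
  so a length-N signal yields ⌈N/2⌉ coefficients per half-band and
  exactly N coefficients in total at every level; 1,600 samples at level 5
  give lengths (A5, D5…D1) = (50, 50, 100, 200, 400, 800), and ceil-halving
  continues past divisibility (level 8 → 7 approximation coefficients).
* **Support widths**: for orthogonal families, filter length − 1. For the
  spline biorthogonal family the widths follow the order, not the stored
  (zero-padded) filter arrays: bior M.N → (2M+1, 2N+1) and
  rbio M.N → (2N+1, 2M+1), e.g. rbio3.1 → (3, 7). This matches the
  mathematical support of the underlying spline filters; the raw filter
  arrays are padded to equal even lengths and would misreport it.
* **Discrete Meyer caveat**: the standard 62-tap FIR approximation is not
  exactly orthogonal (Σh² ≈ 1.00224). Its reconstruction error is ~10⁻²
  rather than machine precision, so perfect-reconstruction checks use a
  5·10⁻² tolerance for `dmey` only (10⁻⁸ otherwise) and `dmey` is excluded
  from the Parseval energy identity, which is asserted at 10⁻⁶ relative
  error for the orthogonal families.
* **Energy distribution ratios**: with E_T the total coefficient energy,
  EDR_A = ‖A_i‖²/E_T, EDR_Dj = ‖D_j‖²/E_T; they are non-negative and sum
  to 1. A zero-energy decomposition raises `ValueError` rather than
  returning NaNs.
* **Variance conventions**: per-vector coefficient variances use the
  unbiased estimator (ddof = 1), requiring ≥ 2 coefficients per vector;
  the variance *of the EDR_Dj values across sub-bands* (a summary over a
  fixed, small set) uses the population estimator (ddof = 0), so a single
  detail level yields 0, not NaN.

## 3. Feature sets (`gyrowave.features`)

Twelve sets, coded `a`–`l`; per-channel dimensions at level *i* (pattern
dimension is twice this, channels concatenated above-knee first):

| Code | Contents | Dim/channel | At i=5 (two-channel) |
|---|---|---|---|
| a | approximation coefficients | N/2^i | 100 |
| b | all coefficients | N | 3200 |
| c | EDR_D1…EDR_Di | i | 10 |
| d | EDR_A, EDR_D1…EDR_Di | i+1 | 12 |
| e | EDR_A + 4 EDR_D summaries (min, max, mean, var) | 5 | 10 |
| f | the 4 EDR_D summaries | 4 | 8 |
| g | EDR_A, mean(EDR_D), var(EDR_D) | 3 | 6 |
| h | EDR_A, mean(EDR_D) | 2 | 4 |
| i | means and variances of each vector | 2(i+1) | 24 |
| j | means of each vector | i+1 | 12 |
| k | variances of each vector | i+1 | **12** |
| l | EDRs and variances | 2(i+1) | 24 |

Set `k` (sub-band variances) at level 5 is the recommended default: 12
inputs, strong class separation, insensitive to the signal mean.

Normalization is per-feature min–max to [0, 1], fitted on the training
set only; test values are clipped into [0, 1], a constant training column
maps to 0 (with a `RuntimeWarning` at fit time). Min–max (rather than
z-scoring) keeps inputs inside the sigmoid's responsive range and makes
saturation behavior predictable.

## 4. Classifier (`gyrowave.mlp`)

Architecture n1:n2:n3 — log-sigmoid hidden layer, linear outputs, one-hot
targets, decision by maximum output with ties broken toward the lowest
class index (classes are 1-based). Weights initialize uniformly in
±√(6/(fan_in+fan_out)); biases start at 0. A 12:8:8 network has 176
trainable parameters.

**Levenberg–Marquardt training**: per epoch, solve
Δw = (JᵀJ + λI)⁻¹Jᵀe with the full analytic Jacobian of all per-pattern,
per-output residuals; accept the step only if the sum of squared errors
decreases (λ ← λ·0.1), else retry with λ ← λ·10. Defaults: λ₀ = 10⁻³,
`max_lambda` = 10¹⁰, `max_epochs` = 200, `goal_mse` = 10⁻⁴, optional
`goal_accuracy` (experiments use 100 % so training stops as soon as the
training set is fully learned). The accepted-loss history is monotone
non-increasing by construction. LM is quadratic-convergent near a
minimum, which is what makes repeated full retraining (scans, enlarging,
confusion statistics) affordable at these problem sizes.

**Enlarging**: the hidden size starts at `h_min` = 2 and grows by
`h_step` = 2 up to `h_max` = 32, retraining from scratch each time, until
training accuracy reaches 100 %; the last network is returned either way.

## 5. Experiments (`gyrowave.experiments`)

* `run_single`: split → normalize → train (fixed `n_hidden` or enlarging)
  → report complexity string and train/test accuracies.
* `level_scan` / `wavelet_scan`: the same pipeline across decomposition
  levels 1–8 or across the wavelet catalogue, with per-family summaries.
* `confusion_over_runs`: n ≥ 2 repetitions (default 10) with fresh weight
  initializations on a fixed split (`fixed_split`) or fresh splits
  (`resplit`); reports per-cell mean ± sd of row-normalized confusion
  percentages and the overall accuracy mean ± sd. By default the hidden
  size is found once by enlarging and reused across repetitions.

Problem sizes used throughout: 384 patterns (128 train / 256 test),
feature dimension 12 (set `k`, level 5), networks of 2–32 hidden units.
A full default-protocol dataset builds in ~2 s and one training run takes
~1 s on commodity hardware.

## 6. Known limitations

* Synthetic data only; see the generator caveats above.
* LM forms the normal-equations matrix JᵀJ explicitly — fine at 10²–10³
  parameters, unsuitable for large networks.
* Enlarging retrains from a single initialization per hidden size; a
  hidden size that barely reaches 100 % training accuracy for one seed
  may be fragile for others (visible as large per-cell standard
  deviations in `confusion_over_runs`).
* The decomposition level is capped at 8, and sub-band variance features
  require every coefficient vector to have at least two elements, which
  bounds the usable level for short segments.
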