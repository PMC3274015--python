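# gyrowave

Classification of repetitive leg motions from a pair of body-worn,
single-axis rate gyroscopes (one above, one below the knee), for
physiotherapy and home-rehabilitation style monitoring: given a 12-second
two-channel angular-rate segment, decide which of eight exercises
(standing still, lower-leg swings, straight-leg swings, squatting, ...)
produced it.

## Method

Raw segments are long (1,600 samples per channel) and noisy; the package
condenses each one into a handful of wavelet-domain features before
classification.

1. **Dyadic DWT.** Each channel is decomposed by the discrete wavelet
   transform with periodic boundary handling into an approximation vector
   **A**_i and detail vectors **D**_1 … **D**_i at level *i*; **A**_i and
   **D**_j carry N/2^i and N/2^j coefficients respectively.
2. **Sub-band statistics.** With total coefficient energy
   E_T = **A**_i **A**_iᵀ + Σ_j **D**_j **D**_jᵀ, the energy distribution
   ratios are EDR_A = ‖**A**_i‖²/E_T and EDR_Dj = ‖**D**_j‖²/E_T (they sum
   to one). Twelve candidate feature sets combine raw coefficients, EDRs,
   and per-vector means/variances; the most informative in practice is the
   *normalized variances* of (**A**_i, **D**_1 … **D**_i) of both channels
   — 2(i+1) values per channel, i.e. 12 features at level 5 — min–max
   scaled to [0, 1] on the training set.
3. **Classifier.** A three-layer feed-forward network n1:n2:n3
   (log-sigmoid hidden layer, linear outputs, one-hot targets, max-selection
   decisions) trained with the Levenberg–Marquardt update
   Δw = (JᵀJ + λI)⁻¹ Jᵀe, with the hidden size chosen by *enlarging* —
   growing n2 until the training set is fully learned.
4. **Wavelet choice.** The whole catalogue is scannable: Haar, Daubechies
   2–32, Symlets 2–8, Coiflets 1–5, the 15 spline biorthogonal and reverse
   biorthogonal orders, and the discrete Meyer approximation. The reverse
   biorthogonal 3.1 wavelet combines high accuracy with the shortest
   analysis filter (support widths 3/7).

The original single-subject recordings are not publicly available, so the
package ships a first-class synthetic generator that emulates the
acquisition chain — quasi-periodic motion bursts (10–14 repetitions per
72 s interval), the ±90 °/s gyro with 0.5–4.5 V output around a 2.5 V zero
rate, saturation, 8-bit A/D conversion at 2,668 Hz, decimation by 20 to
133.4 Hz, and segmentation into 1,600-sample segments: 768 single-channel
segments = 384 two-channel patterns under the default protocol.

## Worked example

```python
from gyrowave import build_dataset, get_wavelet, run_single

dataset = build_dataset(seed=1)            # 384 labeled two-channel patterns
wavelet = get_wavelet("reverse_biorthogonal", "3.1")
result = run_single(dataset, "k", wavelet, level=5, split_seed=1, init_seed=1)
print(f"complexity {result.complexity}  "
      f"train {result.train_accuracy:.1f}%  test {result.test_accuracy:.1f}%")
```

prints

```
complexity 12:6:8  train 100.0%  test 100.0%
```

i.e. the variance feature set at level 5 has 12 elements, enlarging settled
on 6 hidden neurons for the 8 output classes, the 128 training patterns
(one third, stratified) are fully learned, and all 256 held-out patterns
are classified correctly. Repeating the training ten times with fresh
random initializations (`confusion_over_runs`) yields a mean confusion
matrix whose errors concentrate in the motion pairs that differ mostly in
movement direction — a distinction energy features cannot express:

```
overall: 94.5 ± 6.8 % over 10 iterations (fixed_split)
```

The same pipeline is available from the shell:

```sh
gyrowave simulate --seed 1 --out data/
gyrowave features --in data/ --set k --wavelet rbio3.1 --level 5 --out feat.csv
gyrowave train --features feat.csv --out model/
gyrowave scan-levels --in data/ --set k --wavelet db4 --levels 1-8 --out levels.csv
gyrowave scan-wavelets --in data/ --family coiflet --out coif.csv
gyrowave confusion --in data/ --wavelet rbio3.1 --iterations 10 --out conf.json
```

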