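# csibreathe

Contactless respiratory monitoring from Wi-Fi channel state information
(CSI): a physics-based simulator of breathing-modulated MIMO-OFDM CSI
streams, FFT-based preprocessing, a bidirectional-LSTM respiratory
rate/pattern classifier, and the full confusion-matrix characterization
methodology (attenuation, acquisition-length and frame-rate sweeps).

The package is aimed at researchers and medical-device engineers who want
to understand, prototype or stress-test Wi-Fi-sensing-based respiration
monitors without hardware: every input is synthetic, seeded and
reproducible.

## The model in brief

A breathing chest modulates the multipath channel between a Wi-Fi access
point and client. Each CSI entry is

    h(f, t) = Σ_ℓ ξ_ℓ(t) · exp(−j 2π f τ_ℓ(t)),

a sum over multipath components with complex gains ξ_ℓ and delays τ_ℓ; one
reflection's delay carries the round trip to the moving chest,
τ(t) = τ₀ + 2 d(t)/c, where d(t) is the chest displacement (peak-to-peak
proportional to tidal volume). An acquisition is a 4-D complex tensor
[rx × tx × subcarrier × time] — 3×2×56 = 336 streams at the default radio
plan (20 MHz 802.11n at 5280 MHz, 10 frames/s, 60 s). Streams are demeaned,
transformed to the frequency domain, restricted to the breathing band
(0.03–0.7 Hz) and standardized; a bidirectional LSTM (50 hidden units per
direction, learning rate 0.01, batch size 64, cross-entropy/Adam) maps each
stream to one of the respiratory classes. Performance is evaluated with an
R×R confusion matrix (rows = predicted), per-class and macro precision /
recall / specificity / F1, and seeded stratified 10-fold cross-validation.
The free-space path-loss link budget 20 log10(4πdf/c) maps added
attenuation to an equivalent distance (0 dB ↔ 2.30 m, 20 dB ↔ 23.0 m,
30 dB ↔ 72.7 m).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate two contrasting motions — pattern #2 (6 breaths/min, 705 mL) and
pattern #4 (18 breaths/min, 171 mL) — then train and evaluate a classifier
on their streams:

```sh
csibreathe simulate --pattern 2 --duration 60 --subcarriers 8 --seed 1 --out p2.h5
csibreathe simulate --pattern 4 --duration 60 --subcarriers 8 --seed 2 --out p4.h5
csibreathe preprocess --inputs p2.h5 --inputs p4.h5 --out ds.h5
csibreathe train --dataset ds.h5 --max-epochs 30 --seed 0 --out model.h5
csibreathe evaluate --model model.h5 --dataset ds.h5
```

prints

```json
{
  "accuracy": 1.0,
  "macro_precision": 1.0,
  "macro_recall": 1.0,
  "macro_specificity": 1.0,
  "macro_f1": 1.0,
  "n_total": 96
}
```

96 streams (2 acquisitions × 3 rx × 2 tx × 8 subcarriers) are all assigned
to the correct motion: at clean-channel SNR these two patterns are fully
separable from one 60 s acquisition. The same flow is available from
Python:

```python
from csibreathe.experiments import ExperimentSpec, run_cv

spec = ExperimentSpec.scaled("pattern-9", seed=1)   # 1/6 scale, 8 subcarriers
res = run_cv(spec)                                   # 3-fold stratified CV
print(f"{100 * res.mean_accuracy:.2f} % "
      f"(folds {res.fold_accuracies.round(3)}, std {res.std_accuracy:.3f})")
```

which trains the BiLSTM on the nine-pattern task at the desk-scale
operating point and reports the cross-validated accuracy (≈ 98–100 % at
0 dB added attenuation; see below for how accuracy decays with
attenuation).

A characterization sweep from the shell:

```sh
csibreathe sweep --task pattern-9 --variable attenuation \
    --values 0,10,20,30 --scale 0.167 --subcarriers 8 --folds 3 --seed 1
```

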