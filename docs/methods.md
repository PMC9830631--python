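# Methods

## Problem and model

`csibreathe` studies contactless respiratory monitoring with Wi-Fi channel
state information (CSI). A breathing person perturbs the multipath
propagation between a Wi-Fi access point and client; the per-subcarrier
complex channel estimates reported by the receiver therefore carry a
periodic amplitude/phase modulation at the breathing frequency. The package
simulates this physics, classifies the resulting CSI streams with a
bidirectional LSTM, and characterizes how classification degrades with path
loss, acquisition length and frame rate.

### Channel model

Each CSI entry is a multipath sum

    h(f, t) = Σ_ℓ ξ_ℓ(t) exp(−j 2π f τ_ℓ(t)),

over L = 3 components per antenna pair: a unit-amplitude line-of-sight path
(delay = baseline distance / c), one static clutter reflection (amplitude
≈ 0.4, random excess delay up to 30 ns), and one chest-wall reflection
(amplitude ≈ 0.3) whose delay is modulated by the round trip to the moving
chest, τ(t) = τ₀ + 2 d(t)/c. Three paths are the minimal set exhibiting the
interference structure the classifier exploits; gains and phases are drawn
per antenna pair from a seeded RNG. The transmit pilot is taken as unity,
so the reported CSI equals the channel. The radio plan follows 20 MHz
802.11n at 5280 MHz: 56 tones at 312.5 kHz spacing symmetric about the
carrier with the DC tone skipped, 2 transmit and 3 receive antennas by
default (3×2×56 = 336 streams per acquisition), CSI at 10 frames/s for
60 s.

With a 7 mm chest excursion the per-subcarrier phase swing of the breathing
path is 2π f · 2Δd/c ≈ 1.5 rad — a strong, clearly resolvable modulation;
at 1.7 mm (the shallowest pattern) it is ≈ 0.4 rad.

### Breathing patterns

Nine reference motions ship with the package, keyed by (rate, maximum
tidal volume): (25 BPM, 319 mL), (6, 705), (18, 488), (18, 171), (22, 651),
(15, 587), (28, 442), (19, 513), (25, 463); the 15 BPM/587 mL pattern is
eupnea ("normal"), the others are abnormal motions. Two pairs share a rate
and differ only in depth and waveform shape, which forces the classifier to
use more than the spectral peak location.

The chest displacement waveform is a harmonically shaped periodic signal:
an inspiration/expiration asymmetry implemented as a piecewise-linear phase
warp (inspiration occupies a configurable fraction, 0.30–0.45, of the
cycle), up to four harmonics with pattern-specific weights (fundamental
dominant in all patterns), and per-breath lognormal-free Gaussian jitter of
amplitude (3–5 % relative s.d.) and period (2–4 %). Tidal volume maps to
displacement linearly at 1 mm peak-to-peak per 100 mL (705 mL ≈ 7 mm), a
representative chest-wall excursion; only relative scale matters to the
classifier. The waveform generator guarantees: sample count = frame rate ×
duration, fundamental frequency = rate/60 Hz up to jitter, peak-to-peak
amplitude ∝ tidal volume, and an all-zero series in the zero-volume limit.

### Noise, attenuation and AGC

Complex white Gaussian noise represents receiver noise. The noise floor is
fixed while added attenuation scales the signal by 10^(−att/20), so SNR
falls dB-for-dB with attenuation; the default floor is set for 30 dB SNR at
0 dB added attenuation. An emulated automatic gain control (off by
default) rescales every stream to a fixed mean amplitude, reproducing the
receiver behaviour that makes absolute signal level — and hence the absence
of motion — unobservable. The free-space path-loss formula
FSPL = (4πdf/c)², i.e. 20 log10(4πdf/c) dB, converts added attenuation to
an equivalent distance from the 2.30 m baseline: 0 dB ↔ 2.30 m (54 dB path
loss), 20 dB ↔ 23.0 m (74 dB), 30 dB ↔ 72.7 m, 33 dB ↔ 102.7 m.

## Preprocessing

Each complex stream is demeaned and transformed with a full-length FFT
(rectangular window, no zero padding): frequency resolution is 1/T Hz and
is deliberately tied to the acquisition length, which is what makes the
duration sweep informative. Features are restricted to a breathing band of
0.03–0.7 Hz, covering 3–30 breaths/min with margin. Three feature modes:

* `time` — [T, 2] real/imaginary parts over time;
* `spectrum` — band-limited power bins, with power at +f and −f folded
  together (the breathing modulation of a complex stream appears at both);
* `hybrid` (default) — the band-limited complex DFT coefficients plus the
  folded power, [n_bins, 3]. This retains amplitude-and-phase information
  and the spectral representation in one short sequence (41 steps at 60 s),
  and is the default classifier input.

Per-channel standardization to zero mean and unit variance is fitted on
the training fold only and applied unchanged to the test fold; constant
channels map to zeros. A Hampel filter (rolling median, 3 scaled-MAD
threshold, reflected edges) is available for amplitude cleanup but is off
by default in the main pipeline. Note that the filter is exactly idempotent
only when the cleaned series has no residual samples beyond the threshold;
on Gaussian-floored data a second application may touch a small tail
fraction. On smooth oscillatory series with windows comparable to the
oscillation period it will clip legitimate extrema — one reason it is off
by default.

## Classifier

Sequence input → bidirectional LSTM → fully connected → softmax. The LSTM
cell is the standard formulation (input/forget/output gates via logistic
sigmoid, tanh candidate, c_t = f⊙c_{t−1} + i⊙g_t, h_t = o⊙tanh c_t). The
final hidden states of the forward and backward passes are concatenated
(100 values at the default 50 hidden units per direction) and fed to one
fully-connected layer; argmax of the softmax gives the class, ties breaking
to the lowest class index.

Training minimizes cross-entropy with Adam at the default hyperparameters
hidden units 50, learning rate 0.01, batch size 64. The implementation is
plain numpy with exact analytic backpropagation through time; gradients
are verified against central-difference numerics in the test suite (≤1e−4
relative). Weights are Glorot-uniform from a seeded RNG with the forget
gate biased to 1; identical seeds give bit-identical trained models.
Default epoch budget 150 with early stopping after 20 epochs without a
1e−4 improvement of the full-dataset loss evaluated at each epoch end (the
minibatch loss is too noisy a stopping signal at this learning rate). The
final weights are kept — there is no validation signal in this pipeline,
and restoring the minimum-training-loss snapshot would select the
most-memorized epoch rather than the best-generalizing one. Working precision is float32 by default (ample for a
classifier readout, about twice as fast); float64 is available for
gradient diagnostics.

## Evaluation

Confusion matrices use rows = predicted, columns = true. Per-class
TP/FP/FN/TN, precision, recall, specificity and F1 follow the standard
matrix formulas; macro metrics are arithmetic means over classes; classes
with a zero denominator report 0 with a warning. Cross-validation uses a
seeded shuffle and stratified near-equal folds built by class-wise
round-robin dealing with a rotating remainder offset — fold sizes differ by
at most one (3024 streams → folds of 302/303) and leave-one-out is
supported. Dispersion is reported three ways, since interval conventions
differ across publications: across-fold mean ± sample s.d. (and a
mean ± 1.96 s.d./√k interval), the min–max fold interval, and a binomial
normal-approximation interval on the pooled accuracy.

## Study conditions and problem sizes

Full-scale datasets mirror the standard acquisition: 336 streams per
pattern (3024 for the 9-pattern task), a class-balanced binary set of 2688
abnormal (8 patterns) + 2688 normal streams (the normal class is extended
with additional fresh-seed acquisitions), and 9408 streams for the 28-rate
task; 10-fold stratified CV.

The desk-scale operating point used by the bundled studies and the
reproduction script is 1/6 of the streams per class with 8 of 56
subcarriers and 3-fold CV, with the epoch budget shortened to 80. These
sizes keep a full characterization campaign within minutes on one CPU core
while leaving each class with enough streams (56) for stable fold
estimates. For the large 28-class task the bundled studies use a single
stratified hold-out fold (one third of the data) instead of full
cross-validation — a problem-size choice, not a methodological one; the
full CV path supports every task. The attenuation sweep covers {0, 10, 20, 30} dB added
attenuation; the acquisition-length sweep {60, 30, 15, 10} s runs at 20 dB,
where the resolution loss actually bites; the frame-rate sweep stops at
3 Hz, still ≥ 2× the highest breathing frequency (0.5 Hz). The pipeline
refuses frame rates below twice the highest class frequency outright.

## What the synthetic data does and does not show

The simulator reproduces the mechanisms that make the problem hard or
easy — multipath interference, SNR loss with distance, FFT resolution
limits, rate/shape ambiguity between patterns sharing a rate, AGC masking —
under controlled, seeded conditions. It does not reproduce hardware
artifacts of real CSI (transmit-power and reference-level jumps, firmware
quantization, antenna asymmetries), environmental dynamics (other moving
people, fading), or a real chest's non-rigid geometry. Passing the bundled
studies therefore demonstrates the correctness and internal consistency of
the pipeline and the qualitative degradation trends, not field performance;
absolute accuracies on laboratory data depend on conditions the simulator
fixes by construction.

### Rate vs pattern difficulty at extreme attenuation

On real laboratory data, rate classification (28 classes) degrades faster
than pattern classification (9 classes) as attenuation grows, the intuition
being that more classes are harder. The synthetic conditions here invert
that at the highest attenuation: every rate class uses the deep eupneic
waveform, whose spectral peak survives 0 dB per-sample SNR thanks to the
FFT's processing gain, while the pattern set spans tidal volumes from
171 to 705 mL and contains two same-rate pairs separable only by
amplitude/shape cues that noise destroys first. At 30 dB added attenuation
the shallow patterns are effectively invisible and the pattern task scores
*below* the rate task. This is a real property of the stated class
definitions, not an implementation artifact; it illustrates that
class-count intuitions do not transfer across feature geometries.

### A note on stream-level shuffling

Cross-validation here shuffles and stratifies at the *stream* level, the
convention of the field's measurement campaigns. Streams that originate
from the same acquisition share a channel realization, so a fold can
benefit from having seen sibling streams of a test stream during training.
One observable consequence on synthetic data: at high attenuation, adding
more acquisitions per class can *lower* cross-validated accuracy, because
the per-acquisition memorization advantage is diluted as channel
realizations multiply. Campaigns that need realization-independent
estimates should split by acquisition instead; the trainer interface
accepts any index partition.

## Numerical choices and edge cases

* FFT band edges are inclusive within 1e−12 Hz; the peak is the in-band
  argmax (ties resolve to the lower frequency via argmax).
* Constant feature channels standardize to zeros rather than NaN.
* Zero-denominator metrics report 0 and warn.
* Tie-breaking at the classifier argmax: lowest class index.
* Containers store complex data as paired real arrays; round trips are
  bit-exact. Format version is checked on read; mismatches and truncated
  payloads raise distinct structured errors.
* All randomness flows through explicit seeds (numpy `SeedSequence`
  derivation keyed by task, class, replicate and operating point), so any
  artifact is reproducible from its logged seed.

## Known limitations

* The chest-displacement scale and path geometry are representative
  choices, not measurements; only relative and spectral structure should be
  interpreted.
* The LSTM runs on CPU in numpy; it is sized for the bundled studies, not
  for large-scale training.
* Apnea (absence of motion) is deliberately out of scope: with AGC enabled
  the mean amplitude is pinned, which is precisely why absence of breathing
  is hard to observe in this modality.
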