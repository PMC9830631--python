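"""CSI stream preprocessing: outlier suppression, spectra, standardization.

Turns raw complex CSI streams into real-valued feature sequences for the
classifier. Three feature modes are supported:

``time``
    [T, 2] real/imaginary parts of the stream over time.
``spectrum``
    [n_bins, 1] power spectrum of the demeaned stream restricted to the
    breathing band (default 0.03-0.7 Hz, covering 3-30 breaths/min with
    margin), with power at +f and -f folded together.
``hybrid`` (default)
    [n_bins, 3] frequency-domain complex features in the breathing band:
    (Re X_k, Im X_k, folded power). This keeps both the complex (amplitude
    and phase) information and the spectral representation in one short
    sequence.

An optional Hampel filter (rolling median / median-absolute-deviation
outlier replacement) is provided for amplitude cleanup; it is off by
default in the main pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BREATHING_BAND_HZ",
    "FeatureSequence",
    "FeatureDataset",
    "hampel_filter",
    "SpectrumResult",
    "spectrum_features",
    "stream_features",
    "standardize",
    "SequenceStandardizer",
    "build_dataset",
]

#: Default breathing band (Hz): 3-30 BPM is 0.05-0.5 Hz; margins included.
BREATHING_BAND_HZ = (0.03, 0.7)

#: Gaussian consistency constant relating MAD to standard deviation.
_MAD_SCALE = 1.4826


@dataclass
class FeatureSequence:
    """One classifier input: [n_steps, n_channels] real matrix + label."""

    values: np.ndarray
    label: int
    stream_index: int = -1

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D [n_steps, n_channels]")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        self.values = v


@dataclass
class FeatureDataset:
    """Stacked feature sequences: X [n, n_steps, n_channels], labels y."""

    X: np.ndarray
    y: np.ndarray
    label_names: dict = field(default_factory=dict)
    stream_indices: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return self.X.shape[0]


def hampel_filter(series, half_window: int = 3, n_sigmas: float = 3.0) -> np.ndarray:
    """Rolling-median outlier replacement.

    A sample farther than ``n_sigmas`` scaled median-absolute-deviations
    from the rolling median (window ``2 * half_window + 1``, edges
    reflected) is replaced by that median; all other samples pass through
    unchanged.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    if x.size <= 2 * half_window:
        raise ValueError("series must be longer than 2 * half_window")
    from scipy.ndimage import median_filter

    size = 2 * half_window + 1
    med = median_filter(x, size=size, mode="reflect")
    mad = median_filter(np.abs(x - med), size=size, mode="reflect")
    sigma = _MAD_SCALE * mad
    out = x.copy()
    mask = np.abs(x - med) > n_sigmas * sigma
    out[mask] = med[mask]
    return out


@dataclass
class SpectrumResult:
    """Band-limited power spectrum of one stream.

    ``power`` holds folded two-sided power: P(+f) + P(-f) for each positive
    in-band frequency, normalized so that summing the folded spectrum over
    all positive bins (plus DC, removed here by demeaning) equals the mean
    power (variance) of the stream.
    """

    freqs_hz: np.ndarray
    power: np.ndarray
    peak_freq_hz: float
    bin_width_hz: float
    total_power: float
    #: complex positive-frequency DFT coefficients in the band, scaled 1/N
    coeffs: np.ndarray = None


def spectrum_features(stream, frame_rate_hz: float, band_hz=BREATHING_BAND_HZ) -> SpectrumResult:
    """One-sided power spectrum of the demeaned stream, restricted to a band.

    The reported peak is the argmax bin inside the band; the bin width is
    ``frame_rate_hz / n_samples`` (full-length FFT, rectangular window, no
    zero padding — frequency resolution is set by the acquisition length).
    """
    x = np.asarray(stream)
    if x.ndim != 1:
        raise ValueError("stream must be 1-D")
    n = x.size
    low, high = band_hz
    nyq = frame_rate_hz / 2.0
    if not (0.0 < low < high) or low > nyq:
        raise ValueError(f"band ({low}, {high}) must satisfy 0 < low < high, low <= Nyquist {nyq}")
    high = min(high, nyq)

    x = x - x.mean()
    X = np.fft.fft(x) / n
    f = np.fft.fftfreq(n, d=1.0 / frame_rate_hz)
    p = np.abs(X) ** 2  # sums to mean power over all bins (Parseval)

    bin_width = frame_rate_hz / n
    # strictly positive frequencies below Nyquist; bin -f_k lives at index n-k
    half = (n - 1) // 2
    idx = np.arange(1, half + 1)
    f_pos = f[idx]
    folded = p[idx] + p[n - idx]
    in_band = (f_pos >= low - 1e-12) & (f_pos <= high + 1e-12)
    if not np.any(in_band):
        raise ValueError("band contains no FFT bins at this resolution")
    freqs = f_pos[in_band]
    power = folded[in_band]
    peak = float(freqs[np.argmax(power)])
    return SpectrumResult(
        freqs_hz=freqs,
        power=power,
        peak_freq_hz=peak,
        bin_width_hz=bin_width,
        total_power=float(p.sum()),
        coeffs=X[idx][in_band],
    )


def stream_features(stream, frame_rate_hz: float, mode: str = "hybrid",
                    band_hz=BREATHING_BAND_HZ) -> np.ndarray:
    """Feature matrix [n_steps, n_channels] for one complex CSI stream."""
    x = np.asarray(stream)
    if mode == "time":
        return np.column_stack([x.real, x.imag]).astype(float)
    sr = spectrum_features(x, frame_rate_hz, band_hz)
    if mode == "spectrum":
        return sr.power[:, None].astype(float)
    if mode == "hybrid":
        return np.column_stack([sr.coeffs.real, sr.coeffs.imag, sr.power]).astype(float)
    raise ValueError(f"unknown feature mode {mode!r}")


def standardize(features, axis: int = 0) -> np.ndarray:
    """Scale to zero mean, unit standard deviation per channel.

    Constant channels map to all-zeros (divide-by-zero guard). Idempotent
    within floating-point tolerance.
    """
    x = np.asarray(features, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if x.shape[axis] < 2:
        raise ValueError("need at least 2 samples per channel")
    mean = x.mean(axis=axis, keepdims=True)
    std = x.std(axis=axis, keepdims=True)
    out = x - mean
    nonconst = std > 0
    out = np.divide(out, np.where(nonconst, std, 1.0))
    out = np.where(nonconst, out, 0.0)
    return out


class SequenceStandardizer:
    """Per-channel standardization fitted on a training set of sequences.

    Statistics are computed over all samples and timesteps per channel
    (fit on training folds only, then reused on test folds). Constant
    channels transform to zeros. sklearn-style transformer.
    """

    def __init__(self):
        pass

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[0] == 0:
            raise ValueError("X must be [n_samples, n_steps, n_channels], non-empty")
        flat = X.reshape(-1, X.shape[2])
        self.mean_ = flat.mean(axis=0)
        self.scale_ = flat.std(axis=0)
        self.constant_mask_ = self.scale_ == 0
        self.n_features_in_ = X.shape[2]
        return self

    def transform(self, X):
        if not hasattr(self, "mean_"):
            raise ValueError("SequenceStandardizer is not fitted")
        X = np.asarray(X, dtype=float)
        scale = np.where(self.constant_mask_, 1.0, self.scale_)
        out = (X - self.mean_) / scale
        out[..., self.constant_mask_] = 0.0
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self


def build_dataset(tensors, feature_mode: str = "hybrid", band_hz=BREATHING_BAND_HZ,
                  labels=None, label_names=None) -> FeatureDataset:
    """Assemble labeled feature sequences from a list of CSI tensors.

    One FeatureSequence per stream h_m, in deterministic order (tensor
    order, then stream index). The label of each tensor is taken from
    ``labels`` (parallel list) or from the tensor's pattern id.
    """
    tensors = list(tensors)
    if labels is not None and len(labels) != len(tensors):
        raise ValueError("labels must parallel tensors")
    if len(tensors) == 0:
        return FeatureDataset(X=np.zeros((0, 0, 0)), y=np.zeros(0, dtype=int),
                              label_names=label_names or {})
    fr = tensors[0].channel.frame_rate_hz
    nt = tensors[0].n_frames
    for tns in tensors:
        if tns.channel.frame_rate_hz != fr or tns.n_frames != nt:
            raise ValueError("all tensors must share frame rate and duration")

    feats, ys, idxs = [], [], []
    for k, tns in enumerate(tensors):
        if labels is not None:
            lab = labels[k]
        elif tns.pattern is not None:
            lab = tns.pattern.pattern_id
        else:
            raise ValueError("tensor has no pattern and no label given")
        for m, h in enumerate(tns.streams()):
            feats.append(stream_features(h, fr, feature_mode, band_hz))
            ys.append(lab)
            idxs.append(m)
    X = np.stack(feats)
    return FeatureDataset(
        X=X,
        y=np.asarray(ys, dtype=int),
        label_names=label_names or {},
        stream_indices=np.asarray(idxs, dtype=int),
        meta=dict(feature_mode=feature_mode, band_hz=tuple(band_hz),
                  frame_rate_hz=fr, n_frames=nt),
    )
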