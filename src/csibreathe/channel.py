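"""Breathing-modulated MIMO-OFDM multipath channel simulator.

The received CSI entry for subcarrier frequency ``f`` at time ``t`` is the
multipath sum

    h(f, t) = sum_l  xi_l(t) * exp(-j 2 pi f tau_l(t))

with complex gains ``xi_l`` and delays ``tau_l``. Static paths (line of
sight, clutter) have constant gain/delay; one reflection off the chest wall
has its delay modulated by the round trip to the moving chest,
``tau(t) = tau0 + 2 d(t) / c`` with ``d(t)`` the chest displacement. With a
unit pilot the reported CSI equals the channel, plus complex white Gaussian
noise; an optional emulated automatic gain control (AGC) rescales every
stream to a fixed mean amplitude, which masks absolute signal level.

A free-space path-loss link budget maps an added attenuation in dB to an
equivalent transmitter-receiver distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import c as SPEED_OF_LIGHT

from .patterns import BreathingPattern, breathing_waveform

__all__ = [
    "ChannelConfig",
    "NoiseConfig",
    "CSITensor",
    "channel_gain",
    "simulate_csi",
    "apply_noise_and_agc",
    "fspl_db",
    "attenuation_to_distance",
]


@dataclass(frozen=True)
class ChannelConfig:
    """Geometry and radio plan of the simulated Wi-Fi link.

    Defaults follow a 20 MHz 802.11n channel at 5280 MHz: 56 subcarriers at
    312.5 kHz spacing symmetric about the carrier (DC skipped), 2 transmit
    and 3 receive antennas, CSI at 10 frames/s for 60 s, and a 2.30 m
    baseline distance.
    """

    center_freq_hz: float = 5.280e9
    n_subcarriers: int = 56
    subcarrier_spacing_hz: float = 312_500.0
    n_tx: int = 2
    n_rx: int = 3
    added_attenuation_db: float = 0.0
    frame_rate_hz: float = 10.0
    duration_s: float = 60.0
    baseline_distance_m: float = 2.30
    #: amplitude of the chest-reflection path relative to the unit LoS path
    breathing_path_gain: float = 0.3
    #: amplitude scale of the static clutter path
    clutter_gain: float = 0.4
    #: extra propagation distance of the chest reflection beyond the LoS (m)
    breathing_excess_path_m: float = 0.8

    def __post_init__(self):
        if self.n_subcarriers < 1:
            raise ValueError("n_subcarriers must be >= 1")
        if self.n_tx < 1 or self.n_rx < 1:
            raise ValueError("antenna counts must be >= 1")
        if self.added_attenuation_db < 0:
            raise ValueError("added_attenuation_db must be >= 0")
        if self.frame_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("frame rate and duration must be > 0")
        n = self.frame_rate_hz * self.duration_s
        if abs(n - round(n)) > 1e-9 or round(n) <= 0:
            raise ValueError("frame_rate_hz * duration_s must be a positive integer")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate_hz * self.duration_s))

    @property
    def n_streams(self) -> int:
        return self.n_rx * self.n_tx * self.n_subcarriers

    def subcarrier_frequencies(self) -> np.ndarray:
        """Absolute subcarrier frequencies (Hz), symmetric about the
        carrier with the DC tone skipped."""
        n = self.n_subcarriers
        n_neg = n // 2
        ks = np.concatenate([np.arange(-n_neg, 0), np.arange(1, n - n_neg + 1)])
        return self.center_freq_hz + ks * self.subcarrier_spacing_hz


@dataclass(frozen=True)
class NoiseConfig:
    """Receiver noise and emulated AGC.

    ``noise_power`` is the linear variance of the complex additive white
    Gaussian noise per sample. When left ``None`` it is derived from the
    clean signal so that the SNR at 0 dB added attenuation equals
    ``snr_db`` (the noise floor is fixed; added attenuation scales only the
    signal, so SNR drops dB-for-dB with attenuation).
    """

    noise_power: float | None = None
    snr_db: float = 30.0
    agc_enabled: bool = False
    agc_target_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_power is not None and self.noise_power < 0:
            raise ValueError("noise_power must be >= 0")


@dataclass
class CSITensor:
    """4-D complex CSI array [n_rx, n_tx, n_subcarriers, n_frames] + metadata.

    Flattens to ``n_rx * n_tx * n_subcarriers`` streams; the stream index m
    enumerates (rx, tx, subcarrier) with rx-major order (rx slowest,
    subcarrier fastest), fixed and documented here.
    """

    values: np.ndarray
    channel: ChannelConfig
    pattern: BreathingPattern | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 4:
            raise ValueError("values must be a 4-D array [rx, tx, subcarrier, time]")
        if not np.all(np.isfinite(v.real)) or not np.all(np.isfinite(v.imag)):
            raise ValueError("CSI values must be finite")
        expected = (self.channel.n_rx, self.channel.n_tx, self.channel.n_subcarriers, self.channel.n_frames)
        if v.shape != expected:
            raise ValueError(f"values shape {v.shape} does not match config {expected}")
        self.values = v.astype(np.complex128, copy=False)

    @property
    def n_streams(self) -> int:
        return self.channel.n_streams

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    def streams(self) -> np.ndarray:
        """Flattened [n_streams, n_frames] complex stream matrix h_m."""
        return self.values.reshape(self.n_streams, self.n_frames)


def channel_gain(f, t, paths) -> np.ndarray:
    """Multipath channel entry h(f, t) = sum_l xi_l exp(-j 2 pi f tau_l).

    Parameters
    ----------
    f : scalar or array
        Subcarrier frequency in Hz.
    t : scalar or array
        Time in seconds (broadcast with f). Only used through time-varying
        paths: each path is ``(xi, tau)`` where either entry may be a
        callable of t or a constant.
    paths : sequence of (xi, tau)
        Complex gain and delay (s) per multipath component.
    """
    if len(paths) == 0:
        raise ValueError("paths must be non-empty")
    f = np.asarray(f, dtype=float)
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast(f, t).shape, dtype=np.complex128)
    for xi, tau in paths:
        xi_t = xi(t) if callable(xi) else xi
        tau_t = tau(t) if callable(tau) else tau
        if np.any(np.asarray(tau_t) < 0):
            raise ValueError("path delays must be >= 0")
        out = out + np.asarray(xi_t) * np.exp(-2j * np.pi * f * np.asarray(tau_t))
    return out


def fspl_db(distance_m, freq_hz):
    """Free-space path loss 20 log10(4 pi d f / c) in dB."""
    d = np.asarray(distance_m, dtype=float)
    f = np.asarray(freq_hz, dtype=float)
    if np.any(d <= 0) or np.any(f <= 0):
        raise ValueError("distance and frequency must be > 0")
    out = 20.0 * np.log10(4.0 * np.pi * d * f / SPEED_OF_LIGHT)
    return float(out) if out.ndim == 0 else out


def attenuation_to_distance(added_att_db, baseline_m=2.30):
    """Equivalent distance after adding path loss: baseline * 10^(att/20)."""
    if baseline_m <= 0:
        raise ValueError("baseline_m must be > 0")
    out = baseline_m * 10.0 ** (np.asarray(added_att_db, dtype=float) / 20.0)
    return float(out) if out.ndim == 0 else out


def _draw_static_paths(rng: np.random.Generator, cfg: ChannelConfig):
    """Per-antenna-pair static multipath: unit-amplitude LoS + one clutter
    reflection, and the nominal parameters of the breathing path."""
    tau_los = cfg.baseline_distance_m / SPEED_OF_LIGHT
    xi_los = np.exp(2j * np.pi * rng.random())
    xi_clutter = cfg.clutter_gain * rng.uniform(0.5, 1.0) * np.exp(2j * np.pi * rng.random())
    tau_clutter = tau_los + rng.uniform(1e-9, 30e-9)
    xi_breath = cfg.breathing_path_gain * rng.uniform(0.7, 1.0) * np.exp(2j * np.pi * rng.random())
    tau_breath0 = (cfg.baseline_distance_m + cfg.breathing_excess_path_m) / SPEED_OF_LIGHT
    return (xi_los, tau_los), (xi_clutter, tau_clutter), (xi_breath, tau_breath0)


def simulate_csi(
    pattern: BreathingPattern | None,
    channel_cfg: ChannelConfig | None = None,
    noise_cfg: NoiseConfig | None = None,
) -> CSITensor:
    """Simulate a breathing-modulated CSI tensor.

    The chest displacement series modulates the delay of one reflection per
    antenna pair (``tau(t) = tau0 + 2 d(t) / c``); static paths are drawn
    per antenna pair from the seeded RNG. The result is attenuated by the
    configured added attenuation, noise is added, and AGC applied if
    enabled. Reproducible bit-for-bit given (pattern, configs, seed).

    ``pattern=None`` simulates a static (no motion) scene.
    """
    cfg = channel_cfg or ChannelConfig()
    ncfg = noise_cfg or NoiseConfig()
    ss = np.random.SeedSequence(ncfg.seed)
    s_wave, s_paths, s_noise = ss.spawn(3)

    n_t = cfg.n_frames
    t = np.arange(n_t) / cfg.frame_rate_hz
    freqs = cfg.subcarrier_frequencies()

    if pattern is None or pattern.displacement_mm == 0.0:
        disp_m = np.zeros(n_t)
    else:
        disp_mm = breathing_waveform(
            pattern, cfg.frame_rate_hz, cfg.duration_s, seed=s_wave.generate_state(1)[0]
        )
        disp_m = disp_mm * 1e-3

    rng = np.random.default_rng(s_paths)
    values = np.empty((cfg.n_rx, cfg.n_tx, cfg.n_subcarriers, n_t), dtype=np.complex128)
    for rx in range(cfg.n_rx):
        for tx in range(cfg.n_tx):
            (xi0, tau0), (xi1, tau1), (xib, taub0) = _draw_static_paths(rng, cfg)
            tau_b = taub0 + 2.0 * disp_m / SPEED_OF_LIGHT
            # static part: [n_sc] ; breathing part: [n_sc, n_t]
            static = xi0 * np.exp(-2j * np.pi * freqs * tau0) + xi1 * np.exp(-2j * np.pi * freqs * tau1)
            breath = xib * np.exp(-2j * np.pi * freqs[:, None] * tau_b[None, :])
            values[rx, tx] = static[:, None] + breath

    clean = CSITensor(values=values, channel=cfg, pattern=pattern, seed=ncfg.seed)
    return apply_noise_and_agc(clean, ncfg, cfg.added_attenuation_db, _noise_seed=s_noise)


def apply_noise_and_agc(
    tensor: CSITensor,
    noise_cfg: NoiseConfig,
    added_attenuation_db: float = 0.0,
    _noise_seed=None,
) -> CSITensor:
    """Attenuate, add complex white Gaussian noise, optionally apply AGC.

    The signal is scaled by ``10^(-att/20)`` while the noise floor stays
    fixed, so SNR drops dB-for-dB with added attenuation. With AGC enabled
    every stream is rescaled so its mean amplitude equals the AGC target,
    making the reported amplitude attenuation-independent.
    """
    if noise_cfg.noise_power is not None and noise_cfg.noise_power < 0:
        raise ValueError("noise_power must be >= 0")
    if added_attenuation_db < 0:
        raise ValueError("added_attenuation_db must be >= 0")

    v = tensor.values * 10.0 ** (-added_attenuation_db / 20.0)

    noise_power = noise_cfg.noise_power
    if noise_power is None:
        # fixed receiver noise floor referenced to the unattenuated signal
        p_signal = float(np.mean(np.abs(tensor.values) ** 2))
        noise_power = p_signal * 10.0 ** (-noise_cfg.snr_db / 10.0)

    if noise_power > 0:
        rng = np.random.default_rng(_noise_seed if _noise_seed is not None else noise_cfg.seed)
        scale = np.sqrt(noise_power / 2.0)
        v = v + scale * (rng.standard_normal(v.shape) + 1j * rng.standard_normal(v.shape))

    if noise_cfg.agc_enabled:
        flat = v.reshape(tensor.n_streams, -1)
        mean_amp = np.abs(flat).mean(axis=1, keepdims=True)
        mean_amp[mean_amp == 0] = 1.0
        flat = flat * (noise_cfg.agc_target_amplitude / mean_amp)
        v = flat.reshape(v.shape)

    meta = dict(tensor.meta)
    meta.update(added_attenuation_db=added_attenuation_db, noise_power=noise_power,
                agc=noise_cfg.agc_enabled)
    return CSITensor(values=v, channel=tensor.channel, pattern=tensor.pattern,
                     seed=tensor.seed, meta=meta)
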