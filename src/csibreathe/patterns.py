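"""Parametric respiratory motion patterns.

Each pattern describes a periodic chest-wall displacement: a breathing rate
(breaths per minute), a maximum tidal volume (mL) that sets the peak-to-peak
excursion, an inspiration fraction that skews the cycle (inspiration is
typically shorter than expiration), a small set of harmonic weights that give
each pattern its waveform shape, and per-breath amplitude/period jitter.

Nine reference patterns ship as module constants, keyed by the (rate, tidal
volume) pairs used throughout the package; pattern #6 (15 BPM, 587 mL) is the
*normal* (eupneic) pattern, the rest are abnormal (brady-/tachypneic or
altered-depth) motions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BreathingPattern",
    "PATTERN_TABLE",
    "NORMAL_PATTERN_ID",
    "normal_pattern_at",
    "breathing_waveform",
    "MM_PER_ML",
]

#: Linear tidal-volume -> chest displacement gain: 1 mm peak-to-peak per
#: 100 mL of tidal volume (705 mL ~ 7 mm). Only relative scale matters to
#: the classifier; absolute chest excursion is configurable here.
MM_PER_ML = 1.0 / 100.0


@dataclass(frozen=True)
class BreathingPattern:
    """One respiratory motion: rate, depth, waveform shape and variability.

    Parameters
    ----------
    pattern_id : int
        Identifier 1-9 for the shipped patterns, or any integer for
        user-defined motions.
    rate_bpm : int
        Breathing rate in breaths per minute, 3..30.
    max_tidal_volume_ml : float
        Maximum inspiratory/expiratory tidal volume in millilitres; drives
        the peak-to-peak chest displacement via :data:`MM_PER_ML`.
    inspiration_fraction : float
        Fraction of the breath cycle spent inhaling, in (0, 1).
    amplitude_jitter : float
        Relative standard deviation of the per-breath amplitude.
    rate_jitter : float
        Relative standard deviation of the per-breath period.
    harmonic_weights : tuple of float
        Relative amplitudes of the waveform harmonics (fundamental first).
    """

    pattern_id: int
    rate_bpm: int
    max_tidal_volume_ml: float
    inspiration_fraction: float = 0.40
    amplitude_jitter: float = 0.0
    rate_jitter: float = 0.0
    harmonic_weights: tuple = (1.0,)

    def __post_init__(self):
        if not 3 <= self.rate_bpm <= 30:
            raise ValueError(f"rate_bpm must be in [3, 30], got {self.rate_bpm}")
        if self.max_tidal_volume_ml < 0:
            raise ValueError("max_tidal_volume_ml must be >= 0")
        if not 0.0 < self.inspiration_fraction < 1.0:
            raise ValueError("inspiration_fraction must be in (0, 1)")
        if self.amplitude_jitter < 0 or self.rate_jitter < 0:
            raise ValueError("jitter parameters must be >= 0")
        if len(self.harmonic_weights) == 0:
            raise ValueError("harmonic_weights must be non-empty")

    @property
    def rate_hz(self) -> float:
        """Fundamental breathing frequency in Hz."""
        return self.rate_bpm / 60.0

    @property
    def displacement_mm(self) -> float:
        """Nominal peak-to-peak chest displacement in millimetres."""
        return self.max_tidal_volume_ml * MM_PER_ML


def _p(pid, bpm, tv, fi, aj, rj, hw):
    return BreathingPattern(
        pattern_id=pid,
        rate_bpm=bpm,
        max_tidal_volume_ml=tv,
        inspiration_fraction=fi,
        amplitude_jitter=aj,
        rate_jitter=rj,
        harmonic_weights=hw,
    )


#: The nine reference patterns. The (rate, tidal volume) pairs are the class
#: labels the classifier must recover; shape parameters (inspiration
#: fraction, harmonics, jitter) are package choices that make the nine
#: motions distinct waveforms at the stated rates and depths. Patterns #3
#: and #4 share a rate and differ only in depth/shape; so do #1 and #9.
PATTERN_TABLE: dict = {
    1: _p(1, 25, 319.0, 0.35, 0.04, 0.03, (1.0, 0.30, 0.10)),
    2: _p(2, 6, 705.0, 0.30, 0.05, 0.04, (1.0, 0.45, 0.20, 0.08)),
    3: _p(3, 18, 488.0, 0.40, 0.03, 0.02, (1.0, 0.15)),
    4: _p(4, 18, 171.0, 0.45, 0.04, 0.03, (1.0, 0.50, 0.25)),
    5: _p(5, 22, 651.0, 0.32, 0.05, 0.03, (1.0, 0.25, 0.05)),
    6: _p(6, 15, 587.0, 0.40, 0.04, 0.03, (1.0, 0.20)),
    7: _p(7, 28, 442.0, 0.38, 0.04, 0.03, (1.0, 0.35, 0.12)),
    8: _p(8, 19, 513.0, 0.36, 0.03, 0.02, (1.0, 0.08)),
    9: _p(9, 25, 463.0, 0.42, 0.05, 0.04, (1.0, 0.40, 0.18, 0.06)),
}

#: Pattern #6 is eupnea (15 BPM): the "normal" class in the binary task.
NORMAL_PATTERN_ID = 6


def normal_pattern_at(rate_bpm: int) -> BreathingPattern:
    """Normal-shaped breathing at an arbitrary rate (for the rate tasks).

    Keeps the eupneic waveform shape of pattern #6 but overrides the rate;
    pattern_id is set to the rate so labels stay self-describing.
    """
    return replace(PATTERN_TABLE[NORMAL_PATTERN_ID], pattern_id=int(rate_bpm), rate_bpm=int(rate_bpm))


def _cycle_shape(phase: np.ndarray, pattern: BreathingPattern) -> np.ndarray:
    """Unit waveform evaluated at cycle phase in [0, 1).

    The inspiration/expiration asymmetry is a piecewise-linear phase warp:
    phase [0, fi] -> [0, 0.5] (inhale, displacement rising) and [fi, 1] ->
    [0.5, 1] (exhale, falling); harmonics of the warped phase shape the
    waveform. Output is normalized to peak-to-peak 1.
    """
    fi = pattern.inspiration_fraction
    u = np.where(phase < fi, 0.5 * phase / fi, 0.5 + 0.5 * (phase - fi) / (1.0 - fi))
    w = np.zeros_like(u)
    for k, a in enumerate(pattern.harmonic_weights, start=1):
        w += a * (-np.cos(2.0 * np.pi * k * u))
    # normalize to unit peak-to-peak using a dense phase sample
    ug = np.linspace(0.0, 1.0, 2048, endpoint=False)
    wg = np.zeros_like(ug)
    for k, a in enumerate(pattern.harmonic_weights, start=1):
        wg += a * (-np.cos(2.0 * np.pi * k * ug))
    ptp = wg.max() - wg.min()
    return w / ptp


def breathing_waveform(
    pattern: BreathingPattern,
    frame_rate_hz: float,
    duration_s: float,
    seed: int | None = 0,
) -> np.ndarray:
    """Chest displacement time series in millimetres.

    Returns a series of ``frame_rate_hz * duration_s`` samples whose
    fundamental frequency is ``rate_bpm / 60`` Hz (up to rate jitter) and
    whose peak-to-peak amplitude is ``max_tidal_volume_ml * MM_PER_ML``
    (up to amplitude jitter).

    Raises
    ------
    ValueError
        If frame rate or duration is non-positive, or their product is not
        a whole number of samples.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = frame_rate_hz * duration_s
    n_frames = int(round(n))
    if abs(n - n_frames) > 1e-9 or n_frames <= 0:
        raise ValueError("frame_rate_hz * duration_s must be a positive integer")

    t = np.arange(n_frames) / frame_rate_hz
    f0 = pattern.rate_hz
    if pattern.displacement_mm == 0.0:
        return np.zeros(n_frames)

    rng = np.random.default_rng(seed)
    n_cycles = int(np.ceil(duration_s * f0)) + 2
    # per-breath period and amplitude factors
    if pattern.rate_jitter > 0:
        periods = (1.0 / f0) * np.clip(1.0 + pattern.rate_jitter * rng.standard_normal(n_cycles), 0.5, 1.5)
    else:
        periods = np.full(n_cycles, 1.0 / f0)
    if pattern.amplitude_jitter > 0:
        amps = np.clip(1.0 + pattern.amplitude_jitter * rng.standard_normal(n_cycles), 0.1, None)
    else:
        amps = np.ones(n_cycles)

    # piecewise-linear accumulated phase: cycle boundaries at cumsum(periods)
    bounds = np.concatenate([[0.0], np.cumsum(periods)])
    idx = np.searchsorted(bounds, t, side="right") - 1
    idx = np.clip(idx, 0, n_cycles - 1)
    frac = (t - bounds[idx]) / periods[idx]
    phase = np.clip(frac, 0.0, 1.0 - 1e-12)

    shape = _cycle_shape(phase, pattern)
    return pattern.displacement_mm * amps[idx] * shape
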