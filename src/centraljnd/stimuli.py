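"""Calibrated stimulus synthesis for intensity change detection paradigms.

Everything the modeled paradigms need is synthesized here: raised-cosine
gated pure tones, frozen Gaussian noise (broadband, band-limited with
12 dB/octave skirts, or calibrated by spectrum level), multiplicative
increment/decrement envelopes (square, gated-plateau, symmetric linear
up-down ramps), and two-tone beat stimuli.

Calibration convention: samples are dimensionless linear pressure
amplitudes where a full-scale sinusoid (amplitude 1.0) corresponds to
``config.full_scale_db_spl`` (default 100 dB SPL).  So a signal with
mean-square power ``ms`` has a level of ``full_scale + 10*log10(ms/0.5)``
dB SPL.

Frozen noise: every noise realization is produced by a seeded generator
and treated as deterministic, so a pedestal and the pedestal-plus-change
target share bit-identical carrier samples wherever the envelope gain
is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.io import wavfile

from .config import ModelConfig, DEFAULT_CONFIG


class CalibrationError(ValueError):
    """Requested level outside the calibrated range of the pipeline."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class TimeSignal:
    """A calibrated amplitude sample sequence.

    ``samples`` are linear pressure amplitudes; ``full_scale_db_spl``
    records the dB SPL of a full-scale sinusoid so the absolute level of
    the waveform is always recoverable.
    """

    samples: np.ndarray
    sample_rate: float
    full_scale_db_spl: float = 100.0

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def rms_db_spl(self, t0: Optional[float] = None, t1: Optional[float] = None) -> float:
        """Measured rms level in dB SPL over ``[t0, t1)`` (whole signal by default)."""
        i0 = 0 if t0 is None else int(round(t0 * self.sample_rate))
        i1 = len(self.samples) if t1 is None else int(round(t1 * self.sample_rate))
        seg = self.samples[i0:i1]
        ms = float(np.mean(seg ** 2))
        if ms <= 0.0:
            return -np.inf
        return self.full_scale_db_spl + 10.0 * math.log10(ms / 0.5)

    def copy(self) -> "TimeSignal":
        return TimeSignal(self.samples.copy(), self.sample_rate, self.full_scale_db_spl)


@dataclass
class EnvelopeSpec:
    """Declarative description of an increment/decrement envelope.

    ``shape`` is one of ``square``, ``raised_cosine_gated``,
    ``linear_updown`` or ``beat``.  ``increment_db`` is the maximum dB
    difference between target and pedestal (negative for decrements).
    ``onset_s`` places the start of the change; ``duration_s`` is the
    total span of the change (for ``linear_updown`` it equals twice the
    half-ramp; ``half_ramp_ms`` may be given instead).
    """

    shape: str
    increment_db: float = 0.0
    onset_s: float = 0.0
    duration_s: float = 0.0
    half_ramp_ms: float = 0.0
    gate_ms: float = 0.0
    beat_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.shape == "linear_updown" and self.half_ramp_ms > 0:
            self.duration_s = 2.0 * self.half_ramp_ms / 1000.0

    def span(self) -> tuple[float, float]:
        """(onset, offset) of the change in seconds."""
        return self.onset_s, self.onset_s + self.duration_s


@dataclass
class NoiseSpec:
    """Frozen-noise recipe.

    kinds: ``broadband_gaussian`` (flat 0 to ``band_high_hz``),
    ``miller_bandlimited`` (flat passband with 12 dB/octave skirts
    outside it) and ``spectrum_level_noise`` (flat band calibrated by dB
    spectrum level rather than overall level).
    """

    kind: str = "broadband_gaussian"
    band_low_hz: float = 0.0
    band_high_hz: float = 20000.0
    spectrum_level_db: Optional[float] = None
    rolloff_db_per_octave: float = 12.0
    seed: int = 0


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _check_level(level_db_spl: float, config: ModelConfig) -> None:
    if not (config.min_level_db_spl <= level_db_spl <= config.max_level_db_spl):
        raise CalibrationError(
            f"level {level_db_spl:.1f} dB SPL outside calibrated range "
            f"[{config.min_level_db_spl}, {config.max_level_db_spl}]"
        )


def _amplitude_for_rms(level_db_spl: float, config: ModelConfig) -> float:
    """rms amplitude corresponding to a dB SPL level under the full-scale convention."""
    return math.sqrt(0.5) * 10.0 ** ((level_db_spl - config.full_scale_db_spl) / 20.0)


def raised_cosine_gates(n: int, gate_ms: float, sample_rate: float) -> np.ndarray:
    """Multiplicative gating window: raised-cosine on/off ramps, unity in between."""
    w = np.ones(n)
    ng = int(round(gate_ms / 1000.0 * sample_rate))
    if ng > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ng) / ng))
        w[:ng] = ramp
        w[n - ng:] = ramp[::-1]
    return w


# --------------------------------------------------------------------------
# synthesis operations
# --------------------------------------------------------------------------

def make_tone(freq: float, level_db_spl: float, duration: float, gate_ms: float = 0.0,
              config: ModelConfig = DEFAULT_CONFIG, phase: float = 0.0) -> TimeSignal:
    """Raised-cosine gated sinusoidal pedestal at a stated rms level.

    The rms calibration refers to the ungated (steady) portion of the
    tone; gating is applied afterwards.
    """
    _check_level(level_db_spl, config)
    fs = config.sample_rate
    if freq >= fs / 2:
        raise ValueError(f"tone frequency {freq} Hz at or above Nyquist ({fs / 2} Hz)")
    if gate_ms > 0 and duration <= 2.0 * gate_ms / 1000.0:
        raise ValueError("duration must exceed twice the gate duration")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    amp = _amplitude_for_rms(level_db_spl, config) * math.sqrt(2.0)
    x = amp * np.sin(2.0 * np.pi * freq * t + phase)
    x *= raised_cosine_gates(n, gate_ms, fs)
    return TimeSignal(x, fs, config.full_scale_db_spl)


def _noise_carrier(spec: NoiseSpec, n: int, fs: float) -> np.ndarray:
    """Unit-variance frozen Gaussian noise shaped per the spec (uncalibrated)."""
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    X = np.fft.rfft(x)
    gain = np.ones_like(freqs)
    lo, hi = spec.band_low_hz, spec.band_high_hz
    if spec.kind == "miller_bandlimited":
        # flat passband, skirts falling at rolloff_db_per_octave outside it
        slope = spec.rolloff_db_per_octave
        with np.errstate(divide="ignore"):
            below = freqs < lo
            above = freqs > hi
            gain[below] = 10.0 ** (-slope * np.log2(np.maximum(lo / np.maximum(freqs[below], 1e-6), 1.0)) / 20.0)
            gain[above] = 10.0 ** (-slope * np.log2(freqs[above] / hi) / 20.0)
        gain[freqs == 0.0] = 0.0
    else:
        gain[(freqs < lo) | (freqs > hi)] = 0.0
        gain[freqs == 0.0] = 0.0
    X *= gain
    x = np.fft.irfft(X, n)
    x /= math.sqrt(float(np.mean(x ** 2)))
    return x


def make_noise(spec: NoiseSpec, level_db_spl: Optional[float], duration: float,
               gate_ms: float = 0.0, config: ModelConfig = DEFAULT_CONFIG) -> TimeSignal:
    """Frozen Gaussian noise pedestal, calibrated to an overall level.

    For ``spectrum_level_noise`` the overall level is derived from the
    spectrum level and the bandwidth (overall = spectrum level +
    10 log10(bandwidth)); ``level_db_spl`` must then be None.
    """
    fs = config.sample_rate
    if spec.band_high_hz > fs / 2 + 1e-9:
        raise ValueError("noise band edge above Nyquist")
    if spec.kind == "spectrum_level_noise":
        if spec.spectrum_level_db is None:
            raise ValueError("spectrum_level_noise requires spectrum_level_db")
        bw = spec.band_high_hz - spec.band_low_hz
        if bw <= 0:
            raise ValueError("spectrum-level calibration requested with zero bandwidth")
        level_db_spl = spec.spectrum_level_db + 10.0 * math.log10(bw)
    if level_db_spl is None:
        raise ValueError("overall level required")
    _check_level(level_db_spl, config)
    n = int(round(duration * fs))
    x = _noise_carrier(spec, n, fs)
    x *= _amplitude_for_rms(level_db_spl, config)
    x *= raised_cosine_gates(n, gate_ms, fs)
    return TimeSignal(x, fs, config.full_scale_db_spl)


def envelope_gain(env: EnvelopeSpec, n: int, fs: float) -> np.ndarray:
    """Multiplicative envelope gain g(t) >= 0 with max |20 log10 g| = |increment_db|."""
    g = np.ones(n)
    d = env.increment_db
    if d == 0.0:
        return g
    peak = 10.0 ** (d / 20.0)
    i0 = int(round(env.onset_s * fs))
    i1 = int(round((env.onset_s + env.duration_s) * fs))
    i0, i1 = max(i0, 0), min(i1, n)
    if i1 <= i0:
        raise ValueError("increment has zero length inside the pedestal")
    m = i1 - i0
    if env.shape == "square":
        g[i0:i1] = peak
    elif env.shape == "linear_updown":
        # linear amplitude ramp up immediately followed by an equal linear ramp down
        half = m // 2
        up = np.linspace(1.0, peak, half, endpoint=False)
        down = np.linspace(peak, 1.0, m - half)
        g[i0:i1] = np.concatenate([up, down])
    elif env.shape == "raised_cosine_gated":
        ng = int(round(env.gate_ms / 1000.0 * fs))
        ng = min(ng, m // 2)
        seg = np.full(m, peak)
        if ng > 0:
            ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ng) / ng))
            seg[:ng] = 1.0 + (peak - 1.0) * ramp
            seg[m - ng:] = 1.0 + (peak - 1.0) * ramp[::-1]
        g[i0:i1] = seg
    else:
        raise ValueError(f"unknown envelope shape {env.shape!r}")
    return g


def apply_increment(pedestal: TimeSignal, env: EnvelopeSpec) -> TimeSignal:
    """Impose an increment/decrement envelope multiplicatively on a pedestal.

    The change must fit inside the pedestal; the carrier samples are
    shared with the pedestal wherever the envelope gain is one, so a
    frozen-noise pedestal and its target differ only during the change.
    ``increment_db == 0`` returns the pedestal bit-identically.
    """
    n = len(pedestal.samples)
    fs = pedestal.sample_rate
    if env.onset_s + env.duration_s > pedestal.duration + 1e-9:
        raise ValueError(
            f"increment of {env.duration_s:.3f} s does not fit inside "
            f"pedestal of {pedestal.duration:.3f} s"
        )
    if env.increment_db == 0.0:
        return pedestal.copy()
    g = envelope_gain(env, n, fs)
    return TimeSignal(pedestal.samples * g, fs, pedestal.full_scale_db_spl)


def make_beats(freq: float, beat_hz: float, secondary_ratio: float, level_db_spl: float,
               duration: float, gate_ms: float = 0.0,
               config: ModelConfig = DEFAULT_CONFIG) -> TimeSignal:
    """Two-tone beat stimulus: primary at ``freq`` plus a secondary at
    ``freq + beat_hz`` with amplitude ``secondary_ratio`` times the primary.

    The primary alone is calibrated to ``level_db_spl``; the envelope
    then swings between ``1 - r`` and ``1 + r`` times the primary
    amplitude (full modulation at r = 1).
    """
    if beat_hz >= freq / 10.0:
        raise ValueError("beat rate must be far below the carrier frequency")
    if not (0.0 <= secondary_ratio <= 1.0):
        raise ValueError("secondary_ratio must lie in [0, 1]")
    _check_level(level_db_spl, config)
    fs = config.sample_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    amp = _amplitude_for_rms(level_db_spl, config) * math.sqrt(2.0)
    x = amp * (np.sin(2.0 * np.pi * freq * t)
               + secondary_ratio * np.sin(2.0 * np.pi * (freq + beat_hz) * t))
    x *= raised_cosine_gates(n, gate_ms, fs)
    return TimeSignal(x, fs, config.full_scale_db_spl)


def beat_increment_db(secondary_ratio: float) -> float:
    """Maximum dB difference between the beat stimulus and the unmodulated pedestal."""
    return 20.0 * math.log10(1.0 + secondary_ratio)


def beat_ratio_for_increment_db(increment_db: float) -> float:
    """Inverse of :func:`beat_increment_db`."""
    return 10.0 ** (increment_db / 20.0) - 1.0


# --------------------------------------------------------------------------
# WAV + config I/O
# --------------------------------------------------------------------------

def write_wav(signal: TimeSignal, path: str | Path, subtype: str = "float32") -> None:
    """Export a stimulus as mono PCM WAV plus a key-value calibration sidecar.

    ``subtype`` is ``int16`` or ``float32`` (24-bit PCM is not supported
    by the writer and is rejected).
    """
    path = Path(path)
    x = np.asarray(signal.samples)
    if subtype == "int16":
        data = np.clip(np.round(x * 32767.0), -32768, 32767).astype(np.int16)
    elif subtype == "float32":
        data = x.astype(np.float32)
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")
    wavfile.write(path, int(round(signal.sample_rate)), data)
    sidecar = path.with_suffix(path.suffix + ".cal")
    sidecar.write_text(
        f"full_scale_db_spl = {signal.full_scale_db_spl}\n"
        f"sample_rate = {signal.sample_rate}\n"
        f"subtype = {subtype}\n"
    )


def read_wav(path: str | Path) -> TimeSignal:
    """Read a stimulus written by :func:`write_wav` (uses the calibration sidecar)."""
    path = Path(path)
    fs, data = wavfile.read(path)
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32767.0
    else:
        x = data.astype(np.float64)
    full_scale = 100.0
    sidecar = path.with_suffix(path.suffix + ".cal")
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            key, _, val = line.partition("=")
            if key.strip() == "full_scale_db_spl":
                full_scale = float(val)
    return TimeSignal(x, float(fs), full_scale)


def envelope_from_dict(d: dict) -> EnvelopeSpec:
    return EnvelopeSpec(**d)


def noise_from_dict(d: dict) -> NoiseSpec:
    return NoiseSpec(**d)
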