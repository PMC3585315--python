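"""Time-varying excitation-pattern loudness (instantaneous -> STL -> LTL).

The front end follows the classic excitation-pattern family of loudness
models: a tabulated middle-ear transfer function, a multi-resolution
spectral analysis on a 1-ms hop, rounded-exponential auditory filters
with a level-dependent lower slope laid out on the ERB-number (Cam)
scale, a compressive specific-loudness transform, and integration across
cochlear place.  The instantaneous loudness so obtained is smoothed by
two cascaded asymmetric exponential integrators: short-term loudness
(attack 25 ms / release 50 ms, accounting for greater forward than
backward masking) and long-term loudness (attack 100 ms; release 100 ms
by default, making the long-term window symmetric; the original 2-s
release is available through the config).

The analysis runs internally at 32 kHz so the 1-ms hop is an integer
number of samples; spectral content above 16 kHz is discarded, which is
inconsequential for loudness because the middle-ear transfer already
attenuates that region by tens of dB.

Specific loudness uses N' = C[(G*E + A)^alpha - A^alpha], which is zero
in silence and compressive above threshold.  The model's absolute
threshold is the level at which total long-term loudness reaches the
0.003-sone criterion.  A single diotic calibration gain fixes the
absolute sone scale so that a steady 1-kHz tone at 25 dB SPL sits at
0.215 sones.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Callable, Optional

import numpy as np
from scipy.signal import resample_poly

from .config import ModelConfig, DEFAULT_CONFIG
from .stimuli import TimeSignal

INTERNAL_FS = 32000.0
HOP_SAMPLES = 32  # 1 ms at the internal rate

# ERB-number (Cam) place axis
CAM_LO, CAM_HI, CAM_STEP = 1.8, 39.0, 0.5
PLACES_CAM = np.arange(CAM_LO, CAM_HI + 1e-9, CAM_STEP)

C_SL = 0.047          # specific-loudness scale (sones per Cam)
A_SL = 4.62505        # specific-loudness additive constant
ALPHA_SL = 0.2        # compressive exponent
E_HIGH = 1.0e10       # excitation above which the square-root regime applies


def erb_hz(f: np.ndarray | float) -> np.ndarray | float:
    """Equivalent rectangular bandwidth of the auditory filter at centre f (Hz)."""
    return 24.673 * (0.004368 * np.asarray(f, dtype=float) + 1.0)


def cam(f: np.ndarray | float) -> np.ndarray | float:
    """ERB-number scale (Cam) as a function of frequency in Hz."""
    return 21.366 * np.log10(0.004368 * np.asarray(f, dtype=float) + 1.0)


def cam_to_hz(c: np.ndarray | float) -> np.ndarray | float:
    return (10.0 ** (np.asarray(c, dtype=float) / 21.366) - 1.0) / 0.004368


PLACES_HZ = np.asarray(cam_to_hz(PLACES_CAM))

# Tabulated middle-ear transfer function (dB re 1 kHz region), interpolated
# on a log-frequency axis.
_ME_FREQ = np.array([
    20., 25., 31.5, 40., 50., 63., 80., 100., 125., 160., 200., 250., 315.,
    400., 500., 630., 750., 800., 1000., 1250., 1500., 1600., 2000., 2500.,
    3000., 3150., 4000., 5000., 6000., 6300., 8000., 9000., 10000., 11200.,
    12500., 14000., 15000., 16000., 18000., 20000.])
_ME_DB = np.array([
    -39.6, -32.0, -25.85, -21.4, -18.5, -15.9, -14.1, -12.4, -11.0, -9.6,
    -8.3, -7.4, -6.2, -4.8, -3.8, -3.3, -2.9, -2.6, -2.6, -4.5, -5.4, -6.1,
    -8.5, -10.4, -7.3, -7.0, -6.6, -7.0, -9.2, -10.2, -12.2, -10.8, -10.1,
    -12.7, -15.0, -18.2, -23.8, -32.3, -45.5, -50.0])

# Excitation level at absolute threshold (dB) as a function of filter centre
# frequency; constant at 2.31 dB from 500 Hz upward, rising below.
_ETHRQ_FREQ = np.array([50., 63., 80., 100., 125., 160., 200., 250., 315., 400., 500.])
_ETHRQ_DB = np.array([28.18, 23.9, 19.2, 15.68, 12.67, 10.09, 8.08, 6.3, 5.05, 3.63, 2.31])


def middle_ear_db(f: np.ndarray) -> np.ndarray:
    logf = np.log10(np.maximum(np.asarray(f, dtype=float), 1.0))
    return np.interp(logf, np.log10(_ME_FREQ), _ME_DB)


def excitation_threshold_db(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    out = np.interp(np.log10(np.maximum(f, 1.0)),
                    np.log10(_ETHRQ_FREQ), _ETHRQ_DB)
    out = np.where(f >= 500.0, 2.31, out)
    out = np.where(f <= 50.0, _ETHRQ_DB[0], out)
    return out


# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------

@dataclass
class LoudnessTrace:
    """Loudness in sones on a fixed 1-ms grid."""

    values: np.ndarray
    kind: str  # 'instantaneous' | 'STL' | 'LTL'
    step_ms: float = 1.0

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.step_ms

    def plateau(self, t0_s: float, t1_s: float) -> float:
        """Mean loudness over a settled span (seconds)."""
        i0 = int(round(t0_s * 1000.0 / self.step_ms))
        i1 = int(round(t1_s * 1000.0 / self.step_ms))
        if i1 <= i0:
            raise ValueError("empty plateau window")
        return float(np.mean(self.values[i0:i1]))

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.times_ms, self.values])
        np.savetxt(path, arr, delimiter=",", header="time_ms,sones", comments="")


@dataclass
class TemporalWindow:
    """Asymmetric exponential smoothing window (attack / release, in ms)."""

    attack_ms: float
    release_ms: float

    def __post_init__(self) -> None:
        if self.attack_ms <= 0 or self.release_ms <= 0:
            raise ValueError("time constants must be positive")


# --------------------------------------------------------------------------
# spectral analysis
# --------------------------------------------------------------------------

# (window length in samples at 32 kHz, band low Hz, band high Hz)
_ANALYSIS_BANDS = [
    (2048, 20.0, 80.0),
    (1024, 80.0, 500.0),
    (512, 500.0, 1250.0),
    (256, 1250.0, 2540.0),
    (128, 2540.0, 4050.0),
    (64, 4050.0, 15500.0),
]


def _to_internal_rate(signal: TimeSignal) -> np.ndarray:
    if abs(signal.sample_rate - INTERNAL_FS) < 1e-6:
        return np.asarray(signal.samples, dtype=float)
    frac = Fraction(int(round(INTERNAL_FS)), int(round(signal.sample_rate))).limit_denominator(2000)
    return resample_poly(np.asarray(signal.samples, dtype=float), frac.numerator, frac.denominator)


def _component_spectra(x: np.ndarray, hop: int) -> tuple[np.ndarray, np.ndarray]:
    """Multi-resolution power spectra on a common frame grid.

    Returns (component frequencies [K], power per frame [F, K]) where the
    power is in mean-square signal units (sums to the local mean square).
    """
    n_frames = max(len(x) // hop, 1)
    comps = []
    freqs = []
    for nwin, flo, fhi in _ANALYSIS_BANDS:
        w = np.hanning(nwin)
        wnorm = 2.0 / (nwin * np.sum(w ** 2))
        pad = nwin // 2
        xp = np.pad(x, (pad, pad + nwin))
        idx = np.arange(n_frames)[:, None] * hop + np.arange(nwin)[None, :]
        frames = xp[idx] * w
        X = np.fft.rfft(frames, axis=1)
        p = (X.real ** 2 + X.imag ** 2) * wnorm
        p[:, 0] *= 0.5
        bf = np.fft.rfftfreq(nwin, 1.0 / INTERNAL_FS)
        sel = (bf >= flo) & (bf < fhi)
        comps.append(p[:, sel])
        freqs.append(bf[sel])
    return np.concatenate(freqs), np.concatenate(comps, axis=1)


def _excitation_from_components(freqs: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    """Excitation pattern (linear units, dB == dB SPL scale) per frame.

    ``intensity`` is per-component intensity on the SPL-linear scale,
    already after middle-ear filtering.  Rounded-exponential filter
    weights with fixed upper slope p51 and a level-dependent lower slope.
    """
    fc = PLACES_HZ
    p51 = 4.0 * fc / np.asarray(erb_hz(fc))
    p51_1k = 4.0 * 1000.0 / float(erb_hz(1000.0))
    g = (freqs[None, :] - fc[:, None]) / fc[:, None]
    g_abs = np.abs(g)
    lower = freqs[None, :] < fc[:, None]

    F = intensity.shape[0]
    J, K = len(fc), len(freqs)
    E = np.empty((F, J))
    chunk = max(1, int(4e6 // (J * K)))
    for s in range(0, F, chunk):
        e = min(s + chunk, F)
        I = intensity[s:e]
        X = 10.0 * np.log10(I + 1e-12)
        p_l = p51[None, :, None] * (1.0 - 0.35 / p51_1k * (X[:, None, :] - 51.0))
        np.clip(p_l, 0.1 * p51[None, :, None], 2.0 * p51[None, :, None], out=p_l)
        p = np.where(lower[None, :, :], p_l, p51[None, :, None])
        arg = p * g_abs[None, :, :]
        W = (1.0 + arg) * np.exp(-arg)
        E[s:e] = np.einsum("fjk,fk->fj", W, I)
    return E


def specific_loudness(E: np.ndarray) -> np.ndarray:
    """Compressive transform from excitation to specific loudness (sones/Cam)."""
    g_coch = 10.0 ** ((2.31 - excitation_threshold_db(PLACES_HZ)) / 10.0)
    ge = g_coch * E
    n = C_SL * ((ge + A_SL) ** ALPHA_SL - A_SL ** ALPHA_SL)
    high = E > E_HIGH
    if np.any(high):
        n = np.where(high, C_SL * (E / 1.04e6) ** 0.5, n)
    return n


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _spl_scale(signal: TimeSignal) -> float:
    """Factor mapping mean-square signal units to SPL-linear intensity."""
    return 10.0 ** (signal.full_scale_db_spl / 10.0) / 0.5


def excitation_pattern(signal: TimeSignal, frame: int, hop_ms: float = 1.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Excitation vs ERB-place for one analysis frame.

    Returns ``(places_cam, excitation_db)``.  Mostly a diagnostic /
    plotting aid; the batch pipeline is :func:`instantaneous_loudness`.
    """
    E = _excitation_frames(signal, hop_ms)
    if not 0 <= frame < E.shape[0]:
        raise IndexError(f"frame {frame} outside trace of {E.shape[0]} frames")
    return PLACES_CAM.copy(), 10.0 * np.log10(E[frame] + 1e-12)


def _excitation_frames(signal: TimeSignal, hop_ms: float = 1.0) -> np.ndarray:
    x = _to_internal_rate(signal)
    hop = int(round(HOP_SAMPLES * hop_ms))
    freqs, power = _component_spectra(x, hop)
    intensity = power * _spl_scale(signal) * 10.0 ** (middle_ear_db(freqs)[None, :] / 10.0)
    return _excitation_from_components(freqs, intensity)


def instantaneous_loudness(signal: TimeSignal, config: ModelConfig = DEFAULT_CONFIG,
                           hop_ms: float = 1.0) -> LoudnessTrace:
    """Instantaneous loudness in sones on the analysis grid."""
    E = _excitation_frames(signal, hop_ms)
    n_spec = specific_loudness(E)
    total = 2.0 * config.diotic_calibration * CAM_STEP * n_spec.sum(axis=1)
    return LoudnessTrace(total, "instantaneous", step_ms=hop_ms)


def temporal_integrate(trace: LoudnessTrace, window: TemporalWindow,
                       kind: Optional[str] = None) -> LoudnessTrace:
    """Asymmetric exponential smoothing (attack on rising input, release on falling)."""
    dt = trace.step_ms
    a_att = 1.0 - math.exp(-dt / window.attack_ms)
    a_rel = 1.0 - math.exp(-dt / window.release_ms)
    x = trace.values
    y = np.empty_like(x)
    state = x[0]
    for i in range(len(x)):
        a = a_att if x[i] > state else a_rel
        state = state + a * (x[i] - state)
        y[i] = state
    return LoudnessTrace(y, kind or trace.kind, step_ms=dt)


@dataclass
class LoudnessCascade:
    """All three stages of the loudness pipeline for one stimulus."""

    instantaneous: LoudnessTrace
    stl: LoudnessTrace
    ltl: LoudnessTrace


def loudness_cascade(signal: TimeSignal, config: ModelConfig = DEFAULT_CONFIG,
                     hop_ms: float = 1.0) -> LoudnessCascade:
    inst = instantaneous_loudness(signal, config, hop_ms)
    stl = temporal_integrate(inst, TemporalWindow(config.stl_attack_ms, config.stl_release_ms), "STL")
    ltl = temporal_integrate(stl, TemporalWindow(config.ltl_attack_ms, config.ltl_release_ms), "LTL")
    if hop_ms != 1.0:
        t = np.arange(0.0, len(inst.values) * hop_ms, 1.0)
        inst = LoudnessTrace(np.interp(t, inst.times_ms, inst.values), "instantaneous")
        stl = LoudnessTrace(np.interp(t, stl.times_ms, stl.values), "STL")
        ltl = LoudnessTrace(np.interp(t, ltl.times_ms, ltl.values), "LTL")
    return LoudnessCascade(inst, stl, ltl)


def loudness(signal: TimeSignal, config: ModelConfig = DEFAULT_CONFIG,
             hop_ms: float = 1.0) -> LoudnessTrace:
    """Long-term loudness trace (full cascade) on the 1-ms grid."""
    return loudness_cascade(signal, config, hop_ms).ltl


# --------------------------------------------------------------------------
# trace cache (the peripheral stage is central-parameter independent,
# so optimizers re-using the same stimuli hit this cache)
# --------------------------------------------------------------------------

_CACHE: dict[tuple, LoudnessCascade] = {}
_CACHE_MAX = 512


def _signal_key(signal: TimeSignal, hop_ms: float) -> tuple:
    h = hashlib.sha1(np.ascontiguousarray(signal.samples).tobytes()).hexdigest()
    return (h, signal.sample_rate, signal.full_scale_db_spl, hop_ms)


def cached_loudness_cascade(signal: TimeSignal, config: ModelConfig = DEFAULT_CONFIG,
                            hop_ms: float = 1.0) -> LoudnessCascade:
    key = _signal_key(signal, hop_ms) + (config.diotic_calibration,
                                         config.stl_attack_ms, config.stl_release_ms,
                                         config.ltl_attack_ms, config.ltl_release_ms)
    if key not in _CACHE:
        if len(_CACHE) >= _CACHE_MAX:
            _CACHE.pop(next(iter(_CACHE)))
        _CACHE[key] = loudness_cascade(signal, config, hop_ms)
    return _CACHE[key]


def clear_cache() -> None:
    _CACHE.clear()


# --------------------------------------------------------------------------
# threshold helpers
# --------------------------------------------------------------------------

def plateau_loudness(signal: TimeSignal, config: ModelConfig = DEFAULT_CONFIG,
                     settle_s: float = 0.5) -> float:
    """LTL plateau of a steady stimulus (mean over the settled region)."""
    tr = loudness(signal, config)
    t1 = signal.duration - 0.1
    return tr.plateau(min(settle_s, t1 / 2), t1)


def level_at_loudness(synth: Callable[[float], TimeSignal], target_sones: float,
                      lo_db: float = -20.0, hi_db: float = 40.0,
                      tol_db: float = 0.05, config: ModelConfig = DEFAULT_CONFIG) -> float:
    """Bisect the level (dB SPL) at which the LTL plateau reaches ``target_sones``.

    ``synth`` maps a level in dB SPL to a steady stimulus.  Loudness is
    monotone in level for steady stimuli, which bisection relies on.
    """
    f_lo = plateau_loudness(synth(lo_db), config) - target_sones
    f_hi = plateau_loudness(synth(hi_db), config) - target_sones
    if f_lo > 0 or f_hi < 0:
        raise ValueError("target loudness not bracketed by the level range")
    while hi_db - lo_db > tol_db:
        mid = 0.5 * (lo_db + hi_db)
        if plateau_loudness(synth(mid), config) - target_sones > 0:
            hi_db = mid
        else:
            lo_db = mid
    return 0.5 * (lo_db + hi_db)
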