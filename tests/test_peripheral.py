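"""Peripheral loudness: excitation patterns, cascade, anchors, monotonicity."""

import numpy as np
import pytest

from centraljnd import peripheral_loudness as pl
from centraljnd.peripheral_loudness import (LoudnessTrace, TemporalWindow,
                                            temporal_integrate, loudness,
                                            loudness_cascade, plateau_loudness,
                                            excitation_pattern)
from centraljnd.stimuli import make_tone, make_noise, NoiseSpec, TimeSignal
from centraljnd.config import ModelConfig

CFG = ModelConfig()


def test_silence_is_essentially_soundless():
    sig = TimeSignal(np.zeros(44100 // 2), 44100.0)
    tr = loudness(sig)
    assert np.max(tr.values) < 1e-4


def test_excitation_tonotopy():
    sig = make_tone(1000.0, 60.0, 0.5, 10.0)
    places, exc_db = excitation_pattern(sig, 250)
    peak_place_hz = pl.cam_to_hz(places[np.argmax(exc_db)])
    assert 850.0 < peak_place_hz < 1200.0


def test_excitation_monotone_in_level():
    """Raising the tone level by 10 dB never lowers excitation anywhere."""
    prev = None
    for level in [30.0, 40.0, 50.0, 60.0]:
        sig = make_tone(1000.0, level, 0.3, 10.0)
        _, exc_db = excitation_pattern(sig, 150)
        if prev is not None:
            assert np.all(exc_db >= prev - 1e-9)
        prev = exc_db


def test_loudness_anchor_at_25_db():
    """Steady 1-kHz tone at 25 dB SPL sits at the 0.215-sone anchor."""
    sig = make_tone(1000.0, 25.0, 2.0, 10.0)
    plateau = loudness(sig).plateau(1.0, 1.8)
    assert plateau == pytest.approx(0.215, rel=0.15)


def test_threshold_criterion_near_miss_of_audibility():
    """A 1-kHz tone at the model's threshold criterion lies at a plausible
    absolute threshold level (a few dB SPL)."""
    from centraljnd.experiments import model_tone_threshold_spl
    thr = model_tone_threshold_spl(1000.0)
    assert -2.0 < thr < 8.0


def test_level_monotonicity_of_plateau():
    levels = np.arange(0.0, 90.0, 5.0)
    tone_plateaus = [plateau_loudness(make_tone(1000.0, l, 1.0, 10.0)) for l in levels]
    assert np.all(np.diff(tone_plateaus) > 0)
    spec = NoiseSpec(kind="broadband_gaussian", band_high_hz=20000.0, seed=5)
    noise_plateaus = [plateau_loudness(make_noise(spec, l, 1.0, 10.0))
                      for l in levels[::3]]
    assert np.all(np.diff(noise_plateaus) > 0)


def test_noise_louder_than_tone_at_equal_spl():
    """Broadband noise is louder than a 1-kHz tone at the same moderate SPL
    (regression values recorded from the model)."""
    spec = NoiseSpec(kind="broadband_gaussian", band_high_hz=20000.0, seed=1)
    n = plateau_loudness(make_noise(spec, 40.0, 1.5, 10.0))
    t = plateau_loudness(make_tone(1000.0, 40.0, 1.5, 10.0))
    assert n > t
    assert n == pytest.approx(1.63, rel=0.1)
    assert t == pytest.approx(0.90, rel=0.1)


def test_plateau_independent_of_duration():
    a = plateau_loudness(make_tone(1000.0, 50.0, 2.0, 10.0))
    b = plateau_loudness(make_tone(1000.0, 50.0, 4.0, 10.0))
    assert a == pytest.approx(b, rel=1e-3)


# ---------------------------------------------------------------------------
# temporal integration
# ---------------------------------------------------------------------------

def test_constant_input_is_fixed_point():
    tr = LoudnessTrace(np.full(500, 0.7), "instantaneous")
    out = temporal_integrate(tr, TemporalWindow(25.0, 50.0))
    assert np.allclose(out.values, 0.7)


def test_step_response_time_constants():
    """Rise reaches 1-1/e of the step in ~attack_ms; decay ~release_ms."""
    x = np.zeros(2000)
    x[500:1500] = 1.0
    out = temporal_integrate(LoudnessTrace(x, "instantaneous"),
                             TemporalWindow(25.0, 50.0)).values
    rise = out[500:1500]
    t63 = np.argmax(rise >= 1.0 - np.exp(-1.0))
    assert t63 == pytest.approx(25, abs=2)
    decay = out[1500:]
    t37 = np.argmax(decay <= out[1499] * np.exp(-1.0))
    assert t37 == pytest.approx(50, abs=3)
    # asymmetry: decay is slower than rise (release 50 > attack 25)
    assert t37 > t63


def test_nonpositive_time_constant_rejected():
    with pytest.raises(ValueError):
        TemporalWindow(0.0, 50.0)
    with pytest.raises(ValueError):
        TemporalWindow(25.0, -1.0)


def _max_abs_diff(v):
    return np.max(np.abs(np.diff(v)))


def test_cascade_smoothing_inequality():
    """LTL <= STL <= instantaneous in maximum absolute first difference."""
    spec = NoiseSpec(kind="broadband_gaussian", band_high_hz=20000.0, seed=9)
    casc = loudness_cascade(make_noise(spec, 50.0, 1.0, 10.0))
    assert _max_abs_diff(casc.ltl.values) <= _max_abs_diff(casc.stl.values) <= \
        _max_abs_diff(casc.instantaneous.values)
    assert np.all(casc.ltl.values >= 0)


def test_decimated_hop_agrees_with_full_rate():
    """Traces computed on a coarser analysis hop and interpolated back to the
    1-ms grid agree with the full-rate path for slow envelopes."""
    sig = make_tone(1000.0, 50.0, 1.5, 10.0)
    full = loudness(sig, hop_ms=1.0)
    dec = loudness(sig, hop_ms=4.0)
    n = min(len(full.values), len(dec.values)) - 10
    assert np.max(np.abs(full.values[200:n] - dec.values[200:n])) < 0.01 * np.max(full.values)
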