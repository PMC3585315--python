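"""Stimulus synthesis: calibration, gating, frozen noise, envelopes, beats."""

import math

import numpy as np
import pytest
from scipy.signal import welch, hilbert

from centraljnd import stimuli
from centraljnd.stimuli import (TimeSignal, EnvelopeSpec, NoiseSpec, make_tone,
                                make_noise, apply_increment, make_beats,
                                CalibrationError, raised_cosine_gates)
from centraljnd.config import ModelConfig

CFG = ModelConfig()


@pytest.mark.parametrize("level", [10.0, 25.0, 33.0, 55.0, 85.0])
def test_tone_calibration_round_trip(level):
    sig = make_tone(1000.0, level, 1.0, 10.0)
    assert sig.rms_db_spl(0.1, 0.9) == pytest.approx(level, abs=0.1)


def test_tone_duration_and_ungated_rms():
    sig = make_tone(1000.0, 40.0, 0.5, 0.0)
    assert len(sig.samples) == round(0.5 * CFG.sample_rate)
    # gate = 0: steady sinusoid, rms = amplitude / sqrt(2) exactly
    amp = np.max(np.abs(sig.samples))
    assert np.sqrt(np.mean(sig.samples ** 2)) == pytest.approx(amp / math.sqrt(2), rel=1e-3)


def test_oxenham_style_pedestal_geometry():
    sig = make_tone(4000.0, 55.0, 0.5, 2.0)
    assert len(sig.samples) == round(0.5 * CFG.sample_rate)
    assert sig.rms_db_spl(0.05, 0.45) == pytest.approx(55.0, abs=0.1)


def test_level_floor_and_ceiling_rejected():
    with pytest.raises(CalibrationError):
        make_tone(1000.0, 125.0, 1.0, 10.0)
    with pytest.raises(CalibrationError):
        make_tone(1000.0, -40.0, 1.0, 10.0)


def test_gates_follow_raised_cosine_profile():
    n, gate_ms, fs = 44100, 10.0, 44100.0
    w = raised_cosine_gates(n, gate_ms, fs)
    ng = int(round(gate_ms / 1000.0 * fs))
    t = np.arange(ng)
    expected = 0.5 * (1.0 - np.cos(np.pi * t / ng))
    assert np.max(np.abs(w[:ng] - expected)) < 1e-6
    assert np.max(np.abs(w[n - ng:] - expected[::-1])) < 1e-6
    assert np.all(w[ng:n - ng] == 1.0)


def test_frozen_noise_identity():
    spec = NoiseSpec(kind="broadband_gaussian", band_high_hz=20000.0, seed=7)
    a = make_noise(spec, 33.0, 1.0, 10.0)
    b = make_noise(spec, 33.0, 1.0, 10.0)
    assert np.array_equal(a.samples, b.samples)
    c = make_noise(NoiseSpec(kind="broadband_gaussian", band_high_hz=20000.0, seed=8),
                   33.0, 1.0, 10.0)
    assert not np.array_equal(a.samples, c.samples)


def test_noise_calibration():
    spec = NoiseSpec(kind="broadband_gaussian", band_high_hz=20000.0, seed=3)
    sig = make_noise(spec, 33.0, 2.0, 10.0)
    assert sig.rms_db_spl(0.1, 1.9) == pytest.approx(33.0, abs=0.1)


def test_spectrum_level_to_overall_level():
    spec = NoiseSpec(kind="spectrum_level_noise", band_low_hz=0.0,
                     band_high_hz=20000.0, spectrum_level_db=20.0, seed=5)
    sig = make_noise(spec, None, 1.0, 10.0)
    expected = 20.0 + 10.0 * math.log10(20000.0)
    assert sig.rms_db_spl(0.05, 0.95) == pytest.approx(expected, abs=0.5)


def test_spectrum_level_zero_bandwidth_rejected():
    spec = NoiseSpec(kind="spectrum_level_noise", band_low_hz=100.0,
                     band_high_hz=100.0, spectrum_level_db=20.0, seed=5)
    with pytest.raises(ValueError, match="bandwidth"):
        make_noise(spec, None, 1.0, 10.0)


def test_bandlimited_noise_rolloff_slope():
    """Energy outside the passband falls at 12 dB/octave (within 2 dB/oct)."""
    spec = NoiseSpec(kind="miller_bandlimited", band_low_hz=150.0,
                     band_high_hz=7000.0, seed=11)
    sig = make_noise(spec, 60.0, 4.0, 10.0)
    f, p = welch(sig.samples, fs=CFG.sample_rate, nperseg=8192)
    def band_db(f0, f1):
        m = (f >= f0) & (f < f1)
        return 10.0 * math.log10(np.mean(p[m]))
    # one octave above the upper edge: 8-16 kHz region
    drop = band_db(7000, 8000) - band_db(14000, 16000)
    assert drop == pytest.approx(12.0, abs=2.0)
    drop_low = band_db(120, 160) - band_db(60, 80)
    assert drop_low == pytest.approx(12.0, abs=3.0)


def test_increment_zero_is_identity():
    spec = NoiseSpec(kind="broadband_gaussian", band_high_hz=20000.0, seed=2)
    ped = make_noise(spec, 33.0, 1.0, 10.0)
    env = EnvelopeSpec("linear_updown", increment_db=0.0, onset_s=0.4, half_ramp_ms=100.0)
    tgt = apply_increment(ped, env)
    assert np.array_equal(tgt.samples, ped.samples)


def test_square_increment_level_step():
    """Short-window rms before/during the increment differs by the stated dB."""
    ped = make_tone(1000.0, 40.0, 1.0, 10.0)
    env = EnvelopeSpec("square", increment_db=3.0, onset_s=0.5, duration_s=0.3)
    tgt = apply_increment(ped, env)
    before = tgt.rms_db_spl(0.3, 0.45)
    during = tgt.rms_db_spl(0.55, 0.75)
    assert during - before == pytest.approx(3.0, abs=0.01)


def test_frozen_carrier_shared_outside_increment():
    spec = NoiseSpec(kind="broadband_gaussian", band_high_hz=20000.0, seed=4)
    ped = make_noise(spec, 33.0, 1.0, 10.0)
    env = EnvelopeSpec("square", increment_db=2.0, onset_s=0.4, duration_s=0.2)
    tgt = apply_increment(ped, env)
    fs = ped.sample_rate
    i0, i1 = int(0.4 * fs), int(0.6 * fs)
    assert np.array_equal(tgt.samples[:i0], ped.samples[:i0])
    assert np.array_equal(tgt.samples[i1 + 1:], ped.samples[i1 + 1:])
    assert not np.array_equal(tgt.samples[i0:i1], ped.samples[i0:i1])


def test_linear_updown_envelope_peak_and_symmetry():
    d = 6.0
    ped = make_tone(1000.0, 40.0, 2.0, 10.0)
    env = EnvelopeSpec("linear_updown", increment_db=d, onset_s=0.8, half_ramp_ms=100.0)
    g = stimuli.envelope_gain(env, len(ped.samples), ped.sample_rate)
    assert np.max(g) == pytest.approx(10.0 ** (d / 20.0), rel=1e-6)
    fs = ped.sample_rate
    peak = np.argmax(g)
    assert peak == pytest.approx(round((0.8 + 0.1) * fs), abs=2)
    # symmetric: up-ramp mirrors down-ramp
    up = g[int(0.8 * fs):peak]
    down = g[peak:int(1.0 * fs)]
    assert abs(len(up) - len(down)) <= 1


def test_increment_longer_than_pedestal_rejected():
    ped = make_tone(1000.0, 40.0, 0.5, 10.0)
    env = EnvelopeSpec("square", increment_db=2.0, onset_s=0.1, duration_s=1.0)
    with pytest.raises(ValueError, match="0.5"):
        apply_increment(ped, env)


def test_beats_full_modulation_envelope():
    sig = make_beats(1000.0, 4.0, 1.0, 50.0, 2.0, 10.0)
    envlp = np.abs(hilbert(sig.samples))
    mid = envlp[int(0.2 * sig.sample_rate):int(1.8 * sig.sample_rate)]
    assert np.min(mid) < 0.02 * np.max(mid)


def test_beats_depth_matches_hilbert_envelope():
    r = 0.3
    sig = make_beats(1000.0, 4.0, r, 50.0, 2.0, 10.0)
    envlp = np.abs(hilbert(sig.samples))
    mid = envlp[int(0.2 * sig.sample_rate):int(1.8 * sig.sample_rate)]
    ratio = np.max(mid) / np.min(mid)
    assert ratio == pytest.approx((1 + r) / (1 - r), rel=0.02)


def test_beats_rate_validity_guard():
    with pytest.raises(ValueError):
        make_beats(1000.0, 200.0, 0.5, 50.0, 1.0)


def test_wav_round_trip(tmp_path):
    sig = make_tone(1000.0, 40.0, 0.2, 5.0)
    p = tmp_path / "tone.wav"
    stimuli.write_wav(sig, p, subtype="float32")
    back = stimuli.read_wav(p)
    assert back.sample_rate == sig.sample_rate
    assert back.full_scale_db_spl == sig.full_scale_db_spl
    assert np.allclose(back.samples, sig.samples, atol=1e-6)
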