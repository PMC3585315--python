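"""Central adaptation (conditional normalization) and the rate statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from centraljnd.central_model import (CentralParams, central_adapt, mean_loudness,
                                      max_rate, detection_statistic,
                                      adaptation_gain)
from centraljnd.peripheral_loudness import LoudnessTrace, cached_loudness_cascade
from centraljnd.jnd_solver import solve_jnd
from centraljnd.config import ModelConfig

from conftest import cheap_tone_condition

CFG = ModelConfig()


def _trace(values):
    return LoudnessTrace(np.asarray(values, dtype=float), "LTL")


def test_param_validation():
    with pytest.raises(ValueError):
        CentralParams(alpha=1.2)
    with pytest.raises(ValueError):
        CentralParams(T_CA=-0.1)
    with pytest.raises(ValueError):
        CentralParams(rate_jnd=0.0)


def test_defaults_are_the_optimized_constants():
    p = CentralParams()
    assert p.T_CA == 0.215
    assert p.alpha == 0.95
    assert p.rate_jnd == 5.5e-5


def test_mean_loudness_constant_and_empty_window():
    tr = _trace(np.full(1000, 0.4))
    assert mean_loudness(tr, (100, 900)) == pytest.approx(0.4)
    with pytest.raises(ValueError):
        mean_loudness(tr, (500, 500))


def test_identity_below_threshold():
    tr = _trace(0.1 + 0.01 * np.sin(np.linspace(0, 10, 500)))
    out = central_adapt(tr, CentralParams())
    assert np.array_equal(out.values, tr.values)
    assert out.gain == 1.0


def test_alpha_zero_is_identity_above_threshold():
    tr = _trace(np.full(500, 2.0))
    out = central_adapt(tr, CentralParams(alpha=0.0))
    assert np.array_equal(out.values, tr.values)


def test_alpha_one_pins_mean_at_threshold():
    """Full normalization: the mean central loudness equals T_CA."""
    tr = _trace(2.0 + 0.2 * np.sin(np.linspace(0, 20, 2000)))
    p = CentralParams(alpha=1.0)
    out = central_adapt(tr, p)
    assert np.mean(out.values) == pytest.approx(p.T_CA, rel=1e-3)


@given(lbar=st.floats(0.22, 20.0), alpha=st.floats(0.0, 1.0))
@settings(max_examples=50, deadline=None)
def test_gain_interpolates_between_limits(lbar, alpha):
    """The adapted mean moves a fraction alpha of the way to T_CA."""
    p = CentralParams(alpha=alpha)
    g = adaptation_gain(lbar, p)
    expected_mean = p.T_CA + (1 - alpha) * (lbar - p.T_CA)
    assert g * lbar == pytest.approx(expected_mean, rel=1e-9)
    assert 0.0 < g <= 1.0


def test_max_rate_constant_and_linear():
    assert max_rate(_trace(np.full(100, 1.0)), (0, 100)) == 0.0
    # rising at 2 sones/s = 0.002 sones/ms
    tr = _trace(np.linspace(0.0, 0.2, 101))
    assert max_rate(tr, (0, 101)) == pytest.approx(0.002, rel=1e-9)


def test_max_rate_matches_brute_force_scan():
    rng = np.random.default_rng(42)
    v = np.cumsum(rng.normal(0, 1e-3, 400))
    tr = _trace(v)
    w = (50, 350)
    brute = max(v[i + 1] - v[i] for i in range(50, 349))
    assert max_rate(tr, w) == pytest.approx(brute, rel=1e-12)
    brute_abs = max(abs(v[i + 1] - v[i]) for i in range(50, 349))
    assert max_rate(tr, w, mode="abs") == pytest.approx(brute_abs, rel=1e-12)


def test_max_rate_window_too_short():
    with pytest.raises(ValueError):
        max_rate(_trace(np.ones(100)), (10, 11))


def test_zero_increment_statistic_cancels_exactly():
    cond = cheap_tone_condition()
    ped = cond.pedestal_signal(CFG)
    casc = cached_loudness_cascade(ped, CFG)
    p = CentralParams()
    lbar = cond.mean_peripheral(casc.ltl, CFG)
    cen = central_adapt(casc.ltl, p, mean_peripheral=lbar)
    w = cond.analysis_window_ms(CFG)
    assert detection_statistic(cen, cen, w) == 0.0


def test_statistic_grid_mismatch_rejected():
    a = central_adapt(_trace(np.ones(100)), CentralParams())
    b = central_adapt(_trace(np.ones(90)), CentralParams())
    with pytest.raises(ValueError):
        detection_statistic(a, b, (0, 50))


def _statistic(cond, d, params):
    ped = cond.pedestal_signal(CFG)
    casc = cached_loudness_cascade(ped, CFG)
    lbar = cond.mean_peripheral(casc.ltl, CFG)
    ped_cen = central_adapt(casc.ltl, params, mean_peripheral=lbar)
    tgt = cond.target_signal(d, CFG)
    casc_t = cached_loudness_cascade(tgt, CFG)
    tgt_cen = central_adapt(casc_t.ltl, params, mean_peripheral=lbar)
    return detection_statistic(ped_cen, tgt_cen, cond.analysis_window_ms(CFG))


def test_statistic_monotone_in_increment_size():
    cond = cheap_tone_condition(level_db=40.0)
    p = CentralParams()
    vals = [_statistic(cond, d, p) for d in [0.5, 1.0, 1.5, 2.0, 2.5]]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_adaptation_degrades_sensitivity():
    """Above threshold, alpha > 0 never raises the detection statistic."""
    cond = cheap_tone_condition(level_db=60.0)  # well above T_CA
    s_adapt = _statistic(cond, 1.0, CentralParams(alpha=0.95))
    s_raw = _statistic(cond, 1.0, CentralParams(alpha=0.0))
    assert s_adapt <= s_raw
    assert s_adapt < 0.9 * s_raw  # strictly degraded at this level


def test_tonal_pedestal_statistic_is_target_rate():
    """For a steady tonal pedestal the pedestal max-rate is ~0, so the
    statistic reduces to the target's own max rate.  Uses a pedestal long
    enough that the onset transient has settled before the window."""
    cond = cheap_tone_condition(level_db=40.0, pedestal_s=1.5)
    ped = cond.pedestal_signal(CFG)
    casc = cached_loudness_cascade(ped, CFG)
    p = CentralParams()
    lbar = cond.mean_peripheral(casc.ltl, CFG)
    ped_cen = central_adapt(casc.ltl, p, mean_peripheral=lbar)
    w = cond.analysis_window_ms(CFG)
    ped_rate = max_rate(ped_cen, w)
    tgt = cond.target_signal(2.0, CFG)
    tgt_cen = central_adapt(cached_loudness_cascade(tgt, CFG).ltl, p,
                            mean_peripheral=lbar)
    stat = detection_statistic(ped_cen, tgt_cen, w)
    assert ped_rate < 0.05 * max_rate(tgt_cen, w)
    assert stat == pytest.approx(max_rate(tgt_cen, w), rel=0.05)
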