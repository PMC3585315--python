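"""Threshold solver: the increment size at which the rate criterion is met.

For a condition (pedestal + parametric change envelope), the solver
adjusts the change size (in dB, the maximum pedestal-to-target level
difference) until the central detection statistic equals the rate-JND
criterion, by bracketing bisection.  The solution is reported both as
the level difference and as the intensity JND (Weber fraction
dI/I = 10^(d/10) - 1 at the envelope maximum), together with the two
classical logarithmic conventions 10*log10(dI/I) and 10*log10(1+dI/I).

Also provided are the two domain transforms used to motivate the rate
criterion: the loudness-domain JND corresponding to an intensity JND
(difference of loudness at the two levels), and its time-domain
counterpart (maximum loudness rate produced by the just-detectable
stimulus change, through the full temporal-integration cascade).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .config import ModelConfig, DEFAULT_CONFIG
from .central_model import (CentralParams, central_adapt, detection_statistic,
                            adaptation_gain)
from .peripheral_loudness import cached_loudness_cascade


class UndetectableError(RuntimeError):
    """The criterion is not reached at the bracket ceiling."""

    def __init__(self, message: str, ceiling_statistic: float):
        super().__init__(message)
        self.ceiling_statistic = ceiling_statistic


class NonMonotoneBracketError(RuntimeError):
    """The detection statistic decreases over the bracket; carries a scan table."""

    def __init__(self, message: str, scan: list[tuple[float, float]]):
        super().__init__(message)
        self.scan = scan


def weber_fraction(increment_db: float) -> float:
    """Eq.-5 intensity JND: dI/I at the envelope maximum."""
    return 10.0 ** (increment_db / 10.0) - 1.0


def increment_db_from_weber(w: float) -> float:
    return 10.0 * math.log10(1.0 + w)


def weber_db(increment_db: float) -> float:
    """Classical 10*log10(dI/I) convention."""
    return 10.0 * math.log10(weber_fraction(increment_db))


@dataclass
class JNDResult:
    """Solver output for one condition grid point."""

    increment_db: float
    jnd_intensity: float            # Weber fraction dI/I (Eq. 5 quantity)
    residual: float                 # criterion slack at the solution, sones/ms
    bracket: tuple[float, float]
    converged: bool
    n_evals: int = 0
    mean_peripheral: float = float("nan")
    central_gain: float = 1.0

    @property
    def weber_db(self) -> float:
        return 10.0 * math.log10(self.jnd_intensity)

    @property
    def level_diff_db(self) -> float:
        """10*log10(1 + dI/I): identical to increment_db by construction."""
        return 10.0 * math.log10(1.0 + self.jnd_intensity)


def solve_jnd(condition, params: CentralParams,
              config: ModelConfig = DEFAULT_CONFIG,
              mode: str = "central",
              tol_rate: float = 1e-7, tol_db: float = 1e-3,
              max_evals: int = 60,
              verify_monotone: bool = False) -> JNDResult:
    """Find the change size satisfying the rate criterion at equality.

    ``condition`` is an :class:`~centraljnd.experiments.ExperimentCondition`.
    ``mode='peripheral'`` bypasses central adaptation (alpha forced to 0)
    to expose the unadapted model's prediction.  Monotonicity of the
    statistic over the bracket is checked at the endpoints (and over a
    0.5-dB scan when ``verify_monotone``); the search is bisection, so a
    non-monotone statistic raises rather than silently misconverging.
    """
    if mode == "peripheral":
        params = CentralParams(T_CA=params.T_CA, alpha=0.0, rate_jnd=params.rate_jnd)

    ped = condition.pedestal_signal(config)
    casc_ped = cached_loudness_cascade(ped, config, condition.hop_ms)
    lbar = condition.mean_peripheral(casc_ped.ltl, config)
    window = condition.analysis_window_ms(config)
    rate_mode = "abs" if condition.direction < 0 else "signed"
    ped_cen = central_adapt(casc_ped.ltl, params, mean_peripheral=lbar)

    n_evals = 0

    def statistic(d: float) -> float:
        nonlocal n_evals
        n_evals += 1
        tgt = condition.target_signal(d, config)
        casc_t = cached_loudness_cascade(tgt, config, condition.hop_ms)
        tgt_cen = central_adapt(casc_t.ltl, params, mean_peripheral=lbar)
        return detection_statistic(ped_cen, tgt_cen, window, rate_mode)

    lo, hi = condition.bracket_db
    s_lo = statistic(lo)
    s_hi = statistic(hi)
    if verify_monotone:
        grid = np.arange(lo, hi + 1e-9, 0.5)
        scan = [(float(d), statistic(float(d))) for d in grid]
        vals = [s for _, s in scan]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise NonMonotoneBracketError("statistic not monotone over bracket", scan)
    if s_hi < params.rate_jnd:
        raise UndetectableError(
            f"undetectable at bracket ceiling {hi:.2f} dB "
            f"(statistic {s_hi:.3g} < criterion {params.rate_jnd:.3g})", s_hi)
    if s_lo >= params.rate_jnd:
        # already detectable at the bracket floor: the threshold is below
        # the resolution of the search, report the floor
        return JNDResult(lo, weber_fraction(lo), s_lo - params.rate_jnd,
                         (lo, hi), True, n_evals, lbar,
                         adaptation_gain(lbar, params))

    a, b = lo, hi
    d_mid, s_mid = b, s_hi
    while n_evals < max_evals:
        d_mid = 0.5 * (a + b)
        s_mid = statistic(d_mid)
        if abs(s_mid - params.rate_jnd) <= tol_rate:
            break
        if s_mid < params.rate_jnd:
            a = d_mid
        else:
            b = d_mid
        if b - a <= tol_db:
            d_mid, s_mid = b, statistic(b)
            break
    return JNDResult(d_mid, weber_fraction(d_mid), s_mid - params.rate_jnd,
                     (lo, hi), True, n_evals, lbar, adaptation_gain(lbar, params))


# --------------------------------------------------------------------------
# domain transforms
# --------------------------------------------------------------------------

def loudness_jnd_transform(levels_db: Sequence[float], jnds_db: Sequence[float],
                           loudness_fn: Callable[[float], float]) -> np.ndarray:
    """Loudness-domain JND for each (level, intensity JND) pair.

    ``loudness_fn`` maps a level in dB SPL to steady loudness in sones
    and must be monotone over the grid.  ``jnds_db`` are level
    differences (10*log10(1+dI/I)); the result is
    dL_jnd = L(level + jnd) - L(level).
    """
    levels = np.asarray(levels_db, dtype=float)
    jnds = np.asarray(jnds_db, dtype=float)
    L = np.array([loudness_fn(l) for l in levels])
    if np.any(np.diff(L) <= 0):
        raise ValueError("loudness function not monotone over the level grid")
    L_up = np.array([loudness_fn(l + j) for l, j in zip(levels, jnds)])
    return L_up - L


def rate_jnd_transform(conditions, jnds_db: Sequence[float],
                       params: Optional[CentralParams] = None,
                       config: ModelConfig = DEFAULT_CONFIG,
                       mode: str = "peripheral") -> np.ndarray:
    """Rate-domain JND implied by empirical thresholds, per condition.

    For each condition and its empirically observed threshold (level
    difference in dB), synthesize pedestal and just-detectable target,
    run both through the loudness model and report the rate statistic
    the change produced: the (dL/dt) value that detection equates to the
    criterion.  Reproduces the time-domain unification of tone and noise
    JND data on a 1-ms grid.
    """
    params = params or CentralParams()
    out = []
    for cond, jnd_db in zip(conditions, jnds_db):
        ped = cond.pedestal_signal(config)
        casc_ped = cached_loudness_cascade(ped, config, cond.hop_ms)
        lbar = cond.mean_peripheral(casc_ped.ltl, config)
        p = params if mode == "central" else CentralParams(params.T_CA, 0.0, params.rate_jnd)
        ped_cen = central_adapt(casc_ped.ltl, p, mean_peripheral=lbar)
        tgt = cond.target_signal(jnd_db, config)
        casc_t = cached_loudness_cascade(tgt, config, cond.hop_ms)
        tgt_cen = central_adapt(casc_t.ltl, p, mean_peripheral=lbar)
        rate_mode = "abs" if cond.direction < 0 else "signed"
        out.append(detection_statistic(ped_cen, tgt_cen,
                                       cond.analysis_window_ms(config), rate_mode))
    return np.asarray(out)
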