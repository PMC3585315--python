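"""Central adaptation and the maximum rate-of-change detection statistic.

The central stage models long-term neural adaptation to the prevailing
(mean) loudness level.  When the mean peripheral loudness L-bar of a
continuous pedestal exceeds the central adaptation threshold T_CA, the
whole loudness trace is partially normalized toward the central dynamic
range:

    L_Cen(t) = L(t) * (T_CA + (1 - alpha) * (Lbar - T_CA)) / Lbar,  Lbar > T_CA
    L_Cen(t) = L(t)                                                 otherwise

so that the mean central loudness is pulled a fraction ``alpha`` of the
way from L-bar back to T_CA (alpha = 0: no adaptation, the peripheral
model; alpha = 1: the mean is pinned at T_CA).  Adaptation is static per
condition - no time constant is modeled, because the mean level of a
continuous pedestal is stationary.

Detection operates on the maximum rate of change of central loudness on
a 1-ms grid.  For a frozen carrier, the decision statistic contrasts the
pedestal-plus-change interval with the pedestal interval:

    (dL_Cen/dt)_inc,max - (dL_Cen/dt)_ped,max  >=  (dL/dt)_jnd

with the rate-JND constant (dL/dt)_jnd = 5.5e-5 sones/ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .peripheral_loudness import LoudnessTrace

RATE_JND_SONES_PER_MS = 5.5e-5


@dataclass
class CentralParams:
    """The three central constants.

    T_CA : central adaptation threshold in sones (default 0.215).
    alpha : normalization amount in [0, 1] (default 0.95).
    rate_jnd : rate-of-change JND criterion in sones/ms (default 5.5e-5).
    dt_ms : rate grid in ms (fixed at 1).
    """

    T_CA: float = 0.215
    alpha: float = 0.95
    rate_jnd: float = RATE_JND_SONES_PER_MS
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.T_CA <= 0:
            raise ValueError("T_CA must be positive")
        if self.rate_jnd <= 0:
            raise ValueError("rate_jnd must be positive")


@dataclass
class CentralTrace:
    """Central loudness on the 1-ms grid, plus the adaptation state it used."""

    values: np.ndarray
    mean_peripheral: float
    gain: float
    step_ms: float = 1.0

    def to_csv(self, path) -> None:
        arr = np.column_stack([np.arange(len(self.values)) * self.step_ms, self.values])
        np.savetxt(path, arr, delimiter=",", header="time_ms,sones", comments="")


def mean_loudness(trace: LoudnessTrace, window_ms: tuple[float, float]) -> float:
    """Arithmetic mean of a peripheral trace over an analysis window (ms).

    The window should exclude onset/offset gates; for noise pedestals the
    average over the full steady span smooths the inherent loudness
    fluctuations of the carrier.
    """
    i0 = int(round(window_ms[0] / trace.step_ms))
    i1 = int(round(window_ms[1] / trace.step_ms))
    if i1 <= i0:
        raise ValueError("empty mean-loudness window")
    return float(np.mean(trace.values[i0:i1]))


def adaptation_gain(mean_peripheral: float, params: CentralParams) -> float:
    """Multiplicative gain applied by central adaptation (1 below threshold)."""
    if mean_peripheral <= params.T_CA or params.alpha == 0.0:
        return 1.0
    target_mean = params.T_CA + (1.0 - params.alpha) * (mean_peripheral - params.T_CA)
    return target_mean / mean_peripheral


def central_adapt(trace: LoudnessTrace, params: CentralParams,
                  mean_peripheral: Optional[float] = None,
                  mean_window_ms: Optional[tuple[float, float]] = None) -> CentralTrace:
    """Apply the conditional partial normalization to a loudness trace.

    ``mean_peripheral`` is the adaptation state L-bar; per the continuous
    pedestal logic it should be computed once per condition from the
    increment-free pedestal and passed in when adapting target traces.
    If omitted it is computed from this trace over ``mean_window_ms``
    (full trace by default).
    """
    if mean_peripheral is None:
        w = mean_window_ms or (0.0, len(trace.values) * trace.step_ms)
        mean_peripheral = mean_loudness(trace, w)
    g = adaptation_gain(mean_peripheral, params)
    return CentralTrace(trace.values * g, mean_peripheral, g, trace.step_ms)


def max_rate(trace: CentralTrace | LoudnessTrace, window_ms: tuple[float, float],
             mode: str = "signed") -> float:
    """Maximum forward first difference per 1 ms over a window.

    ``mode='signed'`` takes the maximum positive-going rate (increment
    detection); ``mode='abs'`` the maximum magnitude (decrements)."""
    step = trace.step_ms
    i0 = int(round(window_ms[0] / step))
    i1 = int(round(window_ms[1] / step))
    i0 = max(i0, 0)
    i1 = min(i1, len(trace.values))
    if i1 - i0 < 2:
        raise ValueError("rate window shorter than 2 samples")
    d = np.diff(trace.values[i0:i1]) / step
    if mode == "abs":
        return float(np.max(np.abs(d)))
    return float(np.max(d))


def detection_statistic(pedestal: CentralTrace, target: CentralTrace,
                        window_ms: tuple[float, float], mode: str = "signed") -> float:
    """Difference of the maximum central loudness rates, target minus pedestal.

    Both traces must derive from the same frozen carrier on the same
    grid; the pedestal term is evaluated over the matched window on the
    increment-free trace, so a zero-size change cancels exactly.
    Detection is declared when the statistic reaches ``params.rate_jnd``.
    """
    if pedestal.step_ms != target.step_ms or len(pedestal.values) != len(target.values):
        raise ValueError("pedestal and target traces are on different grids")
    return max_rate(target, window_ms, mode) - max_rate(pedestal, window_ms, mode)
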