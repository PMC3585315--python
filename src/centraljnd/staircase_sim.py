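"""Adaptive 3-down 1-up 2IFC staircase with a model observer.

Replicates the adaptive procedure of the ramped-increment listening
experiment: two observation intervals per trial (pedestal, and pedestal
plus ramped increment, in random order), three consecutive correct
responses lowering the increment and one error raising it.  The starting
increment is 20 dB, the step 5 dB for the first 4 reversals and halved
thereafter; after 12 reversals the threshold is the arithmetic mean of
the last 10 reversal levels.  This rule converges on the 79.4 % correct
point of the psychometric function (0.5^(1/3) = 0.794).

The model observer maps each interval to its maximum central-loudness
rate of change.  With zero internal noise it responds correctly exactly
when the detection statistic reaches the rate-JND criterion; with
internal noise, independent zero-mean Gaussian noise is added to each
interval's statistic and the larger is chosen, giving a smooth
psychometric function whose 79.4 % point sits at the analytic criterion
when the noise standard deviation is the calibrated default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig, DEFAULT_CONFIG
from .central_model import CentralParams, central_adapt, max_rate
from .peripheral_loudness import cached_loudness_cascade
from .experiments import ExperimentCondition

#: z-score of the 79.4 % point of a cumulative normal
_Z_794 = float(stats.norm.ppf(0.5 ** (1.0 / 3.0)))


@dataclass
class StaircaseConfig:
    """Levitt track bookkeeping constants (defaults as administered)."""

    start_db: float = 20.0
    initial_step_db: float = 5.0
    step_halving_after_reversals: int = 4
    total_reversals: int = 12
    threshold_from_last: int = 10
    floor_db: float = 0.05
    ceiling_db: float = 30.0
    max_trials: int = 400


@dataclass
class ModelObserver:
    """Trial-level decision rule on the two interval statistics.

    ``noise_sd`` is the standard deviation (sones/ms) of the internal
    noise added to each interval's max-rate statistic; 0 gives the
    deterministic criterion observer.  ``calibrated_sd`` returns the sd
    at which the 79.4 % point of the resulting 2IFC psychometric
    function coincides with the analytic rate criterion.
    """

    noise_sd: float = 0.0

    @staticmethod
    def calibrated_sd(params: CentralParams) -> float:
        # P(correct) = Phi(delta / (sqrt(2) sd)); set P = 0.794 at delta = rate_jnd
        return params.rate_jnd / (_Z_794 * math.sqrt(2.0))

    def respond(self, ped_stat: float, tgt_stat: float, params: CentralParams,
                rng: Optional[np.random.Generator] = None) -> bool:
        """True if the target interval is identified correctly."""
        if self.noise_sd <= 0.0:
            return (tgt_stat - ped_stat) >= params.rate_jnd
        n1, n2 = rng.normal(0.0, self.noise_sd, size=2)
        return (tgt_stat + n1) > (ped_stat + n2)


class TrackError(RuntimeError):
    def __init__(self, message: str, log: pd.DataFrame):
        super().__init__(message)
        self.log = log


class _StatisticCache:
    """Max-rate statistics for a condition, memoized per increment level.

    The staircase revisits a small set of discrete levels; each level
    needs one loudness-model evaluation of the target interval.  The
    pedestal interval is evaluated once.
    """

    def __init__(self, condition: ExperimentCondition, params: CentralParams,
                 config: ModelConfig):
        self.condition = condition
        self.params = params
        self.config = config
        ped = condition.pedestal_signal(config)
        casc = cached_loudness_cascade(ped, config, condition.hop_ms)
        self.lbar = condition.mean_peripheral(casc.ltl, config)
        self.window = condition.analysis_window_ms(config)
        self.mode = "abs" if condition.direction < 0 else "signed"
        ped_cen = central_adapt(casc.ltl, params, mean_peripheral=self.lbar)
        self.ped_stat = max_rate(ped_cen, self.window, self.mode)
        self._tgt: dict[float, float] = {}

    def target_stat(self, increment_db: float) -> float:
        key = round(increment_db, 6)
        if key not in self._tgt:
            tgt = self.condition.target_signal(increment_db, self.config)
            casc = cached_loudness_cascade(tgt, self.config, self.condition.hop_ms)
            cen = central_adapt(casc.ltl, self.params, mean_peripheral=self.lbar)
            self._tgt[key] = max_rate(cen, self.window, self.mode)
        return self._tgt[key]


def run_track(condition: ExperimentCondition, observer: ModelObserver,
              config_sc: StaircaseConfig = StaircaseConfig(),
              seed: int = 0,
              params: Optional[CentralParams] = None,
              model_config: ModelConfig = DEFAULT_CONFIG,
              cache: Optional[_StatisticCache] = None
              ) -> tuple[float, pd.DataFrame]:
    """Run one adaptive track; returns (threshold_db, trial log).

    Separate named seed streams drive interval randomization and
    observer noise so each is independently reproducible.
    """
    params = params or CentralParams()
    cache = cache or _StatisticCache(condition, params, model_config)
    rng_interval = np.random.default_rng([seed, 101])
    rng_noise = np.random.default_rng([seed, 202])

    level = config_sc.start_db
    step = config_sc.initial_step_db
    n_correct = 0
    reversals: list[float] = []
    last_dir = 0  # +1 increasing, -1 decreasing
    rows = []
    for trial in range(1, config_sc.max_trials + 1):
        target_interval = int(rng_interval.integers(2)) + 1
        correct = observer.respond(cache.ped_stat, cache.target_stat(level),
                                   params, rng_noise)
        move = 0
        if correct:
            n_correct += 1
            if n_correct == 3:
                n_correct = 0
                move = -1
        else:
            n_correct = 0
            move = +1
        reversal = move != 0 and last_dir != 0 and move != last_dir
        rows.append({"trial": trial, "increment_db": level,
                     "interval": target_interval,
                     "response": target_interval if correct else 3 - target_interval,
                     "correct": correct, "reversal": reversal})
        if reversal:
            reversals.append(level)
            if len(reversals) == config_sc.step_halving_after_reversals:
                step /= 2.0
            if len(reversals) >= config_sc.total_reversals:
                break
        if move != 0:
            last_dir = move
            level = float(np.clip(level + move * step,
                                  config_sc.floor_db, config_sc.ceiling_db))
    log = pd.DataFrame(rows)
    if len(reversals) < config_sc.total_reversals:
        raise TrackError(
            f"track failed to reach {config_sc.total_reversals} reversals "
            f"within {config_sc.max_trials} trials", log)
    threshold = float(np.mean(reversals[-config_sc.threshold_from_last:]))
    return threshold, log


def simulate_group(conditions: list[ExperimentCondition], n_tracks: int,
                   observer: ModelObserver, seed: int = 0,
                   config_sc: StaircaseConfig = StaircaseConfig(),
                   params: Optional[CentralParams] = None,
                   model_config: ModelConfig = DEFAULT_CONFIG
                   ) -> pd.DataFrame:
    """Mean threshold and 95 % CI per condition over simulated tracks."""
    if n_tracks < 2:
        raise ValueError("need at least 2 tracks per condition")
    params = params or CentralParams()
    rows = []
    for i, cond in enumerate(conditions):
        cache = _StatisticCache(cond, params, model_config)
        thr = np.array([run_track(cond, observer, config_sc, seed=seed * 10000 + i * 100 + k,
                                  params=params, model_config=model_config, cache=cache)[0]
                        for k in range(n_tracks)])
        mean = float(np.mean(thr))
        sem = float(np.std(thr, ddof=1) / math.sqrt(n_tracks))
        ci = 1.96 * sem
        rows.append({"condition": cond.key(), "x": cond.x, "x_name": cond.x_name,
                     "mean_threshold_db": mean, "ci95_db": ci,
                     "n_tracks": n_tracks})
    return pd.DataFrame(rows)
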