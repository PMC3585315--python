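"""Optimization of the central parameters and goodness-of-fit statistics.

The two central constants (adaptation threshold T_CA and normalization
amount alpha) are fitted to empirical JND datasets by minimizing the
mean over datasets of the per-dataset rms error (in dB, on the
10*log10(dI/I) scale) between predicted and observed thresholds, with
the rate criterion held fixed at 5.5e-5 sones/ms.  A coarse grid search
brackets both slopes of each parameter's minimum; coordinate-wise
golden-section refinement then localizes it.

Because the peripheral stage does not depend on the central parameters,
the expensive loudness computations are done once per condition: the
peripheral detection statistic is sampled on a grid of change sizes and
the threshold for any (T_CA, alpha) is then obtained by inverting the
sampled curve at the criterion divided by the central adaptation gain
(the central stage scales the whole statistic by that gain, exactly).

Empirical datasets are user-supplied CSV tables with the schema
``study,x_value,x_units,jnd_value,jnd_units,notes``; no historical data
ship with the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig, DEFAULT_CONFIG
from .central_model import CentralParams, central_adapt, detection_statistic, adaptation_gain
from .peripheral_loudness import cached_loudness_cascade
from .experiments import ExperimentCondition, JNDCurve
from .jnd_solver import weber_db, increment_db_from_weber

GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class JNDDataset:
    """Observed JNDs for one study: rows of (x, observed increment_db)."""

    study: str
    x: np.ndarray
    jnd_increment_db: np.ndarray
    x_units: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.jnd_increment_db = np.asarray(self.jnd_increment_db, dtype=float)
        if len(self.x) != len(self.jnd_increment_db):
            raise ValueError("x and jnd lengths differ")


CSV_COLUMNS = ["study", "x_value", "x_units", "jnd_value", "jnd_units", "notes"]


def load_dataset_csv(path: str | Path) -> list[JNDDataset]:
    """Load datasets from the package CSV schema.

    ``jnd_units`` must be ``increment_db`` (10*log10(1+dI/I)) or
    ``weber_db`` (10*log10(dI/I)); mixed conventions within one study
    are rejected.
    """
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
    out = []
    for study, grp in df.groupby("study", sort=False):
        units = grp["jnd_units"].unique()
        if len(units) != 1:
            raise ValueError(f"mixed jnd units within study {study!r}")
        vals = grp["jnd_value"].to_numpy(dtype=float)
        if units[0] == "weber_db":
            vals = np.array([increment_db_from_weber(10.0 ** (v / 10.0)) for v in vals])
        elif units[0] != "increment_db":
            raise ValueError(f"unknown jnd units {units[0]!r}")
        out.append(JNDDataset(study=str(study), x=grp["x_value"].to_numpy(dtype=float),
                              jnd_increment_db=vals,
                              x_units=str(grp["x_units"].iloc[0])))
    return out


@dataclass
class FitResult:
    T_CA: float
    alpha: float
    error_db: float
    per_dataset_error_db: dict[str, float]
    surface: pd.DataFrame          # sampled error surface (T_CA, alpha, error_db)
    converged: bool = True
    message: str = ""


# --------------------------------------------------------------------------
# peripheral statistic curves
# --------------------------------------------------------------------------

@dataclass
class PeripheralCurve:
    """Sampled peripheral detection statistic vs change size for one condition."""

    condition: ExperimentCondition
    mean_peripheral: float
    d_grid: np.ndarray
    statistic: np.ndarray

    def threshold_db(self, params: CentralParams) -> float:
        """Invert the curve at the criterion for the given central params.

        The central stage multiplies the statistic by the adaptation
        gain, so the threshold solves S_peripheral(d) = rate_jnd / gain.
        Returns the sampled floor when the criterion is already met
        there, and nan when it is not reached at the sampled ceiling.
        """
        g = adaptation_gain(self.mean_peripheral, params)
        target = params.rate_jnd / g
        s = self.statistic
        if target > s[-1]:
            return float("nan")
        if target <= s[0]:
            return float(self.d_grid[0])
        return float(np.interp(target, s, self.d_grid))


def build_peripheral_curve(condition: ExperimentCondition,
                           config: ModelConfig = DEFAULT_CONFIG,
                           d_grid: Optional[np.ndarray] = None) -> PeripheralCurve:
    ped = condition.pedestal_signal(config)
    casc = cached_loudness_cascade(ped, config, condition.hop_ms)
    lbar = condition.mean_peripheral(casc.ltl, config)
    window = condition.analysis_window_ms(config)
    mode = "abs" if condition.direction < 0 else "signed"
    p0 = CentralParams(alpha=0.0)
    ped_cen = central_adapt(casc.ltl, p0, mean_peripheral=lbar)
    if d_grid is None:
        lo, hi = condition.bracket_db
        d_grid = np.geomspace(max(lo, 0.02), hi, 12)
    vals = []
    for d in d_grid:
        tgt = condition.target_signal(float(d), config)
        casc_t = cached_loudness_cascade(tgt, config, condition.hop_ms)
        tgt_cen = central_adapt(casc_t.ltl, p0, mean_peripheral=lbar)
        vals.append(detection_statistic(ped_cen, tgt_cen, window, mode))
    s = np.maximum.accumulate(np.asarray(vals))  # guard tiny non-monotone jitter
    return PeripheralCurve(condition, lbar, np.asarray(d_grid, dtype=float), s)


def predict_thresholds(curves: Sequence[PeripheralCurve],
                       params: CentralParams) -> np.ndarray:
    return np.array([c.threshold_db(params) for c in curves])


# --------------------------------------------------------------------------
# goodness of fit
# --------------------------------------------------------------------------

def goodness_of_fit(predicted: JNDCurve | pd.DataFrame,
                    observed: JNDDataset) -> tuple[float, float, float]:
    """Pearson r (two-tailed p) and rms error in dB on the 10log10(dI/I) scale.

    Grids must align by construction (matched x values); interpolation
    is deliberately not performed.
    """
    table = predicted.table if isinstance(predicted, JNDCurve) else predicted
    pred = table.set_index("x")["increment_db"]
    if len(observed.x) < 3:
        raise ValueError("need at least 3 matched points")
    try:
        pred_vals = pred.loc[observed.x].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"prediction grid does not cover observed x: {exc}") from exc
    p_db = np.array([weber_db(v) for v in pred_vals])
    o_db = np.array([weber_db(v) for v in observed.jnd_increment_db])
    r, p = stats.pearsonr(p_db, o_db)
    e = float(np.sqrt(np.mean((p_db - o_db) ** 2)))
    return float(r), float(p), e


def _rms_error_db(pred_inc_db: np.ndarray, obs_inc_db: np.ndarray) -> float:
    if np.any(~np.isfinite(pred_inc_db)):
        return float("inf")
    p = np.array([weber_db(v) for v in pred_inc_db])
    o = np.array([weber_db(v) for v in obs_inc_db])
    return float(np.sqrt(np.mean((p - o) ** 2)))


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------

def _mean_error(curve_sets: dict[str, list[PeripheralCurve]],
                datasets: list[JNDDataset], params: CentralParams,
                offsets: Optional[dict[str, float]] = None) -> tuple[float, dict[str, float]]:
    per = {}
    for ds in datasets:
        curves = curve_sets[ds.study]
        pred = predict_thresholds(curves, params)
        if offsets and ds.study in offsets:
            pred = pred + offsets[ds.study]
        per[ds.study] = _rms_error_db(pred, ds.jnd_increment_db)
    return float(np.mean(list(per.values()))), per


def _golden_section(f, lo, hi, tol, max_iter=40):
    a, b = lo, hi
    c = b - GOLDEN * (b - a)
    d = a + GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + GOLDEN * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def fit_central_params(datasets: list[JNDDataset],
                       conditions_by_study: dict[str, list[ExperimentCondition]],
                       rate_jnd: float = 5.5e-5,
                       t_grid: Optional[np.ndarray] = None,
                       a_grid: Optional[np.ndarray] = None,
                       config: ModelConfig = DEFAULT_CONFIG,
                       curves: Optional[dict[str, list[PeripheralCurve]]] = None,
                       refine_tol: tuple[float, float] = (0.002, 0.005),
                       n_sweeps: int = 3) -> FitResult:
    """Grid search + golden-section refinement of (T_CA, alpha).

    ``conditions_by_study`` maps each dataset's study id to the
    conditions whose x grid matches the dataset rows.  The rate
    criterion is held fixed.  Precomputed peripheral curves may be
    passed to amortize the loudness model across repeated fits.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    t_grid = t_grid if t_grid is not None else np.linspace(0.05, 0.6, 12)
    a_grid = a_grid if a_grid is not None else np.linspace(0.5, 1.0, 11)
    if curves is None:
        curves = {study: [build_peripheral_curve(c, config) for c in conds]
                  for study, conds in conditions_by_study.items()}
    for ds in datasets:
        cs = curves[ds.study]
        if len(cs) != len(ds.x) or not np.allclose([c.condition.x for c in cs], ds.x):
            raise ValueError(f"condition grid mismatch for study {ds.study!r}")

    def err(t, a):
        return _mean_error(curves, datasets, CentralParams(t, a, rate_jnd))[0]

    samples = []
    E = np.empty((len(t_grid), len(a_grid)))
    for i, t in enumerate(t_grid):
        for j, a in enumerate(a_grid):
            E[i, j] = err(t, a)
            samples.append((t, a, E[i, j]))
    i0, j0 = np.unravel_index(np.argmin(E), E.shape)
    interior_t = 0 < i0 < len(t_grid) - 1
    interior_a = 0 < j0 < len(a_grid) - 1
    message = ""
    if not (interior_t and interior_a):
        message = ("error-surface minimum on the grid boundary: "
                   f"T_CA index {i0}/{len(t_grid)-1}, alpha index {j0}/{len(a_grid)-1}")

    t_best, a_best = float(t_grid[i0]), float(a_grid[j0])
    for _ in range(n_sweeps):
        t_lo = t_grid[max(i0 - 1, 0)]
        t_hi = t_grid[min(i0 + 1, len(t_grid) - 1)]
        t_best = _golden_section(lambda t: err(t, a_best), t_lo, t_hi, refine_tol[0])
        a_lo = a_grid[max(j0 - 1, 0)]
        a_hi = a_grid[min(j0 + 1, len(a_grid) - 1)]
        a_best = _golden_section(lambda a: err(t_best, a), a_lo, a_hi, refine_tol[1])
    e_best, per = _mean_error(curves, datasets, CentralParams(t_best, a_best, rate_jnd))
    samples.append((t_best, a_best, e_best))
    surface = pd.DataFrame(samples, columns=["T_CA", "alpha", "error_db"])
    return FitResult(t_best, a_best, e_best, per, surface,
                     converged=(interior_t and interior_a), message=message)
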