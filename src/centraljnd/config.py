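"""Model configuration.

All tunable constants of the pipeline live here with their defaults:
the dB SPL calibration convention, the temporal-window time constants of
the short-term / long-term loudness integrators, the absolute-threshold
loudness criterion, and the central-stage parameters.  A config can be
round-tripped through YAML so that a whole simulation is reproducible
from one small text file.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class ModelConfig:
    """Global constants of the stimulus and loudness pipeline.

    Parameters
    ----------
    sample_rate : float
        Synthesis sample rate in Hz.  44100 Hz matches the listening
        experiment the package replicates.
    full_scale_db_spl : float
        dB SPL assigned to a full-scale (amplitude 1.0) sinusoid.  All
        stimulus levels are calibrated relative to this internal
        reference; the model consumes calibrated levels, not hardware
        levels.
    min_level_db_spl, max_level_db_spl : float
        Calibration guard rails; requests outside are rejected.
    stl_attack_ms, stl_release_ms : float
        Short-term loudness integrator (asymmetric: more forward than
        backward masking).
    ltl_attack_ms, ltl_release_ms : float
        Long-term loudness integrator.  The release is 100 ms (symmetric
        with the attack); the original 2-s release of the published
        loudness model is available by setting ``ltl_release_ms=2000``.
    threshold_sones : float
        Absolute-threshold criterion: a stimulus is at threshold when its
        long-term loudness plateau equals this value.
    diotic_calibration : float
        Scalar gain absorbing the diotic presentation convention of the
        loudness model, fixed so that a steady 1-kHz tone at 25 dB SPL
        has a plateau loudness of 0.215 sones.
    gate_settle_margin_s : float
        Settling margin excluded from rate-analysis windows at both ends
        of a pedestal (on top of the gates), shrunk automatically for
        short pedestals.
    miller_spl_minus_sl_db : float
        Per-study SL-to-SPL conversion for the band-limited-noise study
        (SPL = SL + 4 dB).
    """

    sample_rate: float = 44100.0
    full_scale_db_spl: float = 100.0
    min_level_db_spl: float = -30.0
    max_level_db_spl: float = 120.0

    # temporal integration (ms)
    stl_attack_ms: float = 25.0
    stl_release_ms: float = 50.0
    ltl_attack_ms: float = 100.0
    ltl_release_ms: float = 100.0

    threshold_sones: float = 0.003
    # fixed so that a 1-kHz tone at 25 dB SPL -> 0.215 sones (loudness anchor)
    diotic_calibration: float = 1.04735250922961

    gate_settle_margin_s: float = 0.25
    window_lead_s: float = 0.05
    window_lag_s: float = 0.25

    miller_spl_minus_sl_db: float = 4.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


DEFAULT_CONFIG = ModelConfig()
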