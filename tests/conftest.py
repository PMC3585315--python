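import numpy as np
import pytest

from centraljnd import experiments as ex
from centraljnd.central_model import CentralParams
from centraljnd.config import ModelConfig
from centraljnd.experiments import ExperimentCondition
from centraljnd.jnd_solver import solve_jnd


@pytest.fixture(scope="session")
def params():
    return CentralParams()


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


def cheap_tone_condition(level_db=40.0, pedestal_s=1.5, duration_ms=100.0,
                         freq=1000.0, direction=1):
    """Small tone pedestal with a gated increment; fast to evaluate."""
    return ExperimentCondition(
        study="unit", label="tone", carrier="tone", x=level_db,
        x_name="level_db_spl", level_db=level_db, freq_hz=freq,
        pedestal_s=pedestal_s, gate_ms=10.0, env_shape="raised_cosine_gated",
        env_duration_s=duration_ms / 1000.0, env_gate_ms=10.0,
        direction=direction)


@pytest.fixture(scope="session")
def fit_setup():
    """Peripheral statistic curves over the full level grids of the tone and
    noise continuous-pedestal studies, plus model-generated ground-truth
    thresholds at the default central parameters."""
    from centraljnd.fitting import build_peripheral_curve

    vb = ex.condition_registry("viemeister_bacon_1988")
    mi = ex.condition_registry("miller_1947")
    grid = np.geomspace(0.02, 30.0, 10)
    curves = {
        "viemeister_bacon_1988": [build_peripheral_curve(c, d_grid=grid) for c in vb],
        "miller_1947": [build_peripheral_curve(c, d_grid=grid) for c in mi],
    }
    conds = {"viemeister_bacon_1988": vb, "miller_1947": mi}
    truth = CentralParams()
    obs = {s: np.array([c.threshold_db(truth) for c in cs])
           for s, cs in curves.items()}
    return curves, conds, obs


def synthetic_datasets(curves, obs, noise_sd, rng):
    """Model-generated JND observations with noise on the log (weber-dB)
    scale, the scale the thresholds are reported and fitted on."""
    from centraljnd.fitting import JNDDataset
    from centraljnd.jnd_solver import weber_db, increment_db_from_weber

    out = []
    for s in curves:
        wdb = np.array([weber_db(v) for v in obs[s]])
        wdb = wdb + rng.normal(0.0, noise_sd, len(wdb))
        inc = np.array([increment_db_from_weber(10.0 ** (w / 10.0)) for w in wdb])
        out.append(JNDDataset(s, [c.condition.x for c in curves[s]], inc))
    return out


@pytest.fixture(scope="session")
def supp_thresholds(params):
    """Analytic thresholds for the ramped-increment noise paradigm.

    Solved once per session for the half-ramp grid used by the listening
    experiment's short conditions; shared by the duration-tuning and
    staircase checks.
    """
    out = {}
    for h in [5.0, 10.0, 100.0, 1000.0]:
        cond = ex.condition_registry("supplementary_ramps", half_ramps_ms=[h])[0]
        out[h] = (cond, solve_jnd(cond, params))
    return out
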