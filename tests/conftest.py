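"""Shared fixtures: calibrated configs and the controlled-duration curves.

The controlled-duration speed-accuracy curves for the three mistuning
corners (baseline / mistuned / recovery) at C = 12.8 are expensive, so
they are computed once per session and shared by the tests that
compare the models.
"""

import pytest

from robint.decision_tasks import DURATION_GRID_MS
from robint.integrator_core import IntegratorParams, run_duration_curve
from robint.sensory_synth import SensoryConfig, load_default_fits

MASTER_SEED = 20130227


@pytest.fixture(scope="session")
def fits():
    return load_default_fits()


@pytest.fixture(scope="session")
def cfg128():
    return SensoryConfig(coherence=12.8)


@pytest.fixture(scope="session")
def stub_fits():
    """Small linear calibration table for fast engine tests."""
    return {"rate": [5.0, 45.0], "variance": [9.3, 83.7], "tau": [20.2, 20.2]}


@pytest.fixture(scope="session")
def duration_curves(cfg128, fits):
    """Controlled-duration accuracy curves for the three model corners.

    2000 trials per beta-grid point (19 points for the mistuned
    models), dt = 0.5 ms, durations 100-2000 ms.
    """
    models = {
        "baseline": IntegratorParams(beta_sd=0.0, robustness=0.0),
        "mistuned": IntegratorParams(beta_sd=0.1, robustness=0.0),
        "recovery": IntegratorParams(beta_sd=0.1, robustness=1.25),
    }
    out = {}
    for i, (name, params) in enumerate(models.items()):
        out[name] = run_duration_curve(
            cfg128, params, DURATION_GRID_MS, n_trials=2000,
            seed=MASTER_SEED + i, dt=0.5, fits=fits)
    return out
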