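"""Shared fixtures: synthetic study cohorts analyzed end to end.

The cohorts are generated once per session at a reduced scale (12 subjects,
30 test trials per session) so the full pipeline — preprocessing, screening,
wavelet power, RSA, jackknife, strengths and coherence — runs inside the
test budget; the generator itself defaults to the full task schedule.
"""

import warnings

import pytest

from navrsa.pipeline import RunConfig, run_study
from navrsa.synth import NeuralSimConfig, TaskConfig

STUDY_SEED = 93  # fixed cohort seed; all stage seeds derive from it
STUDY_TASK = TaskConfig(test_trials_per_session=30, seed=7)


@pytest.fixture(scope="session")
def study():
    """12-subject cohort at the default generator settings (kappa = 0.8)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(12, task=STUDY_TASK, sim_cfg=NeuralSimConfig(),
                         seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_null_coupling():
    """10-subject cohort with the HC-EC coupling switched off (kappa = 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(
            10, task=STUDY_TASK,
            sim_cfg=NeuralSimConfig(coupling_strength=0.0),
            run_cfg=RunConfig(run_jackknife=False),
            seed=STUDY_SEED)
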