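"""Shared synthetic cohort for the neural analysis scripts.

Builds the 12-subject cohort once and caches it under scratch/ so the
numbered scripts can be run independently without recomputing the
time-frequency pipeline each time.  Delete scratch/cohort.pkl to force a
rebuild.
"""

import pickle
import warnings
from pathlib import Path

from navrsa.pipeline import run_study
from navrsa.synth import NeuralSimConfig, TaskConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
COHORT_SEED = 93
N_SUBJECTS = 12
TASK = TaskConfig(test_trials_per_session=30, seed=7)


def get_cohort(force: bool = False):
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cache = SCRATCH / "cohort.pkl"
    if cache.exists() and not force:
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    print(f"building {N_SUBJECTS}-subject cohort (seed {COHORT_SEED}) ...")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        study = run_study(N_SUBJECTS, task=TASK, sim_cfg=NeuralSimConfig(),
                          seed=COHORT_SEED, progress=True)
    with open(cache, "wb") as fh:
        pickle.dump(study, fh)
    return study
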