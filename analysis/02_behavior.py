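"""Behavioral performance of a simulated 31-subject cohort.

Scores drop errors against the Monte-Carlo chance level, then runs the two
2x2 repeated-measures ANOVAs: session x environment (expected null) and
session x task half (expected learning effect, stronger in session 1).
"""

import json

import numpy as np
import pandas as pd

from _cohort import RESULTS
from navrsa.behavior import chance_threshold, classify_trials, rm_anova_2x2
from navrsa.synth import NeuralSimConfig, TaskConfig, generate_schedule, simulate_trajectories

task = TaskConfig(seed=7)
schedule = generate_schedule(task)
cfg = NeuralSimConfig()
thr = chance_threshold(seed=1).threshold

frames = []
for i in range(31):
    _, trials = simulate_trajectories(schedule, task, cfg, seed=9000 + i)
    t = classify_trials(trials[trials["block"] == "test"], thr)
    t["subject_id"] = f"s{i:02d}"
    frames.append(t)
df = pd.concat(frames, ignore_index=True)

print(f"chance threshold: {thr:.2f} vm")
print(f"mean drop error: {df['drop_error'].mean():.2f} vm; "
      f"good-trial rate: {df['is_good'].mean():.1%}")

# session x environment
cells_env = np.stack([
    g.pivot_table(index="session", columns="environment",
                  values="drop_error").to_numpy()
    for _, g in df.groupby("subject_id")])
anova_env = rm_anova_2x2(cells_env, ("session", "environment"))

# session x half (first 25 vs last 25 test trials)
half = np.where(df["trial_index"] - task.learning_trials_per_session
                < task.test_trials_per_session // 2, "H1", "H2")
df["half"] = half
cells_half = np.stack([
    g.pivot_table(index="session", columns="half",
                  values="drop_error").to_numpy()
    for _, g in df.groupby("subject_id")])
anova_half = rm_anova_2x2(cells_half, ("session", "half"))

for name, res in (("session x environment", anova_env),
                  ("session x half", anova_half)):
    print(f"\n{name}:")
    for eff, r in res.items():
        if eff == "simple_effects":
            continue
        print(f"  {eff}: F(1,{r['df2']}) = {r['F']:.2f}, p = {r['p']:.4f}")

out = dict(threshold=thr, mean_drop_error=float(df["drop_error"].mean()),
           good_rate=float(df["is_good"].mean()),
           session_x_environment=anova_env, session_x_half=anova_half)
(RESULTS / "behavior_anova.json").write_text(json.dumps(out, indent=2, default=float))
keep_cols = ["subject_id", "session", "trial_index", "environment", "object",
             "half", "drop_error", "is_good"]
df[keep_cols].round(3).to_csv(RESULTS / "behavior_trials.tsv", sep="\t",
                              index=False)
print(f"\nwrote {RESULTS / 'behavior_anova.json'}")
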