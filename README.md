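# navrsa

Spectral pattern-similarity analysis of hippocampal–entorhinal intracranial
EEG during context-dependent spatial navigation, packaged with a synthetic
task-and-LFP generator so every stage can be exercised and validated end to
end without patient recordings.

## The scientific problem

When people retrieve an object's location from memory they must reinstate
both the spatial *context* ("which environment am I in?") and the *object*
("what am I looking for?").  Rodent work places these codes in the
hippocampus (HC; place-cell remapping across environments) and entorhinal
cortex (EC; object coding).  In humans, depth-electrode recordings during a
two-environment virtual navigation task make it possible to ask, at the
local-field-potential level:

1. Does HC activity during movement distinguish the two environments, and
   does EC activity distinguish the two target objects?
2. Do the trial-by-trial strengths of these two codes covary, and does
   their *joint* strength predict navigation accuracy?
3. Which frequencies carry the codes, and does low-frequency HC–EC
   synchronization relate to the strength of the entorhinal object code?

## What the package implements

- **Task model** (`navrsa.synth`): a 2-session schedule (20 learning + 50
  test trials per session; environments alternating in runs of 3–5), a
  square (29 vm side) and a circular (29 vm diameter) arena with the task's
  object coordinates, a movement-state machine (stationary / rotation /
  translation / turning), a behavior model linking representation strengths
  to the drop error, and multichannel LFP: 1/f background + line noise +
  narrowband (2–8 Hz) context/object codes during translation + a
  phase-lagged HC→EC theta driver whose per-trial strength scales the EC
  object code (coupling strength κ).
- **Behavior** (`navrsa.behavior`): drop error, the Monte-Carlo surrogate
  chance level (5th percentile of resampled mean drop errors over the eight
  session × environment × object cells), good/bad trial classification, and
  2×2 repeated-measures ANOVAs.
- **Preprocessing** (`navrsa.preprocess`): anti-aliased downsampling to
  500 Hz, white-matter re-referencing, 50/100/150 Hz notch filters,
  two-criterion artifact masking (±4 SD amplitude; 25–80 Hz envelope
  mean + 5 SD; ±0.5 s dilation), and 2-s translation/stationary epochs
  locked to the longest qualifying movement segment (≥1 s / ≥0.5 s).
- **Spectral analysis** (`navrsa.spectral`): Morlet wavelet power (5
  cycles) at 50 log-spaced frequencies 2–150 Hz, log-transformed and
  z-scored per channel × frequency against the artifact-free full task.
- **RSA** (`navrsa.rsa`): voltage-based task-selective electrode screening
  (conjunction of context and object t-tests at p < 0.001), sliding-window
  feature vectors (500 ms / 50 ms → 31 windows of frequency × time ×
  channel z-power), Spearman correlations between within-session epoch
  pairs with Fisher-z transform, Same/Different contrasts, and 4×4
  (environment × object) similarity matrices.
- **Statistics** (`navrsa.stats`): cluster-based permutation tests
  (condition-label shuffle and subject sign-flip variants, 1000
  permutations), and Benjamini–Hochberg FDR.
- **Coordination** (`navrsa.coordination`): leave-one-trial-out
  representation strength, cross-trial and time-lagged HC–EC strength
  correlations, and the median-split linear mixed-effects model
  `drop_error ~ context*object + (1|subject)` with a self-contained REML
  fitter and Satterthwaite degrees of freedom.
- **Band contributions** (`navrsa.bandcontrib`): jackknife removal of the
  2–8 / 8–30 / 30–150 Hz bands from the RSA vectors, band-restricted RSA,
  and robust log–log separation of periodic from aperiodic (1/f) power.
- **Connectivity** (`navrsa.connectivity`): cross-time imaginary coherence
  between ipsilateral HC–EC pairs over the 2-s epoch, z-scored against
  1000 trial-shuffle surrogates, band-averaged, and correlated with
  trial-level representation strengths.

## Worked example

```python
import numpy as np
from navrsa.behavior import chance_threshold
from navrsa.pipeline import run_study
from navrsa.stats import cluster_perm_label
from navrsa.synth import TaskConfig, NeuralSimConfig

print(round(chance_threshold(seed=1).threshold, 2))   # 9.92 vm chance level

study = run_study(6, task=TaskConfig(test_trials_per_session=24, seed=7),
                  sim_cfg=NeuralSimConfig(), seed=42)
A = np.stack([s.contrasts[("HC", "context")].mean_same for s in study.subjects])
B = np.stack([s.contrasts[("HC", "context")].mean_diff for s in study.subjects])
print(round(float((A - B).mean()), 3))                # 0.094 Fisher-z units
print(cluster_perm_label(A, B, rng=1).min_p)          # 0.018
```

The first number is the drop-error threshold below which a trial counts as
"good" (placement closer to the target than the 5th percentile of chance).
The second is the mean Same-minus-Different context similarity in HC
(positive = the hippocampal spectral pattern distinguishes the two
environments), and the third its cluster-corrected permutation p-value
across the 31 time windows.

The numbered scripts under `analysis/` run the full study narrative —
chance level, behavioral ANOVAs, the HC/EC double dissociation, the band
jackknife, the coherence–strength link, and the mixed-effects behavior
model — writing tables under `results/`.  The neural scripts (03–05) share
a cached 12-subject cohort (~6 minutes to build on one CPU).

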