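# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Task and behavior model

The simulated experiment follows a two-session object-location memory task.
Each session has 20 learning and 50 test trials; the two virtual arenas — a
square of 29 vm side length and a circle of 29 vm diameter, both centered
at the origin — alternate in runs of 3–5 trials with equal totals per
environment, and each session uses two objects placed at fixed coordinates
(session 1: square (4, 9) and (−10, −5), circle (−4, 9) and (10, −5);
session 2: square (−2, 5) and (7, −4), circle (2, 5) and (−7, −4)). Start
positions come from a fixed seeded list shared across subjects; start
orientations are randomized per subject. Run-length feasibility is checked
(e.g. runs of exactly 4 cannot tile 25 trials per environment and the
configuration is rejected).

**Chance level.** The drop error is the Euclidean distance between the
placed and true object position. The chance threshold is the 5th percentile
of a surrogate distribution built by drawing 10,000 random drop positions
per (session, environment, object) cell and averaging one draw per cell
10,000 times. The surrogate's sampling density is not uniquely determined
by the procedure's description; this implementation defaults to uniform
sampling over the 29 × 29 vm square extent in *both* environments, which
reproduces the reference threshold of 9.87 vm for this geometry (our Monte-Carlo value: ~9.9
vm, SE < 0.03). Uniform sampling restricted to the circular wall
(`sampling="interior"`) is also provided; it yields a slightly lower
threshold (~9.4 vm) because positions outside the circle — farther from the
objects on average — are excluded. Trials are "good" when the drop error is
*strictly* below the threshold; ties classify as bad.

**Behavior link.** Drop errors are generated as
`base + subject offset + first-half penalty − β_c(s_c−1) − β_o(s_o−1) −
δ·1[both strengths above their within-subject medians] + noise`, clipped at
zero. Defaults: base 6.5 vm, subject SD 0.8, per-subject session-level SD
1.2 vm (fatigue/electrode state; it keeps the session main effect in the
weak-to-marginal regime), first-half penalties 2.4 vm (session 1) and
1.2 vm (session 2) — producing the learning effect the 2×2 session × half
ANOVA should detect, stronger in session 1 — β_c = β_o = 0, δ = 3 vm,
trial noise SD 2 vm. Block sequences are additionally composed so each
half of a block is environment-balanced to ±1 trial; with one sequence
shared by all subjects, an unbalanced first half would otherwise confound
the environment factor with the learning curve. With these values roughly three quarters of test trials fall below
the 9.87 vm threshold. The interaction-only default mirrors the qualitative
finding the coordination analysis probes: accuracy improves only when both
codes are strong.

## Synthetic LFP

Each subject's recording covers the test blocks at 500 Hz (simulated
directly at the analysis rate) with 4 HC, 4 EC and 2 amygdala channels plus
two white-matter reference channels. HC and EC electrodes are placed in one
hemisphere (unilateral medial-temporal coverage), so all HC–EC combinations
are ipsilateral pairs.

- **Background**: 1/f (exponent 1.0) noise at 10 µV RMS per channel with
  tails softly compressed at 3.2 SD — the ongoing LFP background is
  lighter-tailed than Gaussian at these amplitudes, and the compression
  keeps the ±4 SD artifact criterion focused on genuine transients — plus
  50 Hz line noise (2 µV) and a slow per-hemisphere drift shared with the
  reference channel (removed exactly by re-referencing).
- **Codes**: during each test trial's main translation segment, HC channels
  receive a context code and EC channels an object code. A label is coded
  by (i) a sub-band frequency profile inside 2–8 Hz — one label rides
  low-theta (≈2.3–4.2 Hz), the other high-theta (≈4.9–6.9 Hz), assignment
  randomized per subject — and (ii) an antipodal channel-amplitude pattern
  (channels loaded at 1 ± 0.25 with opposite signs for the two labels).
  Carriers are constant-envelope frequency-modulated oscillations generated
  independently per channel and trial; the constant envelope keeps peak
  factors at √2 so codes do not trip the amplitude artifact criterion.
  Code amplitude defaults to 0.7 × background RMS with 15% per-trial
  jitter. The EC code starts 0.2 s after translation onset (object
  reinstatement follows context reinstatement).
- **Shared gain**: a per-trial latent g (SD 0.35) scales both codes by
  (1 + 0.75 g), inducing the cross-trial covariation of HC context and EC
  object strength that the coordination analysis measures.
- **Theta driver**: a subject-specific narrow theta tone (f₀ ~ U(3.0, 4.2)
  Hz) is injected into HC (amplitude 0.75 × RMS) and, lagged by a quarter
  cycle (HC leads), into EC with amplitude 0.85 × κ × (1 + c_t) × RMS,
  where c_t (SD 0.5) is the trial's driver strength and κ ∈ [0, 1] the
  coupling constant (default 0.8). The EC object code amplitude is further
  scaled by (1 + κ c_t), so trial-level HC–EC imaginary coherence and EC
  object strength covary through c_t; at κ = 0 both the EC driver and the
  code modulation vanish and the linkage is null by construction. The
  driver rides on the same channel patterns as the codes (it entrains the
  code-expressing assembly) and its frequency stays low in the band so that
  wavelet bandwidth does not carry driver coherence past 8 Hz.
- **Selectivity offsets**: small per-label DC offsets (SD 1.2 µV, constant
  over a whole trial) make ROI channels separable by the voltage-based
  conjunction screen. Because Morlet wavelets are zero-mean and trial
  boundaries lie > 1.5 s from epoch windows, these offsets contribute no
  band-limited power to the RSA features.
- **Artifacts**: occasional large transients (6–10 × RMS, 0.1–0.3 s, 0.2
  events/min) exercise the artifact detector and per-ROI epoch exclusion.

What the generator does **not** emulate: epileptiform activity, volume
conduction, electrode impedance drift, realistic trajectory kinematics
(only segment timing matters downstream), learning-block neural data, or
any anatomical gradient. Passing tests therefore show that the analysis
recovers the structure it assumes from signals of realistic scale and
noise — not that the biological claims hold.

## Analysis pipeline

Preprocessing mirrors standard iEEG practice: FIR decimation to 500 Hz
(when data arrive at a higher rate), subtraction of the white-matter
reference, zero-phase band-stop filters at 48–52 / 98–102 / 148–152 Hz,
and a two-criterion artifact mask — samples beyond the whole-recording
mean ± 4 SD (two-sided, per channel), or where the analytic-signal envelope
of the 25–80 Hz band exceeds its mean + 5 SD — dilated by ±0.5 s. Epochs
are 2 s from the onset of each test trial's longest translation segment
(≥ 1 s; stationary control epochs ≥ 0.5 s); a strict mode additionally
requires the state to persist the full window. Epochs overlapping the mask
on any channel of a region are excluded for that region only.

Wavelet power (Morlet, 5 cycles, 50 log-spaced frequencies 2–150 Hz; the
grid yields 16/15/19 points in the 2–8/8–30/30–150 Hz bands with half-open
band intervals, top band closed) is computed on the reflect-padded
continuous recording and then epoched, so no filter edges fall inside
windows. The natural log of power is z-scored per channel × frequency
against the artifact-free full task.

RSA flattens z-power over frequencies × window samples × channels into one
vector per epoch and 500 ms window (50 ms steps, 31 windows; 200/20 and
100/10 ms schemes available), computes Spearman correlations (Pearson on
average ranks, exact under ties) between all within-session epoch pairs,
and Fisher-z transforms them with |rho| clipped at 1 − 1e−10. Contrasts
average Same- and Different-label pair z per session and then across
sessions; group inference is a one-tailed t per window with cluster-based
permutation correction (cluster-forming α = 0.05; condition-label shuffle =
per-subject swap with probability 0.5, equivalent to sign-flipping the
paired difference; 1000 permutations; p floored at 1/(n_perm+1); tied
cluster masses broken by earlier onset).

Leave-one-trial-out strength is each epoch's mean similarity to same-label
epochs minus different-label epochs, within session; with balanced labels
its trial average equals the contrast difference exactly (tested to 1e−12).
Trial-level strengths are averaged over a fixed 0.65–0.80 s window (the
interval in which cross-trial HC–EC coupling is reported for this task). A
data-driven alternative — the largest significant cluster of the group
cross-trial strength correlation (sign-flip test) — is available
(`derive_strength_window`), but because the generator's shared gain is
sustained over the whole movement period, the cross-trial correlation it
produces is temporally flat and the derived cluster's location is
essentially sampling noise; the fixed window is therefore the default. The mixed model `drop ~ context*object + (1|subject)`
uses centered ±0.5 factor coding (so each effect is a single-df contrast,
F = t²), a self-contained REML fitter for the random-intercept structure
(closed-form per-group algebra, Nelder-Mead over log variances), and
Satterthwaite degrees of freedom via df = 2φ²/(gᵀVg) with finite-difference
gradient g of the contrast variance φ and V the inverse observed REML
information. statsmodels' MixedLM does not provide Satterthwaite dfs; the
fitter is cross-checked against lmerTest (via Rscript) in the test suite.
Singular fits (τ² ≈ 0) fall back to the fixed-effects residual df with a
warning.

The band jackknife removes one band's grid points from the RSA vectors,
recomputes the contrast, and subtracts it from the full-band contrast;
reductions are tested one-tailed with the sign-flip cluster test. Removal
of a band with no grid points gives exactly zero. Additivity across bands
is *not* assumed (rank correlation is nonlinear). Aperiodic separation fits
a line to ln(power) vs ln(frequency) of the epoch's time-averaged spectrum
by bisquare robust regression, iteratively excluding bins well above the
line (oscillatory peaks) and refitting, then subtracts the back-transformed
line at every time point and clips negatives to zero; it is applied per
epoch per channel.

Imaginary coherence |Im(Sxy)| / √(Sxx·Syy) is computed per frequency from
the complex wavelet coefficients summed over the 2-s epoch, for every
ipsilateral HC–EC pair. Per-trial values are z-scored against 1000
surrogates that re-pair one electrode's epochs with a uniform within-
session permutation of the other's (self-pairings allowed with probability
1/n), then averaged over pairs and over each band's grid points. Group
tests of the coherence–strength Fisher-z correlations are one-tailed
positive for the hypothesized 2–8 Hz band and two-tailed elsewhere, with
BH-FDR across the three bands.

## Problem sizes and numerical choices

The test cohorts use 12 subjects with 30 test trials per session (the
generator's schedule default remains 50) and 10 channels across HC/EC; at
this scale a full single-subject pass (simulation, preprocessing, wavelet
transform, RSA, jackknife, strengths, coherence) takes ~25 s on one CPU
and the injected effects are recovered with comfortable margins, as the
acceptance tests verify. Monte-Carlo sizes for the chance level follow the
procedure definition (10,000/10,000). Permutation counts default to 1000.
Spearman correlations on the ~40,000-dimensional window vectors are
computed as Pearson correlations of average ranks via matrix products;
rank vectors with zero variance make the affected pairs NaN and they are
excluded from all averages.

## Design choices on genuinely open points

- Surrogate drop positions: square-extent uniform by default (reproduces
  the reference threshold); interior-uniform available.
- Electrode screening uses all test-trial epochs (not only good trials),
  with the trial filter applied downstream; the object factor for the
  binary screen is the within-session object slot.
- Same Context pairs pool same- and different-object pairs without
  reweighting; self-pairs are excluded everywhere; cross-session pairs are
  never formed.
- Cross-trial strength correlations concatenate within-session strengths
  rather than averaging session-wise correlations.
- Coherence surrogate shuffles are constrained within session.
- The 0.1–150 Hz grid extension adds a configurable number of log-spaced
  points below 2 Hz (default 10) forming an additional removable band.

## Known limitations

- The generator's amplitude/frequency-profile codes are one concrete
  mechanism consistent with power-pattern RSA; real codes are unknown and
  likely mixed (phase, amplitude, broadband).
- Trial-to-trial pattern variability (jitter SD 0.15) is a free parameter,
  not an empirical estimate.
- The time-lagged strength analysis is validated on constructed series;
  with sustained amplitude codes the generator does not produce a sharp
  lag peak, so lag recovery is exercised at the operation level.
- Because the theta driver rides the same channel patterns as the codes,
  per-trial pattern-expression jitter couples HC coherence weakly to HC
  context strength; empirically that correlation is reported as null, so
  the generator overstates it somewhat.
- The LME fitter supports a single random intercept only (the model used
  here); no random slopes.
- Chance-level and permutation p-values are Monte-Carlo estimates; exact
  reproduction requires the recorded seeds.
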