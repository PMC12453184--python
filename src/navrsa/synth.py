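"""Synthetic task-and-LFP generator.

Emulates a two-session object-location memory experiment in a square and a
circular virtual arena (29 vm side / diameter), together with multichannel
intracranial LFP in which hippocampal channels carry a context-specific
narrowband (2-8 Hz) amplitude pattern and entorhinal channels carry an
object-specific pattern during translational movement.  A shared per-trial
theta driver couples the two regions: its strength scales the entorhinal
object code (coupling strength ``kappa``) and injects phase-lagged common
oscillation into both regions, so that trial-level HC-EC synchronization and
entorhinal representation strength co-vary by construction.

Everything is driven by explicit seeds; identical seeds give bit-identical
schedules, segments and voltage arrays.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import Recording

# ---------------------------------------------------------------------------
# task geometry and schedule
# ---------------------------------------------------------------------------

#: object coordinates (vm) per (session, environment, object label)
DEFAULT_OBJECT_POSITIONS: dict[tuple[int, str, str], tuple[float, float]] = {
    (1, "square", "cone"): (4.0, 9.0),
    (1, "square", "pumpkin"): (-10.0, -5.0),
    (1, "circle", "cone"): (-4.0, 9.0),
    (1, "circle", "pumpkin"): (10.0, -5.0),
    (2, "square", "lamp"): (-2.0, 5.0),
    (2, "square", "plant"): (7.0, -4.0),
    (2, "circle", "lamp"): (2.0, 5.0),
    (2, "circle", "plant"): (-7.0, -4.0),
}

SESSION_OBJECTS = {1: ("cone", "pumpkin"), 2: ("lamp", "plant")}


@dataclass(frozen=True)
class ArenaGeometry:
    """Arena footprint: a square (side ``size``) or circle (diameter ``size``)."""

    shape: str
    size: float = 29.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.shape not in ("square", "circle"):
            raise ValueError(f"unknown arena shape {self.shape!r}")
        if self.size <= 0:
            raise ValueError("arena size must be positive")

    @property
    def half(self) -> float:
        return self.size / 2.0

    def contains(self, xy) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        dx = xy[:, 0] - self.center[0]
        dy = xy[:, 1] - self.center[1]
        if self.shape == "square":
            return (np.abs(dx) <= self.half) & (np.abs(dy) <= self.half)
        return dx**2 + dy**2 <= self.half**2

    def sample_uniform(self, rng: np.random.Generator, n: int,
                       mode: str = "interior", margin: float = 0.0) -> np.ndarray:
        """Uniform points either inside the arena or over its bounding square.

        ``mode='interior'`` respects the wall (circle sampled by radius
        transform); ``mode='square_extent'`` draws from the full size x size
        square regardless of wall shape.
        """
        h = self.half - margin
        if mode == "square_extent" or self.shape == "square":
            pts = rng.uniform(-h, h, size=(n, 2))
        elif mode == "interior":
            r = h * np.sqrt(rng.uniform(0.0, 1.0, n))
            th = rng.uniform(0.0, 2.0 * np.pi, n)
            pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        else:
            raise ValueError(f"unknown sampling mode {mode!r}")
        return pts + np.asarray(self.center)


def default_geometries() -> dict[str, ArenaGeometry]:
    return {"square": ArenaGeometry("square"), "circle": ArenaGeometry("circle")}


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the navigation task schedule."""

    n_sessions: int = 2
    learning_trials_per_session: int = 20
    test_trials_per_session: int = 50
    run_length_range: tuple[int, int] = (3, 5)
    object_positions: dict = field(default_factory=lambda: dict(DEFAULT_OBJECT_POSITIONS))
    max_speed: float = 3.0  # vm/s
    feedback_bins: tuple[float, ...] = (3.0, 6.0, 9.0, 12.0)
    seed: int = 2024

    def geometries(self) -> dict[str, ArenaGeometry]:
        return default_geometries()

    def __post_init__(self) -> None:
        lo, hi = self.run_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid run_length_range")
        if self.test_trials_per_session % 2:
            raise ValueError("test trials must split equally between environments")
        if self.learning_trials_per_session % 2:
            raise ValueError("learning trials must split equally between environments")
        geoms = self.geometries()
        for (sess, shape, obj), xy in self.object_positions.items():
            if not geoms[shape].contains(xy)[0]:
                raise ValueError(f"object {obj!r} lies outside the {shape} arena")


def _n_runs_options(n: int, lo: int, hi: int) -> list[int]:
    return [k for k in range(1, n // lo + 1) if k * lo <= n <= k * hi]


def _random_composition(n: int, k: int, lo: int, hi: int, rng: np.random.Generator) -> list[int]:
    """Random composition of n into k parts, each within [lo, hi]."""
    parts = []
    rem = n
    for i in range(k):
        left = k - i - 1
        lo_i = max(lo, rem - hi * left)
        hi_i = min(hi, rem - lo * left)
        val = int(rng.integers(lo_i, hi_i + 1))
        parts.append(val)
        rem -= val
    return parts


def generate_schedule(task: TaskConfig) -> pd.DataFrame:
    """Build the full trial table (identical for every subject).

    Environments alternate in runs whose lengths are drawn from
    ``run_length_range``; each block contains equally many trials per
    environment.  Raises ``ValueError`` when the per-environment trial count
    cannot be tiled by runs in the allowed range.
    """
    lo, hi = task.run_length_range
    rng = np.random.default_rng(task.seed)
    rows = []
    for sess in range(1, task.n_sessions + 1):
        objects = SESSION_OBJECTS.get(sess, SESSION_OBJECTS[1])
        trial_index = 0
        for block, n_block in (("learning", task.learning_trials_per_session),
                               ("test", task.test_trials_per_session)):
            per_env = n_block // 2
            options = _n_runs_options(per_env, lo, hi)
            if not options:
                raise ValueError(
                    f"{per_env} trials per environment cannot be tiled by runs of "
                    f"length {lo}-{hi}")
            # compose alternating runs; keep the two halves of the block
            # environment-balanced so half-based learning contrasts are not
            # confounded (the sequence is shared by every subject)
            order = None
            for _ in range(200):
                k = int(rng.choice(options))
                runs = {env: _random_composition(per_env, k, lo, hi, rng)
                        for env in ("square", "circle")}
                first = "square" if rng.random() < 0.5 else "circle"
                cand = []
                for i in range(k):
                    for env in (first,
                                "circle" if first == "square" else "square"):
                        cand.extend([env] * runs[env][i])
                half = cand[:n_block // 2]
                if abs(half.count("square") - half.count("circle")) <= 1:
                    order = cand
                    break
            if order is None:
                order = cand
            # balanced object labels within each environment, shuffled
            labels = {}
            for env in ("square", "circle"):
                lab = list(objects) * math.ceil(per_env / 2)
                lab = lab[:per_env]
                rng.shuffle(lab)
                labels[env] = lab
            counters = {"square": 0, "circle": 0}
            geoms = task.geometries()
            for env in order:
                obj = labels[env][counters[env]]
                counters[env] += 1
                start = geoms[env].sample_uniform(rng, 1, mode="interior", margin=1.0)[0]
                true = task.object_positions[(sess, env, obj)]
                rows.append(dict(
                    session=sess, trial_index=trial_index, block=block,
                    environment=env, object=obj,
                    object_slot=objects.index(obj),
                    start_x=start[0], start_y=start[1],
                    start_orientation=np.nan,  # randomized per subject later
                    true_x=true[0], true_y=true[1],
                ))
                trial_index += 1
    sched = pd.DataFrame(rows)
    sched["trial_id"] = np.arange(len(sched))
    return sched


# ---------------------------------------------------------------------------
# behavior model and trial latents
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorLink:
    """Maps trial-level representation strengths onto the drop error (vm).

    drop_error = base + learning offset
                 - beta_context * (s_ctx - 1) - beta_object * (s_obj - 1)
                 - delta * 1[s_ctx and s_obj above their within-subject medians]
                 + N(0, noise_sd), clipped at zero.
    """

    base_error: float = 6.5
    subject_sd: float = 0.8
    #: per-subject session-level variability (fatigue, electrode state)
    session_sd: float = 1.2
    #: extra error in the first half of each session (session 1, session 2)
    first_half_penalty: tuple[float, float] = (2.4, 1.2)
    beta_context: float = 0.0
    beta_object: float = 0.0
    delta: float = 3.0
    noise_sd: float = 2.0

    @classmethod
    def zero(cls) -> "BehaviorLink":
        return cls(base_error=0.0, subject_sd=0.0, session_sd=0.0,
                   first_half_penalty=(0.0, 0.0), beta_context=0.0,
                   beta_object=0.0, delta=0.0, noise_sd=0.0)


@dataclass(frozen=True)
class NeuralSimConfig:
    """Parameters of the synthetic LFP.

    Code amplitudes (``*_code_snr``) are expressed relative to the broadband
    background RMS.  ``coupling_strength`` (kappa, in [0, 1]) scales the
    entorhinal object code by ``1 + kappa * c_t`` where ``c_t`` is the trial's
    zero-mean theta-driver strength; the driver itself is injected into EC
    with amplitude proportional to ``kappa * (1 + c_t)`` and into HC with a
    fixed amplitude, a quarter cycle ahead of EC.
    """

    sample_rate: float = 500.0
    channels_per_region: dict = field(
        default_factory=lambda: {"HC": 4, "EC": 4, "AMY": 2})
    noise_exponent: float = 1.0
    noise_rms: float = 10.0  # microvolt
    line_noise_hz: float = 50.0
    line_noise_amp: float = 2.0
    code_band: tuple[float, float] = (2.0, 8.0)
    context_code_snr: float = 0.7
    object_code_snr: float = 0.7
    pattern_contrast: float = 0.25  # antipodal channel-pattern separation
    coupling_strength: float = 0.8  # kappa
    shared_gain_weight: float = 0.75  # lambda, weight of the shared gain g_t
    trial_strength_jitter: float = 0.15
    driver_amp_hc: float = 0.75  # x noise_rms
    driver_amp_ec: float = 0.85  # x noise_rms, further scaled by kappa*(1+c_t)
    driver_lag_s: float | None = None  # EC lags HC; None = 1/4 cycle of the
    # subject's theta frequency (maximal imaginary coherence)
    object_code_delay_s: float = 0.2
    selectivity_offset_sd: float = 1.2  # microvolt, per-label DC offsets
    artifact_rate: float = 0.2  # events / minute
    behavior_link: BehaviorLink = field(default_factory=BehaviorLink)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.context_code_snr < 0 or self.object_code_snr < 0:
            raise ValueError("code SNRs must be non-negative")
        for region in ("HC", "EC"):
            if self.channels_per_region.get(region, 0) < 1:
                raise ValueError(f"no channels requested in region {region}")

    def digest(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items() if k != "behavior_link"}
        payload["behavior_link"] = self.behavior_link.__dict__ | {
            "first_half_penalty": list(self.behavior_link.first_half_penalty)}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def draw_trial_latents(n_trials: int, cfg: NeuralSimConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Per-trial latent states: shared gain g_t and theta-driver strength c_t.

    Both are zero-mean and clipped to keep all amplitude factors positive.
    The resulting representation strengths are
    ``s_context = 1 + lambda*g`` and ``s_object = (1 + lambda*g)(1 + kappa*c)``.
    """
    g = np.clip(rng.normal(0.0, 0.35, n_trials), -0.8, 1.2)
    c = np.clip(rng.normal(0.0, 0.50, n_trials), -0.95, 1.8)
    lam, kap = cfg.shared_gain_weight, cfg.coupling_strength
    s_ctx = 1.0 + lam * g
    s_obj = (1.0 + lam * g) * (1.0 + kap * c)
    return pd.DataFrame(dict(g=g, c=c, s_context=s_ctx, s_object=s_obj))


# ---------------------------------------------------------------------------
# trajectories / movement states
# ---------------------------------------------------------------------------

MOVEMENT_STATES = ("stationary", "rotation", "translation", "turning")


def _trial_states(rng: np.random.Generator, min_long_frac: float = 0.85
                  ) -> list[tuple[str, float]]:
    """Dwell-time state machine for the return phase of one test trial.

    The main translation segment is >= 1 s always and >= 2 s with
    probability ``min_long_frac``; a short second translation and flanking
    stationary/rotation/turning segments complete the trial.
    """
    if rng.random() < min_long_frac:
        main = min(2.05 + rng.exponential(0.7), 4.0)
    else:
        main = 1.0 + rng.uniform(0.0, 0.95)
    return [
        ("stationary", rng.uniform(1.5, 2.2)),
        ("rotation", rng.uniform(0.3, 0.8)),
        ("translation", main),
        ("turning", rng.uniform(0.2, 0.6)),
        ("translation", rng.uniform(0.5, 0.95)),
        ("stationary", rng.uniform(0.5, 1.0)),
    ]


def simulate_trajectories(schedule: pd.DataFrame, task: TaskConfig,
                          cfg: NeuralSimConfig, seed: int,
                          latents: pd.DataFrame | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Movement segments and behavioral outcomes for one subject.

    Returns ``(segments, trials)`` where ``segments`` covers the test trials
    (state, onset, duration; contiguous within each trial) and ``trials`` is
    the schedule augmented with per-trial latent strengths, drop positions and
    drop errors.  Learning trials carry behavior only (no drop phase, no
    segments).
    """
    rng = np.random.default_rng(seed)
    trials = schedule.copy()
    test_mask = trials["block"].to_numpy() == "test"
    n_test = int(test_mask.sum())
    if latents is None:
        latents = draw_trial_latents(n_test, cfg, rng)
    trials["start_orientation"] = rng.uniform(0.0, 360.0, len(trials))

    for col in ("g", "c", "s_context", "s_object"):
        trials[col] = np.nan
        trials.loc[test_mask, col] = latents[col].to_numpy()

    # movement segments, test trials concatenated in schedule order
    seg_rows = []
    t = 0.0
    onsets = np.full(len(trials), np.nan)
    for i in np.flatnonzero(test_mask):
        onsets[i] = t
        for state, dur in _trial_states(rng):
            seg_rows.append(dict(trial_id=int(trials["trial_id"].iloc[i]),
                                 state=state, onset=t, duration=dur))
            t += dur
    trials["trial_onset_s"] = onsets
    trials["trial_end_s"] = np.nan
    segments = pd.DataFrame(seg_rows)
    ends = segments.groupby("trial_id").apply(
        lambda s: s["onset"].iloc[-1] + s["duration"].iloc[-1], include_groups=False)
    trials.loc[test_mask, "trial_end_s"] = ends.reindex(
        trials.loc[test_mask, "trial_id"]).to_numpy()

    # behavior: drop error from the link model
    link = cfg.behavior_link
    sub_off = rng.normal(0.0, link.subject_sd)
    sess_off = {s: rng.normal(0.0, link.session_sd)
                for s in sorted(trials["session"].unique())}
    err = np.full(len(trials), np.nan)
    s_ctx = trials["s_context"].to_numpy()
    s_obj = trials["s_object"].to_numpy()
    med_c = np.nanmedian(s_ctx[test_mask])
    med_o = np.nanmedian(s_obj[test_mask])
    for i in np.flatnonzero(test_mask):
        sess = int(trials["session"].iloc[i])
        idx_in_block = int(
            (trials["trial_index"].iloc[i])
            - task.learning_trials_per_session)
        first_half = idx_in_block < task.test_trials_per_session // 2
        e = link.base_error + sub_off + sess_off[sess]
        if first_half:
            e += link.first_half_penalty[min(sess - 1, 1)]
        e -= link.beta_context * (s_ctx[i] - 1.0)
        e -= link.beta_object * (s_obj[i] - 1.0)
        if s_ctx[i] > med_c and s_obj[i] > med_o:
            e -= link.delta
        e += rng.normal(0.0, link.noise_sd)
        err[i] = max(e, 0.0)
    trials["drop_error"] = err
    theta = rng.uniform(0.0, 2.0 * np.pi, len(trials))
    trials["drop_x"] = trials["true_x"] + err * np.cos(theta)
    trials["drop_y"] = trials["true_y"] + err * np.sin(theta)
    return segments, trials


# ---------------------------------------------------------------------------
# LFP synthesis
# ---------------------------------------------------------------------------


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent background noise via spectral shaping, unit RMS.

    The tails are softly compressed at 3.2 SD: the ongoing LFP background is
    lighter-tailed than Gaussian at these amplitudes, and this keeps the
    +-4 SD amplitude criterion of the artifact detector focused on genuine
    injected transients instead of chance background excursions.
    """
    freqs = np.fft.rfftfreq(n, d=1.0)
    spec = (rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs)))
    with np.errstate(divide="ignore"):
        shaping = freqs ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    x /= x.std()
    x = 3.2 * np.tanh(x / 3.2)
    return x / x.std()


def _narrowband(n: int, rate: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise, unit RMS."""
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    pad = int(rate)  # settle the filter away from the segment
    x = sps.sosfiltfilt(sos, rng.normal(size=n + 2 * pad))[pad:pad + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _fm_oscillation(n: int, rate: float, band: tuple[float, float],
                    rng: np.random.Generator) -> np.ndarray:
    """Constant-envelope oscillation wandering inside ``band``, unit RMS.

    The instantaneous frequency follows smoothed noise clipped to the band;
    the constant envelope keeps the peak factor at sqrt(2) so injected codes
    do not trip the +-4 SD amplitude artifact criterion.
    """
    lo, hi = band
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    drift = _narrowband(n, rate, (0.05, 0.5), rng)
    finst = mid + half * 0.75 * np.tanh(1.2 * drift)  # soft edges, stays in band
    phase = 2.0 * np.pi * np.cumsum(finst) / rate + rng.uniform(0, 2 * np.pi)
    return np.sqrt(2.0) * np.sin(phase)


def _make_channel_table(cfg: NeuralSimConfig) -> pd.DataFrame:
    # HC and EC electrodes sit in one hemisphere (unilateral medial-temporal
    # coverage), so every HC-EC combination is an ipsilateral pair; control
    # regions alternate hemispheres
    rows = []
    for region, count in cfg.channels_per_region.items():
        unilateral = region in ("HC", "EC")
        for i in range(count):
            hemi = "L" if (unilateral or i % 2 == 0) else "R"
            rows.append(dict(id=f"{region}-{hemi}{i + 1}", region=region,
                             hemisphere=hemi, reference_id=f"WM-{hemi}"))
    for hemi in ("L", "R"):
        rows.append(dict(id=f"WM-{hemi}", region="other", hemisphere=hemi,
                         reference_id=f"WM-{hemi}"))
    return pd.DataFrame(rows)


def simulate_ieeg(trials: pd.DataFrame, segments: pd.DataFrame,
                  cfg: NeuralSimConfig, seed: int) -> Recording:
    """Continuous multichannel LFP for the test blocks of one subject.

    Background = pink noise + line noise + per-hemisphere slow drift (removed
    by white-matter re-referencing).  During each test trial's main
    translation segment, HC channels receive the context-specific narrowband
    code, EC channels the object-specific code scaled by the trial's driver
    strength, and both regions receive the shared theta driver with a fixed
    lag (HC leads).  Small per-label DC offsets spanning whole trials make
    ROI channels separable by the voltage-based task-selectivity screen
    without adding band-limited power inside the epochs.
    """
    rng = np.random.default_rng(seed)
    rate = cfg.sample_rate
    channels = _make_channel_table(cfg)
    test = trials[trials["block"] == "test"]
    head_pad = 3.0
    dur = float(test["trial_end_s"].max()) + head_pad + 3.0
    n = int(round(dur * rate))
    n_ch = len(channels)

    volt = np.empty((n_ch, n), dtype=np.float64)
    for ci in range(n_ch):
        volt[ci] = cfg.noise_rms * _pink_noise(n, cfg.noise_exponent, rng)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        tt = np.arange(n) / rate
        volt[ci] += cfg.line_noise_amp * np.sin(
            2.0 * np.pi * cfg.line_noise_hz * tt + phase)
    # slow per-hemisphere drift shared with the white-matter reference
    for hemi in ("L", "R"):
        drift = 5.0 * _narrowband(n, rate, (0.02, 0.3), rng)
        sel = channels["hemisphere"].to_numpy() == hemi
        volt[sel] += drift

    regions = channels["region"].to_numpy()
    hc_idx = np.flatnonzero(regions == "HC")
    ec_idx = np.flatnonzero(regions == "EC")
    roi_idx = np.flatnonzero(np.isin(regions, ["HC", "EC", "AMY"]))

    envs = ("square", "circle")
    # labels are coded by (i) a sub-band frequency profile within code_band
    # (one label rides low-theta, the other high-theta; assignment random
    # per subject) and (ii) a milder antipodal channel-amplitude pattern
    # sub-bands sit well inside code_band so that wavelet bandwidth does not
    # leak label-dependent power into the neighboring band
    blo, bhi = cfg.code_band
    span = bhi - blo
    sub_bands = [(blo + 0.05 * span, blo + 0.37 * span),
                 (blo + 0.48 * span, blo + 0.82 * span)]
    ctx_band = dict(zip(envs, rng.permutation(2)))
    slot_band = dict(zip((0, 1), rng.permutation(2)))
    # the HC-EC driver is a subject-specific theta rhythm: a narrow tone
    # whose coherence concentrates at one frequency instead of smearing
    # over the band
    # kept low in the band so wavelet bandwidth does not carry driver
    # coherence across the 8 Hz boundary
    f0 = rng.uniform(3.0, 4.2)
    driver_band = (f0 - 0.4, f0 + 0.4)
    lag_s = cfg.driver_lag_s if cfg.driver_lag_s is not None else 0.25 / f0
    pc = cfg.pattern_contrast
    u_ctx = rng.choice([-1.0, 1.0], len(hc_idx))
    u_obj = rng.choice([-1.0, 1.0], len(ec_idx))
    w_ctx = {"square": 1.0 + pc * u_ctx, "circle": 1.0 - pc * u_ctx}
    w_obj_slot = {0: 1.0 + pc * u_obj, 1: 1.0 - pc * u_obj}
    # DC offsets are keyed by environment and by within-session object slot
    # (first/second object), the binary factors of the selectivity screen
    dc_ctx = {(int(ci), env): rng.normal(0.0, cfg.selectivity_offset_sd)
              for ci in roi_idx for env in envs}
    dc_obj = {(int(ci), slot): rng.normal(0.0, cfg.selectivity_offset_sd)
              for ci in roi_idx for slot in (0, 1)}

    lag = int(round(lag_s * rate))
    delay = int(round(cfg.object_code_delay_s * rate))
    a_hc = cfg.driver_amp_hc * cfg.noise_rms
    a_ec = cfg.driver_amp_ec * cfg.noise_rms
    kap, lam, jit = (cfg.coupling_strength, cfg.shared_gain_weight,
                     cfg.trial_strength_jitter)

    main_tr = (segments[segments["state"] == "translation"]
               .sort_values("duration").groupby("trial_id").last())

    for _, tr in test.iterrows():
        tid = int(tr["trial_id"])
        seg = main_tr.loc[tid]
        i0 = int(round((seg["onset"] + head_pad) * rate))
        ns = int(round(seg["duration"] * rate))
        taper = sps.windows.tukey(ns, alpha=0.2)
        g, c = tr["g"], tr["c"]
        env, obj = tr["environment"], tr["object"]

        driver = _fm_oscillation(ns + lag, rate, driver_band, rng)
        drv_hc = driver[lag:] * taper          # HC leads ...
        drv_ec = driver[:ns] * taper           # ... EC lags by driver_lag_s

        # the driver rides on the same channel patterns as the codes (it
        # entrains the code-expressing assembly), so stronger coupling
        # sharpens rather than masks the spatial pattern
        amp_ctx = cfg.context_code_snr * cfg.noise_rms * (1.0 + lam * g)
        band_hc = sub_bands[ctx_band[env]]
        for k, ci in enumerate(hc_idx):
            w = w_ctx[env][k] * (1.0 + jit * rng.normal())
            carrier = _fm_oscillation(ns, rate, band_hc, rng) * taper
            volt[ci, i0:i0 + ns] += w * (amp_ctx * carrier + a_hc * drv_hc)

        amp_obj = (cfg.object_code_snr * cfg.noise_rms
                   * (1.0 + lam * g) * (1.0 + kap * c))
        b_ec = a_ec * kap * min(max(1.0 + c, 0.0), 2.2)
        slot = int(tr["object_slot"])
        band_ec = sub_bands[slot_band[slot]]
        for k, ci in enumerate(ec_idx):
            w = w_obj_slot[slot][k] * (1.0 + jit * rng.normal())
            carrier = _fm_oscillation(ns, rate, band_ec, rng) * taper
            j0 = i0 + delay
            ns_d = ns - delay
            if ns_d > 0:
                volt[ci, j0:j0 + ns_d] += amp_obj * w * carrier[:ns_d]
            volt[ci, i0:i0 + ns] += w * b_ec * drv_ec

        # whole-trial DC offsets for the voltage-based selectivity screen
        t0 = int(round((tr["trial_onset_s"] + head_pad) * rate))
        t1 = int(round((tr["trial_end_s"] + head_pad) * rate))
        slot = int(tr["object_slot"])
        for ci in roi_idx:
            volt[ci, t0:t1] += dc_ctx[(int(ci), env)] + dc_obj[(int(ci), slot)]

    # occasional large transients
    n_art = rng.poisson(cfg.artifact_rate * dur / 60.0)
    for _ in range(n_art):
        ci = int(rng.integers(0, n_ch))
        at = int(rng.integers(0, n - int(0.3 * rate)))
        span = int(rng.uniform(0.1, 0.3) * rate)
        volt[ci, at:at + span] += rng.choice([-1.0, 1.0]) * rng.uniform(6, 10) * cfg.noise_rms

    meta = dict(seed=seed, config_digest=cfg.digest(), head_pad_s=head_pad)
    return Recording(voltage=volt, rate=rate, channels=channels, meta=meta)


# ---------------------------------------------------------------------------
# subject-level convenience
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    subject_id: str
    trials: pd.DataFrame
    segments: pd.DataFrame
    recording: Recording
    head_pad_s: float


def simulate_subject(task: TaskConfig, cfg: NeuralSimConfig, subject_id: str,
                     seed: int, schedule: pd.DataFrame | None = None) -> SubjectData:
    """Schedule -> trajectories/behavior -> LFP for one subject."""
    if schedule is None:
        schedule = generate_schedule(task)
    ss = np.random.SeedSequence(seed)
    s_beh, s_lfp = ss.spawn(2)
    segments, trials = simulate_trajectories(
        schedule, task, cfg, seed=int(s_beh.generate_state(1)[0] % (2**31)))
    rec = simulate_ieeg(trials, segments, cfg,
                        seed=int(s_lfp.generate_state(1)[0] % (2**31)))
    trials = trials.copy()
    trials["subject_id"] = subject_id
    return SubjectData(subject_id=subject_id, trials=trials, segments=segments,
                       recording=rec, head_pad_s=rec.meta["head_pad_s"])
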