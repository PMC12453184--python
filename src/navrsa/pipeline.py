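"""End-to-end orchestration of the synthetic study.

``run_subject`` carries one simulated subject through preprocessing, epoch
extraction, electrode screening, time-frequency decomposition, RSA
contrasts, band jackknife, trial-level strengths and HC-EC coherence;
``run_study`` loops subjects and collects the group-level matrices that the
statistical tests consume.  All stages receive explicit seeds derived from
the study seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import bandcontrib, behavior, connectivity, coordination, preprocess, rsa, spectral
from .containers import Recording
from .synth import NeuralSimConfig, SubjectData, TaskConfig, generate_schedule, simulate_subject

BANDS = ("low", "mid", "high")


@dataclass
class RunConfig:
    """Analysis-side switches and parameters (generator settings live in
    :class:`navrsa.synth.NeuralSimConfig`)."""

    rois: tuple[str, ...] = ("HC", "EC")
    trial_filter: str = "good"            # good | all | bad
    electrode_filter: str = "task_selective"  # task_selective | all
    epoch_kind: str = "translation"
    strict_epochs: bool = False
    scheme: rsa.WindowScheme = field(default_factory=rsa.WindowScheme)
    grid: spectral.FrequencyGrid = field(default_factory=spectral.make_grid)
    n_permutations: int = 1000
    strength_window: tuple[float, float] = (0.65, 0.80)
    coherence_shuffles: int = 1000
    conjunction_alpha: float = 0.001
    chance_threshold: float | None = None  # computed when None
    run_jackknife: bool = True
    run_coherence: bool = True


@dataclass
class SubjectResult:
    subject_id: str
    trials: pd.DataFrame
    contrasts: dict = field(default_factory=dict)     # (region, kind) -> ContrastSeries
    reductions: dict = field(default_factory=dict)    # (region, kind, band) -> ndarray
    strengths: dict = field(default_factory=dict)     # region -> StrengthMatrix
    cross_z: np.ndarray | None = None
    lag_matrix: np.ndarray | None = None
    coh_table: pd.DataFrame | None = None  # trial_id + z coherence per band
    n_selected: dict = field(default_factory=dict)
    n_epochs: dict = field(default_factory=dict)

    def strength_at(self, region: str, window_idx: np.ndarray,
                    trial_ids: np.ndarray) -> np.ndarray:
        """Strengths averaged over a window interval, aligned to trial ids
        (NaN where a trial has no strength estimate)."""
        sm = self.strengths[region]
        tid_to_row = {t: i for i, t in enumerate(sm.trial_ids)}
        out = np.full(len(trial_ids), np.nan)
        for k, t in enumerate(trial_ids):
            if t in tid_to_row:
                vals = sm.values[tid_to_row[t], window_idx]
                if np.isfinite(vals).any():
                    out[k] = np.nanmean(vals)
        return out


def _epoch_keep(epochs, region: str, trial_filter: str) -> np.ndarray:
    keep = epochs.keep(region)
    good = epochs.table["is_good"].to_numpy()
    if trial_filter == "good":
        keep = keep & good
    elif trial_filter == "bad":
        keep = keep & ~good
    elif trial_filter != "all":
        raise ValueError(f"unknown trial filter {trial_filter!r}")
    return keep


def run_subject(sub: SubjectData, run_cfg: RunConfig, threshold: float,
                seed: int) -> SubjectResult:
    """Full single-subject analysis; see the module docstring."""
    rng = np.random.default_rng(seed)
    rec = preprocess.rereference(sub.recording)
    rec = preprocess.notch(rec)
    rec = preprocess.detect_artifacts(rec)

    trials = behavior.classify_trials(sub.trials, threshold)
    epochs = preprocess.extract_epochs(
        rec, sub.segments, trials, kind=run_cfg.epoch_kind,
        roi_regions=run_cfg.rois, strict=run_cfg.strict_epochs,
        head_pad_s=sub.head_pad_s)

    # voltage-based conjunction screening, all test-trial epochs
    ctx_lab = epochs.table["environment"].to_numpy()
    obj_lab = epochs.table["object_slot"].to_numpy()  # binary across sessions
    sel_channels: dict[str, np.ndarray] = {}
    for region in run_cfg.rois:
        ch_idx = rec.channel_indices(region)
        if run_cfg.electrode_filter == "all":
            sel_channels[region] = ch_idx
            continue
        flags = rsa.select_task_electrodes(
            epochs.data[:, ch_idx, :], ctx_lab, obj_lab,
            alpha=run_cfg.conjunction_alpha)
        if not flags.any():
            warnings.warn(f"no task-selective channels in {region}; using all")
            flags[:] = True
        sel_channels[region] = ch_idx[flags]

    all_ch = np.concatenate([sel_channels[r] for r in run_cfg.rois])
    win_samp = int(round(run_cfg.scheme.epoch_s * rec.rate))
    tf = spectral.compute_epoch_tfr(rec, epochs.onset_samples, win_samp,
                                    run_cfg.grid, all_ch,
                                    keep_coeffs=run_cfg.run_coherence)
    col_of = {ch: i for i, ch in enumerate(all_ch)}

    res = SubjectResult(subject_id=sub.subject_id, trials=trials)
    sims: dict[str, rsa.SimilarityTensor] = {}
    region_keep: dict[str, np.ndarray] = {}
    for region in run_cfg.rois:
        keep = _epoch_keep(epochs, region, run_cfg.trial_filter)
        region_keep[region] = keep
        res.n_epochs[region] = int(keep.sum())
        res.n_selected[region] = len(sel_channels[region])
        cols = [col_of[c] for c in sel_channels[region]]
        zp = tf.z_power[np.ix_(np.flatnonzero(keep), cols)]
        sim = rsa.pairwise_similarity(zp, epochs.table[keep].reset_index(drop=True),
                                      run_cfg.scheme)
        sims[region] = sim
        for kind in ("context", "object"):
            res.contrasts[(region, kind)] = rsa.contrast(sim, kind)
        if run_cfg.run_jackknife:
            kind = "context" if region == "HC" else "object"
            full = res.contrasts[(region, kind)]
            for band in BANDS:
                res.reductions[(region, kind, band)] = bandcontrib.jackknife_reduction(
                    zp, sim.epochs, run_cfg.scheme, run_cfg.grid, kind, band,
                    full_contrast=full)

    # trial-level strengths and HC-EC coordination
    if "HC" in sims and "EC" in sims:
        hc_str = coordination.loto_strength(sims["HC"], "context")
        ec_str = coordination.loto_strength(sims["EC"], "object")
        res.strengths = {"HC": hc_str, "EC": ec_str}
        res.cross_z = coordination.cross_trial_correlation(hc_str, ec_str,
                                                           good_only=False)
        res.lag_matrix = coordination.lagged_correlation(hc_str, ec_str,
                                                         good_only=False)
        if run_cfg.run_coherence:
            both = region_keep["HC"] & region_keep["EC"]
            rows = np.flatnonzero(both)
            if len(rows) >= 10:
                hemis = rec.channels["hemisphere"].to_numpy()
                cols_hc = [col_of[c] for c in sel_channels["HC"]]
                cols_ec = [col_of[c] for c in sel_channels["EC"]]
                coh = connectivity.subject_coherence(
                    tf.coeffs[np.ix_(rows, cols_hc)],
                    tf.coeffs[np.ix_(rows, cols_ec)],
                    hemis[sel_channels["HC"]], hemis[sel_channels["EC"]],
                    epochs.table["session"].to_numpy()[rows],
                    run_cfg.grid, n_shuffles=run_cfg.coherence_shuffles,
                    rng=rng)
                coh.insert(0, "trial_id", epochs.table["trial_id"].to_numpy()[rows])
                res.coh_table = coh
    return res


@dataclass
class StudyResult:
    subjects: list[SubjectResult]
    threshold: float
    task: TaskConfig
    sim_cfg: NeuralSimConfig
    run_cfg: RunConfig

    def contrast_matrix(self, region: str, kind: str) -> np.ndarray:
        return np.stack([s.contrasts[(region, kind)].difference
                         for s in self.subjects])

    def reduction_matrix(self, region: str, kind: str, band: str) -> np.ndarray:
        return np.stack([s.reductions[(region, kind, band)]
                         for s in self.subjects])

    def cross_trial_matrix(self) -> np.ndarray:
        return np.stack([s.cross_z for s in self.subjects
                         if s.cross_z is not None])

    def behavior_table(self) -> pd.DataFrame:
        return pd.concat([s.trials for s in self.subjects], ignore_index=True)

    def derive_strength_window(self, n_perm: int | None = None,
                               rng=0) -> np.ndarray:
        """Window interval for trial-level strength averaging.

        Mirrors the two-step logic of the analysis: the interval is the
        largest significant cluster of the group cross-trial HC-EC strength
        correlation (sign-flip permutation test); when no cluster reaches
        significance, the configured default interval is used.
        """
        from .stats import cluster_perm_signflip

        scheme = self.run_cfg.scheme
        fallback = scheme.window_interval(*self.run_cfg.strength_window)
        X = self.cross_trial_matrix()
        if len(X) < 2:
            return fallback
        ct = cluster_perm_signflip(np.nan_to_num(X),
                                   n_perm=n_perm or self.run_cfg.n_permutations,
                                   rng=rng)
        sig = ct.significant(0.05)
        if not sig:
            return fallback
        best = max(sig, key=lambda c: c["mass"])
        return np.arange(best["start"], best["stop"])

    def coherence_strength_z(self, kind: str,
                             window_idx: np.ndarray | None = None
                             ) -> pd.DataFrame:
        """Subject x band Fisher-z correlations between trial coherence and
        representation strength (HC context or EC object).

        Strengths are averaged over the configured ``strength_window``
        (0.65-0.80 s by default) unless an explicit window interval is
        given; ``derive_strength_window`` can supply a data-driven interval
        where the cross-trial coupling is temporally localized.
        """
        region = "HC" if kind == "context" else "EC"
        if window_idx is None:
            window_idx = self.run_cfg.scheme.window_interval(
                *self.run_cfg.strength_window)
        rows = {}
        for s in self.subjects:
            if s.coh_table is None or region not in s.strengths:
                continue
            tids = s.coh_table["trial_id"].to_numpy()
            strength = s.strength_at(region, window_idx, tids)
            keep = np.isfinite(strength)
            if keep.sum() < 3:
                continue
            bands = s.coh_table.drop(columns="trial_id")
            rows[s.subject_id] = connectivity.coherence_strength_correlation(
                bands, strength, keep)
        return pd.DataFrame(rows).T


def run_study(n_subjects: int, task: TaskConfig | None = None,
              sim_cfg: NeuralSimConfig | None = None,
              run_cfg: RunConfig | None = None, seed: int = 0,
              progress: bool = False) -> StudyResult:
    task = task or TaskConfig()
    sim_cfg = sim_cfg or NeuralSimConfig()
    run_cfg = run_cfg or RunConfig()
    schedule = generate_schedule(task)
    if run_cfg.chance_threshold is None:
        thr = behavior.chance_threshold(objects=task.object_positions,
                                        seed=seed).threshold
    else:
        thr = run_cfg.chance_threshold
    ss = np.random.SeedSequence(seed)
    results = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        s_sim, s_ana = (int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(2))
        sub = simulate_subject(task, sim_cfg, f"sub{i + 1:02d}", s_sim,
                               schedule=schedule)
        results.append(run_subject(sub, run_cfg, thr, s_ana))
        if progress:
            print(f"  subject {i + 1}/{n_subjects} done")
    return StudyResult(subjects=results, threshold=thr, task=task,
                       sim_cfg=sim_cfg, run_cfg=run_cfg)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """YAML study configuration -> keyword dicts for ``run``.

    Recognized top-level keys: ``n_subjects``, ``seed``, ``task`` (TaskConfig
    fields), ``sim`` (NeuralSimConfig fields), ``analysis`` (RunConfig
    fields).  Unknown fields raise, so typos do not silently fall back to
    defaults.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"n_subjects", "seed", "task", "sim", "analysis"}
    extra = set(raw) - known
    if extra:
        raise ValueError(f"unknown config keys: {sorted(extra)}")
    return raw


def run(config: dict | str | Path, out_dir, progress: bool = False
        ) -> StudyResult:
    """Execute a configured synthetic study end to end and write the
    report bundle (group contrast curves, cluster statistics, jackknife
    reductions, coherence-strength correlations) under ``out_dir``."""
    import json as _json

    from .connectivity import group_band_correlation
    from .stats import cluster_perm_label, cluster_perm_signflip

    if not isinstance(config, dict):
        config = load_config(config)
    task = TaskConfig(**config.get("task", {}))
    sim_cfg = NeuralSimConfig(**config.get("sim", {}))
    analysis = dict(config.get("analysis", {}))
    if "scheme" in analysis:
        analysis["scheme"] = rsa.WindowScheme(**analysis["scheme"])
    run_cfg = RunConfig(**analysis)
    seed = int(config.get("seed", 0))
    study = run_study(int(config.get("n_subjects", 12)), task=task,
                      sim_cfg=sim_cfg, run_cfg=run_cfg, seed=seed,
                      progress=progress)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_summary(out_dir / "summary.json", study)
    write_trials(out_dir / "trials.tsv", study.behavior_table())

    report: dict = {"seed": seed, "threshold": study.threshold,
                    "config_digest": sim_cfg.digest(), "clusters": {},
                    "jackknife": {}, "coherence": {}}
    for region in run_cfg.rois:
        for kind in ("context", "object"):
            A = np.stack([s.contrasts[(region, kind)].mean_same
                          for s in study.subjects])
            B = np.stack([s.contrasts[(region, kind)].mean_diff
                          for s in study.subjects])
            ct = cluster_perm_label(A, B, n_perm=run_cfg.n_permutations,
                                    rng=seed + 1)
            report["clusters"][f"{region}-{kind}"] = dict(
                min_p=ct.min_p, clusters=ct.clusters)
    if run_cfg.run_jackknife:
        for region, kind in (("HC", "context"), ("EC", "object")):
            for band in BANDS:
                R = np.stack([s.reductions[(region, kind, band)]
                              for s in study.subjects])
                ct = cluster_perm_signflip(R, n_perm=run_cfg.n_permutations,
                                           rng=seed + 2)
                report["jackknife"][f"{region}-{band}"] = dict(
                    mean=float(R.mean()), min_p=ct.min_p)
    if run_cfg.run_coherence:
        for kind in ("object", "context"):
            Z = study.coherence_strength_z(kind)
            if len(Z):
                g = group_band_correlation(Z)
                report["coherence"][kind] = {
                    b: dict(mean_z=float(g.loc[b, "mean_z"]),
                            p=float(g.loc[b, "p"]),
                            p_fdr=float(g.loc[b, "p_fdr"])) for b in g.index}
    (out_dir / "report.json").write_text(_json.dumps(report, indent=2,
                                                     default=float))
    return study


def write_recording(path, rec: Recording) -> None:
    """Recording -> HDF5 (voltage, mask, rate) + TSV channel table sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("voltage", data=rec.voltage, compression="gzip")
        f.attrs["rate"] = rec.rate
        for k, v in rec.meta.items():
            if isinstance(v, (int, float, str)):
                f.attrs[k] = v
        if rec.artifact_mask is not None:
            f.create_dataset("artifact_mask", data=rec.artifact_mask,
                             compression="gzip")
    rec.channels.to_csv(path.with_suffix(".channels.tsv"), sep="\t", index=False)


def read_recording(path) -> Recording:
    path = Path(path)
    ch_path = path.with_suffix(".channels.tsv")
    if not ch_path.exists():
        raise ValueError(f"missing channel table sidecar {ch_path}")
    channels = pd.read_csv(ch_path, sep="\t")
    for col in ("id", "region", "hemisphere"):
        if col not in channels.columns:
            raise ValueError(f"channel table lacks required column {col!r}")
    with h5py.File(path, "r") as f:
        volt = f["voltage"][()]
        rate = float(f.attrs["rate"])
        mask = f["artifact_mask"][()] if "artifact_mask" in f else None
        meta = {k: v for k, v in f.attrs.items() if k != "rate"}
    return Recording(voltage=volt, rate=rate, channels=channels,
                     artifact_mask=mask, meta=dict(meta))


def write_trials(path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def import_edf(path, channel_table: pd.DataFrame, target_rate: float = 500.0
               ) -> Recording:
    """Optional EDF import; channel metadata must be supplied alongside."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    volt = raw.get_data() * 1e6  # volts -> microvolts
    names = raw.ch_names
    table = channel_table.set_index("id").reindex(names).reset_index()
    if table["region"].isna().any():
        missing = table.loc[table["region"].isna(), "id"].tolist()
        raise ValueError(f"no region metadata for channels {missing}")
    rec = Recording(voltage=volt, rate=float(raw.info["sfreq"]), channels=table)
    if rec.rate > target_rate:
        rec = preprocess.downsample(rec, target_rate)
    return rec


def save_summary(path, study: StudyResult) -> None:
    """Small JSON digest of a study run (group curves and counts)."""
    out = dict(
        threshold=study.threshold,
        n_subjects=len(study.subjects),
        centers_s=study.run_cfg.scheme.centers_s.tolist(),
        contrasts={f"{r}-{k}": study.contrast_matrix(r, k).mean(axis=0).tolist()
                   for r in study.run_cfg.rois for k in ("context", "object")},
    )
    Path(path).write_text(json.dumps(out, indent=2))
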