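"""Sliding-window spectral representational similarity analysis.

Each 2-s epoch is segmented into overlapping windows (500 ms / 50 ms by
default, 31 windows); within a window, the z-power over frequencies x time
points x channels is flattened into one vector per epoch, and Spearman
correlations between all within-session epoch pairs are Fisher-z
transformed.  Same/Different contrasts over context (environment) or object
labels quantify the representations; a 4 x 4 matrix over (environment x
object) categories summarizes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .stats import clip_rho

FULL_EPOCH_SAMPLES = 1000  # 2 s at 500 Hz


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window bookkeeping over a fixed-length epoch."""

    width_ms: float = 500.0
    step_ms: float = 50.0
    epoch_s: float = 2.0
    rate: float = 500.0

    @property
    def win_samples(self) -> int:
        return int(round(self.width_ms / 1000.0 * self.rate))

    @property
    def step_samples(self) -> int:
        return int(round(self.step_ms / 1000.0 * self.rate))

    @property
    def n_windows(self) -> int:
        total = int(round(self.epoch_s * self.rate))
        return (total - self.win_samples) // self.step_samples + 1

    def slices(self) -> list[slice]:
        return [slice(w * self.step_samples, w * self.step_samples + self.win_samples)
                for w in range(self.n_windows)]

    @property
    def centers_s(self) -> np.ndarray:
        starts = np.arange(self.n_windows) * self.step_samples
        return (starts + self.win_samples / 2.0) / self.rate

    def window_interval(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Indices of windows whose centers fall inside [t_lo, t_hi]."""
        c = self.centers_s
        return np.flatnonzero((c >= t_lo - 1e-9) & (c <= t_hi + 1e-9))


def select_task_electrodes(epoch_voltage: np.ndarray, context_labels,
                           object_labels, alpha: float = 0.001) -> np.ndarray:
    """Conjunction screen on raw voltage: a channel is task-selective when
    two-sample t-tests of its pooled epoch samples split by context AND by
    object are both significant at ``alpha``."""
    ctx = np.asarray(context_labels)
    obj = np.asarray(object_labels)
    flags = np.zeros(epoch_voltage.shape[1], dtype=bool)
    for labels in (ctx, obj):
        levels = np.unique(labels)
        if len(levels) != 2 or min((labels == lv).sum() for lv in levels) < 2:
            raise ValueError("need two label levels with >= 2 epochs each")
    for ch in range(epoch_voltage.shape[1]):
        x = epoch_voltage[:, ch, :]
        ok = True
        for labels in (ctx, obj):
            levels = np.unique(labels)
            a = x[labels == levels[0]].ravel()
            b = x[labels == levels[1]].ravel()
            _, p = sstats.ttest_ind(a, b, equal_var=False)
            if not p < alpha:
                ok = False
                break
        flags[ch] = ok
    return flags


def window_matrix(z_power: np.ndarray, scheme: WindowScheme, window: int,
                  freq_idx: np.ndarray | None = None) -> np.ndarray:
    """Flattened feature matrix (epochs, freqs * win_samples * channels)
    for one window."""
    sl = scheme.slices()[window]
    sub = z_power[:, :, :, sl] if freq_idx is None else z_power[:, :, freq_idx, sl]
    return sub.reshape(sub.shape[0], -1)


def build_vectors(z_power: np.ndarray, scheme: WindowScheme,
                  freq_idx: np.ndarray | None = None) -> np.ndarray:
    """All window vectors, (epochs, n_windows, D).  Convenience wrapper; the
    similarity computation streams one window at a time instead."""
    if z_power.shape[1] == 0:
        raise ValueError("empty channel set")
    return np.stack([window_matrix(z_power, scheme, w, freq_idx)
                     for w in range(scheme.n_windows)], axis=1)


@dataclass
class SimilarityTensor:
    """Fisher-z Spearman similarity for every within-session epoch pair."""

    z: np.ndarray            # (n_pairs, n_windows); NaN where undefined
    pair_i: np.ndarray
    pair_j: np.ndarray
    session: np.ndarray      # session label per pair
    epochs: pd.DataFrame     # per-epoch labels: session, environment, object, ...
    scheme: WindowScheme = field(default_factory=WindowScheme)

    @property
    def n_pairs(self) -> int:
        return self.z.shape[0]

    def pair_labels(self, column: str) -> tuple[np.ndarray, np.ndarray]:
        lab = self.epochs[column].to_numpy()
        return lab[self.pair_i], lab[self.pair_j]


def pairwise_similarity(z_power: np.ndarray, epochs: pd.DataFrame,
                        scheme: WindowScheme | None = None,
                        freq_idx: np.ndarray | None = None) -> SimilarityTensor:
    """Spearman rho between window vectors of all within-session epoch
    pairs, Fisher-z transformed.

    Spearman is computed as the Pearson correlation of average ranks, so
    ties are handled exactly; a constant (zero-variance) vector makes every
    pair involving it undefined (NaN) in that window.
    """
    scheme = scheme or WindowScheme(rate=z_power.shape[-1] / 2.0)
    sessions = epochs["session"].to_numpy()
    n_ep = z_power.shape[0]
    if n_ep < 2:
        raise ValueError("need at least two epochs")
    pair_i, pair_j = np.triu_indices(n_ep, k=1)
    within = sessions[pair_i] == sessions[pair_j]
    pair_i, pair_j = pair_i[within], pair_j[within]
    if len(pair_i) == 0:
        raise ValueError("no within-session epoch pairs")

    z = np.empty((len(pair_i), scheme.n_windows), dtype=np.float32)
    for w in range(scheme.n_windows):
        M = window_matrix(z_power, scheme, w, freq_idx)
        R = sstats.rankdata(M, axis=1).astype(np.float64)
        R -= R.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(R, axis=1)
        valid = norms > 0
        R[valid] /= norms[valid, None]
        C = R @ R.T
        rho = C[pair_i, pair_j]
        bad = ~(valid[pair_i] & valid[pair_j])
        zz = np.arctanh(clip_rho(rho))
        zz[bad] = np.nan
        z[:, w] = zz
    return SimilarityTensor(z=z, pair_i=pair_i, pair_j=pair_j,
                            session=sessions[pair_i], epochs=epochs,
                            scheme=scheme)


@dataclass
class ContrastSeries:
    """Per-window Same/Different means for one subject, averaged over
    sessions; ``difference = mean_same - mean_diff``."""

    kind: str
    mean_same: np.ndarray
    mean_diff: np.ndarray
    centers_s: np.ndarray

    @property
    def difference(self) -> np.ndarray:
        return self.mean_same - self.mean_diff


_KIND_COLUMN = {"context": "environment", "object": "object"}


def contrast(sim: SimilarityTensor, kind: str) -> ContrastSeries:
    """Same-minus-Different label contrast, within session then averaged."""
    col = _KIND_COLUMN[kind]
    li, lj = sim.pair_labels(col)
    same = li == lj
    per_session_same, per_session_diff = [], []
    for sess in np.unique(sim.session):
        in_s = sim.session == sess
        if not (same & in_s).any() or not (~same & in_s).any():
            warnings.warn(f"session {sess} lacks Same or Different {kind} "
                          "pairs and is skipped")
            continue
        per_session_same.append(np.nanmean(sim.z[same & in_s], axis=0))
        per_session_diff.append(np.nanmean(sim.z[~same & in_s], axis=0))
    if not per_session_same:
        raise ValueError(f"no session has both Same and Different {kind} pairs")
    return ContrastSeries(kind=kind,
                          mean_same=np.mean(per_session_same, axis=0),
                          mean_diff=np.mean(per_session_diff, axis=0),
                          centers_s=sim.scheme.centers_s)


def rsm4(sim: SimilarityTensor, window_idx: np.ndarray) -> pd.DataFrame:
    """4 x 4 category-averaged similarity over (environment x object) cells
    within the supplied window interval; self-pairs are never present and
    cells with no pairs are NaN."""
    env_i, env_j = sim.pair_labels("environment")
    obj_i, obj_j = sim.pair_labels("object")
    cats = sorted(set(zip(sim.epochs["environment"], sim.epochs["object"])))
    zwin = np.nanmean(sim.z[:, window_idx], axis=1)
    mat = pd.DataFrame(index=pd.MultiIndex.from_tuples(cats),
                       columns=pd.MultiIndex.from_tuples(cats), dtype=float)
    for a in cats:
        for b in cats:
            sel = (((env_i == a[0]) & (obj_i == a[1]) & (env_j == b[0]) & (obj_j == b[1]))
                   | ((env_i == b[0]) & (obj_i == b[1]) & (env_j == a[0]) & (obj_j == a[1])))
            mat.loc[a, b] = float(np.nanmean(zwin[sel])) if sel.any() else np.nan
    return mat
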