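"""Cross-time imaginary coherence between hippocampal and entorhinal
channels, surrogate z-scoring, and trial-level coupling with representation
strength.

The imaginary coherence |Im(Sxy)| / sqrt(Sxx * Syy) over the 2-s epoch is
insensitive to zero-phase-lag (volume-conducted) coupling.  Per-trial values
are z-scored against a surrogate distribution obtained by re-pairing one
electrode's epochs with a random permutation of the other's (within
session), then averaged over ipsilateral HC-EC pairs and over the grid
points of each frequency band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .spectral import FrequencyGrid
from .stats import bh_fdr, clip_rho

BAND_NAMES = ("low", "mid", "high")


def imag_coherence(wx: np.ndarray, wy: np.ndarray) -> np.ndarray:
    """Imaginary coherence per frequency from complex wavelet coefficients.

    ``wx``/``wy`` are ``(n_freqs, n_times)`` coefficients of the same epoch;
    the cross- and auto-spectra are summed over the epoch.  Values lie in
    [0, 1]; identical inputs give exactly 0 (purely real cross-spectrum).
    Frequencies with a zero auto-spectrum return NaN.
    """
    wx = np.asarray(wx)
    wy = np.asarray(wy)
    sxy = np.sum(wx * np.conj(wy), axis=-1)
    sxx = np.sum(np.abs(wx) ** 2, axis=-1)
    syy = np.sum(np.abs(wy) ** 2, axis=-1)
    denom = np.sqrt(sxx * syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, np.abs(np.imag(sxy)) / denom, np.nan)
    return out


def _normalized_cross(wx: np.ndarray, wy: np.ndarray) -> np.ndarray:
    """V[f, i, j] = |Im sum_t Wx[i,f,t] conj(Wy[j,f,t])| / sqrt(Pxx_i Pyy_j)
    for all epoch pairs (i, j) of one electrode pair."""
    E, F, _ = wx.shape
    pxx = np.sum(np.abs(wx) ** 2, axis=-1)  # (E, F)
    pyy = np.sum(np.abs(wy) ** 2, axis=-1)
    V = np.empty((F, E, E))
    for f in range(F):
        C = wx[:, f, :] @ np.conj(wy[:, f, :]).T
        denom = np.sqrt(np.outer(pxx[:, f], pyy[:, f]))
        with np.errstate(invalid="ignore", divide="ignore"):
            V[f] = np.where(denom > 0, np.abs(np.imag(C)) / denom, np.nan)
    return V


def zscore_coherence(wx: np.ndarray, wy: np.ndarray, sessions: np.ndarray,
                     n_shuffles: int = 1000,
                     rng: np.random.Generator | int | None = None
                     ) -> np.ndarray:
    """Surrogate-z-scored per-trial imaginary coherence for one pair.

    The observed value of trial i re-uses its own epoch on both electrodes;
    each surrogate re-pairs electrode x's epochs with a uniformly random
    within-session permutation of electrode y's epochs.  Returns
    ``(n_epochs, n_freqs)``; NaN where the surrogate SD vanishes.
    """
    rng = np.random.default_rng(rng)
    E = wx.shape[0]
    if E < 10:
        raise ValueError("need at least 10 trials for surrogate z-scoring")
    V = _normalized_cross(wx, wy)  # (F, E, E)
    obs = V[:, np.arange(E), np.arange(E)].T  # (E, F)

    perms = np.empty((n_shuffles, E), dtype=int)
    sessions = np.asarray(sessions)
    for sess in np.unique(sessions):
        idx = np.flatnonzero(sessions == sess)
        for k in range(n_shuffles):
            perms[k, idx] = idx[rng.permutation(len(idx))]
    # gather surrogate values: (F, n_shuffles, E)
    vals = V[:, np.arange(E)[None, :], perms]
    mu = vals.mean(axis=1).T  # (E, F)
    sd = vals.std(axis=1).T
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, (obs - mu) / sd, np.nan)


def subject_coherence(coeffs_hc: np.ndarray, coeffs_ec: np.ndarray,
                      hemis_hc, hemis_ec, sessions: np.ndarray,
                      grid: FrequencyGrid, n_shuffles: int = 1000,
                      rng: np.random.Generator | int | None = None,
                      bands: tuple[str, ...] = BAND_NAMES) -> pd.DataFrame:
    """Trial x band table of z-scored HC-EC imaginary coherence.

    ``coeffs_*`` are ``(epochs, channels, freqs, times)`` complex wavelet
    coefficients; pairs are restricted to same-hemisphere HC-EC channel
    combinations and averaged within subject, then over each band's grid
    points.
    """
    rng = np.random.default_rng(rng)
    hemis_hc = np.asarray(hemis_hc)
    hemis_ec = np.asarray(hemis_ec)
    pair_z = []
    for a, ha in enumerate(hemis_hc):
        for b, hb in enumerate(hemis_ec):
            if ha != hb:
                continue
            pair_z.append(zscore_coherence(coeffs_hc[:, a], coeffs_ec[:, b],
                                           sessions, n_shuffles, rng))
    if not pair_z:
        raise ValueError("no ipsilateral HC-EC channel pairs")
    z = np.nanmean(pair_z, axis=0)  # (epochs, freqs)
    out = {}
    for band in bands:
        idx = grid.band_indices(band)
        out[band] = np.nanmean(z[:, idx], axis=1)
    return pd.DataFrame(out)


def coherence_strength_correlation(coh_bands: pd.DataFrame,
                                   strength: np.ndarray,
                                   keep: np.ndarray | None = None
                                   ) -> pd.Series:
    """Per-band Fisher-z Spearman correlation between trial coherence and
    trial representation strength for one subject."""
    strength = np.asarray(strength, dtype=float)
    if keep is None:
        keep = np.ones(len(strength), dtype=bool)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 trials")
    out = {}
    for band in coh_bands.columns:
        rho = sstats.spearmanr(coh_bands[band].to_numpy()[keep],
                               strength[keep]).statistic
        out[band] = np.arctanh(clip_rho(rho)) if np.isfinite(rho) else np.nan
    return pd.Series(out)


def group_band_correlation(subject_z: pd.DataFrame,
                           one_tailed_bands: tuple[str, ...] = ("low",),
                           q: float = 0.05) -> pd.DataFrame:
    """Group t-test of the Fisher-z correlations against zero per band.

    One-tailed (positive) for the hypothesized low-frequency band,
    two-tailed elsewhere; Benjamini-Hochberg correction across bands.
    """
    rows = []
    for band in subject_z.columns:
        vals = subject_z[band].dropna().to_numpy()
        t, p2 = sstats.ttest_1samp(vals, 0.0)
        if band in one_tailed_bands:
            p = p2 / 2.0 if t > 0 else 1.0 - p2 / 2.0
            tail = "greater"
        else:
            p, tail = p2, "two-sided"
        rows.append(dict(band=band, n=len(vals), mean_z=float(vals.mean()),
                         t=float(t), p=float(p), tail=tail))
    df = pd.DataFrame(rows).set_index("band")
    reject, p_adj = bh_fdr(df["p"].to_numpy(), q=q)
    df["p_fdr"] = p_adj
    df["significant"] = reject
    return df
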