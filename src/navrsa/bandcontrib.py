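"""Frequency-band contributions to the similarity contrasts.

A jackknife over frequency bands removes one band's grid points from the
RSA feature vectors, recomputes the Same-Different contrast, and subtracts
it from the full-band contrast; a positive reduction means the removed band
carried representational information.  A robust log-log line fit separates
the aperiodic (1/f) background from periodic (oscillatory) power.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rsa import ContrastSeries, WindowScheme, contrast, pairwise_similarity
from .spectral import FrequencyGrid


def _band_complement(grid: FrequencyGrid, band: str) -> np.ndarray:
    idx = grid.band_indices(band)
    if len(idx) == 0:
        return np.arange(grid.n)
    keep = np.setdiff1d(np.arange(grid.n), idx)
    if len(keep) == 0:
        raise ValueError(f"band {band!r} covers the whole grid")
    return keep


def jackknife_reduction(z_power: np.ndarray, epochs: pd.DataFrame,
                        scheme: WindowScheme, grid: FrequencyGrid,
                        kind: str, band: str,
                        full_contrast: ContrastSeries | None = None
                        ) -> np.ndarray:
    """Per-window representation reduction for one subject:
    (same - diff) with all frequencies minus (same - diff) without ``band``.

    Removing a band with no grid points yields exactly zero."""
    if band not in grid.band_edges:
        raise ValueError(f"unknown band {band!r}")
    if full_contrast is None:
        full_contrast = contrast(pairwise_similarity(z_power, epochs, scheme), kind)
    if len(grid.band_indices(band)) == 0:
        return np.zeros(scheme.n_windows)
    keep = _band_complement(grid, band)
    reduced = contrast(
        pairwise_similarity(z_power, epochs, scheme, freq_idx=keep), kind)
    return full_contrast.difference - reduced.difference


def band_only_rsa(z_power: np.ndarray, epochs: pd.DataFrame,
                  scheme: WindowScheme, grid: FrequencyGrid,
                  kind: str, band: str = "low") -> ContrastSeries:
    """Same-Different contrast computed from one band's grid points only."""
    idx = grid.band_indices(band)
    if len(idx) == 0:
        raise ValueError(f"band {band!r} has no grid points")
    freq_idx = None if len(idx) == grid.n else idx
    return contrast(pairwise_similarity(z_power, epochs, scheme,
                                        freq_idx=freq_idx), kind)


def remove_aperiodic(power: np.ndarray, freqs: np.ndarray,
                     max_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the 1/f background from a spectrogram.

    ``power`` is ``(..., n_freqs, n_times)`` raw (positive) power for one or
    more epochs/channels.  For each leading index, a line is fitted to the
    natural-log time-averaged spectrum against ln(f) by iteratively
    reweighted robust regression (bisquare weights); frequencies sitting
    well above the line (oscillatory peaks) are then excluded and the line
    refitted until stable, so the aperiodic estimate is not dragged up by
    the very oscillations it is meant to isolate.  The fitted line is
    transformed back and subtracted at every time point; negative residuals
    are clipped to zero.

    Returns ``(periodic_power, slopes)`` where ``slopes`` holds the fitted
    aperiodic exponents (the line slopes, typically negative).
    """
    power = np.asarray(power, dtype=float)
    if np.any(power <= 0):
        raise ValueError("power must be strictly positive")
    lead = power.shape[:-2]
    flat = power.reshape(-1, power.shape[-2], power.shape[-1])
    lf = np.log(np.asarray(freqs, dtype=float))
    out = np.empty_like(flat)
    slopes = np.empty(flat.shape[0])
    for i in range(flat.shape[0]):
        logspec = np.log(flat[i].mean(axis=-1))
        keep = np.ones(len(lf), dtype=bool)
        params = None
        for _ in range(5):
            fit = sm.RLM(logspec[keep], sm.add_constant(lf[keep]),
                         M=sm.robust.norms.TukeyBiweight()).fit(maxiter=max_iter)
            params = fit.params
            resid = logspec - (params[0] + params[1] * lf)
            new_keep = resid < max(0.5, np.median(np.abs(resid[keep])) * 3)
            if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
                break
            keep = new_keep
        aper = np.exp(params[0] + params[1] * lf)
        out[i] = np.clip(flat[i] - aper[:, None], 0.0, None)
        slopes[i] = params[1]
    return out.reshape(power.shape), slopes.reshape(lead) if lead else slopes[0]
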