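"""Signal conditioning: decimation, re-referencing, notch filtering,
two-criterion artifact masking, and movement-locked epoch extraction."""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps

from .containers import EpochSet, Recording


def downsample(rec: Recording, target_rate: float = 500.0) -> Recording:
    """Anti-aliased downsampling to ``target_rate``.

    Integer ratios use FIR decimation; rational ratios use polyphase
    resampling.  A target at or above the current rate is returned unchanged
    with a warning.
    """
    if target_rate >= rec.rate:
        warnings.warn("target rate >= current rate; returning recording unchanged")
        return rec.copy()
    ratio = Fraction(rec.rate / target_rate).limit_denominator(1000)
    if ratio.denominator == 1:
        out = sps.decimate(rec.voltage, ratio.numerator, ftype="fir",
                           zero_phase=True, axis=1)
    else:
        frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
        out = sps.resample_poly(rec.voltage, frac.numerator, frac.denominator, axis=1)
    return Recording(voltage=out, rate=target_rate, channels=rec.channels.copy(),
                     meta=dict(rec.meta))


def rereference(rec: Recording) -> Recording:
    """Subtract each channel's reference channel (white-matter referencing)."""
    ids = rec.channels["id"].tolist()
    pos = {cid: i for i, cid in enumerate(ids)}
    out = np.empty_like(rec.voltage)
    for i, ref in enumerate(rec.channels["reference_id"].tolist()):
        if ref is None or (isinstance(ref, float) and np.isnan(ref)):
            out[i] = rec.voltage[i]
            continue
        if ref not in pos:
            raise ValueError(f"reference channel {ref!r} for {ids[i]!r} not found")
        out[i] = rec.voltage[i] - rec.voltage[pos[ref]]
    return Recording(voltage=out, rate=rec.rate, channels=rec.channels.copy(),
                     artifact_mask=None if rec.artifact_mask is None
                     else rec.artifact_mask.copy(), meta=dict(rec.meta))


def notch(rec: Recording,
          bands: tuple = ((48.0, 52.0), (98.0, 102.0), (148.0, 152.0))
          ) -> Recording:
    """Zero-phase band-stop filtering at the line frequency and harmonics."""
    nyq = rec.rate / 2.0
    volt = rec.voltage.astype(np.float64, copy=True)
    for lo, hi in bands:
        if hi >= nyq:
            raise ValueError(f"notch band ({lo}, {hi}) exceeds Nyquist {nyq} Hz")
        sos = sps.butter(4, (lo, hi), btype="bandstop", fs=rec.rate, output="sos")
        volt = sps.sosfiltfilt(sos, volt, axis=1)
    return Recording(voltage=volt, rate=rec.rate, channels=rec.channels.copy(),
                     artifact_mask=None if rec.artifact_mask is None
                     else rec.artifact_mask.copy(), meta=dict(rec.meta))


def detect_artifacts(rec: Recording, amp_sd: float = 4.0,
                     env_band: tuple[float, float] = (25.0, 80.0),
                     env_sd: float = 5.0, pad: float = 0.5) -> Recording:
    """Two-criterion artifact mask, dilated by ``pad`` seconds on each side.

    A sample is flagged when (i) the raw trace deviates from the whole-
    recording channel mean by more than ``amp_sd`` standard deviations, or
    (ii) the analytic-signal envelope of the 25-80 Hz band-passed trace
    exceeds its mean by ``env_sd`` envelope standard deviations.
    """
    if rec.duration < 2.0 * pad:
        raise ValueError("recording shorter than twice the dilation pad")
    volt = rec.voltage
    mu = volt.mean(axis=1, keepdims=True)
    sd = volt.std(axis=1, keepdims=True)
    amp_flag = np.abs(volt - mu) > amp_sd * sd

    sos = sps.butter(4, env_band, btype="bandpass", fs=rec.rate, output="sos")
    bp = sps.sosfiltfilt(sos, volt, axis=1)
    env = np.abs(sps.hilbert(bp, axis=1))
    env_flag = env > env.mean(axis=1, keepdims=True) + env_sd * env.std(axis=1, keepdims=True)

    flag = amp_flag | env_flag
    w = 2 * int(round(pad * rec.rate)) + 1
    mask = ndimage.maximum_filter1d(flag.astype(np.uint8), size=w, axis=1) > 0
    out = rec.copy()
    out.artifact_mask = mask
    out.meta["artifact_flag_fraction"] = flag.mean(axis=1).tolist()
    return out


def extract_epochs(rec: Recording, segments: pd.DataFrame, trials: pd.DataFrame,
                   kind: str = "translation", min_dur: float | None = None,
                   window: float = 2.0, roi_regions: tuple[str, ...] = ("HC", "EC"),
                   strict: bool = False, head_pad_s: float = 0.0) -> EpochSet:
    """One fixed-length epoch per eligible test trial.

    For each test trial the longest segment of the requested movement state
    is selected; it must last at least ``min_dur`` seconds (1 s for
    translation, 0.5 s for stationary by default).  The epoch spans
    ``window`` seconds from segment onset regardless of whether the state
    persists (``strict=True`` additionally requires the segment itself to
    cover the full window).  Epochs whose window overlaps the artifact mask
    on any channel of a ROI are flagged as excluded for that ROI only.
    """
    if kind not in ("translation", "stationary"):
        raise ValueError(f"unknown epoch kind {kind!r}")
    if min_dur is None:
        min_dur = 1.0 if kind == "translation" else 0.5
    segs = segments[segments["state"] == kind]
    longest = segs.sort_values("duration").groupby("trial_id").last()

    rows, onsets = [], []
    win_samp = int(round(window * rec.rate))
    test = trials[trials["block"] == "test"]
    for _, tr in test.iterrows():
        tid = int(tr["trial_id"])
        if tid not in longest.index:
            continue
        seg = longest.loc[tid]
        if seg["duration"] < min_dur:
            continue
        if strict and seg["duration"] < window:
            continue
        i0 = int(round((seg["onset"] + head_pad_s) * rec.rate))
        if i0 + win_samp > rec.n_samples:
            continue
        onsets.append(i0)
        rows.append(dict(trial_id=tid, session=int(tr["session"]),
                         environment=tr["environment"], object=tr["object"],
                         object_slot=int(tr.get("object_slot", 0)),
                         is_good=bool(tr.get("is_good", True)),
                         onset_s=seg["onset"], segment_duration=seg["duration"]))
    if not rows:
        raise ValueError(f"no eligible {kind} epochs")
    onsets = np.asarray(onsets)
    data = np.stack([rec.voltage[:, i0:i0 + win_samp] for i0 in onsets])
    table = pd.DataFrame(rows).reset_index(drop=True)

    excluded: dict[str, np.ndarray] = {}
    if rec.artifact_mask is not None:
        for region in roi_regions:
            ch = rec.channel_indices(region)
            if len(ch) == 0:
                continue
            bad = np.array([rec.artifact_mask[np.ix_(ch, range(i0, i0 + win_samp))].any()
                            for i0 in onsets])
            excluded[region] = bad
    return EpochSet(data=data, rate=rec.rate, kind=kind, onset_samples=onsets,
                    table=table, excluded=excluded)
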