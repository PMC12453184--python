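"""Shared in-memory containers for continuous recordings and epoched data.

The analysis operates on two basic objects: a :class:`Recording` holding
continuous multichannel voltage with channel metadata and an artifact mask,
and an :class:`EpochSet` holding fixed-length windows locked to movement
segments of individual test trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGIONS = ("HC", "EC", "AMY", "temporal", "occipital", "other")


@dataclass
class Recording:
    """Continuous multichannel voltage (microvolt) plus channel metadata.

    Attributes
    ----------
    voltage : ndarray, shape (n_channels, n_samples)
    rate : float
        Sampling rate in Hz.
    channels : pandas.DataFrame
        One row per channel with columns ``id``, ``region`` (one of
        ``REGIONS``), ``hemisphere`` (``L``/``R``), ``reference_id`` and,
        once screening has run, ``is_task_selective``.
    artifact_mask : ndarray of bool, shape (n_channels, n_samples), optional
        True where a sample is artifact-contaminated.
    meta : dict
        Free-form provenance (seeds, config digest, ...).
    """

    voltage: np.ndarray
    rate: float
    channels: pd.DataFrame
    artifact_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage)
        if self.voltage.ndim != 2:
            raise ValueError("voltage must be (channels, samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.channels) != self.voltage.shape[0]:
            raise ValueError("channel table does not match voltage rows")
        if self.artifact_mask is not None and self.artifact_mask.shape != self.voltage.shape:
            raise ValueError("artifact_mask must have the same shape as voltage")

    @property
    def n_channels(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel_indices(self, region: str) -> np.ndarray:
        idx = np.flatnonzero(self.channels["region"].to_numpy() == region)
        return idx

    def copy(self) -> "Recording":
        return Recording(
            voltage=self.voltage.copy(),
            rate=self.rate,
            channels=self.channels.copy(),
            artifact_mask=None if self.artifact_mask is None else self.artifact_mask.copy(),
            meta=dict(self.meta),
        )


@dataclass
class EpochSet:
    """Fixed-length epochs locked to movement-segment onsets of test trials.

    ``data`` holds raw voltage slices (epochs x channels x samples) so that
    electrode screening can operate on the time-domain signal; spectral
    decompositions are computed separately from the continuous recording
    using ``onset_samples``.
    """

    data: np.ndarray
    rate: float
    kind: str  # "translation" | "stationary"
    onset_samples: np.ndarray
    table: pd.DataFrame  # trial_id, session, environment, object, is_good, ...
    excluded: dict[str, np.ndarray] = field(default_factory=dict)
    # excluded[region][i] is True when epoch i overlaps the artifact mask on
    # any channel of that region and must be dropped for that ROI.

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if len(self.table) != self.data.shape[0]:
            raise ValueError("epoch table does not match data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def keep(self, region: str) -> np.ndarray:
        """Boolean mask of epochs retained for a given ROI."""
        if region in self.excluded:
            return ~self.excluded[region]
        return np.ones(self.n_epochs, dtype=bool)
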