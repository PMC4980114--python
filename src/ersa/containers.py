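"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: required columns of an event table
EVENT_COLUMNS = (
    "participant", "trial", "phase", "condition", "association",
    "block_type", "rt_s", "is_artifact",
)


@dataclass
class EpochSet:
    """Trial-indexed single-channel voltage traces with linked metadata.

    Parameters
    ----------
    data
        ``(n_trials, n_samples)`` voltage in microvolts.
    times
        Time axis in seconds relative to the lock event.
    sfreq
        Sampling rate in Hz.
    lock
        ``"stimulus"`` or ``"response"``.
    events
        One row per trial, aligned with ``data``; columns per
        :data:`EVENT_COLUMNS`.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    lock: str = "stimulus"
    events: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_trials, n_samples)")
        if self.data.shape[1] != self.times.size:
            raise ValueError("data and time axis length mismatch")
        if len(self.events) and len(self.events) != self.n_trials:
            raise ValueError("events rows must match n_trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select(self, index) -> "EpochSet":
        """Subset trials by boolean mask or integer indices."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        ev = self.events.iloc[index].reset_index(drop=True) if len(self.events) else self.events
        return replace(self, data=self.data[index], events=ev)

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), events=self.events.copy())


def from_mne_epochs(epochs, events: pd.DataFrame | None = None, picks=0) -> EpochSet:
    """Adapt an :class:`mne.Epochs`/``EpochsArray`` (one channel) to :class:`EpochSet`.

    Allows external recordings read with the MNE ecosystem (EDF, BrainVision,
    ...) to enter the pipeline.  Only the channel selected by *picks* is kept.
    """
    data = epochs.get_data()[:, picks, :] * 1e6  # MNE volts -> microvolts
    ev = events if events is not None else pd.DataFrame()
    return EpochSet(data=data, times=epochs.times.copy(), sfreq=float(epochs.info["sfreq"]),
                    lock="stimulus", events=ev)
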