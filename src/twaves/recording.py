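"""Epoched multichannel EEG container.

The pipeline's unit of input: a ``trials x channels x samples`` tensor with
channel labels, sampling rate, epoch time axis and a per-trial condition
table.  Time zero is the memory-display onset throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["EpochedRecording", "MONTAGE_TEMPLATES"]


#: Montage/epoch templates for the two study layouts the package emulates.
#: DS1: 32-channel 10/10 cap, 1 kHz, epochs -800..1599 ms.
#: DS2: 20-channel cap (10/20 sites plus interpolated posterior sites),
#: 250 Hz, epochs -1400..1544 ms.
MONTAGE_TEMPLATES: dict[str, dict] = {
    "DS1": {
        "fs": 1000.0,
        "tmin": -0.8,
        "n_samples": 2400,
        "ch_names": (
            "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
            "FC5", "FC1", "FC2", "FC6",
            "C3", "Cz", "C4", "TP9", "TP10",
            "CP5", "CP1", "CP2", "CP6",
            "P7", "P3", "Pz", "P4", "P8",
            "PO7", "PO3", "PO4", "PO8",
            "O1", "Oz", "O2",
        ),
    },
    "DS2": {
        "fs": 250.0,
        "tmin": -1.4,
        "n_samples": 737,
        "ch_names": (
            "F3", "Fz", "F4", "T3", "C3", "Cz", "C4", "T4",
            "P3", "Pz", "P4", "T5", "T6",
            "OL", "OR", "PO3", "PO4", "POz",
            "O1", "O2",
        ),
    },
}


@dataclass
class EpochedRecording:
    """Epoched EEG: ``data[trial, channel, sample]`` plus metadata.

    Parameters
    ----------
    data
        Float array of shape ``(n_trials, n_channels, n_samples)``.
    ch_names
        Channel labels, one per data row, order matching ``data``.
    fs
        Sampling rate in Hz.
    tmin
        Time of the first sample in seconds relative to memory-display onset.
    trials
        One row per trial with the condition labels (e.g. ``side``, ``load``).
    participant
        Participant identifier.
    template
        Montage template tag ("DS1"/"DS2") if the recording follows one.
    experiment
        Source (sub)experiment tag, used when pooling.
    """

    data: np.ndarray
    ch_names: tuple[str, ...]
    fs: float
    tmin: float
    trials: pd.DataFrame
    participant: str = "p0"
    template: str | None = None
    experiment: str | None = None
    _ch_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples); got shape {self.data.shape}"
            )
        self.ch_names = tuple(self.ch_names)
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.ch_names)} channel names for {self.data.shape[1]} data channels"
            )
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError(
                f"trial table has {len(self.trials)} rows for {self.data.shape[0]} epochs"
            )
        self._ch_index = {name: i for i, name in enumerate(self.ch_names)}

    # -- geometry ----------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in seconds (sample times, memory onset = 0)."""
        return self.tmin + np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self._ch_index[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in recording (has {', '.join(self.ch_names)})"
            ) from None

    def pick(self, names: list[str] | tuple[str, ...]) -> np.ndarray:
        """Return ``(n_trials, len(names), n_samples)`` view-ordered by names."""
        idx = [self.channel_index(n) for n in names]
        return self.data[:, idx, :]

    def copy_with(self, **kwargs) -> "EpochedRecording":
        return replace(self, **kwargs)

    # -- interop -----------------------------------------------------------
    def to_mne(self):
        """Convert to :class:`mne.EpochsArray` (requires mne)."""
        import mne

        info = mne.create_info(list(self.ch_names), self.fs, ch_types="eeg")
        return mne.EpochsArray(
            self.data, info, tmin=self.tmin, metadata=self.trials.reset_index(drop=True),
            verbose="error",
        )
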