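"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EpochedRecording:
    """One subject's epoched single-trial EEG.

    data is (trials, channels, samples) in microvolts (or uV/m^2 after a
    current-source-density transform); epoch_start is the time of the first
    sample relative to the stimulus, in ms.
    """

    subject_id: str
    group: str
    data: np.ndarray
    sampling_rate: float
    epoch_start: float
    channel_names: list
    channel_positions: np.ndarray
    ground_truth: dict | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length does not match data")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

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
    def epoch_end(self) -> float:
        return self.epoch_start + 1000.0 * self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in ms relative to the stimulus."""
        return self.epoch_start + 1000.0 * np.arange(self.n_samples) / self.sampling_rate

    def time_to_sample(self, t_ms: float) -> int:
        """Index of the sample nearest to time t_ms."""
        return int(round((t_ms - self.epoch_start) * self.sampling_rate / 1000.0))

    def copy_with(self, data: np.ndarray, **updates) -> "EpochedRecording":
        kw = dict(
            subject_id=self.subject_id, group=self.group, data=data,
            sampling_rate=self.sampling_rate, epoch_start=self.epoch_start,
            channel_names=list(self.channel_names),
            channel_positions=self.channel_positions,
            ground_truth=self.ground_truth,
        )
        kw.update(updates)
        return EpochedRecording(**kw)
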