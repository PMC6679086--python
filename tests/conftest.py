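"""Shared fixtures: small synthetic recordings and model specs."""

import numpy as np
import pytest

from erpdecode import montage
from erpdecode.containers import EpochedRecording
from erpdecode.model import ModelSpec


@pytest.fixture(scope="session")
def montage19():
    return montage.standard_1020_19()


@pytest.fixture()
def tiny_recording(montage19):
    """A 6-trial, 19-channel, 1-second recording of mild Gaussian noise."""
    names, pos = montage19
    rng = np.random.default_rng(42)
    data = rng.normal(0.0, 5.0, size=(6, len(names), 125)).astype(np.float32)
    return EpochedRecording(
        subject_id="s00", group="control", data=data, sampling_rate=125.0,
        epoch_start=-200.0, channel_names=names, channel_positions=pos,
    )


@pytest.fixture()
def tiny_spec():
    return ModelSpec(C=5, T=40, n_classes=2, F1=2, D=2, temporal_kernel=7,
                     separable_kernel=5, pool1=2, pool2=2, dropout=0.0)
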