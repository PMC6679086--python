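"""Cohort directory format: cohort.json + one HDF5 file per subject.

cohort.json holds the shared metadata (sampling rate, epoch window, channel
names/positions, group labels, seed, per-subject ground truth); each
subject file holds dataset ``epochs`` (trials x channels x samples, float32,
microvolts) with ``subject_id`` and ``group`` attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .containers import EpochedRecording


def save_cohort(directory, recordings, seed=None, extra_meta=None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    first = recordings[0]
    meta = {
        "sampling_rate": first.sampling_rate,
        "epoch_start_ms": first.epoch_start,
        "epoch_end_ms": first.epoch_end,
        "channel_names": list(first.channel_names),
        "channel_positions": np.asarray(first.channel_positions).tolist(),
        "groups": sorted({r.group for r in recordings}),
        "seed": seed,
        "subjects": {
            r.subject_id: {"group": r.group, "ground_truth": r.ground_truth}
            for r in recordings
        },
    }
    if extra_meta:
        meta.update(extra_meta)
    (directory / "cohort.json").write_text(json.dumps(meta, indent=1))
    for rec in recordings:
        with h5py.File(directory / f"{rec.subject_id}.h5", "w") as fh:
            dset = fh.create_dataset("epochs", data=rec.data.astype(np.float32))
            dset.attrs["subject_id"] = rec.subject_id
            dset.attrs["group"] = rec.group
    return directory


def load_cohort(directory):
    directory = Path(directory)
    meta = json.loads((directory / "cohort.json").read_text())
    positions = np.array(meta["channel_positions"])
    recordings = []
    for subject_id, info in meta["subjects"].items():
        with h5py.File(directory / f"{subject_id}.h5", "r") as fh:
            data = fh["epochs"][...]
        recordings.append(EpochedRecording(
            subject_id=subject_id, group=info["group"], data=data,
            sampling_rate=meta["sampling_rate"],
            epoch_start=meta["epoch_start_ms"],
            channel_names=list(meta["channel_names"]),
            channel_positions=positions,
            ground_truth=info.get("ground_truth"),
        ))
    return recordings, meta
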