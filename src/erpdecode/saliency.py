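"""Gradient saliency: which channels/time points drive the classifier.

The saliency map of a trial is the gradient of the pre-softmax class score
with respect to the input, evaluated in inference mode — the same shape as
the trial (channels x samples).  Group-level maps average the per-trial maps
of every trial of a group (gradient of each trial's true-class score by
default) and are min-max normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass
class SaliencyMap:
    values: np.ndarray          # (channels, samples)
    class_label: object
    normalized: bool = False
    channel_names: list | None = None
    times: np.ndarray | None = None


def trial_saliency(model, trial, class_index: int,
                   use_abs: bool = False) -> SaliencyMap:
    """d(score of class_index) / d(input) for a single (C, T) trial."""
    sal = batch_saliency(model, np.asarray(trial)[None],
                         np.array([class_index]), use_abs=use_abs)
    return SaliencyMap(values=sal[0], class_label=class_index)


def batch_saliency(model, X, class_indices, use_abs: bool = False) -> np.ndarray:
    """Per-trial input gradients for a batch; (B, C, T).

    class_indices selects, per trial, which pre-softmax score to
    differentiate.  Trials are independent in inference mode, so one
    backward pass with a one-hot upstream gradient per row yields all
    per-trial gradients at once.
    """
    X = np.asarray(X, dtype=nn.DTYPE)
    spec = model.spec
    if X.shape[1:] != (spec.C, spec.T):
        raise ValueError(f"trial shape {X.shape[1:]} != model input "
                         f"({spec.C}, {spec.T})")
    class_indices = np.asarray(class_indices)
    if np.any((class_indices < 0) | (class_indices >= spec.n_classes)):
        raise ValueError("class index out of range")
    grads = np.empty_like(X)
    for i in range(0, len(X), 64):
        xb = X[i : i + 64]
        logits = model.forward(xb, training=False)
        dlogits = np.zeros_like(logits)
        dlogits[np.arange(len(xb)), class_indices[i : i + 64]] = 1.0
        grads[i : i + 64] = model.backward(dlogits, to_input=True)
    return np.abs(grads) if use_abs else grads


def group_saliency(model, recordings, class_of: dict, class_index=None,
                   use_abs: bool = False) -> SaliencyMap:
    """Averaged, normalized map over every trial of the given recordings.

    By default each trial's gradient is taken with respect to its subject's
    true-class score; pass class_index to differentiate a fixed class.
    """
    label = class_index
    acc, total = None, 0
    for rec in recordings:
        ci = class_of[rec.group] if class_index is None else class_index
        label = ci if label is None else label
        sal = batch_saliency(model, rec.data,
                             np.full(rec.n_trials, ci), use_abs=use_abs)
        s = sal.sum(axis=0, dtype=np.float64)
        acc = s if acc is None else acc + s
        total += rec.n_trials
    mean = acc / total  # mean over every trial of every recording
    out = SaliencyMap(values=mean, class_label=label,
                      channel_names=list(recordings[0].channel_names),
                      times=recordings[0].times())
    return normalize_map(out)


def aggregate_and_normalize(maps) -> SaliencyMap:
    """Element-wise mean of same-shape maps, min-max rescaled to [0, 1].

    A constant mean map (max == min) degenerates to all zeros.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to aggregate")
    shape = maps[0].values.shape
    label = maps[0].class_label
    for m in maps:
        if m.values.shape != shape:
            raise ValueError("saliency maps differ in shape")
        if m.class_label != label:
            raise ValueError("saliency maps differ in class label")
    mean = np.mean([m.values for m in maps], axis=0)
    out = SaliencyMap(values=mean, class_label=label,
                      channel_names=maps[0].channel_names, times=maps[0].times)
    return normalize_map(out)


def normalize_map(m: SaliencyMap) -> SaliencyMap:
    lo, hi = float(m.values.min()), float(m.values.max())
    if hi == lo:
        values = np.zeros_like(m.values)
    else:
        values = (m.values - lo) / (hi - lo)
    return SaliencyMap(values=values, class_label=m.class_label,
                       normalized=True, channel_names=m.channel_names,
                       times=m.times)


def top_features(m: SaliencyMap, k: int, window_ms: float,
                 sampling_rate: float) -> list:
    """Top-k non-overlapping (channel, time window) pairs by relevance mass.

    Relevance is summed in sliding windows (one-sample steps) per channel;
    candidates are ranked by mass with deterministic tie-breaking by
    (channel index, window start); windows on the same channel may not
    overlap a selected one.  Returns a list of dicts with channel, window
    start/end (ms if the map carries a time axis, else samples) and mass.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not m.normalized:
        raise ValueError("top_features expects a normalized map")
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    w = max(1, int(round(window_ms * sampling_rate / 1000.0)))
    vals = m.values
    n_ch, n_samp = vals.shape
    w = min(w, n_samp)
    csum = np.concatenate([np.zeros((n_ch, 1)), np.cumsum(vals, axis=1)], axis=1)
    mass = csum[:, w:] - csum[:, :-w]  # (n_ch, n_samp - w + 1)
    order = np.lexsort((
        np.tile(np.arange(mass.shape[1]), n_ch),
        np.repeat(np.arange(n_ch), mass.shape[1]),
        -mass.ravel(),
    ))
    chosen = []
    taken = [[] for _ in range(n_ch)]
    for flat in order:
        if len(chosen) == k:
            break
        ch, start = divmod(int(flat), mass.shape[1])
        if any(start < s + w and s < start + w for s in taken[ch]):
            continue
        taken[ch].append(start)
        entry = {"channel": ch, "start_sample": start,
                 "end_sample": start + w, "mass": float(mass[ch, start])}
        if m.channel_names is not None:
            entry["channel_name"] = m.channel_names[ch]
        if m.times is not None:
            entry["start_ms"] = float(m.times[start])
            entry["end_ms"] = float(m.times[min(start + w, n_samp - 1)])
        chosen.append(entry)
    return chosen


def localization_enrichment(m: SaliencyMap, channel_mask, time_mask,
                            top_fraction: float = 0.1) -> float:
    """Enrichment of top-relevance mass inside a ground-truth region.

    Takes the top ``top_fraction`` of map entries by value and compares the
    share of their mass falling inside the (channel x time) region with the
    region's share of the map area.  A value of 1 means no localization;
    2 means twice the mass expected under a uniform spread.
    """
    vals = np.asarray(m.values, dtype=float)
    region = np.outer(np.asarray(channel_mask, bool), np.asarray(time_mask, bool))
    area_share = region.mean()
    if area_share in (0.0, 1.0):
        raise ValueError("ground-truth region must be a proper subset of the map")
    n_top = max(1, int(round(top_fraction * vals.size)))
    flat = vals.ravel()
    top_idx = np.argpartition(flat, -n_top)[-n_top:]
    top_mass = flat[top_idx]
    in_region = region.ravel()[top_idx]
    total = top_mass.sum()
    if total <= 0:
        return 0.0
    return float((top_mass[in_region].sum() / total) / area_share)
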