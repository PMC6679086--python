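"""Compact convolutional classifier for single-trial epoched EEG.

The architecture is the EEGNet family: a temporal convolution learns F1
band-pass-like filters, a depthwise convolution spanning all C electrodes
learns D spatial filters per temporal filter, and a separable convolution
mixes the resulting F1*D feature maps before a softmax head.  Two variants
are provided:

``prose`` (default)
    one separable block — temporal conv -> BN -> depthwise spatial conv ->
    BN -> ELU -> avgpool(4) -> dropout -> separable conv (width 16) -> BN ->
    ELU -> avgpool(8) -> dropout -> dense/softmax.

``table``
    no pooling in block 1 and two separable stages (width 8, the second with
    twice the maps), each followed by avgpool(4).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np

from . import nn


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    C, T are the electrode and sample counts of one trial; F1 temporal
    filters of width ``temporal_kernel`` samples; D spatial filters per
    temporal filter.
    """

    C: int
    T: int
    n_classes: int
    F1: int = 4
    D: int = 2
    temporal_kernel: int = 64
    separable_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.25
    variant: str = "prose"

    def __post_init__(self):
        for field in ("C", "T", "n_classes", "F1", "D", "temporal_kernel",
                      "separable_kernel", "pool1", "pool2"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be a positive integer")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.temporal_kernel > self.T:
            raise ValueError(
                f"temporal_kernel ({self.temporal_kernel}) exceeds trial length T ({self.T})"
            )
        if self.variant not in ("prose", "table"):
            raise ValueError("variant must be 'prose' or 'table'")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls(**json.loads(s))


def _layer_plan(spec: ModelSpec):
    """(name, constructor-args) plan shared by build_model and count_parameters."""
    M = spec.F1 * spec.D
    if spec.variant == "prose":
        t1 = spec.T // spec.pool1
        t2 = t1 // spec.pool2
        return [
            ("temporal", "conv", dict(F=spec.F1, K=spec.temporal_kernel)),
            ("bn1", "bn", dict(n=spec.F1, axis=0)),
            ("spatial", "dwconv", dict(F=spec.F1, D=spec.D, C=spec.C)),
            ("bn2", "bn", dict(n=M)),
            ("elu1", "elu", {}),
            ("pool1", "pool", dict(p=spec.pool1)),
            ("drop1", "drop", {}),
            ("sep1", "sep", dict(n_in=M, n_out=M, K=spec.separable_kernel)),
            ("bn3", "bn", dict(n=M)),
            ("elu2", "elu", {}),
            ("pool2", "pool", dict(p=spec.pool2)),
            ("drop2", "drop", {}),
            ("flatten", "flatten", {}),
            ("dense", "dense", dict(n_in=M * t2, n_out=spec.n_classes)),
        ]
    # table variant: two separable stages, pooling (1,4) after each
    k = 8
    t1 = spec.T // 4
    t2 = t1 // 4
    return [
        ("temporal", "conv", dict(F=spec.F1, K=spec.temporal_kernel)),
        ("bn1", "bn", dict(n=spec.F1, axis=0)),
        ("spatial", "dwconv", dict(F=spec.F1, D=spec.D, C=spec.C)),
        ("bn2", "bn", dict(n=M)),
        ("elu1", "elu", {}),
        ("drop1", "drop", {}),
        ("sep1", "sep", dict(n_in=M, n_out=M, K=k)),
        ("bn3", "bn", dict(n=M)),
        ("elu2", "elu", {}),
        ("pool1", "pool", dict(p=4)),
        ("drop2", "drop", {}),
        ("sep2", "sep", dict(n_in=M, n_out=2 * M, K=k)),
        ("bn4", "bn", dict(n=2 * M)),
        ("elu3", "elu", {}),
        ("pool2", "pool", dict(p=4)),
        ("drop3", "drop", {}),
        ("flatten", "flatten", {}),
        ("dense", "dense", dict(n_in=2 * M * t2, n_out=spec.n_classes)),
    ]


class EEGNetModel(nn.Sequential):
    """A built classifier; carries its ModelSpec for serialization."""

    def __init__(self, spec: ModelSpec, layers):
        super().__init__(layers)
        self.spec = spec

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch (B, C, T), inference mode."""
        return nn.softmax(self.forward(x, training=False))


def build_model(spec: ModelSpec, rng=None) -> EEGNetModel:
    """Instantiate the classifier with Glorot-uniform weight initialization."""
    if rng is None:
        rng = np.random.default_rng(0)
    layers = []
    for name, kind, kw in _layer_plan(spec):
        if kind == "conv":
            layers.append((name, nn.TemporalConv(kw["F"], kw["K"], rng)))
        elif kind == "bn":
            layers.append((name, nn.BatchNorm(kw["n"], feature_axis=kw.get("axis", 1))))
        elif kind == "dwconv":
            layers.append((name, nn.DepthwiseSpatialConv(kw["F"], kw["D"], kw["C"], rng)))
        elif kind == "elu":
            layers.append((name, nn.ELU()))
        elif kind == "pool":
            layers.append((name, nn.AvgPool(kw["p"])))
        elif kind == "drop":
            layers.append((name, nn.Dropout(spec.dropout)))
        elif kind == "sep":
            layers.append((name, nn.SeparableConv(kw["n_in"], kw["n_out"], kw["K"], rng)))
        elif kind == "flatten":
            layers.append((name, nn.Flatten()))
        elif kind == "dense":
            layers.append((name, nn.Dense(kw["n_in"], kw["n_out"], rng)))
    return EEGNetModel(spec, layers)


def count_parameters(spec: ModelSpec) -> dict:
    """Closed-form per-layer learnable parameter counts.

    Temporal conv: temporal_kernel * F1 (bias-free); depthwise spatial:
    C * F1 * D; separable: depthwise kernel * maps + pointwise in*out;
    each batch-norm: 2 per feature map; dense: in*out + out.
    Returns {"layers": {name: count}, "total": int}.
    """
    counts: dict[str, int] = {}
    for name, kind, kw in _layer_plan(spec):
        if kind == "conv":
            counts[name] = kw["K"] * kw["F"]
        elif kind == "bn":
            counts[name] = 2 * kw["n"]
        elif kind == "dwconv":
            counts[name] = kw["C"] * kw["F"] * kw["D"]
        elif kind == "sep":
            counts[name] = kw["n_in"] * kw["K"] + kw["n_in"] * kw["n_out"]
        elif kind == "dense":
            counts[name] = kw["n_in"] * kw["n_out"] + kw["n_out"]
    return {"layers": counts, "total": sum(counts.values())}


def shape_trace(spec: ModelSpec) -> list[tuple[str, tuple]]:
    """Per-layer logical output shapes (without the batch axis).

    Block 1 is computed internally in a features-first layout; the trace
    reports the conventional (maps, channels, samples) ordering so it can be
    compared against the published architecture table.
    """
    model = build_model(spec)
    x = np.zeros((1, spec.C, spec.T), dtype=nn.DTYPE)
    trace = []
    for name, layer in model.layers:
        x = layer.forward(x, training=False, rng=None)
        shape = x.shape[1:]
        if x.ndim == 4:  # (F, B, C, T) -> logical (F, C, T)
            shape = (x.shape[0], x.shape[2], x.shape[3])
        trace.append((name, shape))
    return trace


def class_scores(model: EEGNetModel, trial: np.ndarray) -> np.ndarray:
    """Pre-softmax score vector for one trial of shape (C, T)."""
    trial = np.asarray(trial)
    expected = (model.spec.C, model.spec.T)
    if trial.shape != expected:
        raise ValueError(f"trial shape {trial.shape} does not match model input {expected}")
    return model.forward(trial[None], training=False)[0]


def save_model(model: EEGNetModel, path) -> None:
    """Checkpoint weights (+ batch-norm buffers) and the spec as .npz/JSON."""
    state = model.get_state()
    np.savez(path, __spec__=np.frombuffer(model.spec.to_json().encode(), dtype=np.uint8),
             **state)


def load_model(path) -> EEGNetModel:
    with np.load(path) as data:
        spec = ModelSpec.from_json(bytes(data["__spec__"]).decode())
        model = build_model(spec)
        model.set_state({k: data[k] for k in data.files if k != "__spec__"})
    return model
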