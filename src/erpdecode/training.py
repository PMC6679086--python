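"""Class-weighted training with leave-one-subject-out (LOOS) evaluation.

Each LOOS fold holds out every trial of one subject as the test set, uses a
per-group random subset of the remaining subjects for validation-based
model selection (lowest validation cross-entropy across epochs), and trains
the classifier on the rest with class weights equal to the inverse trial
proportion (majority class = 1).  Per-subject accuracy is the percentage of
correctly classified test trials; the cohort summary is the mean and SD of
those per-subject accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .model import ModelSpec, build_model


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 500
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    n_val_subjects_per_group: int = 4
    eval_batch_size: int = 64

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class Fold:
    test_subject: str
    train_subjects: list
    val_subjects: list


@dataclass
class FoldResult:
    test_subject: str
    group: str
    n_test_trials: int
    predictions: np.ndarray        # predicted class indices, per trial
    probabilities: np.ndarray      # (trials, classes)
    accuracy: float                # percent
    best_epoch: int = 0            # 1-based
    val_loss: float = float("nan")


def compute_class_weights(trial_counts: dict) -> dict:
    """Inverse-proportion class weights with the majority class set to 1.

    weight_c = n_majority / n_c, so every weight is >= 1.
    """
    for cls, n in trial_counts.items():
        if n <= 0:
            raise ValueError(f"class {cls!r} has no trials")
    n_major = max(trial_counts.values())
    return {cls: n_major / n for cls, n in trial_counts.items()}


def loos_folds(subject_groups: dict, n_val_per_group: int = 4, seed: int = 0):
    """One fold per subject; per-group random validation subjects.

    subject_groups maps subject id -> group label.  The requested
    validation count applies whenever a group retains at least
    n_val_per_group + 1 non-test subjects; in smaller groups it is reduced
    to min(n_val_per_group, max(1, remaining_in_group // 3)) so the
    training set stays nonempty in every group.
    """
    by_group: dict[str, list] = {}
    for sid, grp in subject_groups.items():
        by_group.setdefault(grp, []).append(sid)
    for grp, members in by_group.items():
        if len(members) < 2:
            raise ValueError(f"group {grp!r} has a single subject; LOOS needs >= 2")
    rng = np.random.default_rng(seed)
    folds = []
    for test in subject_groups:  # preserves insertion order
        val, train = [], []
        for grp, members in by_group.items():
            remaining = [s for s in members if s != test]
            if len(remaining) >= n_val_per_group + 1:
                nv = n_val_per_group
            else:
                nv = min(n_val_per_group, max(1, len(remaining) // 3))
            chosen = rng.choice(len(remaining), size=nv, replace=False)
            chosen = set(int(i) for i in chosen)
            for i, sid in enumerate(remaining):
                (val if i in chosen else train).append(sid)
        folds.append(Fold(test_subject=test, train_subjects=train,
                          val_subjects=val))
    return folds


def _stack(recordings, class_of: dict):
    X = np.concatenate([r.data for r in recordings]).astype(np.float32)
    y = np.concatenate([
        np.full(r.n_trials, class_of[r.group], dtype=np.int64)
        for r in recordings
    ])
    return X, y


def _forward_batches(model, X, batch_size):
    outs = []
    for i in range(0, len(X), batch_size):
        outs.append(model.forward(X[i : i + batch_size], training=False))
    return np.concatenate(outs)


def train_model(X_train, y_train, X_val, y_val, spec: ModelSpec,
                config: TrainConfig, rng=None):
    """Core fitting loop; returns (model at best epoch, history dict).

    Minimizes class-weighted cross-entropy with Adam; after every epoch the
    unweighted validation cross-entropy is computed in inference mode, and
    the checkpoint with the lowest validation loss (earliest epoch on ties)
    is restored at the end.
    """
    classes = np.unique(y_train)
    counts = {int(c): int((y_train == c).sum()) for c in classes}
    if len(counts) < spec.n_classes:
        raise ValueError("a class has no trials in the training data")
    weights = compute_class_weights(counts)
    w_per_class = np.zeros(spec.n_classes)
    for c, w in weights.items():
        w_per_class[c] = w

    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = build_model(spec, rng)
    opt = nn.Adam(model, lr=config.learning_rate)
    n = len(X_train)
    best = (np.inf, -1, None)
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        ep_loss = 0.0
        for i in range(0, n, config.batch_size):
            sel = order[i : i + config.batch_size]
            xb, yb = X_train[sel], y_train[sel]
            logits = model.forward(xb, training=True, rng=rng)
            loss, dlogits = nn.weighted_cross_entropy(
                logits, yb, sample_weights=w_per_class[yb])
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * len(sel)
        logits_val = _forward_batches(model, X_val, config.eval_batch_size)
        val_loss, _ = nn.weighted_cross_entropy(logits_val, y_val)
        history["train_loss"].append(ep_loss / n)
        history["val_loss"].append(float(val_loss))
        if val_loss < best[0]:
            best = (float(val_loss), epoch, model.get_state())
    model.set_state(best[2])
    history["best_epoch"] = best[1]
    history["best_val_loss"] = best[0]
    return model, history


def evaluate_subject(model, recording, class_of: dict) -> FoldResult:
    """Per-trial predictions and accuracy on one held-out subject.

    Predictions are argmax of the class probabilities (lowest class index on
    exact ties, which is numpy argmax behaviour).
    """
    if recording.n_trials == 0:
        raise ValueError(f"subject {recording.subject_id} has no test trials")
    probs = nn.softmax(_forward_batches(model, recording.data.astype(np.float32), 64))
    preds = np.argmax(probs, axis=1)
    true = class_of[recording.group]
    acc = 100.0 * float(np.mean(preds == true))
    return FoldResult(
        test_subject=recording.subject_id, group=recording.group,
        n_test_trials=recording.n_trials, predictions=preds,
        probabilities=probs, accuracy=acc,
    )


def run_loos(recordings, classes, spec: ModelSpec, config: TrainConfig,
             progress=None):
    """Full LOOS evaluation over a cohort.

    classes is the ordered label list defining class indices (e.g.
    ["control", "ADHD"]); recordings not belonging to a listed class are
    ignored.  Returns (list of FoldResult, summary dict with mean/sd
    accuracy).  Fully deterministic given config.seed.
    """
    class_of = {grp: i for i, grp in enumerate(classes)}
    cohort = [r for r in recordings if r.group in class_of]
    by_id = {r.subject_id: r for r in cohort}
    folds = loos_folds({r.subject_id: r.group for r in cohort},
                       config.n_val_subjects_per_group, seed=config.seed)
    results = []
    for k, fold in enumerate(folds):
        X_tr, y_tr = _stack([by_id[s] for s in fold.train_subjects], class_of)
        X_va, y_va = _stack([by_id[s] for s in fold.val_subjects], class_of)
        fold_rng = np.random.default_rng([config.seed, k])
        model, history = train_model(X_tr, y_tr, X_va, y_va, spec, config,
                                     rng=fold_rng)
        res = evaluate_subject(model, by_id[fold.test_subject], class_of)
        res.best_epoch = history["best_epoch"]
        res.val_loss = history["best_val_loss"]
        results.append(res)
        if progress:
            progress(k, len(folds), res)
    accs = np.array([r.accuracy for r in results])
    summary = {
        "mean_accuracy": float(accs.mean()),
        "sd_accuracy": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        "n_subjects": len(accs),
    }
    return results, summary


def results_frame(results) -> pd.DataFrame:
    """folds.csv-style table of per-subject outcomes."""
    return pd.DataFrame([
        {"subject": r.test_subject, "group": r.group,
         "n_trials": r.n_test_trials, "accuracy": r.accuracy,
         "best_epoch": r.best_epoch, "val_loss": r.val_loss}
        for r in results
    ])
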