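"""Class weights, LOOS fold construction, fitting and evaluation."""



import numpy as np
import pytest

from erpdecode.containers import EpochedRecording
from erpdecode.model import ModelSpec
from erpdecode.training import (TrainConfig, compute_class_weights,
                                evaluate_subject, loos_folds, run_loos,
                                train_model)
from erpdecode import montage


class TestClassWeights:
    def test_study_trial_counts(self):
        # control/ADD/ADHD trial totals of the full three-class dataset
        w = compute_class_weights({"control": 10129, "ADD": 13031,
                                   "ADHD": 10742})
        assert w["ADD"] == 1.0
        assert w["control"] == pytest.approx(13031 / 10129, abs=1e-4)  # ~1.2865
        assert w["ADHD"] == pytest.approx(13031 / 10742, abs=1e-4)     # ~1.2131

    def test_equal_counts_unit_weights(self):
        assert compute_class_weights({"a": 7, "b": 7}) == {"a": 1.0, "b": 1.0}

    def test_two_to_one_ratio(self):
        assert compute_class_weights({"a": 100, "b": 50}) == {"a": 1.0, "b": 2.0}

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights({"a": 10, "b": 0})

    def test_invariant_under_duplication(self):
        counts = {"a": 31, "b": 57, "c": 44}
        doubled = {k: 2 * v for k, v in counts.items()}
        assert compute_class_weights(counts) == compute_class_weights(doubled)


class TestLoosFolds:
    def _subjects(self, n_per_group, groups=("g1", "g2", "g3")):
        return {f"{g}_{i}": g for g in groups for i in range(n_per_group)}

    def test_each_subject_tested_exactly_once(self):
        subs = self._subjects(5, groups=("a", "b"))
        folds = loos_folds(subs, n_val_per_group=1, seed=0)
        assert len(folds) == 10
        assert sorted(f.test_subject for f in folds) == sorted(subs)

    def test_paper_scale_validation_counts(self):
        # 3 groups x 10 subjects with 4 validation subjects per group:
        # every fold holds 12 validation and 17 training subjects
        folds = loos_folds(self._subjects(10), n_val_per_group=4, seed=1)
        for fold in folds:
            assert len(fold.val_subjects) == 12
            assert len(fold.train_subjects) == 17

    def test_no_leakage(self):
        folds = loos_folds(self._subjects(6), n_val_per_group=2, seed=2)
        for fold in folds:
            train, val = set(fold.train_subjects), set(fold.val_subjects)
            assert fold.test_subject not in train | val
            assert not train & val

    def test_small_groups_reduce_validation(self):
        folds = loos_folds(self._subjects(3, groups=("a", "b")),
                           n_val_per_group=4, seed=0)
        for fold in folds:
            # remaining 2 or 3 per group -> 1 validation subject each
            assert len(fold.val_subjects) == 2
            assert len(fold.train_subjects) >= 2

    def test_seeded_reproducibility(self):
        subs = self._subjects(8)
        a = loos_folds(subs, 4, seed=11)
        b = loos_folds(subs, 4, seed=11)
        assert [(f.val_subjects, f.train_subjects) for f in a] == \
               [(f.val_subjects, f.train_subjects) for f in b]

    def test_single_subject_group_rejected(self):
        with pytest.raises(ValueError, match="single subject"):
            loos_folds({"a_0": "a", "a_1": "a", "b_0": "b"}, 1, seed=0)


def _toy_data(rng, n_per_class=30, C=4, T=64, gap=2.0, noise=0.0):
    """Two classes separated by a channel-mean offset (linearly separable)."""
    X0 = rng.normal(0, noise, (n_per_class, C, T)) if noise else np.zeros((n_per_class, C, T))
    X1 = X0 + gap
    X = np.concatenate([X0, X1]).astype(np.float32)
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


TOY_SPEC = ModelSpec(C=4, T=64, n_classes=2, temporal_kernel=8,
                     separable_kernel=4, pool1=2, pool2=2, dropout=0.0)


class TestTrainModel:
    def test_separable_toy_reaches_full_training_accuracy(self):
        rng = np.random.default_rng(0)
        X, y = _toy_data(rng)
        model, hist = train_model(X, y, X, y, TOY_SPEC,
                                  TrainConfig(epochs=30, seed=0))
        acc = (model.predict_proba(X).argmax(1) == y).mean()
        assert acc == 1.0

    def test_single_epoch_returns_first_checkpoint(self):
        rng = np.random.default_rng(1)
        X, y = _toy_data(rng, n_per_class=10)
        _, hist = train_model(X, y, X, y, TOY_SPEC, TrainConfig(epochs=1, seed=0))
        assert hist["best_epoch"] == 1

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        X, y = _toy_data(rng, n_per_class=10, noise=0.5)
        runs = []
        for _ in range(2):
            model, hist = train_model(X, y, X, y, TOY_SPEC,
                                      TrainConfig(epochs=5, seed=3))
            runs.append((hist["best_epoch"], hist["best_val_loss"],
                         model.predict_proba(X[:4])))
        assert runs[0][0] == runs[1][0]
        assert runs[0][1] == runs[1][1]
        np.testing.assert_array_equal(runs[0][2], runs[1][2])

    def test_missing_class_rejected(self):
        rng = np.random.default_rng(3)
        X, y = _toy_data(rng, n_per_class=8)
        y[:] = 0
        with pytest.raises(ValueError, match="class"):
            train_model(X, y, X, y, TOY_SPEC, TrainConfig(epochs=1, seed=0))


def _recording(sid, group, data):
    names, pos = montage.standard_1020_19()
    names, pos = names[: data.shape[1]], pos[: data.shape[1]]
    return EpochedRecording(sid, group, data.astype(np.float32), 125.0,
                            -200.0, names, pos)


class _ConstantModel:
    """Stub emitting fixed logits (for evaluation-rule tests)."""

    def __init__(self, logits, C, T):
        import types
        self._l = np.asarray(logits, dtype=np.float32)
        self.spec = types.SimpleNamespace(C=C, T=T, n_classes=len(logits))

    def forward(self, x, training=False, rng=None):
        return np.tile(self._l, (len(x), 1))


class TestEvaluateSubject:
    def test_accuracy_arithmetic(self):
        rec = _recording("s", "patient", np.zeros((4, 3, 16)))
        # logits favouring class 1 -> predicted patient (class 1) for all 4
        model = _ConstantModel([0.0, 1.0], C=3, T=16)
        res = evaluate_subject(model, rec, {"control": 0, "patient": 1})
        assert res.accuracy == 100.0
        model = _ConstantModel([1.0, 0.0], C=3, T=16)
        res = evaluate_subject(model, rec, {"control": 0, "patient": 1})
        assert res.accuracy == 0.0

    def test_tie_breaks_to_lowest_index(self):
        rec = _recording("s", "control", np.zeros((6, 3, 16)))
        model = _ConstantModel([0.5, 0.5], C=3, T=16)
        res = evaluate_subject(model, rec, {"control": 0, "patient": 1})
        assert np.all(res.predictions == 0)
        assert res.accuracy == 100.0  # control is class 0

    def test_empty_subject_rejected(self):
        rec = _recording("s", "control", np.zeros((0, 3, 16)))
        with pytest.raises(ValueError, match="test trials"):
            evaluate_subject(_ConstantModel([0., 0.], 3, 16), rec,
                             {"control": 0, "patient": 1})


class TestRunLoos:
    def _cohort(self, rng, n_per_group=3, n_trials=12, gap=0.0):
        names_len = 4
        recs = []
        for g, off in (("control", 0.0), ("patient", gap)):
            for i in range(n_per_group):
                data = rng.normal(off, 1.0, (n_trials, names_len, 64))
                recs.append(_recording(f"{g}_{i}", g, data))
        return recs

    def test_fold_count_and_summary(self):
        rng = np.random.default_rng(0)
        recs = self._cohort(rng, gap=3.0)
        spec = ModelSpec(C=4, T=64, n_classes=2, temporal_kernel=8,
                         separable_kernel=4, pool1=2, pool2=2, dropout=0.0)
        results, summary = run_loos(recs, ["control", "patient"], spec,
                                    TrainConfig(epochs=15, seed=0,
                                                batch_size=8))
        assert len(results) == 6
        assert summary["n_subjects"] == 6
        accs = [r.accuracy for r in results]
        assert summary["mean_accuracy"] == pytest.approx(np.mean(accs))
        # a 3-sigma channel-mean offset is trivially decodable
        assert summary["mean_accuracy"] > 90.0

    def test_no_test_subject_leak(self, monkeypatch):
        from erpdecode import training as tr
        seen = []
        orig = tr.train_model

        def spy(Xtr, ytr, Xv, yv, spec, config, rng=None):
            seen.append((len(Xtr), len(Xv)))
            return orig(Xtr, ytr, Xv, yv, spec, config, rng)

        monkeypatch.setattr(tr, "train_model", spy)
        rng = np.random.default_rng(1)
        recs = self._cohort(rng, n_per_group=3, n_trials=8)
        spec = ModelSpec(C=4, T=64, n_classes=2, temporal_kernel=8,
                         separable_kernel=4, pool1=2, pool2=2, dropout=0.0)
        results, _ = run_loos(recs, ["control", "patient"], spec,
                              TrainConfig(epochs=1, seed=0))
        # per fold: 6 subjects total, 1 test, 2 val (1/group) -> 3 train
        for n_train, n_val in seen:
            assert n_train == 3 * 8
            assert n_val == 2 * 8
        for r in results:
            assert r.n_test_trials == 8
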