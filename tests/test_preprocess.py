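"""Preprocessing chain: filtering, baseline, rejection, CSD."""

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from erpdecode import montage
from erpdecode.containers import EpochedRecording
from erpdecode.preprocess import (CsdParams, RejectionCriteria,
                                  baseline_correct, bandpass_filter,
                                  csd_matrices, csd_transform,
                                  reject_artifacts)

RATE = 500.0


def _recording(data, rate=RATE, names=None, pos=None):
    if names is None:
        names, pos = montage.standard_1020_19()
        names, pos = names[: data.shape[1]], pos[: data.shape[1]]
    return EpochedRecording("s", "control", np.asarray(data, dtype=np.float64),
                            rate, -200.0, names, pos)


class TestBandpass:
    def test_dc_offset_removed(self):
        rec = _recording(np.full((1, 3, 2000), 10.0))
        out = bandpass_filter(rec, 0.5, 20.0)
        # away from the filter edges the DC component is essentially gone
        assert np.abs(out.data[..., 500:1500]).max() < 0.1

    def test_passband_sine_preserved(self):
        t = np.arange(4000) / RATE
        sine = np.sin(2 * np.pi * 10.0 * t)
        rec = _recording(np.tile(sine, (1, 2, 1)))
        out = bandpass_filter(rec, 0.5, 20.0)
        mid = out.data[0, 0, 1000:3000]
        amp = (mid.max() - mid.min()) / 2
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_stopband_sine_attenuated_40db(self):
        # attenuation measured at 50 Hz itself (the slow edge transient of
        # the 0.5 Hz high-pass would otherwise dominate the time domain)
        n = 4000
        t = np.arange(n) / RATE
        sine = np.sin(2 * np.pi * 50.0 * t)
        rec = _recording(sine[None, None, :])
        out = bandpass_filter(rec, 0.5, 20.0)
        spectrum = np.abs(np.fft.rfft(out.data[0, 0])) / (n / 2)
        amp50 = spectrum[int(50.0 * n / RATE)]
        assert amp50 < 10 ** (-40 / 20)

    def test_invalid_cutoffs_rejected(self):
        rec = _recording(np.zeros((1, 2, 100)))
        for low, high in [(0.0, 20.0), (20.0, 5.0), (0.5, 300.0)]:
            with pytest.raises(ValueError):
                bandpass_filter(rec, low, high)

    def test_shape_preserved(self, tiny_recording):
        out = bandpass_filter(tiny_recording, 1.0, 30.0)
        assert out.data.shape == tiny_recording.data.shape


class TestBaseline:
    def test_constant_trial_becomes_zero(self):
        rec = _recording(np.full((2, 3, 1600), 5.0))
        out = baseline_correct(rec)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_constant_shift_preserves_peaks(self):
        data = np.full((1, 1, 1600), 2.0)
        data[0, 0, 500] = 7.0
        out = baseline_correct(_recording(data))
        assert out.data[0, 0, 500] == pytest.approx(5.0, abs=1e-9)

    def test_idempotence(self, tiny_recording):
        once = baseline_correct(tiny_recording)
        twice = baseline_correct(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-6)

    def test_baseline_mean_zero(self, tiny_recording):
        out = baseline_correct(tiny_recording)
        i1 = out.time_to_sample(0.0)
        np.testing.assert_allclose(out.data[:, :, :i1].mean(axis=-1), 0.0,
                                   atol=1e-5)

    def test_window_outside_epoch_rejected(self, tiny_recording):
        with pytest.raises(ValueError):
            baseline_correct(tiny_recording, (-500.0, 0.0))


def brute_force_rules(data, rate, criteria):
    """Independent per-trial rule checker using explicit sliding windows."""
    wd = int(round(criteria.diff_window * rate / 1000.0))
    wl = int(round(criteria.low_window * rate / 1000.0))
    flags = []
    for trial in data:
        amp = bool(np.any((trial > criteria.amp_max) | (trial < criteria.amp_min)))
        wins = sliding_window_view(trial, wd, axis=-1)
        diff = bool(np.any(wins.max(-1) - wins.min(-1) > criteria.max_diff))
        wins = sliding_window_view(trial, wl, axis=-1)
        low = bool(np.any(wins.max(-1) - wins.min(-1) < criteria.low_activity))
        flags.append((amp, diff, low))
    return flags


class TestRejection:
    def _base(self, n=6, c=3, t=1500):
        rng = np.random.default_rng(0)
        t_ax = np.arange(t) / RATE
        clean = 50.0 * np.sin(2 * np.pi * 10.0 * t_ax)
        data = np.tile(clean, (n, c, 1)) + rng.normal(0, 5, (n, c, t))
        return data

    def test_amplitude_spike_rejected(self):
        data = self._base()
        data[2, 1, 700] = 250.0
        rec = _recording(data)
        kept, log = reject_artifacts(rec)
        assert kept.n_trials == rec.n_trials - 1
        assert log == [{"trial": 2, "channel": 1, "rule": "amplitude"}]

    def test_low_activity_rejected(self):
        data = self._base()
        data[4, 0, 200:800] = 1.0  # flat: ptp ~ 0 << 0.5 uV over >100 ms
        kept, log = reject_artifacts(_recording(data))
        assert {e["trial"] for e in log} == {4}
        assert log[0]["rule"] == "low_activity"

    def test_gradient_rejected(self):
        data = self._base()
        data[1, 2, 600:] += 220.0  # step > 200 uV within any 200 ms window
        kept, log = reject_artifacts(_recording(data))
        assert any(e["trial"] == 1 and e["rule"] in ("amplitude", "gradient")
                   for e in log)

    def test_clean_sine_kept(self):
        t_ax = np.arange(1500) / RATE
        data = np.tile(50.0 * np.sin(2 * np.pi * 10.0 * t_ax), (3, 4, 1))
        kept, log = reject_artifacts(_recording(data))
        assert kept.n_trials == 3
        assert log == []

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(3)
        data = self._base(n=20)
        # sprinkle artifacts of each kind
        data[3, 0, 100] = 230.0
        data[7, 1, 400:900] = -2.0
        data[11, 2, 800:] += 260.0
        data[15, 0, :] *= 4.5  # large swings: gradient rule via sine slope
        crit = RejectionCriteria()
        kept, log = reject_artifacts(_recording(data), crit)
        brute = brute_force_rules(data, RATE, crit)
        expect_rejected = {i for i, f in enumerate(brute) if any(f)}
        assert {e["trial"] for e in log} == expect_rejected
        # first-rule attribution matches the a -> b -> c precedence
        order = ("amplitude", "gradient", "low_activity")
        for e in log:
            flags = brute[e["trial"]]
            first = next(r for r, f in zip(order, flags) if f)
            assert e["rule"] == first


class TestCsd:
    def test_uniform_potential_annihilated(self, montage19):
        names, pos = montage19
        rec = _recording(np.full((2, 19, 5), 10.0), names=names, pos=pos)
        out = csd_transform(rec)
        assert np.abs(out.data).max() < 1e-6 * 10.0

    def test_linearity(self, tiny_recording):
        one = csd_transform(tiny_recording)
        two = csd_transform(tiny_recording.copy_with(2.0 * tiny_recording.data))
        np.testing.assert_allclose(two.data, 2.0 * one.data, rtol=1e-5, atol=1e-8)

    def test_impulse_center_surround(self, montage19):
        names, pos = montage19
        data = np.zeros((1, 19, 1))
        ich = names.index("Pz")
        data[0, ich, 0] = 1.0
        out = csd_transform(_recording(data, names=names, pos=pos))
        v = out.data[0, :, 0]
        neighbours = np.argsort(-(pos @ pos[ich]))[1:3]
        assert v[ich] > 0
        assert np.all(v[neighbours] < 0)

    def test_matches_mne_reference(self, montage19):
        """Cross-check the spline Laplacian against MNE's implementation."""
        mne = pytest.importorskip("mne")
        names, pos = montage19
        rng = np.random.default_rng(1)
        data = rng.normal(size=(2, 19, 4))
        radius = 0.1
        info = mne.create_info(names, 125.0, ch_types="eeg")
        mont = mne.channels.make_dig_montage(
            ch_pos={n: p * radius for n, p in zip(names, pos)},
            coord_frame="head")
        ep = mne.EpochsArray(data * 1e-6, info, verbose="error")
        ep.set_montage(mont)
        ref = mne.preprocessing.compute_current_source_density(
            ep, sphere=(0.0, 0.0, 0.0, radius), stiffness=4, lambda2=1e-5,
            n_legendre_terms=50, verbose="error").get_data()
        ours = csd_transform(
            _recording(data, rate=125.0, names=names, pos=pos),
            params=CsdParams(head_radius=radius)).data * 1e-6
        np.testing.assert_allclose(ours, ref, rtol=1e-6,
                                   atol=1e-9 * np.abs(ref).max())

    def test_duplicate_positions_rejected(self, montage19):
        names, pos = montage19
        pos = pos.copy()
        pos[1] = pos[0]
        with pytest.raises(ValueError, match="duplicate"):
            csd_matrices(pos)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            CsdParams(m=1)
        with pytest.raises(ValueError):
            CsdParams(legendre_terms=5)
        with pytest.raises(ValueError):
            CsdParams(smoothing=-1.0)
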