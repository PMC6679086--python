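"""Synthetic multi-subject ERP cohort generator.

Simulates three-group (control / ADD / ADHD) epoched EEG with known
ground-truth discriminative structure so that the entire decoding pipeline
— preprocessing, classifier training, leave-one-subject-out evaluation,
chance-level statistics, saliency attribution — is testable end to end
without any clinical recordings.

The generative model for one trial is

    x(c, t) = sum_i a_i * g_i(c) * exp(-(t - mu_i)^2 / (2 s_i^2)) + noise(c, t)

a sum of Gaussian-windowed deflections (stand-ins for stimulus-locked ERP
components such as P1 / N1 / P2) plus 1/f^alpha background noise.  Group
membership enters through the component amplitudes and topographies;
subject identity enters through multiplicative amplitude jitter and additive
latency jitter; trial-to-trial variability enters through per-trial latency
jitter and independent noise.  A configurable fraction of patient subjects
("effect carriers") expresses the group effect; the remainder receive the
control template, mimicking the empirical observation that a subset of
subjects is not classifiable from their EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import EpochedRecording
from . import montage


@dataclass
class ErpComponent:
    """One Gaussian-windowed ERP deflection.

    latency/width in ms (Gaussian mean / SD), amplitude in microvolts
    (signed), channel_gains a per-channel topography in [-1, 1].
    """

    label: str
    latency: float
    width: float
    amplitude: float
    channel_gains: np.ndarray

    def __post_init__(self):
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)
        if self.width <= 0:
            raise ValueError(f"component {self.label!r}: width must be > 0")


@dataclass
class CohortConfig:
    """Simulator parameters for one synthetic cohort.

    components maps group label -> list of ErpComponent.  Trial counts are
    drawn per subject from round(Normal(trial_count_mean, trial_count_sd))
    clipped below at 50.  noise_sd is the RMS of the 1/f^alpha background in
    microvolts; one_over_f_exponent = 0 gives white noise.
    """

    components: dict
    n_subjects_per_group: int = 10
    groups: tuple = ("control", "ADD", "ADHD")
    control_group: str = "control"
    trial_count_mean: float = 235.0
    trial_count_sd: float = 50.0
    effect_carrier_fraction: float = 1.0
    noise_sd: float = 10.0
    one_over_f_exponent: float = 1.0
    amplitude_jitter: float = 0.15
    latency_jitter: float = 10.0
    trial_latency_jitter: float = 5.0
    artifact_fraction: float = 0.0
    sampling_rate: float = 500.0
    epoch_window: tuple = (-200.0, 3000.0)
    channel_names: list = field(default_factory=lambda: list(montage.CHANNELS_56))
    channel_positions: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be positive")
        if self.trial_count_mean <= 0:
            raise ValueError("trial_count_mean must be positive")
        for name, frac in (("effect_carrier_fraction", self.effect_carrier_fraction),
                           ("artifact_fraction", self.artifact_fraction)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (self.epoch_window[0] <= -200.0 and self.epoch_window[1] >= 0.0):
            raise ValueError("epoch window must contain the [-200, 0] ms baseline")
        if self.channel_positions is None:
            self.channel_positions = montage.positions_for(self.channel_names)
        for group in self.groups:
            if group not in self.components:
                raise ValueError(f"no components defined for group {group!r}")

    @property
    def n_samples(self) -> int:
        span = self.epoch_window[1] - self.epoch_window[0]
        return int(round(span * self.sampling_rate / 1000.0))


def generate_erp_template(components, channel_names, epoch_window, sampling_rate):
    """Noise-free (channels, samples) template: sum of Gaussian deflections.

    Linear in component amplitudes.  Raises if a component's latency falls
    outside the epoch window or its topography does not match the montage.
    """
    n_channels = len(channel_names)
    t0, t1 = epoch_window
    n_samples = int(round((t1 - t0) * sampling_rate / 1000.0))
    times = t0 + 1000.0 * np.arange(n_samples) / sampling_rate
    template = np.zeros((n_channels, n_samples))
    for comp in components:
        if not (t0 <= comp.latency <= t1):
            raise ValueError(
                f"component {comp.label!r}: latency {comp.latency} ms outside "
                f"epoch window [{t0}, {t1}] ms"
            )
        if comp.channel_gains.shape != (n_channels,):
            raise ValueError(
                f"component {comp.label!r}: channel_gains length "
                f"{comp.channel_gains.size} != channel count {n_channels}"
            )
        wave = np.exp(-0.5 * ((times - comp.latency) / comp.width) ** 2)
        template += comp.amplitude * np.outer(comp.channel_gains, wave)
    return template


def one_over_f_noise(rng, shape, exponent, sd, sampling_rate):
    """Gaussian noise with a 1/f^exponent amplitude spectrum, RMS = sd.

    Synthesized by spectrally shaping white noise in the frequency domain
    (the DC bin is zeroed); exponent 0 reduces to white noise.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    if exponent == 0:
        spec_noise = white
    else:
        freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
        scale = np.zeros_like(freqs)
        scale[1:] = freqs[1:] ** (-exponent / 2.0)
        spec = np.fft.rfft(white, axis=-1) * scale
        spec_noise = np.fft.irfft(spec, n=n, axis=-1)
    rms = np.sqrt(np.mean(spec_noise ** 2, axis=-1, keepdims=True))
    rms = np.where(rms == 0, 1.0, rms)
    return sd * spec_noise / rms


def _jittered(components, rng, amp_jitter, lat_jitter):
    out = []
    for comp in components:
        out.append(replace(
            comp,
            amplitude=comp.amplitude * (1.0 + amp_jitter * rng.standard_normal()),
            latency=comp.latency + lat_jitter * rng.standard_normal(),
        ))
    return out


def ground_truth_mask(config: CohortConfig, group: str,
                      rel_threshold: float = 0.25):
    """(channel_mask, time_window_ms) where ``group`` differs from control.

    A channel is marked discriminative when its peak template difference
    from control reaches ``rel_threshold`` of the maximum difference across
    channels (Gaussian topographies never reach exactly zero, so an
    absolute criterion would mark every channel).  The window is the union
    of latency +- 2 widths over the differing components.
    """
    ctrl = {c.label: c for c in config.components[config.control_group]}
    diff_peak = np.zeros(len(config.channel_names))
    lo, hi = np.inf, -np.inf
    def add(diff, comp):
        nonlocal lo, hi
        np.maximum(diff_peak, diff, out=diff_peak)
        lo = min(lo, comp.latency - 2 * comp.width)
        hi = max(hi, comp.latency + 2 * comp.width)
    for comp in config.components[group]:
        ref = ctrl.get(comp.label)
        eff_ref = ref.amplitude * ref.channel_gains if ref is not None else 0.0
        diff = np.abs(comp.amplitude * comp.channel_gains - eff_ref)
        if np.any(diff > 1e-12):
            add(diff, comp)
    for ref in config.components[config.control_group]:
        if not any(c.label == ref.label for c in config.components[group]):
            add(np.abs(ref.amplitude * ref.channel_gains), ref)
    if diff_peak.max() <= 0:
        return np.zeros(len(config.channel_names), dtype=bool), None
    chan_mask = diff_peak >= rel_threshold * diff_peak.max()
    return chan_mask, (float(lo), float(hi))


def simulate_cohort(config: CohortConfig):
    """Generate the cohort: list of EpochedRecording, one per subject.

    Identical config (including seed) produces bit-identical output.  Each
    recording's ground_truth records the subject's effect-carrier status and
    the injected discriminative channels/window of its group.
    """
    rng = np.random.default_rng(config.seed)
    t0, t1 = config.epoch_window
    recordings = []
    for group in config.groups:
        is_control = group == config.control_group
        chan_mask, window = ground_truth_mask(config, group) if not is_control else (None, None)
        for i in range(config.n_subjects_per_group):
            n_trials = int(round(rng.normal(config.trial_count_mean,
                                            config.trial_count_sd)))
            n_trials = max(n_trials, 50)
            carrier = True
            if not is_control:
                carrier = bool(rng.random() < config.effect_carrier_fraction)
            comp_source = config.components[group if carrier else config.control_group]
            subj_comps = _jittered(comp_source, rng, config.amplitude_jitter,
                                   config.latency_jitter)
            trials = np.empty((n_trials, len(config.channel_names),
                               config.n_samples), dtype=np.float32)
            for j in range(n_trials):
                comps = subj_comps
                if config.trial_latency_jitter > 0:
                    shift = config.trial_latency_jitter * rng.standard_normal()
                    comps = [replace(c, latency=c.latency + shift) for c in subj_comps]
                template = generate_erp_template(
                    comps, config.channel_names, config.epoch_window,
                    config.sampling_rate)
                if config.noise_sd > 0:
                    template = template + one_over_f_noise(
                        rng, template.shape, config.one_over_f_exponent,
                        config.noise_sd, config.sampling_rate)
                trials[j] = template
            rec = EpochedRecording(
                subject_id=f"{group}_{i:02d}", group=group, data=trials,
                sampling_rate=config.sampling_rate, epoch_start=t0,
                channel_names=list(config.channel_names),
                channel_positions=config.channel_positions,
                ground_truth={
                    "effect_carrier": carrier,
                    "effect_channels": None if chan_mask is None else chan_mask.tolist(),
                    "effect_window_ms": window,
                },
            )
            if config.artifact_fraction > 0:
                rec, idx = inject_artifacts(rec, config.artifact_fraction, rng)
                rec.ground_truth["artifact_trials"] = [int(k) for k in idx]
            recordings.append(rec)
    return recordings


def inject_artifacts(recording: EpochedRecording, fraction: float, rng):
    """Contaminate a share of trials with one artifact each.

    Artifact types cycle through: amplitude spike beyond +-200 uV, a step of
    more than 200 uV within 200 ms, and a flat (< 0.5 uV peak-to-peak)
    stretch of at least 100 ms.  Returns (new recording, sorted indices of
    modified trials); all other trials are bit-identical to the input.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n = recording.n_trials
    n_bad = int(round(fraction * n))
    idx = np.sort(rng.choice(n, size=n_bad, replace=False))
    data = recording.data.copy()
    fs = recording.sampling_rate
    n_samp = recording.n_samples
    for rank, j in enumerate(idx):
        ch = int(rng.integers(recording.n_channels))
        kind = rank % 3
        if kind == 0:  # spike
            t = int(rng.integers(0, n_samp))
            sign = -1.0 if rng.random() < 0.5 else 1.0
            data[j, ch, t] += sign * rng.uniform(250.0, 400.0)
        elif kind == 1:  # step within < 200 ms
            t = int(rng.integers(0, n_samp - 1))
            data[j, ch, t:] += rng.uniform(230.0, 350.0)
        else:  # low activity for >= 100 ms
            w = int(round(0.150 * fs)) + 1
            t = int(rng.integers(0, n_samp - w))
            data[j, ch, t : t + w] = data[j, ch, t]
    return recording.copy_with(data), idx


# ---------------------------------------------------------------------------
# Default study-like component sets


def default_components(channel_names=None, positions=None, patient_attenuation=0.7):
    """Study-like component dictionary for the three groups.

    Controls carry P1 (110 ms, occipital), N1 (170 ms, parieto-occipital),
    P2 (240 ms, parietal), a late parietal positivity and a slow
    fronto-central negativity (interval-timing preparation).  Patient groups
    express attenuated early components (default 70% of control amplitude)
    over parietal/occipital sites — ADD predominantly occipital, ADHD
    predominantly parietal — leaving later activity unchanged.
    """
    if channel_names is None:
        channel_names, positions = montage.standard_1010_56()
    if positions is None:
        positions = montage.positions_for(channel_names)

    def topo(focus, spread=35.0):
        return montage.topography(channel_names, positions, focus, spread)

    def comps(p1_amp, n1_amp, p2_amp):
        return [
            ErpComponent("P1", 110.0, 25.0, p1_amp, topo("Oz", 30.0)),
            ErpComponent("N1", 170.0, 30.0, n1_amp, topo("Pz", 40.0)),
            ErpComponent("P2", 240.0, 40.0, p2_amp, topo("Pz", 35.0)),
            ErpComponent("P3b", 420.0, 80.0, 5.0, topo("Pz", 45.0)),
            ErpComponent("CNV", 1100.0, 300.0, -4.0, topo("Cz", 50.0)),
        ]

    a = patient_attenuation
    return {
        "control": comps(6.0, -8.0, 7.0),
        "ADD": comps(6.0 * a, -8.0 * a, 7.0),      # occipital/parieto-occipital
        "ADHD": comps(6.0, -8.0 * a, 7.0 * a),     # parietal-weighted
    }
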