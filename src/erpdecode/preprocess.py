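"""Single-trial preprocessing: band-pass, baseline, rejection, CSD.

The chain mirrors standard ERP practice: zero-phase band-pass filtering
(0.5–20 Hz, 4th-order Butterworth applied forward-backward, i.e. an
effective 48 dB/oct roll-off), baseline correction over the pre-stimulus
interval, automated per-trial artifact rejection (amplitude, gradient and
low-activity criteria), and a reference-free current-source-density
transform via Perrin-style spherical splines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .containers import EpochedRecording


@dataclass(frozen=True)
class RejectionCriteria:
    """Automated artifact-rejection thresholds.

    A trial is rejected if, on any channel, (a) any sample exceeds amp_max
    or falls below amp_min; (b) the value range within any sliding window of
    diff_window ms exceeds max_diff; or (c) the range within some sliding
    window of low_window ms falls below low_activity.
    """

    amp_max: float = 200.0
    amp_min: float = -200.0
    max_diff: float = 200.0
    diff_window: float = 200.0
    low_activity: float = 0.5
    low_window: float = 100.0

    def __post_init__(self):
        if self.amp_max <= self.amp_min:
            raise ValueError("amp_max must exceed amp_min")
        if self.diff_window <= 0 or self.low_window <= 0:
            raise ValueError("criterion windows must be positive")


@dataclass(frozen=True)
class CsdParams:
    """Spherical-spline surface-Laplacian parameters.

    m is the spline stiffness (order), legendre_terms the truncation of the
    Legendre series, smoothing the Tikhonov regularization added to the
    diagonal of the G matrix, head_radius the assumed sphere radius in
    metres (sets the uV/m^2 scale).
    """

    m: int = 4
    legendre_terms: int = 50
    smoothing: float = 1e-5
    head_radius: float = 0.1

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("spline order m must be >= 2")
        if self.legendre_terms < 10:
            raise ValueError("legendre_terms must be >= 10")
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")


def bandpass_filter(recording: EpochedRecording, low: float = 0.5,
                    high: float = 20.0) -> EpochedRecording:
    """Zero-phase Butterworth band-pass (4th order, forward-backward).

    The two-pass application doubles the one-pass 24 dB/oct slope to an
    effective 48 dB/oct and cancels phase distortion, preserving component
    latencies.
    """
    nyq = recording.sampling_rate / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(
            f"cutoffs must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got ({low}, {high})"
        )
    sos = signal.butter(4, [low, high], btype="bandpass",
                        fs=recording.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data.astype(np.float64), axis=-1)
    return recording.copy_with(filtered.astype(recording.data.dtype))


def baseline_correct(recording: EpochedRecording,
                     window=(-200.0, 0.0)) -> EpochedRecording:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    lo, hi = window
    if lo >= hi:
        raise ValueError("baseline window must have positive length")
    if lo < recording.epoch_start - 1e-9 or hi > recording.epoch_end + 1e-9:
        raise ValueError(
            f"baseline window [{lo}, {hi}] ms outside epoch "
            f"[{recording.epoch_start}, {recording.epoch_end}] ms"
        )
    i0 = recording.time_to_sample(lo)
    i1 = max(recording.time_to_sample(hi), i0 + 1)
    base = recording.data[:, :, i0:i1].mean(axis=-1, keepdims=True)
    return recording.copy_with(recording.data - base)


def _sliding_range(x: np.ndarray, width: int) -> np.ndarray:
    """Max-minus-min over every fully-contained sliding window of ``width``.

    x is (..., T); returns (..., T - width + 1).
    """
    off = width // 2
    mx = maximum_filter1d(x, size=width, axis=-1, mode="nearest")
    mn = minimum_filter1d(x, size=width, axis=-1, mode="nearest")
    T = x.shape[-1]
    sl = slice(off, off + T - width + 1)
    return mx[..., sl] - mn[..., sl]


def reject_artifacts(recording: EpochedRecording,
                     criteria: RejectionCriteria = RejectionCriteria()):
    """Drop trials violating any rejection criterion on any channel.

    Returns (kept recording, log) where log is a list of dicts
    {trial, channel, rule} recording, per rejected trial, the first violated
    rule in the order amplitude -> gradient -> low_activity and the lowest
    offending channel for that rule.
    """
    data = recording.data
    fs = recording.sampling_rate
    wd = int(round(criteria.diff_window * fs / 1000.0))
    wl = int(round(criteria.low_window * fs / 1000.0))
    if wd < 1 or wl < 1:
        raise ValueError("criterion windows shorter than one sample")
    wd = min(wd, data.shape[-1])
    wl = min(wl, data.shape[-1])

    amp_bad = np.any((data > criteria.amp_max) | (data < criteria.amp_min), axis=-1)
    diff_bad = np.any(_sliding_range(data, wd) > criteria.max_diff, axis=-1)
    low_bad = np.any(_sliding_range(data, wl) < criteria.low_activity, axis=-1)

    log = []
    rejected = np.zeros(recording.n_trials, dtype=bool)
    for j in range(recording.n_trials):
        for rule, bad in (("amplitude", amp_bad[j]), ("gradient", diff_bad[j]),
                          ("low_activity", low_bad[j])):
            if bad.any():
                log.append({"trial": j, "channel": int(np.argmax(bad)),
                            "rule": rule})
                rejected[j] = True
                break
    kept = recording.copy_with(recording.data[~rejected])
    return kept, log


# ---------------------------------------------------------------------------
# Current source density (spherical-spline surface Laplacian)


def _legendre_gh(cosang: np.ndarray, m: int, n_terms: int):
    """G and H kernels of the spherical-spline interpolator.

    g(x) = (1/4pi) sum_n (2n+1) / (n(n+1))^m     * P_n(x)
    h(x) = (1/4pi) sum_n (2n+1) / (n(n+1))^(m-1) * P_n(x)
    """
    n = np.arange(1, n_terms + 1)
    factors = (2 * n + 1) / (n * (n + 1.0)) ** m
    factors_h = (2 * n + 1) / (n * (n + 1.0)) ** (m - 1)
    coef_g = np.concatenate(([0.0], factors)) / (4 * np.pi)
    coef_h = np.concatenate(([0.0], factors_h)) / (4 * np.pi)
    return npleg.legval(cosang, coef_g), npleg.legval(cosang, coef_h)


def csd_matrices(positions: np.ndarray, params: CsdParams = CsdParams()):
    """Precompute the CSD operator pieces (LU-factorizable system and H).

    positions must be distinct unit vectors, one per channel.
    """
    from scipy.linalg import lu_factor

    pos = np.asarray(positions, dtype=float)
    norms = np.linalg.norm(pos, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("electrode positions must lie on the unit sphere")
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    nch = len(pos)
    if np.any(cosang[~np.eye(nch, dtype=bool)] > 1 - 1e-12):
        raise ValueError("duplicate electrode positions")
    G, H = _legendre_gh(cosang, params.m, params.legendre_terms)
    G = G + params.smoothing * np.eye(nch)
    # augmented system enforcing sum(c) = 0 (charge conservation)
    A = np.zeros((nch + 1, nch + 1))
    A[:nch, :nch] = G
    A[:nch, nch] = 1.0
    A[nch, :nch] = 1.0
    try:
        lu = lu_factor(A)
    except Exception as exc:  # singular regularized system
        raise np.linalg.LinAlgError(
            f"regularized spline system is singular (lambda={params.smoothing})"
        ) from exc
    return lu, H


def csd_transform(recording: EpochedRecording, positions=None,
                  params: CsdParams = CsdParams()) -> EpochedRecording:
    """Surface-Laplacian (CSD) transform of every trial, in uV/m^2.

    Spline coefficients are solved per time sample under the zero-sum
    constraint; the operator is linear and annihilates spatially uniform
    potentials.
    """
    from scipy.linalg import lu_solve

    if positions is None:
        positions = recording.channel_positions
    lu, H = csd_matrices(positions, params)
    n_tr, nch, n_samp = recording.data.shape
    V = recording.data.reshape(n_tr, nch, n_samp).transpose(1, 0, 2).reshape(nch, -1)
    rhs = np.vstack([V, np.zeros((1, V.shape[1]))])
    sol = lu_solve(lu, rhs)
    coeffs = sol[:nch]
    out = (H.T @ coeffs) / params.head_radius ** 2
    out = out.reshape(nch, n_tr, n_samp).transpose(1, 0, 2)
    return recording.copy_with(out.astype(recording.data.dtype))


def preprocess_recording(recording: EpochedRecording, low: float = 0.5,
                         high: float = 20.0, baseline=(-200.0, 0.0),
                         criteria: RejectionCriteria = RejectionCriteria(),
                         csd: bool = True,
                         csd_params: CsdParams = CsdParams()):
    """Full chain: filter -> baseline -> reject -> (optional) CSD.

    Returns (processed recording, rejection log).
    """
    rec = bandpass_filter(recording, low, high)
    rec = baseline_correct(rec, baseline)
    rec, log = reject_artifacts(rec, criteria)
    if csd:
        rec = csd_transform(rec, params=csd_params)
    return rec, log
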