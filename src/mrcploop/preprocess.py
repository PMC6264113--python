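"""EEG conditioning: zero-phase band-pass, decimation and Cz-centred spatial filtering.

The standard chain mirrors the BCI's calibration path: 0.05-10 Hz 2nd-order
zero-phase Butterworth, decimation to 32 Hz (the 10 Hz low-pass doubles as the
anti-alias filter), then a zero-sum spatial filter centred on Cz that collapses
the montage to a single surrogate channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, signal

from .errors import (
    InsufficientDataError, InvalidArgumentError, InvalidConfigError, MissingChannelError,
)
from .types import EEGRecording

__all__ = [
    "FilterSpec", "SpatialFilter", "large_laplacian",
    "bandpass_zero_phase", "bandpass_causal", "downsample",
    "apply_spatial_filter", "optimize_spatial_weights",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (defaults 0.05-10 Hz, order 2)."""

    low: float = 0.05
    high: float = 10.0
    order: int = 2
    kind: str = "bandpass"

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise InvalidConfigError("need 0 < low < high")
        if self.order < 1:
            raise InvalidConfigError("order must be >= 1")
        if self.kind != "bandpass":
            raise InvalidConfigError("only bandpass filters are supported")

    def sos(self, rate: float) -> np.ndarray:
        if self.high >= rate / 2:
            raise InvalidConfigError(
                f"high corner {self.high} Hz is not below Nyquist ({rate / 2} Hz)")
        return signal.butter(self.order, (self.low, self.high),
                             btype="bandpass", fs=rate, output="sos")


@dataclass(frozen=True)
class SpatialFilter:
    """Zero-sum channel weights with a dominant centre electrode.

    Invariants: the centre carries the largest |weight|; the remaining weights
    sum to minus the centre weight (total zero-sum); FP1 is never mixed in
    (weight 0) since it carries ocular artifact.
    """

    weights: dict[str, float]
    center: str = "Cz"

    def __post_init__(self):
        w = dict(self.weights)
        object.__setattr__(self, "weights", w)
        if self.center not in w:
            raise InvalidConfigError("center channel missing from weights")
        if abs(w.get("FP1", 0.0)) > 1e-12:
            raise InvalidConfigError("FP1 weight must be 0")
        total = sum(w.values())
        if abs(total) > 1e-9 * max(1.0, max(abs(v) for v in w.values())):
            raise InvalidConfigError("spatial filter weights must sum to zero")
        wc = abs(w[self.center])
        if any(abs(v) > wc + 1e-12 for k, v in w.items() if k != self.center):
            raise InvalidConfigError("center must carry the largest |weight|")


def large_laplacian(center: str = "Cz",
                    neighbors: tuple[str, ...] = ("C3", "C4", "Fz", "Pz")) -> SpatialFilter:
    """The fixed fallback: centre 1, four surrounding electrodes -0.25 each."""
    w = {center: 1.0}
    for n in neighbors:
        w[n] = -1.0 / len(neighbors)
    return SpatialFilter(weights=w, center=center)


def bandpass_zero_phase(rec: EEGRecording, spec: FilterSpec = FilterSpec()) -> EEGRecording:
    """Forward-backward Butterworth filtering (no phase distortion).

    Edge padding is three times the filter's impulse-response settling length
    (~1/low corner), capped by the record length; the very slow 0.05 Hz corner
    otherwise leaks transients deep into short records.
    """
    sos = spec.sos(rec.rate)
    padlen = min(rec.n_samples - 1, int(3 * rec.rate / spec.low))
    data = signal.sosfiltfilt(sos, rec.data, axis=-1, padlen=padlen)
    return replace(rec, data=data)


def bandpass_causal(rec: EEGRecording, spec: FilterSpec = FilterSpec()) -> EEGRecording:
    """Causal (online) version of the band-pass; introduces the filter's phase lag."""
    sos = spec.sos(rec.rate)
    data = signal.sosfilt(sos, rec.data, axis=-1)
    return replace(rec, data=data)


def downsample(rec: EEGRecording, target_rate: float) -> EEGRecording:
    """Decimate to ``target_rate`` by an integer factor.

    The caller must band-limit below ``target_rate / 2`` first; in the
    standard chain the 10 Hz band-pass guarantees this for the 32 Hz target
    (2048 / 32 = 64 exactly).
    """
    if target_rate >= rec.rate:
        raise InvalidArgumentError("target_rate must be below the current rate")
    factor = rec.rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise InvalidArgumentError(
            f"target_rate {target_rate} must divide the rate {rec.rate}")
    factor = int(round(factor))
    return replace(rec, data=rec.data[..., ::factor].copy(), rate=target_rate)


def apply_spatial_filter(rec: EEGRecording, filt: SpatialFilter) -> np.ndarray:
    """Per-sample weighted sum over channels -> single surrogate channel."""
    out = np.zeros(rec.n_samples)
    for label, w in filt.weights.items():
        if abs(w) < 1e-300:
            continue
        out += w * rec.channel(label)
    return out


def _objective(w: np.ndarray, A: np.ndarray, B: np.ndarray) -> float:
    den = w @ B @ w
    return float(w @ A @ w / den) if den > 0 else np.inf


def spatial_filter_objective(epochs: np.ndarray, filt: SpatialFilter,
                             channels: tuple[str, ...]) -> float:
    """Template-window SNR of a filter on an epoch stack (mean-power ratio)."""
    A, B = _snr_matrices(np.asarray(epochs, dtype=float))
    w = np.array([filt.weights.get(c, 0.0) for c in channels])
    return _objective(w, A, B)


def _snr_matrices(epochs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signal (epoch-average) and noise (residual) channel covariance matrices."""
    mean = epochs.mean(axis=0)                       # (ch, T)
    resid = epochs - mean[None]
    T = epochs.shape[2]
    A = mean @ mean.T / T
    B = np.einsum("ect,edt->cd", resid, resid) / (max(epochs.shape[0] - 1, 1) * T)
    B += 1e-12 * np.trace(B) / B.shape[0] * np.eye(B.shape[0])
    return A, B


def optimize_spatial_weights(
    epochs: np.ndarray,
    channels: tuple[str, ...],
    center: str = "Cz",
    snr_floor: float = 1.0,
) -> SpatialFilter:
    """Zero-sum weights maximizing template-window SNR (generalized eigenproblem).

    ``epochs`` has shape (n_epochs, n_channels, n_samples) and should already
    be restricted to the template window. The SNR objective is the power of
    the epoch average passed through the filter over the power of the
    epoch-to-epoch residual. The search space honours the SpatialFilter
    invariants (zero-sum, FP1 excluded); whenever the problem is
    ill-conditioned, the best SNR does not beat ``snr_floor`` (no recoverable
    evoked signal), or the solution violates the centre-dominance invariant,
    the fixed large-Laplacian fallback is returned.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] < 2:
        raise InsufficientDataError("need >= 2 epochs of shape (epoch, channel, sample)")
    if center not in channels:
        raise MissingChannelError(center)
    fallback = large_laplacian(center=center)
    if not all(c in channels for c in fallback.weights):
        raise MissingChannelError("fallback Laplacian channels missing")

    A, B = _snr_matrices(epochs)
    # Constraint basis: FP1 weight 0 and zero total sum.
    usable = [i for i, c in enumerate(channels) if c != "FP1"]
    k = len(usable)
    ones = np.ones((k, 1))
    P_zero_sum = linalg.null_space(ones.T)           # (k, k-1)
    P = np.zeros((len(channels), k - 1))
    P[usable, :] = P_zero_sum

    Ar, Br = P.T @ A @ P, P.T @ B @ P
    try:
        vals, vecs = linalg.eigh(Ar, Br)
    except linalg.LinAlgError:
        return fallback
    if not np.all(np.isfinite(vals)):
        return fallback
    best_snr = vals[-1]
    if best_snr < snr_floor:
        return fallback
    w = P @ vecs[:, -1]
    ci = channels.index(center)
    if abs(w[ci]) < 1e-12 or abs(w[ci]) < np.max(np.abs(w)) - 1e-12:
        return fallback
    w = w / w[ci]                                     # centre weight +1
    w = w - w.sum() / len(usable) * np.isin(np.arange(len(channels)), usable)
    weights = {c: float(w[i]) for i, c in enumerate(channels)}
    weights["FP1"] = 0.0
    try:
        cand = SpatialFilter(weights=weights, center=center)
    except InvalidConfigError:
        return fallback
    # Keep the candidate only if it actually beats the fallback's objective.
    wf = np.array([fallback.weights.get(c, 0.0) for c in channels])
    if _objective(np.array([weights[c] for c in channels]), A, B) < _objective(wf, A, B):
        return fallback
    return cand
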