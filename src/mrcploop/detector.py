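"""Self-paced MRCP detector: template, matched filtering, ROC calibration, online pass.

Calibration works on the zero-phase-preprocessed 32 Hz surrogate channel: the
template is the mean-subtracted epoch average of the 2 s of EEG preceding each
EMG-confirmed movement onset, and the detector output is the normalized
(Pearson) correlation between the template and the signal window ending at the
current sample, so thresholds are scale-free across subjects and sessions.

The calibration ROC counts detections as similarity peaks separated by at
least the lockout (refractory) interval; counting peaks rather than raw
threshold crossings makes both the true-positive rate and the false-positive
rate non-increasing in the threshold by construction. The online pass is
causal: a causal band-pass replaces the zero-phase training filter, detections
fire on upward threshold crossings, the detector is then disabled for the
lockout interval, and no detection may fire while the frontopolar channel
exceeds the artifact limit (or within a short guard window afterwards).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientDataError, InvalidArgumentError, MissingChannelError
from .preprocess import (
    FilterSpec, SpatialFilter, apply_spatial_filter, bandpass_causal,
    bandpass_zero_phase, downsample, large_laplacian, optimize_spatial_weights,
)
from .types import EEGRecording

__all__ = [
    "MRCPTemplate", "ROCCurve", "DetectorConfig", "DetectionLog", "Calibration",
    "extract_epochs", "extract_template", "match_template", "compute_roc",
    "select_threshold", "run_online_detection", "match_events", "calibrate",
]

SURROGATE_RATE = 32.0


@dataclass
class MRCPTemplate:
    """Mean-subtracted epoch-average MRCP template at 32 Hz.

    ``window`` is relative to the movement onset and must end at or before it
    (the detector sees only the pre-movement negativity).
    """

    samples: np.ndarray
    window: tuple[float, float] = (-2.0, 0.0)
    n_train: int = 1
    rate: float = SURROGATE_RATE

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.window[1] > 0:
            raise InvalidArgumentError("template window must end at or before the onset")
        if self.n_train < 1:
            raise InvalidArgumentError("n_train must be >= 1")


@dataclass
class ROCCurve:
    """Detection trade-off over a threshold grid (rates per 10 min of data)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fp_per_10min: np.ndarray

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        self.fp_per_10min = np.asarray(self.fp_per_10min, dtype=float)


@dataclass
class DetectorConfig:
    """Online detector settings: similarity threshold, refractory lockout,
    frontopolar artifact gate and the TP matching tolerance."""

    threshold: float = 0.7
    lockout: float = 5.0
    artifact_channel: str = "FP1"
    artifact_limit: float = 125.0
    artifact_guard: float = 0.5
    tp_tolerance: float = 1.0

    def __post_init__(self):
        if self.lockout <= 0:
            raise InvalidArgumentError("lockout must be positive")
        if self.artifact_limit <= 0:
            raise InvalidArgumentError("artifact_limit must be positive")


@dataclass
class DetectionLog:
    """Labelled detector output for one run: (time, label) detections with
    label in {TP, FP}, missed onsets (FN), and the run duration in seconds."""

    detections: list[tuple[float, str]]
    misses: list[float]
    duration: float

    @property
    def tp(self) -> int:
        return sum(1 for _, lab in self.detections if lab == "TP")

    @property
    def fp(self) -> int:
        return sum(1 for _, lab in self.detections if lab == "FP")

    @property
    def fn(self) -> int:
        return len(self.misses)


@dataclass
class Calibration:
    """Everything the online detector needs, as produced by ``calibrate``."""

    template: MRCPTemplate
    spatial: SpatialFilter
    filter_spec: FilterSpec
    config: DetectorConfig
    roc: ROCCurve | None = None


def extract_epochs(surrogate: np.ndarray, rate: float, onsets,
                   window: tuple[float, float]) -> np.ndarray:
    """Stack complete windows (relative to each onset) from a 1-D signal."""
    surrogate = np.asarray(surrogate, dtype=float)
    i0 = int(round(window[0] * rate))
    i1 = int(round(window[1] * rate))
    out = []
    for t in np.asarray(onsets, dtype=float):
        c = int(round(t * rate))
        if c + i0 >= 0 and c + i1 <= surrogate.size:
            out.append(surrogate[c + i0: c + i1])
    if not out:
        raise InsufficientDataError("no onset has a complete window inside the record")
    return np.asarray(out)


def extract_template(surrogate: np.ndarray, rate: float, onsets,
                     window: tuple[float, float] = (-2.0, 0.0)) -> MRCPTemplate:
    """Pointwise mean over epochs, then mean-subtracted."""
    epochs = extract_epochs(surrogate, rate, onsets, window)
    mean = epochs.mean(axis=0)
    return MRCPTemplate(samples=mean - mean.mean(), window=window,
                        n_train=epochs.shape[0], rate=rate)


def match_template(surrogate: np.ndarray, template: MRCPTemplate) -> np.ndarray:
    """Normalized cross-correlation trace.

    ``out[t]`` is the Pearson correlation between the template and the signal
    window *ending* at sample ``t`` (inclusive); values lie in [-1, 1]. The
    first ``len(template) - 1`` samples, where no full window exists, are 0,
    as are samples whose window has zero variance.
    """
    x = np.asarray(surrogate, dtype=float)
    tmpl = template.samples - template.samples.mean()
    L = tmpl.size
    if x.size < L:
        raise InvalidArgumentError("signal shorter than template")
    t_norm = np.sqrt(np.sum(tmpl ** 2))
    out = np.zeros(x.size)
    if t_norm == 0:
        return out
    win = np.lib.stride_tricks.sliding_window_view(x, L)      # (n-L+1, L)
    wmean = win.mean(axis=1)
    num = win @ tmpl                                           # sum((w - mean)*t) since t sums to 0
    wss = np.einsum("ij,ij->i", win, win) - win.shape[1] * wmean ** 2
    wss = np.maximum(wss, 0.0)
    den = np.sqrt(wss) * t_norm
    corr = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-12 * t_norm)
    out[L - 1:] = np.clip(corr, -1.0, 1.0)
    return out


def match_events(detection_times, true_onsets, tolerance: float):
    """One-to-one greedy matching of detections to onsets within ``tolerance``.

    Both sequences must be sorted. Returns (matched detection indices,
    matched onset indices); the greedy two-pointer sweep attains the maximum
    matching for this interval structure, and a superset of detections never
    yields a smaller matching.
    """
    det = np.asarray(detection_times, dtype=float)
    ons = np.asarray(true_onsets, dtype=float)
    di = oi = 0
    md, mo = [], []
    while di < det.size and oi < ons.size:
        if det[di] < ons[oi] - tolerance:
            di += 1
        elif det[di] > ons[oi] + tolerance:
            oi += 1
        else:
            md.append(di)
            mo.append(oi)
            di += 1
            oi += 1
    return md, mo


def _lockout_peaks(similarity: np.ndarray, rate: float, lockout: float):
    """Similarity peaks pruned to a minimum separation of one lockout."""
    distance = max(int(round(lockout * rate)), 1)
    idx, _ = find_peaks(similarity, distance=distance)
    return idx


def compute_roc(similarity: np.ndarray, rate: float, true_onsets,
                config: DetectorConfig, thresholds) -> ROCCurve:
    """Sweep a threshold grid over the lockout-pruned similarity peaks.

    For each threshold the candidate detections are the pruned peaks at or
    above it; candidates within ``tp_tolerance`` of a true onset are matched
    one-to-one (TP), the rest are FP. ``tpr = TP / n_onsets`` and the FP count
    is scaled to a per-10-minute rate.
    """
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    if thresholds.size == 0:
        raise InvalidArgumentError("empty threshold vector")
    similarity = np.asarray(similarity, dtype=float)
    ons = np.sort(np.asarray(true_onsets, dtype=float))
    duration = similarity.size / rate
    peaks = _lockout_peaks(similarity, rate, config.lockout)
    pt = peaks / rate
    ph = similarity[peaks]
    tpr = np.empty_like(thresholds)
    fp10 = np.empty_like(thresholds)
    for i, th in enumerate(thresholds):
        cand = pt[ph >= th]
        md, _ = match_events(cand, ons, config.tp_tolerance)
        tp = len(md)
        fp = cand.size - tp
        tpr[i] = tp / ons.size if ons.size else 0.0
        fp10[i] = fp * 600.0 / duration
    return ROCCurve(thresholds=thresholds, tpr=tpr, fp_per_10min=fp10)


def select_threshold(roc: ROCCurve, min_fp10: float = 10.0) -> float:
    """Trade-off policy: maximize TPR subject to FP/10min <= ``min_fp10``.

    Among thresholds attaining the constrained maximum TPR the *lowest* one
    is returned: it leaves the widest margin below the training similarity
    peaks for unseen epochs, whose match is systematically weaker than the
    (self-fitted) training match. If no threshold is feasible, return the one
    closest in Euclidean distance to the ideal corner (TPR 1, FP 0) with the
    FP axis scaled by ``min_fp10``.
    """
    if roc.thresholds.size == 0:
        raise InvalidArgumentError("empty ROC")
    feasible = roc.fp_per_10min <= min_fp10
    if feasible.any():
        idx = np.flatnonzero(feasible)
        order = sorted(idx, key=lambda i: (-roc.tpr[i], roc.thresholds[i]))
        return float(roc.thresholds[order[0]])
    d = np.hypot(1.0 - roc.tpr, roc.fp_per_10min / min_fp10)
    return float(roc.thresholds[int(np.argmin(d))])


def _artifact_blocked(eeg: EEGRecording, config: DetectorConfig,
                      out_rate: float, n_out: int) -> np.ndarray:
    """Boolean mask on the surrogate time base of gated (non-firing) samples."""
    art = np.abs(eeg.channel(config.artifact_channel)) > config.artifact_limit
    blocked = np.zeros(n_out, dtype=bool)
    if not art.any():
        return blocked
    exceed = np.flatnonzero(art) / eeg.rate
    # Collapse to intervals [t, t + guard] and mark surrogate samples inside.
    starts = np.floor(exceed * out_rate).astype(int)
    stops = np.ceil((exceed + config.artifact_guard) * out_rate).astype(int) + 1
    for s, e in zip(starts, stops):
        blocked[max(s, 0): min(e, n_out)] = True
    return blocked


def run_online_detection(
    eeg: EEGRecording,
    template: MRCPTemplate,
    spatial: SpatialFilter,
    filt: FilterSpec,
    config: DetectorConfig,
    true_onsets,
) -> DetectionLog:
    """Causal detection pass over a continuous recording.

    Chain: causal band-pass, decimation to the template rate, spatial
    filtering, sliding normalized correlation. A detection fires when the
    similarity crosses the threshold upward, outside both the post-detection
    lockout and the artifact gate; detections are then labelled TP/FP against
    the true onsets (one-to-one within ``tp_tolerance``) and unmatched onsets
    are logged as misses (FN).
    """
    if config.artifact_channel not in eeg.channels:
        raise MissingChannelError(config.artifact_channel)
    filtered = bandpass_causal(eeg, filt)
    low = downsample(filtered, template.rate)
    surrogate = apply_spatial_filter(low, spatial)
    sim = match_template(surrogate, template)
    blocked = _artifact_blocked(eeg, config, template.rate, sim.size)

    th = config.threshold
    above = sim >= th
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    lock_n = config.lockout * template.rate
    det_idx = []
    last = -np.inf
    for c in crossings:
        if c - last < lock_n or blocked[c]:
            continue
        det_idx.append(c)
        last = c
    det_times = np.asarray(det_idx, dtype=float) / template.rate

    ons = np.sort(np.asarray(true_onsets, dtype=float))
    md, mo = match_events(det_times, ons, config.tp_tolerance)
    md = set(md)
    mo = set(mo)
    detections = [
        (float(t), "TP" if i in md else "FP") for i, t in enumerate(det_times)
    ]
    misses = [float(t) for i, t in enumerate(ons) if i not in mo]
    return DetectionLog(detections=detections, misses=misses, duration=eeg.duration)


def calibrate(
    eeg: EEGRecording,
    onsets,
    filt: FilterSpec = FilterSpec(),
    config: DetectorConfig = None,
    window: tuple[float, float] = (-2.0, 0.0),
    thresholds: np.ndarray | None = None,
    min_fp10: float = 10.0,
    optimize_weights: bool = True,
    edge_exclude: float = 5.0,
) -> Calibration:
    """Full offline calibration from a training recording and movement onsets.

    Zero-phase preprocessing, spatial-weight optimization on the onset-locked
    epochs (with large-Laplacian fallback), template extraction, a ROC sweep
    of the similarity trace, and threshold selection. Onsets within
    ``edge_exclude`` seconds of either record edge are not used for template
    extraction (filter transients).
    """
    config = config or DetectorConfig()
    onsets = np.asarray(sorted(float(t) for t in onsets))
    usable = onsets[(onsets > edge_exclude) & (onsets < eeg.duration - edge_exclude)]
    filtered = bandpass_zero_phase(eeg, filt)
    low = downsample(filtered, SURROGATE_RATE)

    if optimize_weights:
        i0 = int(round(window[0] * SURROGATE_RATE))
        i1 = int(round(window[1] * SURROGATE_RATE))
        stacks = []
        for t in usable:
            c = int(round(t * SURROGATE_RATE))
            if c + i0 >= 0 and c + i1 <= low.n_samples:
                stacks.append(low.data[:, c + i0: c + i1])
        if len(stacks) >= 2:
            spatial = optimize_spatial_weights(np.asarray(stacks), low.channels)
        else:
            spatial = large_laplacian()
    else:
        spatial = large_laplacian()

    surrogate = apply_spatial_filter(low, spatial)
    template = extract_template(surrogate, SURROGATE_RATE, usable, window)
    # Threshold calibration runs on the *causal* similarity trace: thresholds
    # must hold under deployment conditions, and the online causal band-pass
    # both weakens the signal match and makes 1/f background noticeably more
    # template-like than the zero-phase training trace suggests.
    low_causal = downsample(bandpass_causal(eeg, filt), SURROGATE_RATE)
    sim = match_template(apply_spatial_filter(low_causal, spatial), template)
    if thresholds is None:
        thresholds = np.linspace(0.0, 0.99, 100)
    roc = compute_roc(sim, SURROGATE_RATE, usable, config, thresholds)
    threshold = select_threshold(roc, min_fp10=min_fp10)
    cfg = DetectorConfig(
        threshold=threshold, lockout=config.lockout,
        artifact_channel=config.artifact_channel,
        artifact_limit=config.artifact_limit,
        artifact_guard=config.artifact_guard,
        tp_tolerance=config.tp_tolerance,
    )
    return Calibration(template=template, spatial=spatial, filter_spec=filt,
                       config=cfg, roc=roc)
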