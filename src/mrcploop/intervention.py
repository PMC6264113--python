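"""One BCI-intervention session end-to-end, with the 50-correct-pairings stop rule.

The participant produces self-paced motor-imagery events at random intervals
(uniform 8-16 s, comfortably above the 5 s detector lockout); each event
plants an MRCP in the streaming EEG. The calibrated detector runs causally
over the stream and the session stops at the configured number of true
positives. Performance is summarized the way BCI studies report it: TPR (%),
false positives per minute, total task time and the number of movement
repetitions executed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detector import Calibration, DetectionLog, run_online_detection
from .errors import InterventionTimeoutError
from .synthetic import generate_background_eeg, inject_mrcp
from .types import SyntheticConfig

__all__ = ["PerformanceMetrics", "summarize_until_stop", "simulate_intervention"]


@dataclass
class PerformanceMetrics:
    """Session summary: TPR in percent, FP/min, task time in minutes and the
    number of movement repetitions executed (attempts = TP + FN)."""

    tpr: float
    fp_per_min: float
    t_total: float
    m_rep: int


def summarize_until_stop(log: DetectionLog, stop_tp: int) -> tuple[DetectionLog, PerformanceMetrics]:
    """Truncate a detection log at the ``stop_tp``-th true positive and compute metrics.

    The stop rule ends the session the moment the required number of correct
    pairings is reached, so detections and misses after that instant are
    discarded. Metrics are pure functions of the truncated log:
    ``tpr = TP / (TP + FN) * 100``, ``fp_per_min = FP / t_total``,
    ``m_rep = TP + FN``.
    """
    tp_times = [t for t, lab in log.detections if lab == "TP"]
    if len(tp_times) < stop_tp:
        raise InterventionTimeoutError(
            f"only {len(tp_times)} true positives available; {stop_tp} required")
    t_stop = tp_times[stop_tp - 1]
    detections = [(t, lab) for t, lab in log.detections if t <= t_stop]
    misses = [t for t in log.misses if t <= t_stop]
    clipped = DetectionLog(detections=detections, misses=misses, duration=t_stop)
    t_total = t_stop / 60.0
    attempts = clipped.tp + clipped.fn
    metrics = PerformanceMetrics(
        tpr=100.0 * clipped.tp / attempts if attempts else 0.0,
        fp_per_min=clipped.fp / t_total if t_total > 0 else 0.0,
        t_total=t_total,
        m_rep=attempts,
    )
    return clipped, metrics


def simulate_intervention(
    generator: SyntheticConfig,
    calibration: Calibration,
    stop_tp: int = 50,
    seed: int = 0,
    interval: tuple[float, float] = (8.0, 16.0),
    max_events: int = 400,
) -> tuple[DetectionLog, PerformanceMetrics]:
    """Stream imagery events through the online detector until ``stop_tp`` TPs.

    Event times are drawn first (inter-event intervals uniform over
    ``interval``); the synthetic EEG stream long enough to contain them is
    generated in one piece, detection runs causally over it, and the log is
    truncated at the stop instant. If the event budget (``max_events``,
    raised adaptively up to a hard cap) cannot deliver enough true positives
    — e.g. a detector whose threshold can never fire — an
    ``InterventionTimeoutError`` is raised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1A7]))
    lead_in = generator.mrcp_rise + 8.0
    n_events = max(int(np.ceil(stop_tp * 2.0)), 20)
    gaps = rng.uniform(interval[0], interval[1], size=max_events)
    all_events = lead_in + np.concatenate([[0.0], np.cumsum(gaps)])
    eeg_seed = int(rng.integers(0, 2**31 - 1))

    while True:
        events = all_events[:n_events]
        duration = events[-1] + 8.0
        cfg = replace(generator, duration=duration, seed=eeg_seed)
        eeg = generate_background_eeg(cfg)
        eeg = inject_mrcp(eeg, events, cfg)
        log = run_online_detection(
            eeg, calibration.template, calibration.spatial,
            calibration.filter_spec, calibration.config, events,
        )
        if log.tp >= stop_tp:
            return summarize_until_stop(log, stop_tp)
        if n_events >= max_events:
            raise InterventionTimeoutError(
                f"stop rule not reached: {log.tp}/{stop_tp} true positives "
                f"after {n_events} imagery events")
        n_events = min(n_events * 2, max_events)
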