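"""EMG movement-onset detection anchoring MRCP template extraction.

Standard envelope-threshold scheme: rectify, zero-phase low-pass at 10 Hz,
threshold at baseline mean + k standard deviations, and require the envelope
to stay above threshold for a sustained period so isolated spikes do not
trigger. The baseline statistics come from an initial movement-free window.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import InvalidArgumentError
from .types import EMGRecording, MovementEvent

__all__ = ["emg_envelope", "detect_emg_onsets"]


def emg_envelope(emg: EMGRecording, cutoff: float = 5.0, order: int = 2) -> np.ndarray:
    """Rectified, zero-phase low-pass-filtered EMG amplitude envelope."""
    sos = signal.butter(order, cutoff, btype="low", fs=emg.rate, output="sos")
    return signal.sosfiltfilt(sos, np.abs(emg.data))


def detect_emg_onsets(
    emg: EMGRecording,
    baseline_window: float = 5.0,
    k: float = 3.0,
    min_separation: float = 6.0,
    sustain: float = 0.05,
    envelope_cutoff: float = 10.0,
) -> list[MovementEvent]:
    """Threshold-crossing onsets on the EMG envelope.

    An event marks the first sample of a run in which the envelope exceeds
    ``baseline mean + k * SD`` for at least ``sustain`` seconds; events closer
    than ``min_separation`` to the previous one are discarded. A flat or
    all-zero record yields an empty list.

    The first ``baseline_window`` seconds are assumed movement-free and supply
    the baseline statistics.
    """
    if emg.duration <= baseline_window:
        raise InvalidArgumentError("recording must be longer than baseline_window")
    if not np.any(emg.data):
        return []
    env = emg_envelope(emg, cutoff=envelope_cutoff)
    n_base = int(round(baseline_window * emg.rate))
    base = env[:n_base]
    thresh = base.mean() + k * base.std()
    above = env > thresh
    if not above.any():
        return []
    # Run-length encode the boolean trace.
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = edges[~above[edges]] + 1
    stops = edges[above[edges]] + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        stops = np.concatenate([stops, [above.size]])
    n_sustain = max(int(round(sustain * emg.rate)), 1)
    events: list[MovementEvent] = []
    last = -np.inf
    for s, e in zip(starts, stops):
        if e - s < n_sustain:
            continue
        t = s / emg.rate + emg.start_time
        if t - last >= min_separation:
            events.append(MovementEvent(time=float(t), kind="detected_onset"))
            last = t
    return events
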