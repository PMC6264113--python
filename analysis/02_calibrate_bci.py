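"""Calibrate the self-paced MRCP detector from the archived training session.

Reads the session written by 01_simulate_session.py, recovers movement onsets
from the EMG envelope, runs the calibration chain (zero-phase 0.05-10 Hz
band-pass, 32 Hz, SNR-optimized Cz-centred spatial filter, 2 s pre-movement
template) and sweeps the detection threshold on a ROC whose operating point
maximizes TPR subject to at most 10 false positives per 10 minutes. The
calibration artifact (JSON) and the ROC table go to results/.

Usage: python analysis/02_calibrate_bci.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mrcploop import detector, io, onset

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "session"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    eeg = io.read_eeg_csv(SCRATCH / "eeg.csv")
    emg = io.read_emg_csv(SCRATCH / "emg.csv")
    truth = io.read_ground_truth(SCRATCH / "ground_truth.json")

    events = onset.detect_emg_onsets(emg)
    err = [
        min(abs(e.time - t) for t in truth.onsets) for e in events
    ]
    print(f"EMG onsets: {len(events)} detected / {len(truth.onsets)} planted; "
          f"median |latency error| {1000 * np.median(err):.0f} ms")
    io.write_events_csv(events, RESULTS / "emg_onsets.csv")

    calib = detector.calibrate(eeg, [e.time for e in events])
    io.save_calibration(calib, RESULTS / "calibration.json")
    roc = pd.DataFrame({
        "threshold": calib.roc.thresholds,
        "tpr": calib.roc.tpr,
        "fp_per_10min": calib.roc.fp_per_10min,
    })
    roc.to_csv(RESULTS / "roc_curve.csv", index=False)

    i = int(np.argmin(np.abs(calib.roc.thresholds - calib.config.threshold)))
    print(f"Selected threshold {calib.config.threshold:.2f} "
          f"(training TPR {100 * calib.roc.tpr[i]:.1f}%, "
          f"{calib.roc.fp_per_10min[i]:.1f} FP/10 min)")
    print(f"Spatial weights: "
          f"{ {k: round(v, 2) for k, v in calib.spatial.weights.items() if v} }")
    print(f"Calibration -> {RESULTS / 'calibration.json'}")


if __name__ == "__main__":
    main()
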