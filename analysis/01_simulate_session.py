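"""Generate one synthetic BCI training session and archive it.

A training session is 50 self-paced dorsiflexions: continuous 10-channel EEG
at 2048 Hz with a movement-related cortical potential planted before each
movement (plus occasional blinks on FP1), and the matching tibialis-anterior
EMG at 4000 Hz. Raw signals go to scratch/session/ (they are large); the
ground truth and a small summary table go to results/.

Usage: python analysis/01_simulate_session.py [seed]
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from mrcploop import io, synthetic
from mrcploop.types import GroundTruth, SyntheticConfig

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "session"
RESULTS = ROOT / "results"


def main(seed: int = 11) -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    n_events, gap = 50, 11.0
    cfg = SyntheticConfig(duration=n_events * gap + 20.0, seed=seed)
    onsets = 10.0 + np.arange(n_events) * gap
    rng = np.random.default_rng(seed + 1)
    blink_times = np.sort(rng.uniform(5.0, cfg.duration - 5.0, size=8))

    eeg = synthetic.generate_background_eeg(cfg)
    eeg = synthetic.inject_mrcp(eeg, onsets, cfg)
    eeg = synthetic.inject_blinks(eeg, blink_times, cfg)
    emg = synthetic.generate_emg(onsets, cfg)
    truth = GroundTruth(onsets=list(onsets), blink_times=list(blink_times))

    io.write_eeg_csv(eeg, SCRATCH / "eeg.csv")
    io.write_emg_csv(emg, SCRATCH / "emg.csv")
    io.write_ground_truth(truth, SCRATCH / "ground_truth.json")

    summary = pd.DataFrame([{
        "seed": seed,
        "duration_s": cfg.duration,
        "n_movements": n_events,
        "n_blinks": len(blink_times),
        "eeg_rate_hz": cfg.rate,
        "emg_rate_hz": cfg.emg_rate,
        "mrcp_amplitude_uv": cfg.mrcp_amplitude,
        "noise_rms_uv": cfg.noise_rms,
    }])
    summary.to_csv(RESULTS / "session_summary.csv", index=False)
    print(f"Simulated a {cfg.duration:.0f} s training session with "
          f"{n_events} movements and {len(blink_times)} blinks.")
    print(f"Signals -> {SCRATCH}; summary -> {RESULTS / 'session_summary.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 11)
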