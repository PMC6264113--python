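"""Simulate BCI-intervention sessions and summarize detector performance.

Each subject gets a fresh calibration (own training session) and then one
intervention per feedback condition (ES, PM, Comb), each running until 50
correct pairings of imagery and afferent feedback. The feedback condition
does not alter the detection problem, so per-condition differences in TPR and
FP/min are pure session-to-session variability — which is exactly what the
repeated-measures ANOVA at the end should (and does) call null.

The default 4 subjects keep this demo quick; pass a subject count to scale up.

Usage: python analysis/03_run_interventions.py [n_subjects]
"""

import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from mrcploop import detector, synthetic
from mrcploop.intervention import simulate_intervention
from mrcploop.stats import oneway_rm_anova
from mrcploop.types import SESSIONS, SyntheticConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def calibrate_subject(seed: int):
    cfg = SyntheticConfig(duration=50 * 11.0 + 20.0, seed=seed)
    onsets = 10.0 + np.arange(50) * 11.0
    eeg = synthetic.inject_mrcp(synthetic.generate_background_eeg(cfg), onsets, cfg)
    return detector.calibrate(eeg, onsets)


def main(n_subjects: int = 4) -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for subj in range(1, n_subjects + 1):
        calib = calibrate_subject(seed=1000 + subj)
        for k, session in enumerate(SESSIONS):
            t0 = time.perf_counter()
            log, metrics = simulate_intervention(
                SyntheticConfig(), calib, stop_tp=50,
                seed=10_000 + 10 * subj + k)
            rows.append({
                "subject": f"S{subj:02d}", "session": session,
                "tpr": metrics.tpr, "fp_m": metrics.fp_per_min,
                "t_t": metrics.t_total, "m_r": metrics.m_rep,
                "tp": log.tp, "fp": log.fp, "fn": log.fn,
                "wall_s": time.perf_counter() - t0,
            })
            print(f"S{subj:02d} {session:>4}: TPR {metrics.tpr:5.1f}%  "
                  f"FP/min {metrics.fp_per_min:4.2f}  "
                  f"Tt {metrics.t_total:5.1f} min  Mr {metrics.m_rep}")
    perf = pd.DataFrame(rows)
    perf.to_csv(RESULTS / "bci_performance.csv", index=False)

    print("\nMeans:", perf[["tpr", "fp_m", "t_t", "m_r"]].mean().round(2).to_dict())
    anova_rows = []
    for metric in ("tpr", "fp_m"):
        res = oneway_rm_anova(perf, value=metric)
        anova_rows.append({"metric": metric, "F": res.f,
                           "df1": res.df[0], "df2": res.df[1], "p": res.p})
        print(f"One-way RM ANOVA on {metric}: "
              f"F({res.df[0]}, {res.df[1]}) = {res.f:.2f}, p = {res.p:.2f}")
    pd.DataFrame(anova_rows).to_csv(RESULTS / "bci_performance_anova.csv", index=False)
    print(f"\nPerformance table -> {RESULTS / 'bci_performance.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 4)
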