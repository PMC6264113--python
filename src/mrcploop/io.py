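"""Plain-text readers and writers: CSV signals and tables, JSON sidecars.

Signals travel as long-format CSV (time, channel, value); the calibrated
detector state is a single JSON document so a session's calibration can be
archived and replayed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import Calibration, DetectionLog, DetectorConfig, MRCPTemplate, ROCCurve
from .errors import InvalidArgumentError
from .preprocess import FilterSpec, SpatialFilter
from .types import EEGRecording, EMGRecording, GroundTruth, MovementEvent

__all__ = [
    "write_eeg_csv", "read_eeg_csv", "write_emg_csv", "read_emg_csv",
    "write_ground_truth", "read_ground_truth",
    "write_events_csv", "read_events_csv",
    "write_trial_table", "read_trial_table",
    "write_detection_log", "read_detection_log",
    "save_calibration", "load_calibration",
]


def write_eeg_csv(rec: EEGRecording, path) -> None:
    t = rec.times
    frames = [
        pd.DataFrame({"time": t, "channel": ch, "value": rec.data[i]})
        for i, ch in enumerate(rec.channels)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_eeg_csv(path, rate: float | None = None) -> EEGRecording:
    df = pd.read_csv(path)
    channels = tuple(df["channel"].unique())
    wide = df.pivot(index="time", columns="channel", values="value")
    times = wide.index.to_numpy(dtype=float)
    if rate is None:
        dt = np.diff(times)
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise InvalidArgumentError("cannot infer a uniform sampling rate")
        rate = 1.0 / dt[0]
    data = np.vstack([wide[ch].to_numpy(dtype=float) for ch in channels])
    return EEGRecording(data=data, rate=float(rate), channels=channels,
                        start_time=float(times[0]))


def write_emg_csv(rec: EMGRecording, path) -> None:
    pd.DataFrame({"time": rec.times, "value": rec.data}).to_csv(path, index=False)


def read_emg_csv(path, rate: float | None = None,
                 passband: tuple[float, float] = (20.0, 1000.0)) -> EMGRecording:
    df = pd.read_csv(path)
    times = df["time"].to_numpy(dtype=float)
    if rate is None:
        rate = 1.0 / (times[1] - times[0])
    return EMGRecording(data=df["value"].to_numpy(dtype=float), rate=float(rate),
                        passband=passband, start_time=float(times[0]))


def write_ground_truth(gt: GroundTruth, path) -> None:
    doc = {
        "onsets": list(map(float, gt.onsets)),
        "blink_times": list(map(float, gt.blink_times)),
        "mep_effects": {f"{s}:{t}": float(v) for (s, t), v in gt.mep_effects.items()},
        "subject_session_sd": gt.subject_session_sd,
        "gamma_shape": gt.gamma_shape,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_ground_truth(path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    effects = {tuple(k.split(":")): v for k, v in doc["mep_effects"].items()}
    return GroundTruth(onsets=doc["onsets"], blink_times=doc["blink_times"],
                       mep_effects=effects,
                       subject_session_sd=doc["subject_session_sd"],
                       gamma_shape=doc["gamma_shape"])


def write_events_csv(events: list[MovementEvent], path) -> None:
    pd.DataFrame({"time": [e.time for e in events],
                  "kind": [e.kind for e in events]}).to_csv(path, index=False)


def read_events_csv(path) -> list[MovementEvent]:
    df = pd.read_csv(path)
    return [MovementEvent(time=float(r.time), kind=str(r.kind)) for r in df.itertuples()]


def write_trial_table(table: pd.DataFrame, path) -> None:
    from .stats.design import TRIAL_TABLE_COLUMNS
    table.loc[:, list(TRIAL_TABLE_COLUMNS)].to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    from .stats.design import validate_trial_table
    return validate_trial_table(pd.read_csv(path))


def write_detection_log(log: DetectionLog, path) -> None:
    rows = [{"time": t, "label": lab} for t, lab in log.detections]
    rows += [{"time": t, "label": "FN"} for t in log.misses]
    df = pd.DataFrame(rows, columns=["time", "label"]).sort_values("time")
    df.attrs["duration"] = log.duration
    with open(path, "w") as fh:
        fh.write(f"# duration_s={log.duration}\n")
        df.to_csv(fh, index=False)


def read_detection_log(path) -> DetectionLog:
    with open(path) as fh:
        header = fh.readline().strip()
        duration = float(header.split("=", 1)[1]) if header.startswith("#") else np.nan
        df = pd.read_csv(fh)
    detections = [(float(r.time), str(r.label)) for r in df.itertuples()
                  if r.label in ("TP", "FP")]
    misses = [float(r.time) for r in df.itertuples() if r.label == "FN"]
    return DetectionLog(detections=detections, misses=misses, duration=duration)


def save_calibration(calib: Calibration, path) -> None:
    doc = {
        "template": {
            "samples": calib.template.samples.tolist(),
            "window": list(calib.template.window),
            "n_train": calib.template.n_train,
            "rate": calib.template.rate,
        },
        "spatial": {"weights": calib.spatial.weights, "center": calib.spatial.center},
        "filter": asdict(calib.filter_spec),
        "config": asdict(calib.config),
        "roc": None if calib.roc is None else {
            "thresholds": calib.roc.thresholds.tolist(),
            "tpr": calib.roc.tpr.tolist(),
            "fp_per_10min": calib.roc.fp_per_10min.tolist(),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_calibration(path) -> Calibration:
    doc = json.loads(Path(path).read_text())
    template = MRCPTemplate(samples=np.asarray(doc["template"]["samples"]),
                            window=tuple(doc["template"]["window"]),
                            n_train=doc["template"]["n_train"],
                            rate=doc["template"]["rate"])
    spatial = SpatialFilter(weights=doc["spatial"]["weights"],
                            center=doc["spatial"]["center"])
    filt = FilterSpec(**doc["filter"])
    config = DetectorConfig(**doc["config"])
    roc = None
    if doc.get("roc"):
        roc = ROCCurve(thresholds=np.asarray(doc["roc"]["thresholds"]),
                       tpr=np.asarray(doc["roc"]["tpr"]),
                       fp_per_10min=np.asarray(doc["roc"]["fp_per_10min"]))
    return Calibration(template=template, spatial=spatial, filter_spec=filt,
                       config=config, roc=roc)
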