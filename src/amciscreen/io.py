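"""Plain-text serialization of pipeline objects.

EEG recordings are stored as a delimited channel × sample matrix (CSV, one
row per 10-20 channel) with the stimulation schedule and sampling rate in a
JSON sidecar; VR sessions as a directory of three CSVs (gaze.csv, hand.csv,
events.csv); feature tables as flat CSV; cohort specifications as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import (
    CohortSpec,
    EEGRecording,
    FeatureSpec,
    StimulationSchedule,
    VRSessionLog,
)


# -- EEG ------------------------------------------------------------------

def save_recording(recording: EEGRecording, csv_path, sidecar_path=None) -> None:
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    df = pd.DataFrame(recording.signal.T, columns=list(recording.channel_labels))
    df.to_csv(csv_path, index=False)
    meta = {
        "sampling_rate": recording.sampling_rate,
        "schedule": {
            "blocks": [list(b) for b in recording.schedule.blocks],
            "rest_blocks": [list(b) for b in recording.schedule.rest_blocks],
            "total_duration": recording.schedule.total_duration,
        },
    }
    sidecar_path.write_text(json.dumps(meta, indent=1))


def load_recording(csv_path, sidecar_path=None) -> EEGRecording:
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    sched = StimulationSchedule(
        tuple(tuple(b) for b in meta["schedule"]["blocks"]),
        tuple(tuple(b) for b in meta["schedule"]["rest_blocks"]),
        meta["schedule"]["total_duration"],
    )
    df = pd.read_csv(csv_path)
    return EEGRecording(
        df.to_numpy(dtype=float).T, tuple(df.columns), meta["sampling_rate"], sched
    )


# -- VR sessions ----------------------------------------------------------

def save_session(log: VRSessionLog, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    log.gaze.to_csv(d / "gaze.csv", index=False)
    log.hand.to_csv(d / "hand.csv", index=False)
    log.events.to_csv(d / "events.csv", index=False)


def load_session(directory) -> VRSessionLog:
    d = Path(directory)
    gaze = pd.read_csv(d / "gaze.csv")
    hand = pd.read_csv(d / "hand.csv")
    events = pd.read_csv(d / "events.csv")
    events["is_error"] = events["is_error"].astype(bool)
    return VRSessionLog(gaze, hand, events)


# -- Feature tables -------------------------------------------------------

def save_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- Cohort specifications ------------------------------------------------

def save_cohort_spec(spec: CohortSpec, path) -> None:
    doc = {
        "n_per_group": spec.n_per_group,
        "seed": spec.seed,
        "features": [
            {"name": f.name, "family": f.family, "mean": dict(f.mean),
             "sd": dict(f.sd), "lower": f.lower}
            for f in spec.features
        ],
        "cross_modal_corr": [
            {"a": a, "b": b, "rho": float(rho)}
            for (a, b), rho in spec.cross_modal_corr.items()
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, allow_unicode=True, sort_keys=False))


def load_cohort_spec(path) -> CohortSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return CohortSpec(
        n_per_group=int(doc["n_per_group"]),
        features=[
            FeatureSpec(name=f["name"], family=f["family"], mean=f["mean"],
                        sd=f["sd"], lower=float(f.get("lower", 0.0)))
            for f in doc["features"]
        ],
        cross_modal_corr={
            (e["a"], e["b"]): float(e["rho"])
            for e in doc.get("cross_modal_corr", [])
        },
        seed=doc.get("seed"),
    )
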