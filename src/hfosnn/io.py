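"""Plain-text (and NPZ) serialisation of recordings, spikes and events.

Formats are deliberately simple: tab-separated tables with a small
``# key=value`` comment header for signals, the annotation schema shared
by the synthetic ground truth and the detector output, and NumPy ``.npz``
for bulk signal storage at run time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .adm import SpikeTrain
from .preprocess import IEEGRecording
from .snn import Raster

ANNOTATION_COLUMNS = ["onset_s", "duration_s", "channel", "type"]


# -- recordings ---------------------------------------------------------------

def save_recording_npz(path, recording: IEEGRecording) -> None:
    np.savez_compressed(
        path,
        data=recording.data,
        fs=recording.fs,
        channel_labels=np.array(recording.channel_labels),
        interval_id=str(recording.interval_id),
        night_id=str(recording.night_id),
    )


def load_recording_npz(path) -> IEEGRecording:
    with np.load(path, allow_pickle=False) as z:
        none = lambda s: None if s == "None" else s
        return IEEGRecording(
            data=z["data"],
            fs=float(z["fs"]),
            channel_labels=[str(c) for c in z["channel_labels"]],
            interval_id=none(str(z["interval_id"])),
            night_id=none(str(z["night_id"])),
        )


def save_recording_tsv(path, recording: IEEGRecording) -> None:
    """Delimited text: comment header, then one column per channel."""
    header = {
        "fs": recording.fs,
        "channels": ",".join(recording.channel_labels),
        "interval_id": recording.interval_id,
        "night_id": recording.night_id,
    }
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}={value}\n")
        np.savetxt(fh, recording.data.T, fmt="%.6f", delimiter="\t")


def load_recording_tsv(path) -> IEEGRecording:
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition("=")
            header[key.strip()] = value
            pos = fh.tell()
        data = np.loadtxt(fh, delimiter="\t", ndmin=2).T
    none = lambda s: None if s in ("None", "") else s
    return IEEGRecording(
        data=data,
        fs=float(header["fs"]),
        channel_labels=header["channels"].split(","),
        interval_id=none(header.get("interval_id", "")),
        night_id=none(header.get("night_id", "")),
    )


def load_recording(path) -> IEEGRecording:
    path = Path(path)
    if path.suffix == ".npz":
        return load_recording_npz(path)
    return load_recording_tsv(path)


# -- spikes, rasters, events --------------------------------------------------

def save_spike_train(path, train: SpikeTrain) -> None:
    df = pd.DataFrame(
        {
            "time_s": train.times,
            "polarity": np.where(train.polarities > 0, "UP", "DN"),
            "source": train.source,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# duration_s={train.duration_s}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_spike_train(path) -> SpikeTrain:
    with open(path) as fh:
        first = fh.readline()
        duration = float(first.strip().split("=")[1]) if first.startswith("#") else 0.0
        if not first.startswith("#"):
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    source = str(df["source"].iloc[0]) if len(df) else ""
    return SpikeTrain(
        times=df["time_s"].to_numpy(dtype=float),
        polarities=np.where(df["polarity"].to_numpy() == "UP", 1, -1),
        source=source,
        duration_s=duration,
    )


def save_raster(path, raster: Raster) -> None:
    rows = [
        (j, t) for j, times in enumerate(raster.spike_times) for t in times
    ]
    df = pd.DataFrame(rows, columns=["neuron_id", "time_s"])
    with open(path, "w") as fh:
        fh.write(f"# duration_s={raster.duration_s} n_neurons={raster.n_neurons}\n")
        df.to_csv(fh, sep="\t", index=False)


def save_annotations(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def load_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- cohort directory layout --------------------------------------------------

def save_patient(directory, patient) -> None:
    """One directory per patient: metadata JSON, truth TSV, interval NPZs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "patient_id": patient.patient_id,
        "channel_labels": patient.channel_labels,
        "pathological_channels": sorted(patient.pathological_channels),
        "resected_channels": sorted(patient.resected_channels),
        "ilae_outcome": patient.ilae_outcome,
        "intervals": [
            {"interval_id": r.interval_id, "night_id": r.night_id,
             "file": f"{r.interval_id}.npz"}
            for r in patient.recordings
        ],
    }
    (directory / "patient.json").write_text(json.dumps(meta, indent=2))
    save_annotations(directory / "annotations.tsv", patient.annotations)
    for rec in patient.recordings:
        save_recording_npz(directory / f"{rec.interval_id}.npz", rec)


def load_patient(directory):
    from .synthetic import SyntheticPatient

    directory = Path(directory)
    meta = json.loads((directory / "patient.json").read_text())
    recordings = [
        load_recording_npz(directory / entry["file"]) for entry in meta["intervals"]
    ]
    annotations_path = directory / "annotations.tsv"
    annotations = (
        load_annotations(annotations_path) if annotations_path.exists() else pd.DataFrame()
    )
    return SyntheticPatient(
        patient_id=meta["patient_id"],
        channel_labels=meta["channel_labels"],
        recordings=recordings,
        annotations=annotations,
        pathological_channels=set(meta["pathological_channels"]),
        resected_channels=set(meta["resected_channels"]),
        ilae_outcome=meta["ilae_outcome"],
    )


def save_cohort(directory, patients) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for patient in patients:
        save_patient(directory / patient.patient_id, patient)


def load_cohort(directory):
    directory = Path(directory)
    patient_dirs = sorted(p.parent for p in directory.glob("*/patient.json"))
    if not patient_dirs:
        raise FileNotFoundError(f"no patients found under {directory}")
    return [load_patient(d) for d in patient_dirs]
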