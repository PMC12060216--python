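"""Reading and writing recordings and derived series.

SNIRF (HDF5) support covers the subset the package produces and consumes:
continuous-wave intensity in ``/nirs/data1`` with a measurement list, probe
wavelengths, and stim groups.  The CSV pair is a plain channels-x-time
matrix (one row per channel/wavelength) plus an event table — convenient
for spreadsheets and language-agnostic pipelines.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .design import Event
from .preprocess import ConcentrationSeries, RawRecording
from .simulate import SyntheticGroundTruth


# ---------------------------------------------------------------------------
# SNIRF


def write_snirf(raw: RawRecording, path: str | Path) -> None:
    """Write a continuous-wave SNIRF file (one data block, stim per condition)."""
    n_wl, n_ch, n_t = raw.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=raw.subject or "unknown")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("Group", data=raw.group)
        data = nirs.create_group("data1")
        # columns ordered channel-major, wavelength-minor
        mat = raw.intensity.transpose(2, 1, 0).reshape(n_t, n_ch * n_wl)
        data.create_dataset("dataTimeSeries", data=mat)
        data.create_dataset("time", data=np.arange(n_t) / raw.sampling_rate)
        k = 1
        for c in range(n_ch):
            for w in range(n_wl):
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=c + 1)
                ml.create_dataset("detectorIndex", data=c + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw.wavelengths, dtype=float))
        conditions = list(dict.fromkeys(ev.condition for ev in raw.events))
        for i, cond in enumerate(conditions, start=1):
            evs = [ev for ev in raw.events if ev.condition == cond]
            stim = nirs.create_group(f"stim{i}")
            stim.create_dataset("name", data=cond)
            stim.create_dataset(
                "data",
                data=np.array([[ev.onset, ev.duration, 1.0] for ev in evs]),
            )


def read_snirf(path: str | Path) -> RawRecording:
    """Read a SNIRF file written by :func:`write_snirf` (CW amplitude only)."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        mat = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        fs = 1.0 / np.median(np.diff(time))
        wavelengths = tuple(np.asarray(nirs["probe/wavelengths"], dtype=float))
        keys = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda s: int(s[len("measurementList"):]),
        )
        n_meas = len(keys)
        n_wl = len(wavelengths)
        n_ch = n_meas // n_wl
        intensity = np.empty((n_wl, n_ch, mat.shape[0]))
        for col, k in enumerate(keys):
            ml = data[k]
            c = int(np.asarray(ml["sourceIndex"])) - 1
            w = int(np.asarray(ml["wavelengthIndex"])) - 1
            intensity[w, c] = mat[:, col]
        events = []
        for k in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = nirs[k]
            name = stim["name"][()]
            if isinstance(name, bytes):
                name = name.decode()
            for onset, dur, _amp in np.atleast_2d(np.asarray(stim["data"])):
                events.append(Event(float(onset), float(dur), str(name)))
        events.sort(key=lambda e: e.onset)
        meta = nirs["metaDataTags"]

        def _tag(name):
            if name in meta:
                v = meta[name][()]
                return v.decode() if isinstance(v, bytes) else str(v)
            return ""

        return RawRecording(
            intensity,
            float(fs),
            wavelengths,
            events=events,
            subject=_tag("SubjectID"),
            group=_tag("Group"),
        )


# ---------------------------------------------------------------------------
# CSV pair


def write_csv_pair(raw: RawRecording, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>_intensity.csv`` (channel, wavelength, t0, t1, ...) and
    ``<prefix>_events.csv`` (onset, duration, condition)."""
    prefix = Path(prefix)
    n_wl, n_ch, n_t = raw.intensity.shape
    rows = []
    for c in range(n_ch):
        for w in range(n_wl):
            rows.append(
                [c + 1, raw.wavelengths[w]] + raw.intensity[w, c].tolist()
            )
    mat_path = prefix.with_name(prefix.name + "_intensity.csv")
    cols = ["channel", "wavelength_nm"] + [f"t{i}" for i in range(n_t)]
    pd.DataFrame(rows, columns=cols).to_csv(mat_path, index=False)
    ev_path = prefix.with_name(prefix.name + "_events.csv")
    pd.DataFrame(
        [{"onset_s": e.onset, "duration_s": e.duration, "condition": e.condition}
         for e in raw.events]
    ).to_csv(ev_path, index=False)
    return mat_path, ev_path


def read_csv_pair(
    intensity_csv: str | Path, events_csv: str | Path, sampling_rate: float
) -> RawRecording:
    df = pd.read_csv(intensity_csv)
    wavelengths = tuple(sorted(df["wavelength_nm"].unique()))
    channels = sorted(df["channel"].unique())
    tcols = [c for c in df.columns if c.startswith("t")]
    intensity = np.empty((len(wavelengths), len(channels), len(tcols)))
    for _, row in df.iterrows():
        w = wavelengths.index(row["wavelength_nm"])
        c = channels.index(row["channel"])
        intensity[w, c] = row[tcols].to_numpy(dtype=float)
    ev = pd.read_csv(events_csv)
    events = [
        Event(float(r.onset_s), float(r.duration_s), str(r.condition))
        for r in ev.itertuples()
    ]
    return RawRecording(intensity, sampling_rate, wavelengths, events=events)


def write_concentration_csv(conc: ConcentrationSeries, prefix: str | Path) -> Path:
    """Channels-x-time oxy/deoxy/total CSV plus a YAML sidecar with every
    preprocessing parameter applied."""
    prefix = Path(prefix)
    n_t = conc.n_samples
    rows = []
    for kind, arr in (("oxy", conc.oxy), ("deoxy", conc.deoxy), ("total", conc.total)):
        for c in range(conc.n_channels):
            rows.append([c + 1, kind] + arr[c].tolist())
    path = prefix.with_name(prefix.name + "_conc.csv")
    cols = ["channel", "chromophore"] + [f"t{i}" for i in range(n_t)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    side = prefix.with_name(prefix.name + "_conc_meta.yaml")
    side.write_text(
        yaml.safe_dump(
            {
                "sampling_rate_hz": conc.sampling_rate,
                "units": "micromolar concentration change",
                "dpf": list(conc.dpf),
                "separation_cm": conc.separation_cm,
                "subject": conc.subject,
                "group": conc.group,
                "provenance": [[s, repr(a)] for s, a in conc.provenance],
            }
        )
    )
    return path


def write_ground_truth(truth: SyntheticGroundTruth, path: str | Path) -> None:
    """Ground truth as JSON, kept separate from the recording it explains."""
    obj = {
        "true_beta": truth.true_beta.tolist(),
        "conditions": list(truth.conditions),
        "state_sequence": truth.state_sequence.tolist(),
        "state_covariances": [C.tolist() for C in truth.state_covariances],
        "artifact_times_s": truth.artifact_times,
        "region_labels": truth.region_labels,
    }
    Path(path).write_text(json.dumps(obj))


def read_ground_truth(path: str | Path) -> SyntheticGroundTruth:
    obj = json.loads(Path(path).read_text())
    return SyntheticGroundTruth(
        true_beta=np.asarray(obj["true_beta"]),
        state_sequence=np.asarray(obj["state_sequence"], dtype=np.int64),
        state_covariances=[np.asarray(C) for C in obj["state_covariances"]],
        artifact_times=list(obj["artifact_times_s"]),
        latent=np.empty((0, 0)),
        region_labels=list(obj["region_labels"]),
        conditions=tuple(obj["conditions"]),
    )
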