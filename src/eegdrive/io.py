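"""Serialization: HDF5 containers for recordings/epochs/leadfields, TSV
events, CSV tables, JSON reports and YAML configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .features import FeatureTable
from .inverse import Leadfield
from .preprocess import EpochSet, Recording
from .simulate import PlantedCoupling, PlantedEffect, SimConfig

GROUP_COLUMNS = ("subject", "lap", "segment")


# ---------------------------------------------------------------------------
# events

def save_events_tsv(path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)


def load_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# recordings / epochs (HDF5)

def save_recording(path, recording: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data, track_times=False)
        f.attrs["fs"] = recording.fs
        f.create_dataset("channel_names",
                         data=np.array(recording.channel_names, dtype="S"),
                         track_times=False)
        ev = f.create_group("events")
        for col in recording.events.columns:
            vals = recording.events[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            ev.create_dataset(col, data=vals, track_times=False)


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        names = tuple(s.decode() for s in f["channel_names"][()])
        ev = {}
        for col in f["events"]:
            vals = f["events"][col][()]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() for v in vals])
            ev[col] = vals
    events = pd.DataFrame(ev)[["onset_sample", "condition", "subject", "lap", "segment"]]
    return Recording(data=data, fs=fs, channel_names=names, events=events)


def save_epochs(path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, track_times=False)
        f.attrs["fs"] = epochs.fs
        f.attrs["tmin"] = epochs.tmin
        f.attrs["tmax"] = epochs.tmax
        f.attrs["baseline_window"] = epochs.baseline_window
        f.create_dataset("channel_names",
                         data=np.array(epochs.channel_names, dtype="S"),
                         track_times=False)
        f.create_dataset("labels", data=epochs.labels.astype("S"),
                         track_times=False)
        for col in GROUP_COLUMNS:
            f.create_dataset(f"groups/{col}", data=epochs.groups[col].to_numpy(),
                             track_times=False)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs, tmin, tmax = float(f.attrs["fs"]), float(f.attrs["tmin"]), float(f.attrs["tmax"])
        baseline = tuple(f.attrs["baseline_window"])
        names = tuple(s.decode() for s in f["channel_names"][()])
        labels = np.array([s.decode() for s in f["labels"][()]])
        groups = pd.DataFrame({col: f[f"groups/{col}"][()] for col in GROUP_COLUMNS})
    return EpochSet(data=data, fs=fs, tmin=tmin, tmax=tmax, channel_names=names,
                    labels=labels, groups=groups, baseline_window=baseline)


# ---------------------------------------------------------------------------
# leadfield

def save_leadfield(path, lf: Leadfield) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain, track_times=False)
        f.create_dataset("source_positions", data=lf.source_positions, track_times=False)
        f.create_dataset("source_normals", data=lf.source_normals, track_times=False)
        f.create_dataset("channel_names",
                         data=np.array(lf.channel_names, dtype="S"),
                         track_times=False)
        for roi, idx in lf.roi_masks.items():
            f.create_dataset(f"roi_masks/{roi}", data=idx, track_times=False)


def load_leadfield(path) -> Leadfield:
    with h5py.File(path, "r") as f:
        return Leadfield(
            gain=f["gain"][()],
            source_positions=f["source_positions"][()],
            source_normals=f["source_normals"][()],
            channel_names=tuple(s.decode() for s in f["channel_names"][()]),
            roi_masks={roi: f[f"roi_masks/{roi}"][()] for roi in f["roi_masks"]},
        )


# ---------------------------------------------------------------------------
# source estimates (per condition/contrast, tagged)

def save_source_estimates(path, stcs: dict) -> None:
    """Write a mapping of tag -> SourceEstimate to one HDF5 container."""
    with h5py.File(path, "w") as f:
        for tag, stc in stcs.items():
            grp = f.create_group(tag)
            grp.create_dataset("values", data=stc.values, track_times=False)
            grp.attrs["fs"] = stc.fs
            grp.attrs["tmin"] = stc.tmin
            grp.attrs["condition"] = stc.condition


def load_source_estimates(path) -> dict:
    from .inverse import SourceEstimate

    out = {}
    with h5py.File(path, "r") as f:
        for tag in f:
            grp = f[tag]
            out[tag] = SourceEstimate(values=grp["values"][()],
                                      fs=float(grp.attrs["fs"]),
                                      tmin=float(grp.attrs["tmin"]),
                                      condition=str(grp.attrs["condition"]))
    return out


# ---------------------------------------------------------------------------
# feature tables (CSV + JSON sidecar)

def save_features(path, ft: FeatureTable) -> None:
    path = Path(path)
    ft.features.to_csv(path, index=False)
    meta = {"labels": ft.labels.tolist(),
            "groups": ft.groups.to_dict(orient="list")}
    path.with_suffix(".meta.json").write_text(json.dumps(meta))


def load_features(path) -> FeatureTable:
    path = Path(path)
    feats = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return FeatureTable(features=feats, labels=np.array(meta["labels"]),
                        groups=pd.DataFrame(meta["groups"]))


# ---------------------------------------------------------------------------
# config (YAML)

def config_to_yaml(config: SimConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["channel_names"] = list(config.channel_names)
    d["effects"] = [dataclasses.asdict(e) | {"channels": list(e.channels),
                                             "band": list(e.band)}
                    for e in config.effects]
    d["couplings"] = [dataclasses.asdict(c) | {"group_a": list(c.group_a),
                                               "group_b": list(c.group_b),
                                               "band": list(c.band)}
                      for c in config.couplings]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path) -> SimConfig:
    d = yaml.safe_load(Path(path).read_text())
    effects = tuple(
        PlantedEffect(name=e["name"], channels=tuple(e["channels"]),
                      band=tuple(e["band"]), base_amplitude=e["base_amplitude"],
                      condition_multipliers=dict(e["condition_multipliers"]),
                      subject_sd=e.get("subject_sd", 0.0))
        for e in d.pop("effects", []))
    couplings = tuple(
        PlantedCoupling(name=c["name"], group_a=tuple(c["group_a"]),
                        group_b=tuple(c["group_b"]), band=tuple(c["band"]),
                        amplitude=c["amplitude"], strength=dict(c["strength"]))
        for c in d.pop("couplings", []))
    d["channel_names"] = tuple(d["channel_names"])
    return SimConfig(effects=effects, couplings=couplings, **d)
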