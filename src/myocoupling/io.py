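"""Reading and writing the on-disk containers.

Subjects are stored one-per-file in HDF5: group ``emg/<muscle>`` holds the
(7, N) single-differential array with ``fs``/``ied`` attributes; group
``kinematics`` holds torque/angle/velocity with ``fs`` and
``trigger_offset``. Datasets are written with ``track_times=False`` so
identical data produce identical files. A plain-CSV reader for kinematics
and tidy-CSV writers for results round out the interfaces.
"""
from __future__ import annotations

import json
import os

import h5py
import numpy as np
import pandas as pd

from .records import KinematicRecording, RawArrayRecording

__all__ = [
    "save_subject_h5",
    "load_subject_h5",
    "read_kinematics_csv",
    "save_cohort",
    "load_cohort",
]


def save_subject_h5(
    path: str,
    emg: dict[str, RawArrayRecording],
    kin: KinematicRecording,
    truth: dict | None = None,
) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("emg")
        for muscle, rec in emg.items():
            gm = g.create_group(muscle)
            gm.create_dataset("sd", data=rec.channels, track_times=False)
            gm.attrs["fs"] = rec.fs
            gm.attrs["ied"] = rec.ied
        gk = fh.create_group("kinematics")
        for name in ("torque", "angle", "velocity"):
            gk.create_dataset(name, data=getattr(kin, name), track_times=False)
        gk.attrs["fs"] = kin.fs
        gk.attrs["trigger_offset"] = kin.trigger_offset
        if truth is not None:
            fh.attrs["truth_json"] = json.dumps(
                {k: v for k, v in truth.items() if not isinstance(v, np.ndarray)})


def load_subject_h5(path: str) -> tuple[dict[str, RawArrayRecording], KinematicRecording]:
    with h5py.File(path, "r") as fh:
        emg = {}
        for muscle, gm in fh["emg"].items():
            emg[muscle] = RawArrayRecording(
                muscle=muscle, channels=gm["sd"][()],
                fs=float(gm.attrs["fs"]), ied=float(gm.attrs["ied"]))
        gk = fh["kinematics"]
        kin = KinematicRecording(
            torque=gk["torque"][()], angle=gk["angle"][()], velocity=gk["velocity"][()],
            fs=float(gk.attrs["fs"]), trigger_offset=float(gk.attrs["trigger_offset"]))
    return emg, kin


def read_kinematics_csv(
    path: str, fs: float = 100.0, trigger_offset: float = 0.0
) -> KinematicRecording:
    """CSV with columns torque, angle, velocity (one row per sample)."""
    df = pd.read_csv(path)
    missing = {"torque", "angle", "velocity"} - set(df.columns)
    if missing:
        raise ValueError(f"kinematics CSV missing columns: {sorted(missing)}")
    return KinematicRecording(torque=df["torque"].to_numpy(),
                              angle=df["angle"].to_numpy(),
                              velocity=df["velocity"].to_numpy(),
                              fs=fs, trigger_offset=trigger_offset)


def save_cohort(outdir: str, subjects, force: bool = False) -> pd.DataFrame:
    """Write a generated cohort to ``outdir`` (one HDF5 per subject).

    ``subjects`` yields (subject_id, group, SubjectData). Returns (and
    writes) the ground-truth sidecar table. Refuses to overwrite an
    existing populated directory unless ``force``.
    """
    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise FileExistsError(f"output directory {outdir} exists and is not empty "
                              "(pass force=True to overwrite)")
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for sid, group, data in subjects:
        save_subject_h5(os.path.join(outdir, f"{sid}.h5"), data.emg, data.kin, data.truth)
        row = {"subject": sid, "group": group}
        for key, val in data.truth.items():
            if isinstance(val, dict):
                row.update({f"{key}_{k}": v for k, v in val.items()})
            elif not isinstance(val, np.ndarray):
                row[key] = val
        rows.append(row)
    truth = pd.DataFrame(rows)
    truth.to_csv(os.path.join(outdir, "ground_truth.csv"), index=False)
    return truth


def load_cohort(datadir: str):
    """Yield (subject_id, group, emg dict, kin) for every subject on disk."""
    truth_path = os.path.join(datadir, "ground_truth.csv")
    groups = {}
    if os.path.exists(truth_path):
        t = pd.read_csv(truth_path)
        groups = dict(zip(t["subject"], t["group"]))
    for name in sorted(os.listdir(datadir)):
        if not name.endswith(".h5"):
            continue
        sid = name[:-3]
        emg, kin = load_subject_h5(os.path.join(datadir, name))
        yield sid, groups.get(sid, "unknown"), emg, kin
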