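"""Serialization: NIfTI-1 volumes, HDF5 signal containers, TSV manifests.

Volumes carry their voxel size in the NIfTI affine (diagonal, mm); the
left-right convention is axis 0 with lesions in the lower-index half.
Uncompressed ``.nii`` is the default so that byte-identical reruns produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .asl import ASLSeries
from .bold import BoldTimeseries
from .geometry import BinaryMask, VolumeGeometry, VolumeMap
from .signals import EpochedSignal, Leadfield, SensorRecording
from .synthetic import SubjectRecord

__all__ = [
    "save_volume",
    "load_volume",
    "load_mask",
    "save_bold",
    "load_bold",
    "save_asl",
    "load_asl",
    "save_epochs",
    "load_epochs",
    "save_leadfield",
    "load_leadfield",
    "save_sensor_recording",
    "load_sensor_recording",
    "save_cohort",
]


def save_volume(vol: VolumeMap | BinaryMask, path: str | Path) -> Path:
    path = Path(path)
    data = vol.data.astype(np.uint8) if isinstance(vol, BinaryMask) else vol.data
    img = nib.Nifti1Image(np.asarray(data), vol.geometry.affine())
    img.header.set_zooms(vol.geometry.voxel_size)
    nib.save(img, str(path))
    return path


def _geometry_from(img: nib.Nifti1Image) -> VolumeGeometry:
    zooms = img.header.get_zooms()[:3]
    return VolumeGeometry(shape=img.shape[:3], voxel_size=tuple(float(z) for z in zooms))


def load_volume(path: str | Path) -> VolumeMap:
    img = nib.load(str(path))
    return VolumeMap(np.asanyarray(img.dataobj, dtype=float), _geometry_from(img))


def load_mask(path: str | Path) -> BinaryMask:
    img = nib.load(str(path))
    return BinaryMask(np.asanyarray(img.dataobj) > 0.5, _geometry_from(img))


def save_bold(ts: BoldTimeseries, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data)
        f.create_dataset("nuisance", data=ts.nuisance)
        f.create_dataset("brain_mask", data=ts.brain_mask.data.astype(np.uint8))
        f.attrs["tr"] = ts.tr
        f.attrs["voxel_size"] = ts.geometry.voxel_size
    return path


def load_bold(path: str | Path) -> BoldTimeseries:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        geom = VolumeGeometry(
            shape=data.shape[:3], voxel_size=tuple(f.attrs["voxel_size"])
        )
        return BoldTimeseries(
            data=data,
            geometry=geom,
            tr=float(f.attrs["tr"]),
            nuisance=f["nuisance"][()],
            brain_mask=BinaryMask(f["brain_mask"][()] > 0, geom),
        )


def save_asl(series: ASLSeries, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=series.data)
        f.create_dataset("m0", data=series.m0.data)
        f.attrs["tr_s"] = series.tr_s
        f.attrs["first_label"] = series.first_label
        f.attrs["voxel_size"] = series.geometry.voxel_size
    return path


def load_asl(path: str | Path) -> ASLSeries:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        geom = VolumeGeometry(
            shape=data.shape[:3], voxel_size=tuple(f.attrs["voxel_size"])
        )
        return ASLSeries(
            data=data,
            geometry=geom,
            m0=VolumeMap(f["m0"][()], geom),
            tr_s=float(f.attrs["tr_s"]),
            first_label=str(f.attrs["first_label"]),
        )


def save_epochs(signal: EpochedSignal, path: str | Path, name: str = "epochs") -> Path:
    path = Path(path)
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=signal.data)
        ds.attrs["fs"] = signal.fs
    return path


def load_epochs(path: str | Path, name: str = "epochs") -> EpochedSignal:
    with h5py.File(path, "r") as f:
        return EpochedSignal(data=f[name][()], fs=float(f[name].attrs["fs"]))


def save_leadfield(lf: Leadfield, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("gains", data=lf.gains)
    return path


def load_leadfield(path: str | Path) -> Leadfield:
    with h5py.File(path, "r") as f:
        return Leadfield(gains=f["gains"][()])


def save_sensor_recording(rec: SensorRecording, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("data", data=rec.data)
        ds.attrs["fs"] = rec.fs
    return path


def load_sensor_recording(path: str | Path) -> SensorRecording:
    with h5py.File(path, "r") as f:
        return SensorRecording(data=f["data"][()], fs=float(f["data"].attrs["fs"]))


def save_cohort(
    subjects: Sequence[SubjectRecord], out_dir: str | Path
) -> pd.DataFrame:
    """One directory per subject (masks/CBF/M0 as NIfTI, BOLD and ASL as
    HDF5) plus a cohort-level TSV manifest with the planted parameters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in subjects:
        sdir = out_dir / subj.subject_id
        sdir.mkdir(exist_ok=True)
        save_volume(subj.lesion_mask, sdir / "lesion.nii")
        save_volume(subj.gm_mask, sdir / "gm.nii")
        save_volume(subj.slowing_map, sdir / "slowing_truth.nii")
        save_volume(subj.cbf_truth, sdir / "cbf_truth.nii")
        save_volume(subj.m0, sdir / "m0.nii")
        save_bold(subj.bold, sdir / "bold.h5")
        save_asl(subj.asl, sdir / "asl.h5")
        planted = {
            k: v for k, v in subj.planted.items() if isinstance(v, (int, float, str))
        }
        rows.append(
            {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "seed": subj._spec.seed,
                "planted": json.dumps(planted, sort_keys=True),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
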