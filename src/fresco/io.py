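"""HDF5 / NIfTI / CSV persistence for cines, phantoms and results."""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .containers import CineSeries

__all__ = [
    "save_cine",
    "load_cine",
    "save_phantom",
    "save_masks_nifti",
    "save_beat_table",
    "load_beat_table",
]


def save_cine(path, cine: CineSeries, group: str = "cine"):
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("frames", data=cine.frames.astype(np.complex64))
        g.attrs["voxel_mm"] = cine.voxel_mm
        g.attrs["frame_ms"] = cine.frame_ms
        g.attrs["venc_cm_s"] = cine.venc_cm_s


def load_cine(path, group: str = "cine") -> CineSeries:
    with h5py.File(path, "r") as f:
        g = f[group]
        return CineSeries(
            frames=g["frames"][()].astype(complex),
            voxel_mm=float(g.attrs["voxel_mm"]),
            frame_ms=float(g.attrs["frame_ms"]),
            venc_cm_s=float(g.attrs["venc_cm_s"]),
        )


def save_phantom(path, phantom):
    """Phantom + ground truth in one HDF5 container; beat table as CSV
    alongside when ``path`` has a parent directory."""
    with h5py.File(path, "w") as f:
        f.create_dataset("magnitude", data=phantom.magnitude.astype(np.float32))
        f.create_dataset("velocity_cm_s", data=phantom.velocity_cm_s.astype(np.float32))
        g = f.create_group("truth")
        g.create_dataset("masks", data=phantom.truth.masks.astype(np.int8))
        g.create_dataset("flow_ml_s", data=phantom.truth.flow_ml_s)
        f.attrs["voxel_mm"] = phantom.config.voxel_mm
        f.attrs["frame_ms"] = phantom.config.frame_ms
        f.attrs["venc_cm_s"] = phantom.config.venc_cm_s
    beats_csv = Path(path).with_suffix(".beats.csv")
    phantom.truth.beats.to_csv(beats_csv, index=False)


def save_raw_kspace(path, comp_k, enc_k, trajs, venc_cm_s: float, frame_ms: float, maps=None):
    """Raw container: ``/kspace/frame{i}/coil{c}`` complex64 per encoding
    (comp, enc interleaved per readout), ``/traj/frame{i}``, ``/maps``."""
    with h5py.File(path, "w") as f:
        f.attrs["venc_cm_s"] = venc_cm_s
        f.attrs["frame_ms"] = frame_ms
        f.attrs["encoding_order"] = "comp,enc"
        for i, (ck, ek) in enumerate(zip(comp_k, enc_k)):
            g = f.create_group(f"kspace/frame{i}")
            for c in range(ck.shape[0]):
                g.create_dataset(
                    f"coil{c}",
                    data=np.stack([ck[c], ek[c]]).astype(np.complex64),
                )
            f.create_dataset(f"traj/frame{i}", data=np.asarray(trajs[i].k_coords))
        if maps is not None:
            f.create_dataset("maps", data=np.asarray(maps.maps).astype(np.complex64))


def load_raw_kspace(path):
    from .trajectory import FrameTrajectory

    comp_k, enc_k, trajs = [], [], []
    with h5py.File(path, "r") as f:
        n = len(f["kspace"])
        for i in range(n):
            g = f[f"kspace/frame{i}"]
            cs = [g[f"coil{c}"][()] for c in range(len(g))]
            comp_k.append(np.stack([c[0] for c in cs]))
            enc_k.append(np.stack([c[1] for c in cs]))
            k = f[f"traj/frame{i}"][()]
            trajs.append(
                FrameTrajectory(
                    frame_index=i,
                    arm_angles=np.array([]),
                    k_coords=k,
                    readout_order=np.zeros((k.shape[0], 2), dtype=int),
                )
            )
        venc = float(f.attrs["venc_cm_s"])
        frame_ms = float(f.attrs["frame_ms"])
    return comp_k, enc_k, trajs, frame_ms, venc


def save_masks_nifti(path, masks: np.ndarray, voxel_mm: float = 2.1):
    """Masks as int8 NIfTI with (x, y, t) axis order."""
    data = np.asarray(masks).astype(np.int8).transpose(2, 1, 0)
    affine = np.diag([voxel_mm, voxel_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def save_beat_table(path, beats: pd.DataFrame):
    beats.to_csv(path, index=False)


def load_beat_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
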