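"""HDF5 / NIfTI / YAML I/O helpers."""

from __future__ import annotations

import dataclasses
import json

import h5py
import nibabel as nib
import numpy as np
import yaml

from .core import DynamicImage
from .kspace import SamplingMask
from .phantom import PhantomGroundTruth

__all__ = [
    "save_series",
    "load_series",
    "save_phantom",
    "load_phantom",
    "save_mask",
    "load_mask",
    "export_nifti",
    "load_yaml_config",
]


def save_series(path, image: DynamicImage, group: str = "series") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("data", data=image.data)
        if image.frame_interval is not None:
            g.attrs["frame_interval"] = image.frame_interval


def load_series(path, group: str = "series") -> DynamicImage:
    with h5py.File(path, "r") as f:
        g = f[group]
        data = g["data"][()]
        fi = g.attrs.get("frame_interval")
    return DynamicImage(data, None if fi is None else float(fi))


def save_phantom(path, image: DynamicImage, gt: PhantomGroundTruth, config=None) -> None:
    """Complex series + ground truth to HDF5 (config serialized as JSON attr)."""
    save_series(path, image)
    with h5py.File(path, "a") as f:
        if "ground_truth" in f:
            del f["ground_truth"]
        g = f.create_group("ground_truth")
        g.create_dataset("label_map", data=gt.label_map)
        g.create_dataset("deformation_fields", data=gt.deformation_fields)
        g.create_dataset("sparse_support", data=gt.sparse_support)
        g.attrs["bh_frames"] = gt.bh_frames
        if gt.kinetic_maps:
            k = g.create_group("kinetic_maps")
            for name, arr in gt.kinetic_maps.items():
                k.create_dataset(name, data=arr)
        if config is not None:
            f.attrs["config"] = json.dumps(dataclasses.asdict(config), default=str)


def load_phantom(path) -> tuple[DynamicImage, PhantomGroundTruth]:
    image = load_series(path)
    with h5py.File(path, "r") as f:
        g = f["ground_truth"]
        kin = None
        if "kinetic_maps" in g:
            kin = {k: g["kinetic_maps"][k][()] for k in g["kinetic_maps"]}
        gt = PhantomGroundTruth(
            label_map=g["label_map"][()],
            kinetic_maps=kin,
            deformation_fields=g["deformation_fields"][()],
            sparse_support=g["sparse_support"][()].astype(bool),
            bh_frames=int(g.attrs["bh_frames"]),
        )
    return image, gt


def save_mask(path, mask: SamplingMask) -> None:
    with h5py.File(path, "a") as f:
        if "mask" in f:
            del f["mask"]
        g = f.create_group("mask")
        g.create_dataset("lines", data=mask.lines)
        g.attrs["accel"] = mask.accel
        g.attrs["n_center"] = mask.n_center
        if mask.seed is not None:
            g.attrs["seed"] = mask.seed


def load_mask(path) -> SamplingMask:
    with h5py.File(path, "r") as f:
        g = f["mask"]
        return SamplingMask(
            lines=g["lines"][()],
            accel=float(g.attrs["accel"]),
            n_center=int(g.attrs["n_center"]),
            seed=int(g.attrs["seed"]) if "seed" in g.attrs else None,
        )


def export_nifti(path, array: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write a magnitude volume/series as NIfTI."""
    mag = np.abs(np.asarray(array)).astype(np.float32)
    affine = np.diag([*voxel_size[:3], 1.0])
    nib.save(nib.Nifti1Image(mag, affine), str(path))


def load_yaml_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
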