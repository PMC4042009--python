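"""File formats: NIfTI-1 image stacks (+ JSON sidecars), HDF5 k-space, YAML specs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .phantom import CineStack, PhantomSpec
from .sampling import KtData
from .indices import SegmentationSeries

__all__ = [
    "write_cine_nifti", "read_cine_nifti",
    "write_ktdata_h5", "read_ktdata_h5",
    "write_phantom_spec_yaml", "read_phantom_spec_yaml",
    "write_segmentation_nifti", "read_segmentation_nifti",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_cine_nifti(stack: CineStack, path) -> Path:
    """Write (y, x, slice, frame) as a 4-D NIfTI-1 with a JSON sidecar."""
    path = Path(path)
    dy, dx, dz = stack.voxel_size_mm
    affine = np.diag([dy, dx, dz, 1.0])
    img = nib.Nifti1Image(np.asarray(stack.values, dtype=np.float64), affine)
    img.header.set_zooms((dy, dx, dz, stack.frame_duration_ms / 1000.0))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    sidecar = {"frame_duration_ms": stack.frame_duration_ms,
               "voxel_size_mm": list(stack.voxel_size_mm),
               "metadata": _jsonable(stack.metadata)}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_cine_nifti(path) -> CineStack:
    path = Path(path)
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    if values.ndim == 3:
        values = values[..., None]
    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())
        voxel = tuple(sidecar["voxel_size_mm"])
        frame_ms = float(sidecar["frame_duration_ms"])
        meta = sidecar.get("metadata", {})
    else:
        zooms = img.header.get_zooms()
        voxel = tuple(float(z) for z in zooms[:3])
        frame_ms = float(zooms[3]) * 1000.0 if len(zooms) > 3 else 1.0
        meta = {}
    return CineStack(values=values, voxel_size_mm=voxel,
                     frame_duration_ms=frame_ms, metadata=meta)


def write_ktdata_h5(kt: KtData, path) -> Path:
    """Complex samples stored as paired float64 real/imag datasets."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("samples_real", data=kt.samples.real, dtype="f8")
        f.create_dataset("samples_imag", data=kt.samples.imag, dtype="f8")
        f.create_dataset("mask", data=kt.mask.astype(np.uint8))
        f.attrs["voxel_size_mm"] = kt.voxel_size_mm
        f.attrs["frame_duration_ms"] = kt.frame_duration_ms
        f.attrs["metadata_json"] = json.dumps(_jsonable(kt.metadata))
    return path


def read_ktdata_h5(path) -> KtData:
    with h5py.File(path, "r") as f:
        samples = f["samples_real"][()] + 1j * f["samples_imag"][()]
        mask = f["mask"][()].astype(bool)
        voxel = tuple(float(v) for v in f.attrs["voxel_size_mm"])
        frame_ms = float(f.attrs["frame_duration_ms"])
        meta = json.loads(f.attrs["metadata_json"])
    return KtData(samples=samples, mask=mask, voxel_size_mm=voxel,
                  frame_duration_ms=frame_ms, metadata=meta)


def write_phantom_spec_yaml(spec: PhantomSpec, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))
    return path


def read_phantom_spec_yaml(path) -> PhantomSpec:
    return PhantomSpec.from_dict(yaml.safe_load(Path(path).read_text()))


def write_segmentation_nifti(seg: SegmentationSeries, path) -> Path:
    path = Path(path)
    dy, dx, dz = seg.voxel_size_mm
    img = nib.Nifti1Image(seg.labels.astype(np.uint8), np.diag([dy, dx, dz, 1.0]))
    nib.save(img, str(path))
    return path


def read_segmentation_nifti(path, voxel_size_mm=None) -> SegmentationSeries:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.uint8)
    if labels.ndim == 3:
        labels = labels[..., None]
    if voxel_size_mm is None:
        voxel_size_mm = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SegmentationSeries(labels=labels, voxel_size_mm=voxel_size_mm)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
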