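"""File formats: NIfTI volumes with JSON sidecars, CSV tables, YAML configs.

Conventions
-----------
* Scalar and multi-echo volumes are NIfTI-1 (``.nii`` / ``.nii.gz``);
  voxel size lives in the header. Invalid voxels are NaN on disk.
* Multi-echo series are 4-D files with a JSON sidecar carrying the echo
  times under the key ``"EchoTimesMs"`` (sidecar path = volume path with
  the NIfTI suffix replaced by ``.json``).
* Label masks are integer NIfTI: 1 = left hippocampus, 2 = right
  hippocampus, 3 = CSF, 4 = other brain tissue, 0 = outside brain.
* The first voxel axis must be the left-right axis (orientation letters
  L/R); lower index on an R+ axis is the left side.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .types import MultiEchoVolume, ScalarMap

__all__ = [
    "write_scalar_map",
    "read_scalar_map",
    "write_multi_echo",
    "read_multi_echo",
    "write_labels",
    "read_labels",
    "load_yaml_config",
    "save_yaml_config",
]

ECHO_TIMES_KEY = "EchoTimesMs"


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def _check_orientation(img: nib.Nifti1Image) -> None:
    axcodes = nib.aff2axcodes(img.affine)
    if axcodes[0] not in ("L", "R"):
        raise ValueError(
            f"first voxel axis must be left-right, got orientation {axcodes}"
        )


def _voxel_size(img: nib.Nifti1Image) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_scalar_map(path, scalar_map: ScalarMap) -> None:
    img = nib.Nifti1Image(
        scalar_map.data.astype(np.float32), _affine(scalar_map.voxel_size)
    )
    img.header.set_zooms(scalar_map.voxel_size)
    nib.save(img, str(path))


def read_scalar_map(path, units: str = "") -> ScalarMap:
    img = nib.load(str(path))
    _check_orientation(img)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    flipped = _reorient_lr(img, data)
    return ScalarMap(flipped, _voxel_size(img), units=units)


def _reorient_lr(img: nib.Nifti1Image, data: np.ndarray) -> np.ndarray:
    """Flip the first axis if it points leftward, so lower index = left."""
    if nib.aff2axcodes(img.affine)[0] == "L":
        return data[::-1].copy()
    return data


def write_multi_echo(path, volume: MultiEchoVolume) -> None:
    path = Path(path)
    img = nib.Nifti1Image(
        volume.data.astype(np.float32), _affine(volume.voxel_size)
    )
    img.header.set_zooms(tuple(volume.voxel_size) + (1.0,))
    nib.save(img, str(path))
    with open(_sidecar_path(path), "w") as fh:
        json.dump({ECHO_TIMES_KEY: list(map(float, volume.echo_times))}, fh)


def read_multi_echo(path, sidecar=None) -> MultiEchoVolume:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing echo-time sidecar {sidecar} for {path}"
        )
    with open(sidecar) as fh:
        meta = json.load(fh)
    if ECHO_TIMES_KEY not in meta:
        raise ValueError(f"{sidecar}: no '{ECHO_TIMES_KEY}' field")
    echo_times = np.asarray(meta[ECHO_TIMES_KEY], dtype=float)
    img = nib.load(str(path))
    _check_orientation(img)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D multi-echo volume")
    if data.shape[3] != echo_times.size:
        raise ValueError(
            f"{path}: {data.shape[3]} echo images but sidecar lists "
            f"{echo_times.size} echo times"
        )
    data = _reorient_lr(img, data)
    return MultiEchoVolume(data, echo_times, _voxel_size(img))


def write_labels(path, labels: np.ndarray, voxel_size) -> None:
    img = nib.Nifti1Image(
        np.asarray(labels, dtype=np.int16), _affine(voxel_size)
    )
    img.header.set_zooms(voxel_size)
    nib.save(img, str(path))


def read_labels(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    _check_orientation(img)
    data = np.asarray(img.dataobj)
    data = _reorient_lr(img, np.rint(data).astype(np.int16))
    return data, _voxel_size(img)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_yaml_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
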