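"""NIfTI / sidecar / table I/O helpers.

All volumes travel with their affine; echo times for 4D multi-echo volumes
live in a JSON sidecar next to the image (``<stem>_echoes.json``) because the
NIfTI header has no slot for an echo-time vector.  Coordinates are 0-based
voxel indices internally; world coordinates exist only through the affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "save_multiecho",
    "load_multiecho",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_json",
    "load_json",
    "load_yaml_config",
]


def _sidecar_path(image_path: Path) -> Path:
    stem = image_path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return image_path.parent / f"{stem}_echoes.json"


def save_multiecho(path, volume: np.ndarray, affine: np.ndarray, echo_times_ms) -> Path:
    """Write a 4D multi-echo volume plus its echo-time sidecar JSON."""
    path = Path(path)
    vol = np.asarray(volume)
    if vol.ndim != 4:
        raise ValueError("multi-echo volume must be 4D (x, y, z, echo)")
    te = np.asarray(echo_times_ms, dtype=float)
    if vol.shape[-1] != len(te):
        raise ValueError("echo dimension does not match echo_times_ms")
    nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), path)
    save_json(_sidecar_path(path), {"echo_times_ms": te.tolist()})
    return path


def load_multiecho(path):
    """Read a 4D volume and its echo-time sidecar; returns (vol, affine, te)."""
    path = Path(path)
    img = nib.load(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing echo-time sidecar: expected {sidecar} next to {path.name}"
        )
    te = np.asarray(load_json(sidecar)["echo_times_ms"], dtype=float)
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4 or vol.shape[-1] != len(te):
        raise ValueError("volume/sidecar echo mismatch")
    return vol, img.affine, te


def save_volume(path, data: np.ndarray, affine: np.ndarray) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), path)
    return path


def load_volume(path):
    img = nib.load(Path(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_mask(path, mask: np.ndarray, affine: np.ndarray) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.int16), affine), path)
    return path


def load_mask(path):
    img = nib.load(Path(path))
    return np.asarray(img.dataobj, dtype=np.int16), img.affine


def save_json(path, obj) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def load_json(path):
    return json.loads(Path(path).read_text())


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"malformed config {path}: expected a mapping")
    return cfg


def check_same_geometry(affine_a: np.ndarray, affine_b: np.ndarray, what: str = "volumes"):
    if not np.allclose(affine_a, affine_b, atol=1e-6):
        raise ValueError(f"geometry mismatch between {what}: affines differ")
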