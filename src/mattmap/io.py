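"""NIfTI / CSV / config I/O helpers.

Label-duration metadata lives in the pipeline configuration, not in NIfTI
headers (headers cannot carry it reliably); volumes keep their input affine
unchanged through the pipeline.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .synthetic import DEFAULT_TIMES


def read_volume(path):
    """Read a 3D NIfTI volume; returns (data, affine, voxel_dims)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return data, img.affine, tuple(float(z) for z in img.header.get_zooms()[:3])


def write_volume(data, path, affine=None):
    affine = np.eye(4) if affine is None else affine
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    return Path(path)


def read_series(label_path, control_path=None, times=None):
    """Read label/control 4D series.

    Accepts either two 4D NIfTI files (one per series) or two lists of 3D
    volume files (one per time point).  ``times`` defaults to the reference
    protocol's 8 label durations and must match the number of volumes.

    Returns (label, control, times, affine, voxel_dims).
    """
    times = np.asarray(DEFAULT_TIMES if times is None else times, float)

    def load4d(p):
        if isinstance(p, (list, tuple)):
            vols, affine, zooms = [], None, None
            for f in p:
                d, a, z = read_volume(f)
                if d.ndim != 3:
                    raise ValueError(f"{f}: expected a 3D volume")
                if affine is not None and not np.allclose(a, affine):
                    raise ValueError(f"{f}: affine differs from first volume")
                affine, zooms = a, z
                vols.append(d)
            return np.stack(vols, axis=3), affine, zooms
        img = nib.load(str(p))
        d = np.asanyarray(img.dataobj)
        if d.ndim != 4:
            raise ValueError(f"{p}: expected a 4D NIfTI, got {d.ndim}D")
        return d, img.affine, tuple(float(z) for z in img.header.get_zooms()[:3])

    label, a1, z1 = load4d(label_path)
    if control_path is None:
        raise ValueError("control series path required")
    control, a2, z2 = load4d(control_path)
    if label.shape != control.shape:
        raise ValueError(
            f"label {label.shape} and control {control.shape} shapes differ")
    if not np.allclose(a1, a2):
        raise ValueError("label and control affines differ")
    if label.shape[3] != times.size:
        raise ValueError(
            f"{label_path}: {label.shape[3]} volumes but {times.size} "
            f"configured times")
    return label, control, times, a1, z1


def write_series(data, path, affine=None):
    """Write a 4D series as a single NIfTI file (time = 4th axis)."""
    return write_volume(data, path, affine)


def normalize_att_units(att, log=None):
    """Arrival-time maps in seconds are auto-converted to ms.

    Heuristic: finite values all below 20 are interpreted as seconds.
    Overridable by passing maps already in ms.
    """
    att = np.asarray(att, float)
    finite = att[np.isfinite(att)]
    if finite.size and np.nanmax(np.abs(finite)) < 20.0:
        if log is not None:
            log("ATT map interpreted as seconds; converted to ms")
        return att * 1000.0
    return att


def save_config(cfg_dict: dict, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    return Path(path)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths, out_path):
    """JSON manifest listing every output file with a content hash."""
    manifest = {
        str(Path(p).name): {"path": str(p), "sha256": file_sha256(p)}
        for p in paths
    }
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return Path(out_path)
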