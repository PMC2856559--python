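"""File I/O: NIfTI / multi-page TIFF volumes, vector fields, sidecars.

NIfTI is the primary interchange format. A 4D volume stores a phase
sequence; a vector field stores its components on a trailing axis. Every
writer drops a JSON sidecar (``<stem>.json``) next to the image recording
units, spacing, phase times, the reference phase for displacement fields,
and the package version, so any artifact on disk is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import tifffile

from . import __version__
from .core import VolumeSequence, DisplacementField

__all__ = [
    "read_volume", "write_volume",
    "read_field", "write_field",
    "read_contours_json", "write_contours_json",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def _write_sidecar(path: Path, payload: dict) -> None:
    payload = dict(payload)
    payload["software"] = {"name": "tagflow3d", "version": __version__}
    _sidecar_path(path).write_text(json.dumps(payload, indent=2))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def write_volume(vol: VolumeSequence, path: str | Path) -> None:
    """Write a phase sequence as 4D NIfTI (or multi-page TIFF) + sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": "volume_sequence",
        "spacing_mm": list(vol.spacing),
        "phase_times_ms": [float(t) for t in vol.phase_times],
        "axes": "x,y,z,phase",
        "intensity_units": "arbitrary",
    }
    if path.name.endswith((".tif", ".tiff")):
        # pages = z*phase, recorded in the sidecar for lossless round trip
        nx, ny, nz, npha = vol.data.shape
        pages = np.moveaxis(vol.data, (0, 1, 2, 3), (3, 2, 1, 0))
        tifffile.imwrite(path, pages.reshape(npha * nz, ny, nx).astype(np.float32))
        meta["tiff_layout"] = {"n_phases": npha, "nz": nz}
        _write_sidecar(path, meta)
        return
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float64), affine), str(path))
    _write_sidecar(path, meta)


def read_volume(path: str | Path) -> VolumeSequence:
    """Read a 3D/4D NIfTI or a multi-page TIFF stack into a sequence.

    Spacing comes from the NIfTI header or, for TIFF, from the JSON
    sidecar written by :func:`write_volume`; a 3D file becomes a
    single-phase sequence. Raises a clear error on a missing/corrupt file
    or missing TIFF spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_sidecar(path)
    if path.name.endswith((".tif", ".tiff")):
        if "spacing_mm" not in meta:
            raise ValueError(
                f"no spacing for TIFF stack {path}; supply a JSON sidecar "
                "with a 'spacing_mm' entry")
        pages = tifffile.imread(path)
        layout = meta.get("tiff_layout", {})
        npha = int(layout.get("n_phases", 1))
        nz = int(layout.get("nz", pages.shape[0] // npha))
        data = pages.reshape(npha, nz, pages.shape[-2], pages.shape[-1])
        data = np.moveaxis(data, (0, 1, 2, 3), (3, 2, 1, 0))
        return VolumeSequence(np.ascontiguousarray(data, dtype=np.float64),
                              tuple(meta["spacing_mm"]),
                              np.asarray(meta.get("phase_times_ms")) if
                              meta.get("phase_times_ms") else None)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # corrupt header, wrong magic, truncated file
        raise ValueError(f"cannot read {path} as NIfTI: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(
            f"{path} has no usable voxel spacing; fix the header or "
            "supply a sidecar")
    if data.ndim == 3:
        data = data[..., np.newaxis]
    times = meta.get("phase_times_ms")
    return VolumeSequence(data, tuple(float(z) for z in zooms),
                          np.asarray(times, dtype=float) if times else None)


def write_field(field: DisplacementField, path: str | Path,
                spacing: Sequence[float] = (1.0, 1.0, 1.0),
                extra_meta: dict | None = None) -> None:
    """Write a displacement/flow field as 4D NIfTI (last axis = component).

    Components are voxel units per axis; the sidecar records the
    reference phase, units and axis order.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(field.U.astype(np.float64), affine), str(path))
    meta = {
        "kind": "displacement_field",
        "units": "voxels",
        "axes": "x,y,z,component",
        "component_order": "x,y,z"[: 2 * field.ndim_vec - 1],
        "reference_phase": int(field.reference_phase),
        "spacing_mm": [float(s) for s in spacing],
    }
    if extra_meta:
        meta.update(extra_meta)
    _write_sidecar(path, meta)


def read_field(path: str | Path) -> DisplacementField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    U = np.asarray(img.dataobj, dtype=np.float64)
    meta = _read_sidecar(path)
    return DisplacementField(U, int(meta.get("reference_phase", 0)))


def write_contours_json(contours, path: str | Path) -> None:
    """Contour polygons as JSON: slice/phase/role + mm vertex lists."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    items = [{
        "slice_index": c.slice_index,
        "phase_index": c.phase_index,
        "role": c.role,
        "provenance": c.provenance,
        "vertices_mm": np.asarray(c.vertices).tolist(),
    } for c in contours]
    path.write_text(json.dumps({"contours": items}, indent=2))


def read_contours_json(path: str | Path):
    from .regions import Contour, ContourSet

    payload = json.loads(Path(path).read_text())
    return ContourSet([
        Contour(int(it["slice_index"]), int(it["phase_index"]), it["role"],
                np.asarray(it["vertices_mm"], dtype=float),
                it.get("provenance", "given"))
        for it in payload["contours"]])
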