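"""NIfTI volume and projection-bundle I/O with JSON provenance sidecars."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import GridSpec, VoxelPhantom
from .simulate import AcquisitionGeometry, ProjectionSet, PsfModel

__all__ = [
    "save_volume",
    "load_volume",
    "save_phantom",
    "load_phantom",
    "save_projection_set",
    "load_projection_set",
    "config_hash",
    "file_hash",
]


def config_hash(obj) -> str:
    """Stable sha256 of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    return np.diag([voxel_size[2], voxel_size[1], voxel_size[0], 1.0])


def save_volume(
    path: str | Path,
    volume: np.ndarray,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    sidecar: dict | None = None,
) -> Path:
    """Write a (z, y, x) volume as NIfTI plus an optional JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64).T, _affine(voxel_size_mm))
    nib.save(img, path)
    if sidecar is not None:
        Path(str(path).replace(".nii.gz", ".nii").replace(".nii", ".json")).write_text(
            json.dumps(sidecar, indent=2, default=str)
        )
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, dict | None]:
    path = Path(path)
    img = nib.load(path)
    vol = np.asarray(img.get_fdata()).T
    sidecar_path = Path(str(path).replace(".nii.gz", ".nii").replace(".nii", ".json"))
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else None
    return vol, sidecar


def save_phantom(directory: str | Path, phantom: VoxelPhantom, prefix: str = "phantom") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vs = phantom.grid.voxel_size
    save_volume(directory / f"{prefix}_activity.nii.gz", phantom.activity, vs)
    save_volume(directory / f"{prefix}_mu.nii.gz", phantom.mu, vs)
    save_volume(directory / f"{prefix}_labels.nii.gz", phantom.labels.astype(float), vs)
    sidecar = {
        "grid": dataclasses.asdict(phantom.grid),
        "analytic_volumes_ml": phantom.analytic_volumes,
        "region_conc_MBq_per_ml": {str(k): v for k, v in phantom.region_conc.items()},
        "sphere_plane_z_mm": phantom.sphere_plane_z,
    }
    path = directory / f"{prefix}.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path


def load_phantom(directory: str | Path, prefix: str = "phantom") -> VoxelPhantom:
    directory = Path(directory)
    meta = json.loads((directory / f"{prefix}.json").read_text())
    grid = GridSpec(
        shape=tuple(meta["grid"]["shape"]),
        voxel_size=tuple(meta["grid"]["voxel_size"]),
        origin=tuple(meta["grid"]["origin"]),
    )
    activity, _ = load_volume(directory / f"{prefix}_activity.nii.gz")
    mu, _ = load_volume(directory / f"{prefix}_mu.nii.gz")
    labels, _ = load_volume(directory / f"{prefix}_labels.nii.gz")
    return VoxelPhantom(
        grid=grid,
        activity=activity,
        mu=mu,
        labels=np.round(labels).astype(np.int16),
        analytic_volumes=meta.get("analytic_volumes_ml", {}),
        region_conc={int(k): v for k, v in meta.get("region_conc_MBq_per_ml", {}).items()},
        sphere_plane_z=meta.get("sphere_plane_z_mm", 0.0),
    )


def save_projection_set(
    directory: str | Path,
    pset: ProjectionSet,
    prefix: str = "proj",
    provenance: dict | None = None,
) -> Path:
    """One NIfTI stack per window plus a JSON sidecar (the bundle format)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    px = pset.geometry.pixel_size
    for label, stack in pset.windows.items():
        save_volume(directory / f"{prefix}_{label}.nii.gz", stack, (1.0, px, px))
    sidecar = {
        "geometry": dataclasses.asdict(pset.geometry),
        "psf": dataclasses.asdict(pset.psf) if pset.psf is not None else None,
        "windows": sorted(pset.windows),
        "component_tallies": pset.component_tallies,
        "meta": {k: v for k, v in pset.meta.items() if k != "expected_totals"},
        "provenance": provenance or {},
    }
    path = directory / f"{prefix}.json"
    path.write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def load_projection_set(directory: str | Path, prefix: str = "proj") -> ProjectionSet:
    directory = Path(directory)
    meta = json.loads((directory / f"{prefix}.json").read_text())
    g = meta["geometry"]
    geometry = AcquisitionGeometry(
        n_projections=g["n_projections"],
        angle_span=g["angle_span"],
        time_per_projection=g["time_per_projection"],
        detector_matrix=tuple(g["detector_matrix"]),
        pixel_size=g["pixel_size"],
        orbit_radius=g["orbit_radius"],
        start_time=g["start_time"],
    )
    psf = PsfModel(**meta["psf"]) if meta.get("psf") else None
    windows = {}
    for label in meta["windows"]:
        stack, _ = load_volume(directory / f"{prefix}_{label}.nii.gz")
        windows[label] = stack
    return ProjectionSet(
        windows=windows,
        geometry=geometry,
        psf=psf,
        component_tallies=meta.get("component_tallies"),
        meta=dict(meta.get("meta", {}), provenance=meta.get("provenance", {})),
    )
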