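"""NIfTI / JSON persistence for phantoms, projections and reconstructions.

Volumes are written RAS-aligned with the isotropic voxel size in the header;
activity maps hold MBq/mL as floating point and attenuation maps go to a
sibling file with the ``_mu`` suffix.  Projection stacks are stored as a 3-D
NIfTI (nu x nv x n_views) next to a JSON sidecar carrying the protocol,
camera preset name, model flags and noise seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantoms import TissueMaps, VoxelGrid
from .presets import get_preset
from .projector import ModelFlags, ProjectionSet, Protocol
from .recon import ReconSettings, ReconVolume

__all__ = [
    "save_tissue_maps",
    "load_tissue_maps",
    "save_projections",
    "load_projections",
    "save_recon_volume",
    "load_recon_volume",
]


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def _mu_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + "_mu" + suffix)
    raise ValueError("expected a .nii or .nii.gz path")


def save_tissue_maps(maps: TissueMaps, path: str | Path) -> None:
    path = Path(path)
    aff = _affine(maps.grid.voxel_size)
    nib.save(nib.Nifti1Image(maps.activity.astype(np.float32), aff), path)
    nib.save(nib.Nifti1Image(maps.mu.astype(np.float32), aff), _mu_path(path))


def load_tissue_maps(path: str | Path) -> TissueMaps:
    path = Path(path)
    act_img = nib.load(path)
    mu_img = nib.load(_mu_path(path))
    # header zooms are float32; round away the representation error
    voxel = round(float(act_img.header.get_zooms()[0]), 4)
    grid = VoxelGrid(tuple(act_img.shape), voxel)
    return TissueMaps(grid,
                      np.asarray(act_img.dataobj, dtype=np.float64),
                      np.asarray(mu_img.dataobj, dtype=np.float64))


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    raise ValueError("expected a .nii or .nii.gz path")


def save_projections(pset: ProjectionSet, path: str | Path) -> None:
    path = Path(path)
    # store as (nu, nv, n_views) so viewers show one view per slice
    stack = np.moveaxis(pset.counts, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(stack, _affine(pset.protocol.bin_size)), path)
    meta = {
        "protocol": asdict(pset.protocol),
        "camera": pset.camera.name,
        "flags": asdict(pset.flags),
        "noise_seed": pset.noise_seed,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_projections(path: str | Path) -> ProjectionSet:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    proto = meta["protocol"]
    proto["detector_bins"] = tuple(proto["detector_bins"])
    protocol = Protocol(**proto)
    counts = np.moveaxis(np.asarray(nib.load(path).dataobj, dtype=np.float64), -1, 0)
    return ProjectionSet(counts=counts, protocol=protocol,
                         camera=get_preset(meta["camera"]),
                         flags=ModelFlags(**meta["flags"]),
                         noise_seed=meta["noise_seed"])


def save_recon_volume(vol: ReconVolume, path: str | Path) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32),
                             _affine(vol.grid.voxel_size)), path)
    meta = {
        "settings": {
            "n_subsets": vol.settings.n_subsets,
            "n_updates": vol.settings.n_updates,
            "flags": asdict(vol.settings.flags),
            "epsilon": vol.settings.epsilon,
        },
        "camera": vol.camera.name,
        "protocol": asdict(vol.protocol),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_recon_volume(path: str | Path) -> ReconVolume:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    img = nib.load(path)
    grid = VoxelGrid(tuple(img.shape), round(float(img.header.get_zooms()[0]), 4))
    s = meta["settings"]
    settings = ReconSettings(n_subsets=s["n_subsets"], n_updates=s["n_updates"],
                             flags=ModelFlags(**s["flags"]), epsilon=s["epsilon"])
    proto = meta["protocol"]
    proto["detector_bins"] = tuple(proto["detector_bins"])
    return ReconVolume(values=np.asarray(img.dataobj, dtype=np.float64),
                       grid=grid, settings=settings,
                       camera=get_preset(meta["camera"]),
                       protocol=Protocol(**proto))
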