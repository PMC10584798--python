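"""Volume and projection persistence.

Volumes travel as NIfTI-1 with mm spacing in the affine; reconstructed
volumes carry a JSON sidecar with the protocol and acquisition
provenance.  Projection sets are stored as a ``.luq`` container: a
compressed NumPy archive holding both windows plus a JSON metadata
header (geometry, windows, grid, seed, timestamps).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import VoxelGrid
from .phantoms import ActivityMap, MuMap
from .recon import ReconParams, ReconVolume
from .simulate import AcquisitionGeometry, EnergyWindows, ProjectionSet

__all__ = [
    "save_volume",
    "load_volume",
    "save_label_map",
    "save_recon",
    "load_recon",
    "save_projections",
    "load_projections",
]


def _grid_from_nifti(img) -> VoxelGrid:
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return VoxelGrid(img.shape, spacing, origin)


def save_volume(path, values: np.ndarray, grid: VoxelGrid) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid.affine())
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), _grid_from_nifti(img)


def save_label_map(path, masks, grid: VoxelGrid) -> None:
    """Write boolean masks as one integer NIfTI label map (1-based,
    in iteration order; later masks overwrite earlier on overlap)."""
    labels = np.zeros(grid.shape, dtype=np.int16)
    for i, m in enumerate(masks, start=1):
        labels[np.asarray(m, bool)] = i
    img = nib.Nifti1Image(labels, grid.affine())
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def save_activity_map(path, amap: ActivityMap) -> None:
    save_volume(path, amap.values, amap.grid)


def save_mu_map(path, mumap: MuMap) -> None:
    save_volume(path, mumap.values, mumap.grid)


def save_recon(path, recon: ReconVolume) -> None:
    """NIfTI volume plus a ``.json`` sidecar with protocol provenance."""
    save_volume(path, recon.values, recon.grid)
    sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
    p = recon.params
    sidecar.write_text(
        json.dumps(
            {
                "algorithm": p.algorithm,
                "iterations": p.iterations,
                "subsets": p.subsets,
                "beta": p.beta,
                "gamma": p.gamma,
                "by_sens": p.by_sens,
                "psf_mode": p.psf_mode,
                "relaxation": list(p.relaxation),
                "duration": recon.duration,
                "acq_start": recon.acq_start,
            },
            indent=2,
        )
    )


def load_recon(path) -> ReconVolume:
    values, grid = load_volume(path)
    sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    params = ReconParams(
        algorithm=meta["algorithm"],
        iterations=meta["iterations"],
        subsets=meta["subsets"],
        beta=meta["beta"],
        gamma=meta["gamma"],
        by_sens=meta["by_sens"],
        psf_mode=meta["psf_mode"],
        relaxation=tuple(meta["relaxation"]),
    )
    return ReconVolume(
        grid=grid,
        values=values,
        params=params,
        duration=meta["duration"],
        acq_start=meta["acq_start"],
    )


def save_projections(path, proj: ProjectionSet) -> None:
    meta = {
        "geometry": {
            "n_views": proj.geometry.n_views,
            "angular_step": proj.geometry.angular_step,
            "detector_radius": proj.geometry.detector_radius,
            "duration": proj.geometry.duration,
        },
        "windows": {
            "photopeak_center": proj.windows.photopeak_center,
            "photopeak_fraction": proj.windows.photopeak_fraction,
            "scatter_center": proj.windows.scatter_center,
            "scatter_fraction": proj.windows.scatter_fraction,
        },
        "grid": {
            "shape": list(proj.grid.shape),
            "spacing": list(proj.grid.spacing),
            "origin": list(proj.grid.origin),
        },
        "acq_start": proj.acq_start,
        "seed": proj.seed,
    }
    arrays = {
        "photopeak_counts": proj.photopeak_counts,
        "scatter_counts": proj.scatter_counts,
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    if proj.noiseless_mean is not None:
        arrays["noiseless_mean"] = proj.noiseless_mean
    if proj.scatter_mean is not None:
        arrays["scatter_mean"] = proj.scatter_mean
    with open(path, "wb") as fh:
        np.savez_compressed(fh, **arrays)


def load_projections(path) -> ProjectionSet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        geom = AcquisitionGeometry(**meta["geometry"])
        windows = EnergyWindows(**meta["windows"])
        grid = VoxelGrid(
            tuple(meta["grid"]["shape"]),
            tuple(meta["grid"]["spacing"]),
            tuple(meta["grid"]["origin"]),
        )
        return ProjectionSet(
            photopeak_counts=z["photopeak_counts"],
            scatter_counts=z["scatter_counts"],
            geometry=geom,
            windows=windows,
            grid=grid,
            acq_start=meta["acq_start"],
            noiseless_mean=z["noiseless_mean"] if "noiseless_mean" in z else None,
            scatter_mean=z["scatter_mean"] if "scatter_mean" in z else None,
            seed=meta["seed"],
        )
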