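"""Recovery coefficients of the NEMA spheres on a CT-resolution grid.

The reconstructed SPECT volume is resampled to the (finer) CT grid by
trilinear interpolation, spherical VOIs are rendered geometrically on
that grid from the known centres and diameters, and for each sphere

``RC = C / (T_acq * ICF * V) / (c_prep * exp(-ln2 * dt / T_half)) * 100``

— the measured activity concentration in the VOI over the decayed true
concentration, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import constants as C
from .calibrate import ICFResult
from .grids import VoxelGrid
from .phantoms import _fractional_mask, _sphere
from .recon import ReconVolume
from .simulate import decay_activity

__all__ = ["SphereVOI", "make_sphere_voi", "resample_to_ct", "compute_rc", "rc_table"]


@dataclass(frozen=True)
class SphereVOI:
    center: tuple[float, float, float]
    diameter: float
    mask: np.ndarray = field(repr=False)
    volume_ml: float


def make_sphere_voi(
    center: tuple[float, float, float], diameter: float, ct_grid: VoxelGrid
) -> SphereVOI:
    """Geometric spherical mask on the CT grid (voxels at least half
    covered); the mask volume must sit within 5 % of (pi/6) d^3."""
    frac = _fractional_mask(ct_grid, _sphere(center, diameter))
    mask = frac >= 0.5
    vol = float(mask.sum()) * ct_grid.voxel_volume_ml
    analytic = np.pi / 6.0 * diameter**3 / 1000.0
    if not 0.95 <= vol / analytic <= 1.05:
        raise ValueError(
            f"{diameter} mm sphere VOI volume {vol:.3f} mL deviates more than 5 % "
            f"from analytic {analytic:.3f} mL; use a finer CT grid"
        )
    return SphereVOI(center=tuple(center), diameter=diameter, mask=mask, volume_ml=vol)


def resample_to_ct(recon: ReconVolume, ct_grid: VoxelGrid) -> ReconVolume:
    """Trilinear resampling of counts-per-voxel values onto a CT grid.

    Values are treated as densities (a constant field stays constant up
    to the voxel-volume rescale), then rescaled by the voxel-volume
    ratio so total counts are conserved wherever the CT grid covers the
    support.  An identical grid is a bitwise passthrough.
    """
    if recon.grid.same_geometry(ct_grid):
        return recon
    # require overlap of physical extents
    for a in range(3):
        lo_s = recon.grid.axis_coords(a)[0]
        hi_s = recon.grid.axis_coords(a)[-1]
        lo_c = ct_grid.axis_coords(a)[0]
        hi_c = ct_grid.axis_coords(a)[-1]
        if hi_c < lo_s or lo_c > hi_s:
            raise ValueError("CT grid does not overlap the SPECT grid")
    xi = np.meshgrid(
        *(ct_grid.axis_coords(a) for a in range(3)), indexing="ij", sparse=False
    )
    pts = np.stack(xi, axis=-1)
    idx = recon.grid.world_to_index(pts.reshape(-1, 3)).T
    vals = ndimage.map_coordinates(
        recon.values, idx, order=1, mode="nearest"
    ).reshape(ct_grid.shape)
    scale = ct_grid.voxel_volume_ml / recon.grid.voxel_volume_ml
    return ReconVolume(
        grid=ct_grid,
        values=np.maximum(vals * scale, 0.0),
        params=recon.params,
        duration=recon.duration,
        acq_start=recon.acq_start,
    )


def compute_rc(
    resampled: ReconVolume,
    voi: SphereVOI,
    icf: ICFResult,
    c_prep: float,
    dt: float = 0.0,
    half_life: float = C.HALF_LIFE_LU177_S,
    allow_protocol_mismatch: bool = False,
) -> float:
    """Recovery coefficient [%] of one sphere VOI."""
    if voi.volume_ml <= 0:
        raise ValueError("VOI volume must be positive")
    if icf.params is not None and icf.params != resampled.params:
        if not allow_protocol_mismatch:
            raise ValueError(
                "ICF protocol does not match the reconstruction protocol"
            )
    counts = float(resampled.values[voi.mask].sum())
    measured = counts / (resampled.duration * icf.icf * voi.volume_ml)
    true_conc = c_prep * decay_activity(1.0, dt, half_life)
    return 100.0 * measured / true_conc


def rc_table(
    recons: list[ReconVolume],
    spheres: list[SphereVOI],
    icfs: list[ICFResult],
    c_prep: float,
    dt: float = 0.0,
    background: str = "cold",
    ct_grid: VoxelGrid | None = None,
) -> pd.DataFrame:
    """Tidy RC table keyed by (algorithm, iterations, subsets, sphere).

    ``recons`` and ``icfs`` pair up positionally (one ICF per protocol).
    Reconstructions are resampled to ``ct_grid`` (default: the grid the
    sphere masks live on, inferred from the first sphere).
    """
    rows = []
    for recon, icf in zip(recons, icfs):
        res = resample_to_ct(recon, ct_grid) if ct_grid is not None else recon
        for voi in spheres:
            rows.append(
                {
                    "algorithm": recon.params.algorithm,
                    "iterations": recon.params.iterations,
                    "subsets": recon.params.subsets,
                    "beta": recon.params.beta,
                    "gamma": recon.params.gamma,
                    "by_sens": recon.params.by_sens,
                    "updates": recon.params.updates,
                    "background": background,
                    "sphere_mm": voi.diameter,
                    "rc_percent": compute_rc(res, voi, icf, c_prep, dt=dt),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "algorithm", "iterations", "subsets", "beta", "gamma", "by_sens",
            "updates", "background", "sphere_mm", "rc_percent",
        ],
    )
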