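"""Image calibration factor (ICF) and activity quantification accuracy.

The ICF converts reconstructed counts into activity:

``ICF = C / (T_acq * A_prep * exp(-ln2 * dt / T_half))``  [cps/MBq]

with ``C`` the total counts in a large VOI around the calibration
phantom, ``A_prep`` the activity at preparation and ``dt`` the
preparation-to-acquisition delay.  Its relative uncertainty propagates
the counting term and the radionuclide-calibrator term:

``u(ICF)/ICF = sqrt((sqrt(C)/C)^2 + (u(A)/A)^2)``

(the sqrt(C) counting model is applied to reconstructed counts even
though reconstructed voxels are not independent Poisson draws — a
deliberate convention of the characterization procedure).

Quantification error is the fractional difference between the
SPECT-based and the true (decayed) activity or activity concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .grids import VoxelGrid
from .recon import ReconParams, ReconVolume
from .simulate import decay_activity

__all__ = [
    "CalibrationInputs",
    "ICFResult",
    "QuantResult",
    "make_cylindrical_voi",
    "compute_icf",
    "compute_icf_uncertainty",
    "quantify",
]


@dataclass(frozen=True)
class CalibrationInputs:
    counts: float  # C: total counts in the calibration VOI
    t_acq: float  # [s]
    a_prep: float  # [MBq]
    dt: float = 0.0  # preparation -> acquisition start [s]
    half_life: float = C.HALF_LIFE_LU177_S
    u_a_rel: float = C.ACTIVITY_REL_UNCERTAINTY

    def __post_init__(self):
        if self.counts < 0:
            raise ValueError("counts must be nonnegative")
        if self.t_acq <= 0 or self.a_prep <= 0:
            raise ValueError("t_acq and a_prep must be positive")


@dataclass(frozen=True)
class ICFResult:
    icf: float  # [cps/MBq]
    u_icf_rel: float
    voi: dict = field(default_factory=dict)
    params: ReconParams | None = None


@dataclass(frozen=True)
class QuantResult:
    a_meas: float
    a_truth_decayed: float
    error: float  # (A_meas - A_truth) / A_truth
    concentration: bool = False  # units MBq/mL when True, MBq otherwise


def make_cylindrical_voi(
    center: tuple[float, float, float],
    diameter: float,
    height: float,
    grid: VoxelGrid,
) -> np.ndarray:
    """Boolean cylindrical mask (axis along z) of voxels whose centres
    fall inside the cylinder.  The mask's volume is the voxel count
    times the voxel volume."""
    if diameter <= 0 or height <= 0:
        raise ValueError("VOI dimensions must be positive")
    cx, cy, cz = center
    half_extent = [
        (grid.axis_coords(a)[0] - grid.spacing[a] / 2,
         grid.axis_coords(a)[-1] + grid.spacing[a] / 2)
        for a in range(3)
    ]
    for c, r, (lo, hi) in zip(
        center, (diameter / 2, diameter / 2, height / 2), half_extent
    ):
        if c - r < lo or c + r > hi:
            raise ValueError("VOI extends beyond the grid")
    x, y, z = grid.meshgrid()
    mask = ((x - cx) ** 2 + (y - cy) ** 2 <= (diameter / 2) ** 2) & (
        np.abs(z - cz) <= height / 2
    )
    if not mask.any():
        raise ValueError("VOI mask is empty")
    return mask


def voi_volume_ml(mask: np.ndarray, grid: VoxelGrid) -> float:
    return float(mask.sum()) * grid.voxel_volume_ml


def compute_icf(
    recon: ReconVolume, voi: np.ndarray, inputs: CalibrationInputs
) -> ICFResult:
    """ICF of one reconstruction from counts in a large VOI.

    ``inputs.counts`` is ignored; the counts are taken from the volume
    (pass :class:`CalibrationInputs` with ``counts=0`` if unknown).
    """
    if voi.shape != recon.grid.shape:
        raise ValueError("VOI must live on the reconstruction grid")
    counts = float(recon.values[voi].sum())
    if counts <= 0:
        raise ValueError("no counts inside the calibration VOI")
    decayed = inputs.a_prep * decay_activity(1.0, inputs.dt, inputs.half_life)
    icf = counts / (inputs.t_acq * decayed)
    u_rel = compute_icf_uncertainty(inputs, counts)
    return ICFResult(
        icf=icf,
        u_icf_rel=u_rel,
        voi={"volume_ml": voi_volume_ml(voi, recon.grid), "voxels": int(voi.sum())},
        params=recon.params,
    )


def compute_icf_uncertainty(inputs: CalibrationInputs, counts: float) -> float:
    """Relative ICF uncertainty: counting term (sqrt(C)/C) plus the
    calibrator term, in quadrature."""
    if counts <= 0:
        raise ValueError("counts must be positive")
    return float(np.sqrt(1.0 / counts + inputs.u_a_rel**2))


def quantify(
    recon: ReconVolume,
    voi: np.ndarray,
    icf: ICFResult,
    truth: float,
    concentration: bool = False,
    allow_protocol_mismatch: bool = False,
) -> QuantResult:
    """SPECT-based activity (or concentration) in a VOI versus truth.

    ``truth`` must already be decayed to the acquisition start.  The ICF
    must come from the same reconstruction protocol unless explicitly
    overridden (applying a mismatched ICF silently is the classic way to
    get an inconsistent calibration chain).
    """
    if icf.params is not None and icf.params != recon.params:
        if not allow_protocol_mismatch:
            raise ValueError(
                f"ICF protocol {icf.params.label} does not match reconstruction "
                f"{recon.params.label}; pass allow_protocol_mismatch=True to override"
            )
        warnings.warn("quantifying with an ICF from a different protocol")
    counts = float(recon.values[voi].sum())
    a_meas = counts / (recon.duration * icf.icf)
    if concentration:
        a_meas /= voi_volume_ml(voi, recon.grid)
    if truth == 0:
        raise ValueError("truth must be nonzero")
    return QuantResult(
        a_meas=a_meas,
        a_truth_decayed=truth,
        error=(a_meas - truth) / truth,
        concentration=concentration,
    )
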