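"""Digital phantoms: voxelized activity and attenuation maps.

Three phantom families mirror the physical objects used to characterize
a quantitative Lu-177 SPECT system:

* a uniform calibration cylinder (Jaszczak-like body, no internal
  structures: it is used only as a uniform source seen through a large
  volume of interest),
* a NEMA IEC-style phantom with six fillable spheres (10-37 mm) on a
  57.2 mm-radius ring in a single transaxial plane,
* a patient-like torso with randomly placed ellipsoidal lesions.

Compartment boundaries are anti-aliased by 3x3x3 subsampling of the
voxels that straddle a surface, so voxelized volumes and totals track
the analytic geometry closely, and activity fills are mass-conserving:
the sum of the map times the voxel volume equals the requested activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy import ndimage

from .constants import MU_WATER_208KEV
from .grids import VoxelGrid

__all__ = [
    "ActivityMap",
    "MuMap",
    "PhantomSpec",
    "NEMA_SPHERE_DIAMETERS_MM",
    "NEMA_RING_RADIUS_MM",
    "make_cylinder_phantom",
    "make_nema_phantom",
    "make_patient_phantom",
]

#: Inner diameters of the six NEMA IEC sphere inserts [mm].
NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
#: Radius of the ring on which the sphere centres sit [mm].
NEMA_RING_RADIUS_MM = 57.2


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------
@dataclass
class ActivityMap:
    """Voxel volume of activity concentration [MBq/mL]."""

    grid: VoxelGrid
    values: np.ndarray
    ref_time: float = 0.0  # timeline reference [s] (time of preparation)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if np.any(self.values < 0):
            raise ValueError("activity concentrations must be nonnegative")

    @property
    def total_activity_mbq(self) -> float:
        return float(self.values.sum()) * self.grid.voxel_volume_ml


@dataclass
class MuMap:
    """Voxel volume of linear attenuation at 208 keV [1/mm]."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if np.any(self.values < 0):
            raise ValueError("attenuation must be nonnegative")


@dataclass
class PhantomSpec:
    """Declarative phantom description (round-trips through YAML)."""

    name: str
    body: dict
    inserts: list = field(default_factory=list)
    activities: dict = field(default_factory=dict)
    prep_time: float = 0.0
    mu_water: float = MU_WATER_208KEV

    def __post_init__(self):
        for ins in self.inserts:
            if ins.get("diameter", 1.0) <= 0:
                raise ValueError("insert diameters must be positive")
        for key, a in self.activities.items():
            if a < 0:
                raise ValueError(f"activity of compartment {key!r} must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "name": self.name,
                    "body": self.body,
                    "inserts": self.inserts,
                    "activities": self.activities,
                    "prep_time": self.prep_time,
                    "mu_water": self.mu_water,
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


# ----------------------------------------------------------------------
# fractional voxelization
# ----------------------------------------------------------------------
def _fractional_mask(
    grid: VoxelGrid, indicator: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
) -> np.ndarray:
    """Fractional occupancy per voxel of the region ``indicator(x,y,z)``.

    Voxels on the region boundary (detected by a one-voxel morphological
    gradient of the centre-sample mask) are refined by 3x subsampling per
    axis; interior and exterior voxels keep 1 and 0.
    """
    x, y, z = grid.meshgrid()
    center = indicator(x, y, z)
    dilated = ndimage.binary_dilation(center)
    eroded = ndimage.binary_erosion(center)
    boundary = dilated & ~eroded
    frac = center.astype(float)
    if not boundary.any():
        return frac

    ii, jj, kk = np.nonzero(boundary)
    offsets = (np.arange(3) - 1.0) / 3.0  # subsample offsets in voxel units
    acc = np.zeros(ii.shape[0])
    cx, cy, cz = (grid.axis_coords(a) for a in range(3))
    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                px = cx[ii] + ox * grid.spacing[0]
                py = cy[jj] + oy * grid.spacing[1]
                pz = cz[kk] + oz * grid.spacing[2]
                acc += indicator(px, py, pz)
    frac[ii, jj, kk] = acc / 27.0
    return frac


def _cylinder(center, diameter, height, axis=2):
    cx, cy, cz = center
    r2 = (diameter / 2.0) ** 2

    def f(x, y, z):
        ax = {0: x - cx, 1: y - cy, 2: z - cz}[axis]
        trans = [x - cx, y - cy, z - cz]
        trans.pop(axis)
        return (trans[0] ** 2 + trans[1] ** 2 <= r2) & (np.abs(ax) <= height / 2.0)

    return f


def _elliptic_cylinder(center, semiaxes_xy, height):
    cx, cy, cz = center
    ax, ay = semiaxes_xy

    def f(x, y, z):
        return (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0) & (
            np.abs(z - cz) <= height / 2.0
        )

    return f


def _sphere(center, diameter):
    cx, cy, cz = center
    r2 = (diameter / 2.0) ** 2

    def f(x, y, z):
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r2

    return f


def _ellipsoid(center, semiaxes):
    cx, cy, cz = center
    ax, ay, az = semiaxes

    def f(x, y, z):
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    return f


def _check_fits(grid: VoxelGrid, half_extents: Sequence[float], what: str) -> None:
    for axis, h in enumerate(half_extents):
        lo = grid.axis_coords(axis)[0] - grid.spacing[axis] / 2.0
        hi = grid.axis_coords(axis)[-1] + grid.spacing[axis] / 2.0
        if -h < lo or h > hi:
            raise ValueError(
                f"{what} (half-extent {h:.1f} mm on axis {axis}) exceeds grid extent "
                f"[{lo:.1f}, {hi:.1f}] mm"
            )


# ----------------------------------------------------------------------
# phantom builders
# ----------------------------------------------------------------------
def make_cylinder_phantom(
    diameter: float,
    height: float,
    activity: float,
    grid: VoxelGrid,
    mu_water: float = MU_WATER_208KEV,
) -> tuple[ActivityMap, MuMap]:
    """Uniform water cylinder holding ``activity`` MBq, axis along z.

    The fill is mass conserving: the concentration is ``activity``
    divided by the *voxelized* volume, so the map totals the requested
    activity irrespective of voxelization error.
    """
    if diameter <= 0 or height <= 0:
        raise ValueError("cylinder dimensions must be positive")
    if activity < 0:
        raise ValueError("activity must be nonnegative")
    _check_fits(grid, (diameter / 2, diameter / 2, height / 2), "cylinder")

    frac = _fractional_mask(grid, _cylinder((0.0, 0.0, 0.0), diameter, height))
    vox_volume_ml = frac.sum() * grid.voxel_volume_ml
    conc = 0.0 if activity == 0 else activity / vox_volume_ml
    act = ActivityMap(grid, conc * frac)
    mu = MuMap(grid, mu_water * frac)
    return act, mu


def make_nema_phantom(
    sphere_conc: float,
    background_conc: float,
    grid: VoxelGrid,
    body_semiaxes: tuple[float, float] = (150.0, 115.0),
    body_height: float = 180.0,
    mu_water: float = MU_WATER_208KEV,
) -> tuple[ActivityMap, MuMap, dict[float, tuple[float, float, float]]]:
    """NEMA IEC-style phantom: six spheres on a ring in one plane.

    Returns the activity map (sphere compartments at ``sphere_conc``
    MBq/mL over a body at ``background_conc``), the attenuation map of
    the water-filled body, and a dict mapping sphere diameter [mm] to
    its centre [mm].  ``background_conc = 0`` is the cold-background
    configuration.
    """
    if sphere_conc < 0 or background_conc < 0:
        raise ValueError("concentrations must be nonnegative")
    _check_fits(
        grid, (body_semiaxes[0], body_semiaxes[1], body_height / 2), "NEMA body"
    )

    centers: dict[float, tuple[float, float, float]] = {}
    angles = np.deg2rad(np.arange(6) * 60.0)
    for d, a in zip(NEMA_SPHERE_DIAMETERS_MM, angles):
        centers[d] = (
            NEMA_RING_RADIUS_MM * float(np.cos(a)),
            NEMA_RING_RADIUS_MM * float(np.sin(a)),
            0.0,
        )
    # geometric sanity: sphere separation and containment
    diams = list(centers)
    for i, di in enumerate(diams):
        ci = np.array(centers[di])
        if np.hypot(ci[0], ci[1]) + di / 2 > min(body_semiaxes):
            raise ValueError(f"{di} mm sphere does not fit inside the body")
        for dj in diams[i + 1 :]:
            cj = np.array(centers[dj])
            if np.linalg.norm(ci - cj) < (di + dj) / 2:
                raise ValueError(f"spheres {di} and {dj} mm overlap")

    body_frac = _fractional_mask(
        grid, _elliptic_cylinder((0, 0, 0), body_semiaxes, body_height)
    )
    sphere_frac = np.zeros(grid.shape)
    for d, c in centers.items():
        sphere_frac += _fractional_mask(grid, _sphere(c, d))
    sphere_frac = np.clip(sphere_frac, 0.0, 1.0)
    bg_frac = np.clip(body_frac - sphere_frac, 0.0, 1.0)

    act = ActivityMap(grid, sphere_conc * sphere_frac + background_conc * bg_frac)
    mu = MuMap(grid, mu_water * body_frac)
    return act, mu, centers


def make_patient_phantom(
    n_lesions: int,
    grid: VoxelGrid,
    lesion_volume_range_ml: tuple[float, float] = (5.3, 29.5),
    lesion_conc_range_kbq_ml: tuple[float, float] = (204.0, 5648.0),
    seed: int | None = None,
    background_kbq_ml: float = 50.0,
    torso_semiaxes: tuple[float, float, float] = (150.0, 100.0, 200.0),
    mu_water: float = MU_WATER_208KEV,
    max_tries: int = 500,
) -> tuple[ActivityMap, MuMap, list[dict]]:
    """Patient-like torso with randomly placed ellipsoidal lesions.

    Lesion volumes are drawn uniformly in ``lesion_volume_range_ml`` and
    concentrations log-uniformly in ``lesion_conc_range_kbq_ml`` (the
    clinical concentrations span more than an order of magnitude, so a
    log draw keeps both decades represented).  Lesions are placed without
    overlap inside the torso; placement is reproducible under ``seed``.

    Returns the activity map [MBq/mL], the attenuation map and one
    record per lesion: ``{"mask", "center", "volume_ml",
    "conc_kbq_ml"}`` where ``mask`` is the boolean truth mask.
    """
    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    if min(lesion_volume_range_ml) <= 0 or min(lesion_conc_range_kbq_ml) <= 0:
        raise ValueError("lesion ranges must be positive")
    rng = np.random.default_rng(seed)
    _check_fits(grid, torso_semiaxes, "torso")

    body_frac = _fractional_mask(grid, _ellipsoid((0, 0, 0), torso_semiaxes))
    act = background_kbq_ml / 1000.0 * body_frac.copy()

    placed: list[dict] = []
    tor = np.array(torso_semiaxes)
    for _ in range(n_lesions):
        ok = False
        for _try in range(max_tries):
            vol_ml = rng.uniform(*lesion_volume_range_ml)
            # random axis ratios around a sphere of equal volume
            ratios = rng.uniform(0.75, 1.3, size=3)
            ratios /= np.prod(ratios) ** (1.0 / 3.0)
            r_eq = (3.0 * vol_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
            semi = r_eq * ratios
            rmax = semi.max()
            # keep the lesion's bounding sphere inside the torso
            center = rng.uniform(-1, 1, size=3) * (tor - rmax - grid.spacing[0])
            if np.sum((np.abs(center) + rmax) ** 2 / tor**2) >= 1.0:
                continue
            if any(
                np.linalg.norm(center - p["center"]) < rmax + p["rmax"] + 2.0
                for p in placed
            ):
                continue
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place lesion {len(placed) + 1} without overlap "
                f"after {max_tries} tries"
            )
        conc = np.exp(rng.uniform(*np.log(lesion_conc_range_kbq_ml))) / 1000.0
        frac = _fractional_mask(grid, _ellipsoid(center, semi))
        act = np.where(frac > 0, 0.0, act) + conc * frac
        placed.append(
            {
                "mask": frac >= 0.5,
                "frac": frac,
                "center": center,
                "rmax": rmax,
                "volume_ml": frac.sum() * grid.voxel_volume_ml,
                "conc_kbq_ml": conc * 1000.0,
            }
        )

    mu = MuMap(grid, mu_water * body_frac)
    return ActivityMap(grid, act), mu, placed
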