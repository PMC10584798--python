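"""Shared fixtures.

The heavy session fixtures run the characterization workflow once at a
compact scale (40^3 or 48^3 voxels over the same 315 mm field of view
as the desk profile, 30 views) and are shared by the trend and
acceptance tests; everything else uses tiny toy problems.
"""

import numpy as np
import pytest
from hypothesis import settings

from luquant.grids import VoxelGrid
from luquant.phantoms import make_cylinder_phantom
from luquant.recon import ReconParams
from luquant.simulate import (
    AcquisitionGeometry,
    DetectorModel,
    add_poisson_noise,
    forward_project,
)
from luquant.workflow import RunConfig, run_characterization, standard_protocols

settings.register_profile("repro", derandomize=True, max_examples=25)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def cyl_study():
    """Calibration + cylinder stages across the full update grid
    (OSEM and BSREM-RDP x {12,48,96,192,576} updates, 1 subset, plus
    the factory protocol) at compact scale."""
    cfg = RunConfig(
        grid_n=40, spacing_mm=7.875, n_views=30, seed=1,
        protocols=standard_protocols(),
        stages=("calibration", "cylinder"),
        keep_volumes=True,
    )
    return run_characterization(cfg)


@pytest.fixture(scope="session")
def nema_study():
    """Calibration + NEMA (cold and hot background) at 12 and 96
    updates plus the factory protocol."""
    cfg = RunConfig(
        grid_n=48, spacing_mm=6.5625, n_views=30, seed=1,
        protocols=standard_protocols(iterations=(12, 96)),
        stages=("calibration", "nema"),
        nema_hot=True,
        keep_volumes=True,
    )
    return run_characterization(cfg)


@pytest.fixture(scope="session")
def penoff_study():
    """Calibration + cylinder with septal penetration disabled."""
    cfg = RunConfig(
        grid_n=40, spacing_mm=7.875, n_views=30, seed=1,
        detector=DetectorModel(pen_fraction=0.0),
        protocols=[ReconParams("OSEM", 96, 1, psf_mode="mismatched")],
        stages=("calibration", "cylinder"),
    )
    return run_characterization(cfg)


@pytest.fixture(scope="session")
def toy_projection():
    """Noisy 16^3 acquisition of a small off-centre cylinder: the
    standard toy for reconstruction-algorithm oracles."""
    grid = VoxelGrid.isotropic(16, 8.0)
    act, mu = make_cylinder_phantom(60.0, 60.0, 50.0, grid)
    geom = AcquisitionGeometry(n_views=8, angular_step=45.0, duration=600.0)
    det = DetectorModel(pen_fraction=0.0, scatter_alpha=0.0)
    proj = forward_project(act, mu, geom, det)
    return add_poisson_noise(proj, seed=42), mu, det
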