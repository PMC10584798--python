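"""Forward-projection physics: conservation, attenuation, penetration,
scatter window, Poisson noise and decay."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from luquant import constants as C
from luquant._projector import Projector
from luquant.grids import VoxelGrid
from luquant.phantoms import ActivityMap, MuMap, make_cylinder_phantom
from luquant.simulate import (
    AcquisitionGeometry,
    DetectorModel,
    EnergyWindows,
    add_poisson_noise,
    decay_activity,
    forward_project,
)

GEOM = AcquisitionGeometry(n_views=12, angular_step=30.0, duration=600.0)


def _point_source(n=48, spacing=8.0, a_mbq=5.0):
    # FOV wide enough that the broad penetration/scatter tails stay on
    # the detector; conservation only holds without truncation
    grid = VoxelGrid.isotropic(n, spacing)
    vals = np.zeros(grid.shape)
    c = n // 2
    vals[c, c, c] = a_mbq / grid.voxel_volume_ml
    return ActivityMap(grid, vals), MuMap(grid, np.zeros(grid.shape))


def test_point_source_count_conservation_in_air():
    """Total expected photopeak counts equal sensitivity x A x T_acq."""
    act, mu = _point_source()
    det = DetectorModel()
    proj = forward_project(act, mu, GEOM, det)
    expected = det.sensitivity * 5.0 * GEOM.duration
    assert proj.total_photopeak == pytest.approx(expected, rel=0.01)


def test_per_view_totals_equal_without_attenuation():
    act, mu = _point_source()
    det = DetectorModel(pen_fraction=0.0)
    proj = forward_project(act, mu, GEOM, det)
    per_view = proj.photopeak_counts.sum(axis=(1, 2))
    assert np.allclose(per_view, per_view[0], rtol=1e-3)


def test_attenuation_monotonicity():
    """Uniformly increasing mu never increases any bin's mean."""
    grid = VoxelGrid.isotropic(24, 8.0)
    act, mu = make_cylinder_phantom(120.0, 120.0, 10.0, grid)
    det = DetectorModel()
    p1 = forward_project(act, mu, GEOM, det)
    p2 = forward_project(act, MuMap(grid, 1.5 * mu.values), GEOM, det)
    assert np.all(p2.photopeak_counts <= p1.photopeak_counts + 1e-9)
    assert p2.total_photopeak < p1.total_photopeak


def test_penetration_spills_counts_outside_body_shadow():
    grid = VoxelGrid.isotropic(32, 8.0)
    act, mu = make_cylinder_phantom(100.0, 100.0, 10.0, grid)
    no_pen = forward_project(act, mu, GEOM, DetectorModel(pen_fraction=0.0))
    pen = forward_project(act, mu, GEOM, DetectorModel(pen_fraction=0.08))
    proj = Projector(grid, GEOM.angles_deg, GEOM.detector_radius)
    shadow = proj.forward(act.values, blur=False) > 1e-12

    def outside_fraction(p):
        return p.photopeak_counts[~shadow].sum() / p.photopeak_counts.sum()

    assert outside_fraction(pen) > outside_fraction(no_pen)


def test_scatter_window_is_fixed_multiple_of_geometric_totals():
    act, mu = _point_source()
    det = DetectorModel()
    proj = forward_project(act, mu, GEOM, det)
    geometric = det.sensitivity * GEOM.duration * 5.0  # all counts, in air
    assert proj.scatter_counts.sum() == pytest.approx(
        det.scatter_alpha * geometric, rel=0.01
    )


def test_energy_windows_printed_bounds():
    w = EnergyWindows()
    assert w.photopeak_bounds == pytest.approx((195.52, 220.48))
    assert w.scatter_bounds == pytest.approx((175.75, 194.25))
    assert w.width_ratio == pytest.approx(24.96 / 18.5, rel=1e-6)
    with pytest.raises(ValueError):
        EnergyWindows(scatter_center=200.0)


def test_grid_mismatch_rejected():
    act, _ = _point_source()
    other = MuMap(VoxelGrid.isotropic(16, 6.0), np.zeros((16, 16, 16)))
    with pytest.raises(ValueError):
        forward_project(act, other, GEOM, DetectorModel())


def test_empty_activity_gives_zero_projections():
    grid = VoxelGrid.isotropic(16, 8.0)
    act = ActivityMap(grid, np.zeros(grid.shape))
    mu = MuMap(grid, np.zeros(grid.shape))
    proj = forward_project(act, mu, GEOM, DetectorModel())
    assert not proj.photopeak_counts.any()


# ---------------------------------------------------------------- noise
def test_poisson_noise_law_and_determinism():
    grid = VoxelGrid.isotropic(4, 8.0)
    geom = AcquisitionGeometry(n_views=1, angular_step=360.0, duration=1.0)
    mean = np.zeros((1, 4, 4))
    mean[0, 1, 1] = 1e4
    from luquant.simulate import ProjectionSet

    proj = ProjectionSet(mean, np.zeros_like(mean), geom, EnergyWindows(), grid,
                         noiseless_mean=mean.copy(), scatter_mean=np.zeros_like(mean))
    draws = np.array(
        [add_poisson_noise(proj, seed=s).photopeak_counts[0, 1, 1]
         for s in range(1000)]
    )
    assert draws.mean() == pytest.approx(1e4, rel=0.1)
    assert draws.var() == pytest.approx(1e4, rel=0.1)
    # zero-mean bins never fire; same seed reproduces exactly
    assert add_poisson_noise(proj, seed=3).photopeak_counts[0, 0, 0] == 0
    a = add_poisson_noise(proj, seed=11).photopeak_counts
    b = add_poisson_noise(proj, seed=11).photopeak_counts
    assert np.array_equal(a, b)


# ---------------------------------------------------------------- decay
def test_decay_closed_form():
    assert decay_activity(10.0, C.HALF_LIFE_LU177_S, C.HALF_LIFE_LU177_S) == (
        pytest.approx(5.0)
    )
    assert decay_activity(10.0, 0.0, C.HALF_LIFE_LU177_S) == 10.0
    # one half-life of Lu-177 (6.6475 d): 541 -> 270.5 MBq
    assert decay_activity(541.0, 6.6475 * 86400, C.HALF_LIFE_LU177_S) == (
        pytest.approx(270.5, abs=0.01)
    )
    with pytest.raises(ValueError):
        decay_activity(1.0, 1.0, 0.0)


@given(st.floats(0.1, 1e4), st.floats(-5e5, 5e5), st.floats(-5e5, 5e5))
def test_decay_is_multiplicative_in_time(a, dt1, dt2):
    one = decay_activity(a, dt1 + dt2, C.HALF_LIFE_LU177_S)
    two = decay_activity(decay_activity(a, dt1, C.HALF_LIFE_LU177_S), dt2,
                         C.HALF_LIFE_LU177_S)
    assert one == pytest.approx(two, rel=1e-9)
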