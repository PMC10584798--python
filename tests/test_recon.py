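"""Reconstruction algorithm oracles: EM count conservation, BSREM/OSEM
equivalence, RDP formula, DEW correction, bySens weighting."""

import numpy as np
import pytest

from luquant.grids import VoxelGrid
from luquant.phantoms import ActivityMap, MuMap, make_cylinder_phantom
from luquant.recon import (
    ReconParams,
    bsrem_reconstruct,
    dew_scatter_estimate,
    osem_reconstruct,
    poisson_loglik,
    rdp_penalty,
    sensitivity_weight_beta,
)
from luquant.simulate import (
    AcquisitionGeometry,
    DetectorModel,
    add_poisson_noise,
    forward_project,
)


def test_recon_params_validation():
    with pytest.raises(ValueError):
        ReconParams(algorithm="FBP")
    with pytest.raises(ValueError):
        ReconParams(iterations=0)
    with pytest.raises(ValueError):
        ReconParams(beta=-1.0)
    with pytest.raises(ValueError):
        ReconParams(psf_mode="exotic")
    assert ReconParams(iterations=12, subsets=16).updates == 192


def test_subsets_must_divide_views(toy_projection):
    proj, mu, det = toy_projection
    with pytest.raises(ValueError):
        osem_reconstruct(proj, mu, ReconParams("OSEM", 4, 5), det)


def test_mlem_conserves_counts_without_attenuation():
    """Converged MLEM total equals total projected counts (no
    attenuation, matched PSF, no scatter): the EM fixpoint oracle."""
    grid = VoxelGrid.isotropic(32, 6.0)
    vals = np.zeros(grid.shape)
    vals[16, 16, 16] = 2.0 / grid.voxel_volume_ml
    act = ActivityMap(grid, vals)
    mu = MuMap(grid, np.zeros(grid.shape))
    geom = AcquisitionGeometry(n_views=12, angular_step=30.0, duration=600.0)
    det = DetectorModel(pen_fraction=0.0, scatter_alpha=0.0)
    proj = forward_project(act, mu, geom, det)  # noiseless
    rec = osem_reconstruct(
        proj, mu, ReconParams("OSEM", 200, 1, psf_mode="matched"), det,
        scatter_correction=False,
    )
    assert rec.total_counts == pytest.approx(proj.total_photopeak, rel=0.005)


def test_bsrem_beta_zero_matches_osem(toy_projection):
    """BSREM with beta=0, alpha0=1, eta=0 is algebraically the OSEM
    update; the iterates must agree voxelwise to 1e-6 relative."""
    proj, mu, det = toy_projection
    o = osem_reconstruct(proj, mu, ReconParams("OSEM", 8, 2), det)
    b = bsrem_reconstruct(
        proj, mu,
        ReconParams("BSREM", 8, 2, beta=0.0, relaxation=(1.0, 0.0)),
        det,
    )
    scale = o.values.max()
    assert np.max(np.abs(o.values - b.values)) <= 1e-6 * scale


def test_mlem_loglikelihood_monotone(toy_projection):
    proj, mu, det = toy_projection
    snaps = osem_reconstruct(
        proj, mu, ReconParams("OSEM", 10, 1), det,
        snapshot_updates=list(range(1, 11)),
    )
    lls = [
        poisson_loglik(proj, snaps[u].values, mu, det)
        for u in sorted(snaps)
    ]
    diffs = np.diff(lls)
    assert np.all(diffs >= -1e-6 * np.abs(lls[0]))


def test_bsrem_penalized_objective_monotone(toy_projection):
    proj, mu, det = toy_projection
    beta, gamma = 0.05, 1.0
    params = ReconParams("BSREM", 16, 2, beta=beta, gamma=gamma)
    snaps = bsrem_reconstruct(
        proj, mu, params, det, snapshot_updates=[2 * i for i in range(1, 17)]
    )
    n = proj.geometry.n_views

    def objective(x):
        u, _ = rdp_penalty(x, gamma, spacing=proj.grid.spacing)
        return poisson_loglik(proj, x, mu, det) - beta / n * u

    objs = [objective(snaps[u].values) for u in sorted(snaps)]
    diffs = np.diff(objs)
    assert np.all(diffs >= -1e-5 * abs(objs[0]))


def test_updates_preserve_nonnegativity(toy_projection):
    proj, mu, det = toy_projection
    for rec in (
        osem_reconstruct(proj, mu, ReconParams("OSEM", 6, 2), det),
        bsrem_reconstruct(proj, mu, ReconParams("BSREM", 6, 2, beta=0.05), det),
    ):
        assert rec.values.min() >= 0.0


def test_osem_subset_invariance_on_noise_and_errors():
    """At fixed updates, OSEM metrics barely depend on the subset
    partitioning (192i1s vs 12i16s within 5 % relative)."""
    grid = VoxelGrid.isotropic(40, 7.875)
    act, mu = make_cylinder_phantom(200.0, 180.0, 700.0, grid)
    geom = AcquisitionGeometry(n_views=32, angular_step=11.25, duration=900.0)
    det = DetectorModel()
    proj = add_poisson_noise(forward_project(act, mu, geom, det), seed=5)
    r1 = osem_reconstruct(proj, mu, ReconParams("OSEM", 192, 1), det,
                          dtype=np.float32)
    r2 = osem_reconstruct(proj, mu, ReconParams("OSEM", 12, 16), det,
                          dtype=np.float32)
    from luquant.calibrate import make_cylindrical_voi
    from luquant.quality import compute_cv

    voi = make_cylindrical_voi((0, 0, 0), 140.0, 126.0, grid)
    cv1 = compute_cv(r1, voi).cv
    cv2 = compute_cv(r2, voi).cv
    assert cv2 == pytest.approx(cv1, rel=0.05)
    assert r2.values[voi].sum() == pytest.approx(r1.values[voi].sum(), rel=0.01)


def test_zero_iterations_rejected(toy_projection):
    proj, mu, det = toy_projection
    with pytest.raises(ValueError):
        osem_reconstruct(proj, mu, ReconParams("OSEM", 0, 1), det)


def test_all_zero_projections_warn_and_return_zero(toy_projection):
    proj, mu, det = toy_projection
    import dataclasses

    silent = dataclasses.replace(
        proj,
        photopeak_counts=np.zeros_like(proj.photopeak_counts),
        scatter_counts=np.zeros_like(proj.scatter_counts),
        noiseless_mean=None,
        scatter_mean=None,
    )
    with pytest.warns(UserWarning):
        rec = osem_reconstruct(silent, mu, ReconParams("OSEM", 2, 1), det)
    assert rec.total_counts == 0.0


# ------------------------------------------------------------------ RDP
def test_rdp_constant_volume_is_flat():
    x = np.full((6, 6, 6), 3.7)
    val, grad = rdp_penalty(x, gamma=1.0)
    assert val == 0.0
    assert np.allclose(grad, 0.0)


def test_rdp_two_voxel_hand_value():
    """(2-0)^2/(2+0) = 2 for a single neighbour pair, gamma=0, w=1."""
    x = np.array([[[2.0]], [[0.0]]])  # two voxels along one axis
    val, grad = rdp_penalty(x, gamma=0.0, eps=0.0)
    assert val == pytest.approx(2.0)
    # hand-derived gradient of d^2/s: (1, -3)
    assert grad.ravel() == pytest.approx([1.0, -3.0])


def test_rdp_large_gamma_limit():
    rng = np.random.default_rng(0)
    x = rng.random((5, 5, 5)) * 10
    val9, _ = rdp_penalty(x, gamma=1e9)
    val6, _ = rdp_penalty(x, gamma=1e6)
    val0, _ = rdp_penalty(x, gamma=0.0)
    assert val9 < val6 < val0  # penalty vanishes as gamma grows
    assert val9 == pytest.approx(0.0, abs=1e-5)


def test_rdp_gradient_matches_finite_differences():
    rng = np.random.default_rng(1)
    x = rng.random((4, 4, 4)) + 0.5
    gamma = 1.3
    val, grad = rdp_penalty(x, gamma, eps=1e-9)
    h = 1e-6
    for idx in [(0, 0, 0), (2, 1, 3), (1, 2, 2)]:
        xp = x.copy()
        xp[idx] += h
        vp, _ = rdp_penalty(xp, gamma, eps=1e-9)
        assert grad[idx] == pytest.approx((vp - val) / h, rel=1e-3, abs=1e-6)


# ------------------------------------------------------------------ DEW
def test_dew_zero_scatter_gives_zero(toy_projection):
    proj, mu, det = toy_projection
    assert not dew_scatter_estimate(proj).any()  # scatter_alpha was 0


def test_dew_off_changes_nothing_without_scatter(toy_projection):
    proj, mu, det = toy_projection
    p = ReconParams("OSEM", 8, 1)
    r_on = osem_reconstruct(proj, mu, p, det, scatter_correction=True)
    r_off = osem_reconstruct(proj, mu, p, det, scatter_correction=False)
    assert r_off.total_counts == pytest.approx(r_on.total_counts, rel=1e-3)


def test_dew_width_ratio_scaling():
    from luquant.simulate import EnergyWindows

    w = EnergyWindows()
    assert w.width_ratio == pytest.approx(1.349, abs=0.001)


# --------------------------------------------------------------- bySens
def test_by_sens_uniform_without_attenuation():
    grid = VoxelGrid.isotropic(24, 8.0)
    mu = MuMap(grid, np.zeros(grid.shape))
    geom = AcquisitionGeometry(n_views=12, angular_step=30.0, duration=600.0)
    bmap = sensitivity_weight_beta(mu, 0.01, geom)
    core = bmap[8:16, 8:16, 8:16]
    assert core.std() / core.mean() < 0.02


def test_by_sens_lower_beta_at_attenuated_centre():
    grid = VoxelGrid.isotropic(24, 8.0)
    _, mu = make_cylinder_phantom(160.0, 160.0, 1.0, grid)
    geom = AcquisitionGeometry(n_views=12, angular_step=30.0, duration=600.0)
    bmap = sensitivity_weight_beta(mu, 0.01, geom)
    centre = bmap[12, 12, 12]
    edge = bmap[12, 3, 12]  # near-periphery, less material in the way
    assert centre < edge
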