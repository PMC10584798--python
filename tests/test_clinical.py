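"""Noise matching, lesion segmentation/quantification and statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from luquant.calibrate import ICFResult
from luquant.clinical import (
    PEAK_SPHERE_RADIUS_MM,
    isocontour_segment,
    lesion_concentration,
    match_noise,
    peak_1ml_mean,
    summary_stats,
    wilcoxon_signed_rank,
)
from luquant.grids import VoxelGrid
from luquant.recon import ReconParams, ReconVolume


# ------------------------------------------------------------ match_noise
def _cand(it, sub, cv):
    return (ReconParams("OSEM", it, sub), cv)


def test_match_noise_selection():
    cands = [_cand(48, 1, 0.12), _cand(72, 1, 0.149), _cand(96, 1, 0.19)]
    best = match_noise(cands, target_cv=0.15)
    assert best.params.iterations == 72
    assert best.delta_cv == pytest.approx(0.001)


def test_match_noise_tie_prefers_fewer_updates():
    cands = [_cand(96, 1, 0.16), _cand(48, 1, 0.14)]
    assert match_noise(cands, 0.15).params.iterations == 48


def test_match_noise_single_candidate_warns_and_permutation_invariance():
    with pytest.warns(UserWarning):
        res = match_noise([_cand(12, 1, 0.9)], 0.15)
    assert res.params.iterations == 12
    cands = [_cand(48, 1, 0.12), _cand(72, 1, 0.149), _cand(96, 1, 0.19),
             _cand(12, 16, 0.151)]
    picks = {
        match_noise(list(perm), 0.15).params
        for perm in itertools.permutations(cands)
    }
    assert len(picks) == 1
    with pytest.raises(ValueError):
        match_noise([], 0.15)


# ------------------------------------------------------- peak / isocontour
def test_peak_sphere_radius_closed_form():
    assert PEAK_SPHERE_RADIUS_MM == pytest.approx(6.20, abs=0.01)


def _lesion_volume(grid, center, diameter, contrast=20.0, background=1.0):
    x, y, z = grid.meshgrid()
    vals = np.full(grid.shape, background)
    inside = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 \
        <= (diameter / 2) ** 2
    vals[inside] = contrast
    return ReconVolume(grid, vals, ReconParams(), 900.0), inside


def test_peak_1ml_uniform_volume():
    grid = VoxelGrid.isotropic(24, 3.0)
    vol = ReconVolume(grid, np.full(grid.shape, 4.2), ReconParams(), 900.0)
    mask = np.zeros(grid.shape, bool)
    mask[8:16, 8:16, 8:16] = True
    _, peak = peak_1ml_mean(vol, mask)
    assert peak == pytest.approx(4.2, rel=1e-3)
    with pytest.raises(ValueError):
        peak_1ml_mean(vol, np.zeros(grid.shape, bool))


def test_peak_1ml_finds_lesion_centroid():
    grid = VoxelGrid.isotropic(32, 3.0)
    vol, inside = _lesion_volume(grid, (6.0, -9.0, 3.0), 24.0)
    center, peak = peak_1ml_mean(vol, np.ones(grid.shape, bool))
    world = grid.index_to_world(np.array(center, float))
    assert np.linalg.norm(world - np.array([6.0, -9.0, 3.0])) <= 3.0 * np.sqrt(3)
    assert peak == pytest.approx(20.0, rel=0.01)


def test_isocontour_matches_threshold_geometry():
    """30 % isocontour of a high-contrast blurred sphere matches the
    threshold-geometry oracle: the volume enclosed by the radius at
    which the radially averaged profile crosses 0.3 x peak mean."""
    from scipy import ndimage

    grid = VoxelGrid.isotropic(48, 2.46)
    vol, inside = _lesion_volume(grid, (0.0, 0.0, 0.0), 30.0, background=0.1)
    blurred = ndimage.gaussian_filter(vol.values, 3.0 / 2.46)
    bvol = ReconVolume(grid, blurred, ReconParams(), 900.0)
    center, peak = peak_1ml_mean(bvol, inside)
    mask = isocontour_segment(bvol, center, peak, fraction=0.30)
    # oracle: radial crossing of the threshold
    x, y, z = grid.meshgrid()
    r = np.sqrt(x**2 + y**2 + z**2).ravel()
    order = np.argsort(r)
    prof = blurred.ravel()[order]
    r_sorted = r[order]
    thr = 0.3 * peak
    r30 = r_sorted[np.nonzero(prof >= thr)[0].max()]
    oracle_ml = 4.0 / 3.0 * np.pi * r30**3 / 1000.0
    got_ml = mask.sum() * grid.voxel_volume_ml
    assert got_ml == pytest.approx(oracle_ml, rel=0.10)
    assert mask[inside].mean() > 0.99  # segment covers the true sphere


def test_isocontour_connectivity_and_errors():
    grid = VoxelGrid.isotropic(32, 3.0)
    vol, _ = _lesion_volume(grid, (-20.0, 0.0, 0.0), 15.0)
    vals = vol.values.copy()
    x, y, z = grid.meshgrid()
    second = (x - 25.0) ** 2 + y**2 + z**2 <= 7.5**2
    vals[second] = 20.0
    two = ReconVolume(grid, vals, ReconParams(), 900.0)
    seed = tuple(grid.world_to_index(np.array([-20.0, 0, 0])).round().astype(int))
    mask = isocontour_segment(two, seed, peak_mean=20.0, fraction=0.3)
    assert mask[seed]
    assert not mask[second].any()  # only the seeded component
    with pytest.raises(ValueError):
        isocontour_segment(two, seed, peak_mean=0.0)
    bg_seed = (0, 0, 0)
    with pytest.raises(ValueError):
        isocontour_segment(two, bg_seed, peak_mean=20.0, fraction=0.3)


# ------------------------------------------------------- concentrations
def test_lesion_concentration_closure_and_scaling():
    grid = VoxelGrid.isotropic(24, 3.0)
    # uniform lesion of known concentration, self-calibrated chain:
    # counts/voxel = conc * voxvol * sens * T
    sens, t_acq, conc = 100.0, 900.0, 0.5  # MBq/mL
    mask = np.zeros(grid.shape, bool)
    mask[8:16, 8:16, 8:16] = True
    counts = np.where(mask, conc * grid.voxel_volume_ml * sens * t_acq, 0.0)
    vol = ReconVolume(grid, counts, ReconParams(), t_acq)
    icf = ICFResult(icf=sens, u_icf_rel=0.02, params=None)
    got = lesion_concentration(vol, mask, icf)
    assert got == pytest.approx(conc * 1000.0, rel=1e-6)
    half = lesion_concentration(vol, mask, ICFResult(2 * sens, 0.02, params=None))
    assert half == pytest.approx(got / 2)
    with pytest.raises(ValueError):
        lesion_concentration(vol, np.zeros(grid.shape, bool), icf)


# ------------------------------------------------------------- Wilcoxon
def _brute_force_p(diffs):
    """Independent oracle: enumerate all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = [
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product((-1, 1), repeat=n)
    ]
    ws = np.asarray(ws, float)
    lo = (ws <= w_obs + 1e-9).mean()
    hi = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(lo, hi))


def test_wilcoxon_all_positive_n5():
    pairs = [(i + 1.0, 0.0) for i in range(5)]
    w, p = wilcoxon_signed_rank(pairs)
    assert p == pytest.approx(2 / 32)
    assert w == 0.0


def test_wilcoxon_matches_enumeration_small_n():
    rng = np.random.default_rng(3)
    for n in range(2, 13):
        d = rng.normal(0.3, 1.0, n)
        d[d == 0] = 0.1
        pairs = [(x, 0.0) for x in d]
        _, p = wilcoxon_signed_rank(pairs)
        assert p == pytest.approx(_brute_force_p(d), abs=1e-12)


def test_wilcoxon_matches_scipy_exact():
    rng = np.random.default_rng(4)
    d = np.round(rng.normal(0.5, 1.0, 10), 3)  # distinct -> no ties
    assert len(set(np.abs(d))) == 10
    _, p = wilcoxon_signed_rank([(x, 0.0) for x in d])
    ref = stats.wilcoxon(d, mode="exact").pvalue
    assert p == pytest.approx(ref, abs=1e-12)


@given(st.lists(st.floats(-10, 10).filter(lambda v: abs(v) > 1e-3),
                min_size=3, max_size=15))
def test_wilcoxon_symmetric_under_swap(diffs):
    pairs = [(d, 0.0) for d in diffs]
    swapped = [(0.0, d) for d in diffs]
    try:
        _, p1 = wilcoxon_signed_rank(pairs)
    except ValueError:
        return
    _, p2 = wilcoxon_signed_rank(swapped)
    assert p1 == pytest.approx(p2)


def test_wilcoxon_type_i_error_rate():
    """Under the null (zero median shift), n=27 pairs, the exact test
    rejects at 5 % about 5 % of the time."""
    rng = np.random.default_rng(12)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        a = rng.normal(0.0, 1.0, 27)
        _, p = wilcoxon_signed_rank([(x, 0.0) for x in a])
        rejections += p < 0.05
    assert 0.03 <= rejections / reps <= 0.07


def test_wilcoxon_degenerate_inputs():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([(1.0, 0.0)])


# ------------------------------------------------------------- summaries
def test_summary_stats_hand_values():
    assert summary_stats([-19, -5, -2, 1, 3])[2] == -2.0
    assert summary_stats([4.2] * 7) == (4.2,) * 5
    with pytest.raises(ValueError):
        summary_stats([])


def test_summary_stats_sampling():
    rng = np.random.default_rng(5)
    v = rng.uniform(-10, 10, 10_000)
    mn, q1, med, q3, mx = summary_stats(v)
    assert med == pytest.approx(0.0, abs=0.5)
    assert q1 == pytest.approx(-5.0, abs=0.5)
    assert q3 == pytest.approx(5.0, abs=0.5)


@given(st.lists(st.floats(-100, 100), min_size=1, max_size=40))
def test_summary_stats_matches_numpy_percentiles(values):
    got = summary_stats(values)
    ref = np.percentile(values, [0, 25, 50, 75, 100])
    assert np.allclose(got, ref)
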