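"""Iterative reconstruction: OSEM and BSREM with relative difference prior.

Both algorithms share one attenuated, resolution-modelling system
operator and an additive dual-energy-window (DEW) scatter term, and
both output volumes in counts per voxel (the convention of the vendor
console they emulate): at convergence of an unregularized fit the sum
of the volume approaches the total recorded photopeak counts.

OSEM is the classic multiplicative ordered-subsets EM update.  BSREM
performs relaxed block-sequential ascent on the penalized Poisson
log-likelihood with the preconditioner
``x / s_subset`` and relaxation ``alpha_n = alpha0 / (1 + eta * n)``
(``n`` counts full passes).  With ``beta = 0``, ``alpha0 = 1`` and
``eta = 0`` the BSREM update reduces algebraically to OSEM.

The relative difference prior is

``U(x) = sum_{j<k in N} w_jk (x_j - x_k)^2 / (x_j + x_k + gamma |x_j - x_k| + eps)``

over 26-neighbourhoods with inverse-distance weights; ``gamma``
controls edge preservation (large gamma forgives large differences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage

from . import constants as C
from ._projector import Projector
from .grids import VoxelGrid
from .phantoms import MuMap
from .simulate import AcquisitionGeometry, DetectorModel, ProjectionSet

__all__ = [
    "ReconParams",
    "ReconVolume",
    "osem_reconstruct",
    "bsrem_reconstruct",
    "rdp_penalty",
    "dew_scatter_estimate",
    "sensitivity_weight_beta",
    "FACTORY_PROTOCOL",
]

_FLOOR = 1e-12  # nonnegativity floor [counts/voxel]
_TINY = 1e-30
_RATIO_CLAMP = 1e6  # bound on y/yhat in pathological (near-empty) bins


@dataclass(frozen=True)
class ReconParams:
    """Algorithm settings; ``name`` style follows the 12i1s convention."""

    algorithm: str = "OSEM"  # "OSEM" | "BSREM"
    iterations: int = 24
    subsets: int = 1
    beta: float = 0.0
    gamma: float = 1.0
    by_sens: bool = False
    psf_mode: str = "matched"  # "matched" | "mismatched" | "none"
    relaxation: tuple[float, float] = (1.0, 0.05)  # (alpha0, eta)

    def __post_init__(self):
        if self.algorithm not in ("OSEM", "BSREM"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.iterations < 1 or self.subsets < 1:
            raise ValueError("iterations and subsets must be >= 1")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be nonnegative")
        if self.psf_mode not in ("matched", "mismatched", "none"):
            raise ValueError(f"unknown psf_mode {self.psf_mode!r}")
        if self.relaxation[0] <= 0 or self.relaxation[1] < 0:
            raise ValueError("relaxation requires alpha0 > 0 and eta >= 0")

    @property
    def updates(self) -> int:
        return self.iterations * self.subsets

    @property
    def label(self) -> str:
        tag = f"{self.algorithm}-{self.iterations}i{self.subsets}s"
        if self.algorithm == "BSREM" and self.beta > 0:
            tag += f"-RDP(b={self.beta:g},g={self.gamma:g})"
            if self.by_sens:
                tag += "+bySens"
        return tag


#: Emulation of the manufacturer-recommended protocol:
#: BSREM 20i10s with RDP (gamma=1, beta=0.08) and sensitivity-weighted beta.
FACTORY_PROTOCOL = ReconParams(
    algorithm="BSREM", iterations=20, subsets=10, beta=0.08, gamma=1.0, by_sens=True
)


@dataclass
class ReconVolume:
    """Reconstructed volume in counts per voxel, with provenance."""

    grid: VoxelGrid
    values: np.ndarray
    params: ReconParams
    duration: float  # T_acq [s]
    acq_start: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if np.any(self.values < 0):
            raise ValueError("reconstructed counts must be nonnegative")

    @property
    def total_counts(self) -> float:
        return float(self.values.sum())


# ----------------------------------------------------------------------
# relative difference prior
# ----------------------------------------------------------------------
def _neighbour_offsets_weights(spacing) -> list[tuple[tuple[int, int, int], float]]:
    """13 unique offsets of the 26-neighbourhood with 1/distance weights
    (distance in units of the smallest spacing, so the axial weight is 1
    on an isotropic grid)."""
    d0 = min(spacing)
    out = []
    for off in product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0) or off < (0, 0, 0):
            continue  # keep one representative of each +/- pair
        dist = np.sqrt(sum((o * s) ** 2 for o, s in zip(off, spacing))) / d0
        out.append((off, 1.0 / dist))
    return out


def rdp_penalty(
    x: np.ndarray,
    gamma: float,
    weights: list | None = None,
    spacing=(1.0, 1.0, 1.0),
    eps: float | None = None,
) -> tuple[float, np.ndarray]:
    """Value and analytic gradient of the relative difference prior.

    Each unordered neighbour pair contributes once.  ``eps`` guards the
    denominator and defaults to ``1e-9 * mean(x)``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("RDP expects a nonnegative image")
    if eps is None:
        eps = 1e-9 * float(x.mean())
    eps = eps + _TINY
    if weights is None:
        weights = _neighbour_offsets_weights(spacing)

    value = 0.0
    grad = np.zeros_like(x)
    for off, w in weights:
        sl_a = tuple(slice(None, -o) if o > 0 else slice(-o, None) for o in off)
        sl_b = tuple(slice(o, None) if o > 0 else slice(None, o or None) for o in off)
        a = x[sl_a]
        b = x[sl_b]
        d = a - b
        s = a + b
        sg = np.sign(d)
        den = s + gamma * np.abs(d) + eps
        value += w * float((d * d / den).sum())
        common = d * d / (den * den)
        grad[sl_a] += w * (2.0 * d / den - common * (1.0 + gamma * sg))
        grad[sl_b] += w * (-2.0 * d / den - common * (1.0 - gamma * sg))
    return value, grad


# ----------------------------------------------------------------------
# scatter and sensitivity-weighted beta
# ----------------------------------------------------------------------
def dew_scatter_estimate(proj: ProjectionSet, k: float = C.DEW_K) -> np.ndarray:
    """Additive photopeak scatter/tailing term from the lower window.

    ``k x (photopeak width / scatter width) x scatter counts``, smoothed
    with a mild 2D blur (one-bin sigma) to temper Poisson noise, and
    clipped below the recorded photopeak counts bin by bin.
    """
    if proj.scatter_counts is None:
        raise ValueError("projection set has no scatter window")
    est = k * proj.windows.width_ratio * proj.scatter_counts
    est = ndimage.gaussian_filter(est, (0.0, 1.0, 1.0), mode="constant")
    return np.minimum(est, proj.photopeak_counts)


def sensitivity_weight_beta(
    mu: MuMap,
    beta: float,
    geom: AcquisitionGeometry,
    det: DetectorModel = DetectorModel(),
    projector: Projector | None = None,
) -> np.ndarray:
    """Voxelwise beta map ``beta * S / mean(S)`` (bySens emulation).

    ``S`` is the backprojection of unit data through the attenuated
    system model, so deeper (more attenuated) voxels receive a smaller
    beta.  Experimental: the vendor's normalization is proprietary.
    """
    if projector is None:
        projector = Projector(
            mu.grid, geom.angles_deg, geom.detector_radius, mu=mu.values,
            psf=det.psf_dict(),
        )
    s = projector.sensitivity_image() / projector.n_views
    return beta * s / s.mean()


# ----------------------------------------------------------------------
# reconstruction drivers
# ----------------------------------------------------------------------
def _build_projector(
    proj: ProjectionSet, mu: MuMap, params: ReconParams, det: DetectorModel,
    dtype=np.float64,
) -> Projector:
    if params.psf_mode == "none":
        psf = None
    elif params.psf_mode == "mismatched":
        psf = det.psf_dict(narrow=0.8)  # deliberately 20 % narrower
    else:
        psf = det.psf_dict()
    return Projector(
        proj.grid, proj.geometry.angles_deg, proj.geometry.detector_radius,
        mu=mu.values, psf=psf, dtype=dtype,
    )


def _subset_views(n_views: int, subsets: int) -> list[list[int]]:
    if n_views % subsets != 0:
        raise ValueError(f"subsets ({subsets}) must divide n_views ({n_views})")
    return [list(range(s, n_views, subsets)) for s in range(subsets)]


def _prepare(proj, mu, params, det, scatter_correction, dtype=np.float64):
    if not proj.grid.same_geometry(mu.grid):
        raise ValueError("mu-map must live on the projection grid")
    op = _build_projector(proj, mu, params, det, dtype=dtype)
    subsets = _subset_views(proj.geometry.n_views, params.subsets)
    y = proj.photopeak_counts
    b = (
        dew_scatter_estimate(proj)
        if scatter_correction
        else np.zeros_like(proj.photopeak_counts)
    )
    n = proj.geometry.n_views
    sens = [op.sensitivity_image(views=s) / n for s in subsets]
    # freeze voxels essentially unseen by a subset (numerically zero
    # sensitivity), and start them at zero when unseen by every subset
    valid = [s > 1e-8 * s.max() for s in sens]
    total = float(y.sum())
    if total <= 0:
        warnings.warn("all-zero projections: returning an all-zero volume")
        x0 = np.zeros(proj.grid.shape)
    else:
        x0 = np.full(proj.grid.shape, total / np.prod(proj.grid.shape))
        x0[~np.logical_or.reduce(valid)] = 0.0
    return op, subsets, y, b, sens, valid, x0


def _finalize(x, proj, params):
    return ReconVolume(
        grid=proj.grid,
        values=np.maximum(x, 0.0),
        params=params,
        duration=proj.geometry.duration,
        acq_start=proj.acq_start,
    )


def osem_reconstruct(
    proj: ProjectionSet,
    mu: MuMap,
    params: ReconParams,
    det: DetectorModel = DetectorModel(),
    scatter_correction: bool = True,
    snapshot_updates=None,
    dtype=np.float64,
    _prepared=None,
):
    """Ordered-subsets EM with attenuation, PSF and additive DEW term.

    Returns a :class:`ReconVolume`, or a dict ``{updates: ReconVolume}``
    when ``snapshot_updates`` is given (the run then continues to the
    largest requested update count — intermediate iterates of a single
    run, exactly as if each had been requested alone, since the schedule
    is deterministic).  No post-filter is applied.
    """
    if params.algorithm != "OSEM":
        raise ValueError("params.algorithm must be 'OSEM'")
    op, subsets, y, b, sens, valid, x = (
        _prepare(proj, mu, params, det, scatter_correction, dtype=dtype)
        if _prepared is None
        else _prepared
    )
    if x.sum() == 0:
        return _snapshot_result(x, proj, params, snapshot_updates)

    n = proj.geometry.n_views
    snaps = {}
    want = sorted(set(snapshot_updates)) if snapshot_updates else []
    total_updates = params.updates if not want else max(params.updates, want[-1])
    u = 0
    while u < total_updates:
        for s_idx, views in enumerate(subsets):
            yhat = op.forward(x, views=views) / n + b[views]
            ratio = np.minimum(y[views] / np.maximum(yhat, _TINY), _RATIO_CLAMP)
            back = op.backward(ratio, views=views) / n
            ok = valid[s_idx]
            x = np.where(ok, x / np.where(ok, sens[s_idx], 1.0) * back, x)
            x = np.maximum(x, 0.0)
            u += 1
            if u in want:
                snaps[u] = _finalize(
                    x, proj, _with_updates(params, u)
                )
            if u >= total_updates:
                break
    if want:
        return snaps
    return _finalize(x, proj, params)


def bsrem_reconstruct(
    proj: ProjectionSet,
    mu: MuMap,
    params: ReconParams,
    det: DetectorModel = DetectorModel(),
    scatter_correction: bool = True,
    snapshot_updates=None,
    dtype=np.float64,
    _prepared=None,
):
    """Relaxed block-sequential regularized EM (optionally with RDP).

    The update is ``x <- x + alpha_n * (x / s_sub) * (grad_L_sub(x)
    - beta_eff * grad_U(x))`` clipped at a small positive floor, with
    ``beta_eff = beta / (n_views * subsets)`` so that ``beta`` carries
    the vendor convention (likelihood summed over views, one prior term
    per subset update);
    with ``by_sens`` the scalar beta is replaced by the attenuation-derived
    voxelwise map of :func:`sensitivity_weight_beta`.
    """
    if params.algorithm != "BSREM":
        raise ValueError("params.algorithm must be 'BSREM'")
    op, subsets, y, b, sens, valid, x = (
        _prepare(proj, mu, params, det, scatter_correction, dtype=dtype)
        if _prepared is None
        else _prepared
    )
    if x.sum() == 0:
        return _snapshot_result(x, proj, params, snapshot_updates)

    n = proj.geometry.n_views
    alpha0, eta = params.relaxation
    beta_map = None
    if params.beta > 0:
        if params.by_sens:
            beta_map = sensitivity_weight_beta(
                mu, params.beta, proj.geometry, det, projector=op
            )
        else:
            beta_map = params.beta

    snaps = {}
    want = sorted(set(snapshot_updates)) if snapshot_updates else []
    total_updates = params.updates if not want else max(params.updates, want[-1])
    u = 0
    while u < total_updates:
        full_pass = u // params.subsets
        alpha = alpha0 / (1.0 + eta * full_pass)
        for s_idx, views in enumerate(subsets):
            yhat = op.forward(x, views=views) / n + b[views]
            ratio = np.minimum(y[views] / np.maximum(yhat, _TINY), _RATIO_CLAMP)
            grad_l = op.backward(ratio - 1.0, views=views) / n
            if beta_map is not None:
                _, grad_u = rdp_penalty(x, params.gamma, spacing=proj.grid.spacing)
                # beta follows the vendor convention of a likelihood summed
                # over views without normalization; our per-view-normalized
                # system model absorbs the factor n_views * subsets here
                grad_l = grad_l - (beta_map / (n * params.subsets)) * grad_u
            ok = valid[s_idx]
            step = alpha * (x / np.where(ok, sens[s_idx], 1.0)) * grad_l
            x = np.where(ok, x + step, x)
            x = np.maximum(x, _FLOOR)
            u += 1
            if u in want:
                snaps[u] = _finalize(x, proj, _with_updates(params, u))
            if u >= total_updates:
                break
    if want:
        return snaps
    return _finalize(x, proj, params)


def _with_updates(params: ReconParams, u: int) -> ReconParams:
    """Params tag for an intermediate snapshot after ``u`` subset updates."""
    if u % params.subsets == 0:
        return ReconParams(
            algorithm=params.algorithm,
            iterations=u // params.subsets,
            subsets=params.subsets,
            beta=params.beta,
            gamma=params.gamma,
            by_sens=params.by_sens,
            psf_mode=params.psf_mode,
            relaxation=params.relaxation,
        )
    return ReconParams(
        algorithm=params.algorithm,
        iterations=u,
        subsets=1,
        beta=params.beta,
        gamma=params.gamma,
        by_sens=params.by_sens,
        psf_mode=params.psf_mode,
        relaxation=params.relaxation,
    )


def _snapshot_result(x, proj, params, snapshot_updates):
    if snapshot_updates:
        return {
            u: _finalize(x, proj, _with_updates(params, u))
            for u in sorted(set(snapshot_updates))
        }
    return _finalize(x, proj, params)


def reconstruct(proj, mu, params, **kw):
    """Dispatch on ``params.algorithm``."""
    fn = osem_reconstruct if params.algorithm == "OSEM" else bsrem_reconstruct
    return fn(proj, mu, params, **kw)


def poisson_loglik(proj: ProjectionSet, volume_values, mu, det=DetectorModel(),
                   psf_mode="matched", scatter_correction=True) -> float:
    """Poisson log-likelihood (up to the data-only constant) of a volume."""
    params = ReconParams(algorithm="OSEM", iterations=1, psf_mode=psf_mode)
    op = _build_projector(proj, mu, params, det)
    b = (
        dew_scatter_estimate(proj)
        if scatter_correction
        else np.zeros_like(proj.photopeak_counts)
    )
    yhat = op.forward(volume_values) / proj.geometry.n_views + b
    yhat = np.maximum(yhat, _TINY)
    y = proj.photopeak_counts
    return float((y * np.log(yhat) - yhat).sum())
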