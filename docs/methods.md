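# Methods

`luquant` reproduces, end to end and on purely synthetic data, the
quantitative characterization workflow of a ring-shaped CZT SPECT/CT
system imaging ¹⁷⁷Lu at 208 keV: digital phantoms → attenuated
dual-window projections → OSEM / BSREM-RDP reconstruction → calibration
factor, quantification errors, noise, matched-filter resolution,
recovery coefficients, noise-matched protocol selection and paired
lesion statistics.

## Forward model

The projector is parallel-beam with one view per gantry angle.  For a
view at angle θ the volume is rotated so the detector lies on the +y
side, each transaxial plane is attenuated by
`exp(-∫ μ dl)` from the voxel centre to the detector (cumulative sum
along +y, half-voxel self-attenuation), blurred in the detector plane
with a Gaussian of distance-dependent width

```
FWHM(d) = sqrt(FWHM_int² + (c₀ + c₁·d)²)
```

and summed along the ray axis.  The volume rotation uses the
mass-conserving *push* (splat) form of bilinear resampling — each voxel
distributes its content with bilinear weights — because a plain gather
interpolation loses a few percent of counts at oblique angles, which
would corrupt every calibration-chain result; the μ-map, a value field
rather than a density, is rotated with the matching gather.  Gaussian
kernels are symmetric and truncated at 3σ, and the rotation is stored
as an explicit sparse matrix, so the backprojector is the exact adjoint
of the projector (verified to round-off in the tests).

The photopeak expectation is a convex mixture

```
E[y_pk] = s·T/N · [ (1 − f_pen − c_sc)·P_psf(a) + f_pen·G_pen(P₀(a)) + c_sc·G_sc(P₀(a)) ]
```

where `P_psf` is the PSF-modelling projector, `P₀` the unblurred
(geometric) projector, `G_pen`, `G_sc` broad normalized Gaussians
(defaults 80 mm and 60 mm FWHM), `s` the in-air sensitivity (cps/MBq),
`T` the acquisition duration and `N` the number of views.  Because the
mixture is convex, total expected counts in air equal `s·A·T` — the
conservation property the calibration factor relies on.  The lower
scatter window records `α·G_sc(P₀(a))` with `α = 0.15`, and the
photopeak contamination coefficient is chosen self-consistently as
`c_sc = k·(W_pk/W_sc)·α` so that the dual-energy-window (DEW) estimate
`k·(W_pk/W_sc)·y_sc` is unbiased in expectation.  `k` defaults to 0.1:
on a CZT detector the low-energy tailing recorded in the adjacent
window mirrors only part of the photopeak contamination, and the small
value keeps the DEW subtraction (≈2 % of counts) from dominating the
calibration budget.  Septal-penetration tails (`f_pen = 0.08`) are
*not* represented in the reconstruction system model and are not
removed by the DEW term — they are the deliberate model error whose
consequences the calibration study measures.

Poisson noise is drawn independently per bin and window from the
stored expectations; the expectations are retained so noiseless runs
and replicate draws are possible from one simulation.

Default scalar parameters: sensitivity 100 cps/MBq, FWHM_int 2.46 mm,
c₀ = 2 mm, c₁ = 0.03 (≈7 mm system FWHM at 15 cm), detector radius
150 mm, μ_water(208 keV) = 0.0136 mm⁻¹, ¹⁷⁷Lu half-life 6.6475 d.
Detector (u,v) bins inherit the reconstruction grid pitch.

## Phantoms

Three phantom families mirror the physical study: a Jaszczak-like
uniform calibration cylinder (20.9 cm × 18.6 cm, 541 MBq), a plain
cylinder (20 cm × 18 cm, 700 MBq), and a NEMA IEC-style body with six
spheres (10–37 mm diameters, centres on a 57.2 mm ring in one
transaxial plane; 1.6 MBq/mL spheres, cold or 10:1 hot background).
Compartment boundaries are refined by 3× per-axis subsampling of
boundary voxels, and activity fills are mass conserving (the map total
equals the requested activity to <0.1 %).  The Jaszczak internal
structures are not modelled: the calibration analysis sees it only as
a uniform source through a large VOI.  A patient-like generator places
non-overlapping ellipsoidal lesions (5.3–29.5 mL, 204–5648 kBq/mL
log-uniform) in an ellipsoidal torso with 50 kBq/mL background.

## Reconstruction

OSEM and BSREM share the attenuated PSF-modelling system operator and
the additive DEW term.  The volume is in counts per voxel; the system
model divides by the view count, so an unregularized fit converges to
a volume whose total approaches the recorded photopeak counts.

BSREM performs relaxed block-sequential ascent with preconditioner
`x/s_subset` and relaxation `α_n = 1/(1 + 0.05·n)` per full pass.  The
relative difference prior is

```
U(x) = Σ_{j<k∈N26} w_jk (x_j − x_k)² / (x_j + x_k + γ|x_j − x_k| + ε)
```

with inverse-distance weights (1 for face neighbours on an isotropic
grid), `ε = 10⁻⁹·mean(x)`, and an analytic gradient.  Each unordered
pair counts once.  **β normalization:** the penalty strength is applied
as `β/(N_views·N_subsets)` per subset update, which is algebraically
what a vendor-style objective (likelihood summed over views without
normalization) reduces to under our per-view-normalized system model.
Without this factor the clinical β values (0.005, 0.08) over-regularize
by roughly the view count and the factory protocol collapses; with it,
β = 0.005 is a mild smoothing and β = 0.08 with sensitivity weighting
is strong but stable — the qualitative ordering the protocols are meant
to have.  `bySens` replaces the scalar β by `β·S/mean(S)` with `S` the
backprojection of unit data, so deep (low-sensitivity) voxels are
regularized less; the vendor's exact normalization is proprietary and
this emulation is flagged experimental.

Numerical safeguards: voxels with numerically zero subset sensitivity
are frozen (and start at zero when unseen by all subsets); the
data/model ratio is clamped at 10⁶ in pathological near-empty bins;
BSREM clips at a 10⁻¹² floor.  With β = 0, α₀ = 1, η = 0 the BSREM
update is algebraically the OSEM update, and the implementations agree
voxelwise to 10⁻⁶ (an acceptance oracle), so the safeguards are shared
by both code paths.  `psf_mode` selects resolution modelling that is
`matched` to the simulator (inverse crime — used for oracle tests),
`mismatched` (20 % narrower, the default in the characterization
workflow, avoiding trivially perfect resolution recovery) or `none`.
Reconstruction happens directly on the acquisition grid: the synthetic
projector's bins are grid-aligned, so a separate matrix-size rule would
only insert a resample.  Batch reconstructions run the projector in
single precision (percent-level metrics); oracle tests use double.

## Metrics

* **ICF** `C/(T·A_prep·2^(−Δt/T½))` over a 23 cm × 22 cm cylindrical
  VOI; uncertainty `sqrt(C⁻¹ + u_A²)` with u_A = 2 %.  The √C counting
  model is applied to reconstructed counts exactly as in the
  characterization procedure, although reconstructed voxels are not
  independent Poisson draws.
* **Quantification error** in VOI_outside (22 × 20 cm, activity) and
  VOI_inside (14 × 12.6 cm, concentration), each against the decayed
  truth, using the ICF of the same protocol.  Decay is referenced to
  the acquisition start; mid-acquisition decay (<0.2 % over 15 min) is
  ignored.
* **Noise** = sample (n−1) standard deviation over mean in VOI_inside.
* **Resolution** by matched filter: the known digital phantom is
  blurred with isotropic Gaussians (grid 1–30 mm, 0.2 mm steps), both
  images scaled to unit total inside the body bounding box dilated by
  2 cm, and the SSD-minimizing FWHM reported.
* **Recovery coefficients** after trilinear resampling to a CT-grid
  (1.0 × 1.0 × 2.5 mm³), treating counts per voxel as a density and
  rescaling by the voxel-volume ratio so totals are conserved; sphere
  VOIs are rendered geometrically from the known centres (the synthetic
  equivalent of CT delineation).
* **Protocol optimization** picks the candidate with CV closest to the
  factory-protocol CV (ties → fewer updates; selection is
  permutation-invariant).
* **Lesions**: 1-mL spherical peak mean (radius 6.20 mm), 30 %
  isocontour grown as the 26-connected component containing the peak,
  frozen and reused across protocols; concentrations via the matching
  ICF; paired protocols compared by a Wilcoxon matched-pairs
  signed-rank test with an exact null distribution up to n = 25
  (dynamic programming over the mid-rank sum distribution, equivalent
  to full 2ⁿ enumeration; zero differences dropped) and a
  tie-corrected normal approximation beyond.  Quartiles use linear
  interpolation (type 7).

## Study profiles and problem sizes

The desk profile (64³ voxels at 4.92 mm — twice the native pitch —
over a 315 mm field of view, 60 views, 15 min acquisitions) is the
package's standard study size and is what `scripts/acceptance.py`
runs; the full profile (128³ at 2.46 mm, 180 views) uses the same code
path.  The test suite exercises the same workflow at 40³–48³ with 30
views.  At desk scale the simulated count level (≈5·10⁷ photopeak
counts for the calibration phantom) matches the physical study, but
counts per voxel are ≈8× higher than at native resolution, so absolute
CV values are smaller than their real-acquisition counterparts while
their orderings and trends (noise build-up with updates, RDP noise
suppression, subset dependence of BSREM but not OSEM) are preserved.

## What the synthetic study does and does not show

The simulator reproduces the mechanisms the analysis chain is
sensitive to — attenuation, distance-dependent blur, count statistics,
DEW-correctable tailing, and an unmodelled broad penetration
component — so passing tests demonstrate the *pipeline* (formulas,
calibration chain, trend directions) on data with a known ground
truth.  It does not demonstrate hardware fidelity: the 12 sweeping
detector heads, body-contour orbits, energy spectra, dead time and the
true septal-penetration point spread are not modelled.

Two documented behavioural gaps follow from the penetration surrogate.
A Gaussian tail kernel centred on the body necessarily peaks over the
body itself, so diverting 8 % of counts into such tails leaves the
interior concentration slightly *over*-estimated relative to the
ICF-captured average (inner-VOI errors of ≈+2 % at convergence, ≈0
with penetration off, in every configuration we measured; widening the
kernel drives the bias to zero from above, never negative).  The
physical system instead shows an ≈−8 % inner-VOI bias, produced by
structured septal star artefacts that deposit counts far *outside* the
object.  For the same reason a hot background raises, rather than
degrades, small-sphere recovery for unregularized OSEM at high update
counts (classical spill-in); the degradation is reproduced at low
update counts and for the regularized protocols.  Reproducing the
negative bias would require an anisotropic, object-external tail model
for which no public parametrization exists.

## Numerical choices

Nonnegativity floor 10⁻¹²; division guards 10⁻³⁰; ratio clamp 10⁶;
PSF kernels truncated at 3σ and renormalized; trilinear interpolation
with zero padding outside the field of view; matched-filter objective
minimized by exhaustive grid search (no interpolation of the optimum);
sphere VOI masks accept ≥50 % covered voxels and must agree with the
analytic volume within 5 %.  All randomness flows from explicit seeds
through `numpy.random.default_rng`; a run is reproducible byte-for-byte
from (configuration, seed).
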