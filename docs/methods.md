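# Methods

## Model and scope

`iodose` implements the internal-dosimetry chain used for normal organs in
multi-centre radioiodine therapy: quantitative-SPECT calibration, VOI
quantification, time-integrated-activity estimation, voxel-kernel absorbed
dose, whole-body MIRD dose, and cohort statistics. The package deliberately
stops at the reconstructed-image level: projection simulation, iterative
reconstruction, scatter/attenuation physics, image registration and Monte
Carlo radiation transport are out of scope. Synthetic series are generated
pre-aligned on a common grid, standing in for the rigid registration step a
clinical pipeline would perform.

## Kinetic models

All activity kinetics integrate from t = 0 (administration) to infinity
with instantaneous uptake, so for a sum of exponentials
A(t) = Σ aᵢ e^(−λᵢ t) the time-integrated activity is Ã = Σ aᵢ/λᵢ and the
TIAC is Ã/A₀ (hours). Decay constants are bounded below by the physical
decay constant of I-131 (half-life 192.5 h, configurable in
`iodose.config`): biological clearance can only shorten retention. Fits
that violate the bound — flat or rising series — are clamped to it and
flagged (`half_life_clamped`, `uptake_suspected`) rather than rejected, so
the record stays auditable.

* **Organ fits.** Two points use the closed form λ = ln(A₁/A₂)/(t₂−t₁).
  More points use activity-weighted least squares of log A on t (the weights
  counteract the log transform's inflation of late, low-count samples),
  refined by unweighted nonlinear least squares on the linear scale. The
  series is normalised by its maximum before solving so the fit is
  scale-equivariant to machine precision — absorbed doses then scale exactly
  with administered activity.
* **Single-time-point.** Ã = A(t₁) e^(λt₁)/λ with an assumed effective
  half-life: shipped defaults are 68 h for the neck uptake (rhTSH
  population value), 9.3 h parotid and 8.6 h submandibular; any organ can
  instead use the patient's own whole-body half-life. Note Ã is *not*
  monotone in the assumed half-life everywhere: it increases with T only
  for T ≥ ln2·t₁; below that the back-extrapolation to t = 0 dominates.
* **Whole-body retention.** 1- or 2-component exponential with amplitudes
  ≥ 0 constrained to sum to A₀ (retention = 100% at administration; the
  A₀ anchor is explicit, or the first measurement within 4 h is used).
  Optimisation is bounded nonlinear least squares (λ between the physical
  bound and ln2/0.5 h⁻¹) from a deterministic multi-start grid of
  half-life pairs {2, 8, 24, 96} h — a reproducible stand-in for
  spreadsheet solvers whose algorithms are unspecified. A second component
  is kept only when there are ≥ 4 points and it reduces the residual sum
  of squares by ≥ 5%; otherwise the fit falls back to one component and is
  flagged. The number of components real studies used is rarely reported;
  2-with-fallback is this package's choice.

## Calibration and recovery

The calibration factor is count-rate/activity from a known-activity
acquisition. Recovery coefficients RC(V) = measured/true from a sphere
series are clipped into (0, 1] and repaired to monotone non-decreasing by
least-squares isotonic regression (pool-adjacent-violators) — physics
demands monotonicity, but noisy nodes need not satisfy it. Between nodes RC
is interpolated linearly in log₁₀(volume), the conventional axis for
recovery curves; outside the node range it clamps to the nearest node.
Whether recovery correction is applied to organ activities or only
characterised at set-up differs between sites; `extract_time_activity`
takes the curve as an optional argument, so both pathways are supported
without asserting either as canonical.

## Segmentation

Threshold segmentation keeps voxels ≥ 35% (configurable fraction) of the
maximum inside a user-supplied search region, then retains the largest
6-connected component (ties broken by total intensity). The threshold is
applied per time-point against that time-point's regional maximum; applying
it against a series-wide maximum is a legitimate alternative the interface
leaves to the caller. CT-derived outlines are supported as externally
supplied masks; masks must share the image grid exactly — no resampling is
performed anywhere.

## Dose engine

The dose model is charged-particle-only kernel convolution: dose-rate =
(activity ⊛ S) × ρ_ref/ρ(target), with S a voxel S-value kernel (Gy per
MBq·h, water reference) whose energy closure Σ S·m_voxel = Δ is validated
at construction. Δ defaults to the mean charged-particle energy per I-131
decay (0.192 MeV, a configurable constant with a documented source field,
never hard-coded in logic), giving Δ = 0.1107 Gy·g/(MBq·h). The 1×1×1
local-deposition kernel (all energy absorbed in the source voxel) is the
default and is exact in the charged-particle-equilibrium limit; it is
appropriate for organs large relative to the ~1-mm I-131 beta range at
typical SPECT voxel sizes (≥ 2 mm). The density scaling is a first-order
heterogeneity correction that is exact in uniform media. Kernels declare
their voxel spacing and are never resampled (mismatch > 1% is an error):
silent resampling of S-values is a known error source. Convolution uses
zero padding; energy is conserved to 1e−6 relative for sources ≥ a kernel
half-width from the grid edge, and the implementation agrees with a
brute-force per-source superposition oracle to 1e−10 on small grids.
Organ doses are the time integral of the mass-averaged VOI dose rate
(total deposited power / VOI mass), reusing the mono-exponential fitter
with dose-rate in place of activity; single-sample integration requires an
assumed half-life.

Photon cross-dose between organs is a known omission of the
charged-particle-only model: it underestimates doses to low-uptake organs
irradiated by neighbours. Whole-body dose is instead computed from
retention via the mass-adjusted S-factor S_WB = 1.34×10⁻⁴·m_p^(−0.921)
Gy MBq⁻¹ h⁻¹, applied exactly as printed, with no photon/electron split.

## Cohort statistics

Summaries are median (midpoint for even n) and range per group, with
missing organs (outside a centre's field of view) excluded and per-group n
reported — never imputed as zero. The Mann–Whitney test uses midranks; the
p-value is the exact permutation probability of |U − μ| at least as large
as observed when the smaller group has ≤ 8 observations (and ≤ 1e5
arrangements), else a tie-corrected normal approximation with continuity
correction. The exact/approximate agreement band (< 0.03 for n of 5–8)
holds for continuous data; heavy ties degrade the normal approximation
beyond it, which is precisely why the exact branch exists. Reports print
doses per administered activity to 2 decimals (mGy/MBq); full precision is
retained in CSV.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of multi-centre data: organs as
geometric primitives (voxel-centre-inside voxelisation) with uniform
concentration and mono-exponential washout (optionally bi-exponential
uptake–washout to probe model misfit); system resolution as isotropic
Gaussian blur of the activity map — the minimal mechanism that makes
recovery coefficients nontrivial; counting statistics as Poisson noise on
count-rate voxels (an implicit 1-s frame); centre differences as imaging
schedules (1–6 time-points in 6–168 h), retention windows (~167 h for
centres 1–2 vs ~44 h for centres 3–4) and head/neck-only vs full field of
view. Every dataset carries ground truth (true activities, TIAs, and
local-deposition organ doses), and all stochastic generators are
bit-reproducible by seed.

It does **not** emulate: reconstruction artefacts, scatter, attenuation,
dead time, patient motion or misregistration, non-uniform intra-organ
uptake, or calendar-time bookkeeping (all times are hours post
administration). Passing tests therefore demonstrate the correctness of
the dosimetry chain given quantitative images, not robustness to
reconstruction-level degradation.

Cohort defaults (chosen once as field-realistic): bi-exponential whole-body
retention with a fast renal-clearance component (~7 h effective, fraction
~0.8) and a slow retained-iodide component (~30 h), patient mass
~N(70, 12) kg, administrations of nominally 1.1 or 3.7 GBq, mostly rhTSH
stimulation with thyroid-hormone withdrawal in one centre (THW shifts 10%
of the clearance to the slow component, reflecting reduced glomerular
filtration), and 5% relative retention-measurement noise. These settings
produce whole-body TIACs of roughly 15–20 h and per-MBq whole-body doses
around 0.04–0.05 mGy/MBq — the regime reported for this patient
population.

## Problem sizes and numerical choices

The default phantom is a 42×42×58 grid at 4-mm spacing with six organs;
acceptance runs use 20-patient cohorts, 100-seed noise-recovery batches and
≤ 21³ oracle grids — sizes chosen so a full verification pass completes in
seconds on one core while still exercising every code path. Tolerances:
TIA vs adaptive quadrature 1e−6 relative; kernel energy closure 1e−6;
convolution vs superposition oracle 1e−10; noise-free end-to-end organ
doses vs analytic truth 2% (observed: machine precision); per-MBq dose
invariance under activity rescaling 1e−12. Ties in segmentation and the
component ordering of retention fits (faster first) are fixed
deterministically. Degenerate inputs (zero activity, all-zero retention,
empty masks, zero VOI mass) either short-circuit to zero where that is the
mathematically correct limit or raise with the offending object named.
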