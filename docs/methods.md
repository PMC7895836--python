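# Methods

## Data model

The unit of analysis is a `SubjectFieldStack`: an `n_subjects × n_voxels`
matrix of electric-field magnitudes (V/m, at device current) over a boolean
analysis mask on one shared grid (shape + 4×4 affine; voxel-to-world in mm,
MNI-like frame). All inputs must already be co-registered — affines are
compared to 1e-6 and any mismatch is an error, as is any non-finite value
inside the mask (silent zeros would bias every downstream regression).
Masked storage keeps the 20 000-permutation loops touching brain voxels
only. Columns are ordered by lexicographic (i, j, k); voxel indices are
0-based; cluster peaks are reported in world mm.

## Field preparation

Finite-element solves are linear in the injected current, so a solution
obtained at 1 mA is scaled by the ratio of device to solve current
(default 900 for a 0.9 A constant-current device; configurable for 0.8 A
hardware). Magnitude is the per-voxel Euclidean norm of the 3-component
field; only magnitudes enter the statistics (field direction is not
analysed). Group maps use the sample SD (n−1). The paired comparison is
BL − RUL within subject, so positive values mean the bitemporal montage
delivers the stronger field. The isotropic tissue conductivities of the
upstream solves (white matter 0.126, gray matter 0.275, CSF 1.654, bone
0.01, scalp 0.465, eyes 0.5 S/m) are recorded as provenance metadata only.

## Inverse GLM

At voxel v the outcome y (end-MADRS, or response ∈ {0,1} as a linear
probability model — the same least-squares machinery, deliberately not
logistic, so one inference pipeline covers both) is regressed on
X_v = [1, E_v, z] with z the clinical covariates. Since only the field
column varies across voxels, the covariate block Z = [1, z] is reduced once
to an orthonormal basis Q (QR); with f̃_v = (I−QQᵀ)f_v and ỹ = (I−QQᵀ)y,

    β̂_v = f̃_vᵀỹ / ‖f̃_v‖²,   RSS_v = ‖ỹ‖² − β̂_v f̃_vᵀỹ,
    t_v = β̂_v / √(RSS_v /(df·‖f̃_v‖²)),   df = n − p,

identical (Frisch–Waugh–Lovell) to the per-voxel pseudoinverse solve; the
test suite verifies equality to 1e-8 against explicit normal-equations fits.
Effect sizes: R²_full = 1 − RSS/TSS and the field's semi-partial
R² = t²(1−R²_full)/df, the share of outcome variance uniquely attributable
to the field. Voxels with zero field variance across subjects are flagged
and score t = 0 / sp_R² = 0 rather than being dropped, keeping map geometry
intact. Covariates are used on their raw scales (t is invariant to affine
covariate rescaling). Missing baseline scores are mean-imputed once on the
cohort, before — never inside — the permutation loop. Degenerate outcomes
(y in the span of the covariates, e.g. constant) yield an all-zero t map
rather than round-off ratios.

## TFCE

TFCE(v) = Σ_k e(v, h_k)^E · h_k^H · dh over the ladder
h_k = h_max·(k/n), k = 1…n, with e(v, h) the size of the connected
component containing v in {s ≥ h}. Defaults H = 2, E = 0.5, n = 100 steps,
26-connectivity — the canonical volumetric choices; all configurable and
logged. The ladder is anchored to the maximum (h_n equals h_max bitwise)
rather than accumulated as dh·k: the accumulated form can leave the top
step empty through floating-point rounding, a knife-edge where a 1e-15
perturbation of the statistic map moves the score by O(h_max²·dh).
Negative-direction enhancement is a separate pass on the negated map.

The engine inserts voxels in descending order into a union-find structure,
maintaining component sizes across all thresholds in one sweep
(numba-compiled; the permutation null needs tens of thousands of
transforms). For null permutations only the image-wide maximum is needed,
and it provably lies on a regional maximum of the statistic map (a voxel
with a strictly greater neighbour shares that neighbour's component
wherever both are supra-threshold), so the fast path accumulates scores
only there. Both paths are verified against a literal threshold-loop +
flood-fill oracle at 1e-10, and max-path ≡ full-path exactly.

## Permutation inference

Corrected p at voxel v is (1 + #{null maxima ≥ TFCE_obs(v)}) / (1 + N): the
observed arrangement counts once and p can never be 0. By default dh is
recomputed from each permutation's own maximum (the canonical behaviour); a
fixed-dh mode (ladder from the observed map) is available. Two one-sided
passes (positive, negative), each at α = 0.05, mirror reporting positive
associations while checking for negative ones; no across-direction
correction by default.

* **Sign flipping** (paired BL−RUL): under exchangeability of signs each
  permutation multiplies every subject's difference map by ±1; the
  one-sample t is recomputed via the flip-invariant sum of squares.
* **Freedman–Lane** (GLM default, matching standard practice for nuisance
  covariates): y is regressed on the nuisance block once; permuted outcomes
  are the nuisance fit plus permuted reduced-model residuals — equivalently
  the test statistic sees (I−QQᵀ)Pε̂. Plain permutation of y
  (`unrestricted_y`) is also available.

When the permutation group is small (2ⁿ−1 sign patterns or n!−1 orders not
exceeding the requested count) the scheme switches to exhaustive
enumeration and the test is exact; the suite verifies exact agreement with
independent full-enumeration oracles at n = 4–10 (signs) and n = 6
(orders). Monte-Carlo draws are i.i.d. with replacement; each permutation's
RNG stream derives from (seed, permutation index), so results are bitwise
independent of the worker count (joblib parallelism optional). A warning is
raised when 1/(1+N) > α (no voxel can be significant).

## Cluster report

Connected components (26-connectivity by default, matching TFCE) of the
corrected-significance mask, largest first: voxel count, size = count ×
voxel volume (mm³), peak voxel = member with minimal corrected p (ties →
larger |t|, then lexicographic index), peak world coordinate via the
affine, mean R² / semi-partial R² over members, and covariate-adjusted
scatter pairs (cluster-mean field and outcome, each residualised on
[1, covariates]). Effect sizes averaged over voxels *selected by* the
significance procedure are optimistically biased; every record and the TSV
header carry a `selection_biased` flag. Anatomical labelling needs an atlas
and is out of scope (a free-text label column is provided).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
head anatomy:

* **Grid**: 24×28×24 at 4 mm (≈16k voxels, ≈5.4k in the ellipsoidal brain
  mask) — desk-scale while preserving 3D cluster geometry.
* **Fields**: base profile = 250 V/m × exp(−d/45 mm) summed over electrode
  foci (one right-temporal focus for RUL; two temporal foci for BL, so BL
  delivers the globally stronger field); per subject this is multiplied by
  a lognormal global scale (σ = 0.05, the shared current-delivery
  variability) and by (1 + smooth perturbation): Gaussian-filtered white
  noise, FWHM 4 voxels = 16 mm, rescaled to relative SD 0.15, clipped at 0.
  The covariance model is a package choice — no spatial covariance of
  between-subject field variability is established for real cohorts. The
  16 mm correlation length was set from an identifiability analysis: the
  outcome driver is the *mean* field over the effect sphere (radius 12 mm),
  and a much shorter correlation length averages the local perturbation
  out of the driver, leaving the global scale dominant so that every brain
  voxel correlates equally with the outcome and localisation becomes
  ill-posed. With FWHM 16 mm the voxel-to-driver correlation is ≈0.7 inside
  the sphere vs ≈0.1 far away. Paired (switcher) subjects share one scale
  and one perturbation across their RUL and BL volumes — anatomy is a
  within-subject constant.
* **Covariates** match the study population's marginals: age N(58, 15²),
  baseline MADRS N(35.7, 8.3²), total sessions N(17.8, 7.5²) rounded ≥ 1,
  seizure threshold N(55.3, 34.3²) truncated > 0 by redraw, sex
  Bernoulli(0.61 female); groups 25 RUL-only / 16 BL-only / 26 switchers.
* **Outcome**: end-MADRS = 12.8 + β·(ROI-mean field − placement-expected
  ROI mean) + 0.4·(baseline−35.7) + 0.05·(age−58) + 5·switched + ε,
  ε ~ N(0, 4.5²). β > 0 means stronger field → worse outcome. Centring on
  the placement-specific expected ROI mean keeps the marginal outcome on
  target in every group while leaving the within-placement slope untouched.
  Responder (≥50 % baseline-to-end reduction) and remitter (end ≤ 10) flags
  are derived; a configurable number of baselines (default 2) is blanked to
  exercise imputation. Outcomes are not clipped at 0 — clipping would break
  the linearity the recovery tests rely on.
* Generation is a pure function of the seed (`SeedSequence`/PCG64, one
  spawned child stream per component), bitwise reproducible across runs.

What passing tests on these cohorts do **not** show: robustness to
registration error, non-Gaussian or heteroscedastic outcomes, nonlinear
dose–response, anatomy-dependent field covariance, or realistic tissue
boundaries. They do show that the estimator, the enhancement and the
inference are correct and calibrated under the model's own assumptions.

`slope_for_power(spec, n, power, alpha)` converts a target power for the
ROI-level two-sided t test into an outcome slope via the noncentral-t
distribution (noncentrality β·σ_ROI·√n/σ_ε, with σ_ROI measured from the
generator under a fixed probe seed); the planted-effect recovery study uses
it at 90 % power, n = 60. Note the information limit this implies: every
voxel's association with the outcome is mediated by the ROI mean, so
per-voxel evidence cannot exceed the ROI-level correlation (≈0.41 at that
calibration), which sits near — often below — the FWER-corrected detection
level; whole-sphere recovery at that slope is therefore only partial, and
the recovery test documents the achieved rates.

## Problem sizes and defaults in the validation suite

Oracle-equivalence checks run on 6×6×6–8×8×8 volumes at machine precision.
Calibration studies use the full 24×28×24 grid: the null family-wise error
rate is estimated from 200 independent null cohorts (n = 40) at 1000
Freedman–Lane permutations each, and planted-effect recovery from 50 seeds
(n = 60, 1000 permutations) — permutation counts chosen as the package's
validation scale; production analyses default to 5000 (sign-flip) and
20 000 (GLM) iterations.

## Known limitations

Linear probability model for binary response (coefficients are risk
differences; no link function); no variance smoothing; no
cluster-extent/mass alternatives; no surface TFCE; no atlas lookup; no
resampling — inputs must share a grid. Exhaustive enumeration materialises
the n! order list only for tiny n (n ≤ 7 given default permutation counts).
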