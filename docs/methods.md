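# Methods

`sctdoseval` evaluates how well an MR-derived synthetic CT (sCT) stands in
for a planning CT in brain photon radiotherapy, and implements the bone
volume ratio, a per-case predictor of that dosimetric accuracy.  This note
documents the models, the numerical choices, and what the synthetic study
data do and do not emulate.

## Geometry and data model

All volumes live on regular, axis-aligned voxel lattices with a
voxel-center convention: voxel `(i, j, k)` sits at `origin + (i,j,k) ·
spacing` (mm).  Masks are binary on voxel centers with no partial-volume
weighting, so every volume, ratio, and DVH is an exact function of voxel
counts — this keeps all downstream metrics reproducible to the bit.
Resampling interpolates at target voxel centers: trilinear for images and
dose, nearest-neighbor for masks (preserving binarity).  Points outside the
source extent take fixed fill values (−1000 HU for images, 0 Gy for dose).
Oblique grids and 4D data are out of scope.

When grids differ, metrics are computed on the natural grid of each
quantity: HU agreement on the planning-CT grid (the reference modality, sCT
resampled to it), the bone volume ratio on the sCT grid (bone is defined
*on the sCT*), and gamma/DVH metrics on the dose grid.

## Image agreement

Per region (body, brain, skull bone): MAE = mean |sCT − CT| and
ME = mean (sCT − CT), both in HU.  The sign convention (sCT − CT) makes an
sCT that is "too dark" negative, and is recorded in the report.  Skull bone
is segmented by thresholding at ≥100 HU inside the supplied skull-region
mask, on CT and sCT independently; their Dice coefficient
2|A∩B|/(|A|+|B|) summarizes skull segmentation agreement.  MAE/ME are also
reported over the full skull region, where both error directions
(missed bone, hallucinated bone) contribute.

## DVH and plan metrics

Cumulative DVHs use uniform bins (default width 0.05% of the prescription —
well below the 0.1% granularity at which differences are reported).  Dx is
computed as the exact inverse of the binned step curve: the largest bin
edge at which at least x% of the structure volume remains.  This makes the
analytic cases exact (uniform dose → D2 = D50 = D98, HI = 0) and bounds the
error on any input by one bin width; a full sort of structure doses
reproduces every metric.  Dmax is the single-voxel maximum (no D0.03cc
surrogate) so it, too, is oracle-checkable.  HI = (D2 − D98)/D50 × 100;
RTOG CI = V_RI/TV with the prescription isodose volume V_RI restricted to
the body mask (dose outside the patient is non-physical).  Plan-difference
tables report PTV dose metrics in percent of prescription (the alternative
normalization, relative to the evaluated plan's own value, is selectable),
OAR metrics in cGy (serial organs by Dmax, parallel organs by Dmean), and
HI/CI as raw differences.

## Gamma analysis

3D global gamma between a reference (planning-CT) and evaluated (sCT) dose:

    γ(r) = min over p in ball(r, 3·DTA) of
           sqrt( ((D_eval(p) − D_ref(r))/ΔD)² + (|p−r|/DTA)² )

with ΔD given as a percent of the normalization dose (default: global
maximum of the reference distribution; prescription normalization is
selectable) and D_eval interpolated trilinearly.  Voxels whose reference
dose falls below the low-dose threshold (default 10% of the normalization
dose) are excluded.  γ ≤ 1 passes, boundary inclusive.  The evaluation
suite is 3%/2 mm, 3%/1 mm, 2%/1 mm and 1%/1 mm, each over the entire
analyzed volume and inside the PTV.

The continuous minimization is discretized: candidate offsets fill the
search ball on a cubic lattice of step DTA/10; the best candidate is then
refined once on a ±DTA/10 local lattice of step DTA/100.  Because
refinement can only lower γ, it is applied where it can change pass/fail
(coarse γ > 1); passing rates are identical to refining everywhere, and
passing voxels carry a coarse γ that is conservative by at most the coarse
quantization.  Voxels whose minimum lies on the search-ball boundary are
flagged: their γ is a lower bound.  The production engine prunes
radius-sorted candidates once the spatial term alone exceeds the running
minimum — a lossless prune, validated voxel-by-voxel against an unpruned
exhaustive search over the same candidate set (agreement to 1e-6).

## Bone volume ratio

BVR = volume of {sCT ≥ 100 HU} ∩ PTV divided by the PTV volume, computed
on the sCT grid (PTV resampled nearest if needed).  The threshold is
configurable; 100 HU matches the skull-bone segmentation above.  No
acceptability cut-off is shipped: sites should calibrate a cut-off against
their own tolerated gamma passing rates.

## Cohort statistics

Paired plan-metric differences use the two-sided Wilcoxon signed-rank test:
exact (full null distribution) for n ≤ 25 with untied non-zero absolute
differences, otherwise a tie-corrected normal approximation with continuity
correction.  Zero differences are dropped before ranking (classical
treatment; Pratt's method selectable).  BVR is correlated against each of
the eight gamma settings with the Pearson test (two-sided t, n − 2 dof).
Raw p-values are reported with a 0.05 significance flag; a Holm-adjusted
column is emitted alongside for transparency but does not drive the flags.
Degenerate inputs (all-zero differences, zero-variance rates) are flagged
rather than tested.

## Synthetic study data

The generator stands in for a 20-patient post-surgical brain cohort that
is not otherwise available, reproducing the *conditions* of such a study:

* **Phantom.** An ellipsoidal head (semi-axes 70 × 88 × 80 mm) with a 4 mm
  scalp, a 6 mm skull shell, a solid bony skull base below z = −55 mm,
  a brain separated from the inner table by a 4 mm CSF gap, five air-filled
  sinus cavities carved into bone, and the standard OARs (brainstem,
  chiasm, optic nerves, lenses, cochleae).  HU: soft tissue 40, brain 35,
  bone 1000, sinus air −990, screws 3000, implant 20.  Planning CT renders
  at 1.2 × 1.2 × 3 mm, sCT at 1.0 × 1.0 × 1.5 mm — the acquisition grids of
  the emulated protocol.  Surgical features: 1–3 drill holes (soft tissue
  in truth), 1–3 metal screws, and optionally a low-density implant plate
  replacing part of the shell.
* **sCT corruption.** The truth CT is resampled to the sCT grid, then:
  Gaussian HU noise inside the body (σ = 17 HU default); spatially
  correlated label flips (a smoothed Gaussian field thresholded at the
  empirical quantile, blob scale ≈ 2.5 mm) inside a ±1.5 mm band around
  bone boundaries, flipping bone→soft and soft/air→bone; and deterministic
  feature mislabeling — drill holes, screws and the implant are painted as
  bone, the characteristic failure of MR-based reconstruction around
  surgical anomalies.  The defaults (flip probability 0.45, shell 1.5 mm)
  were calibrated once so a default phantom lands at the clinically
  reported error levels for this class of sCT: skull-bone MAE ≈ 237 HU,
  body MAE ≈ 110 HU, brain MAE ≈ 10 HU, skull DSC ≈ 0.94.
* **Dose model.** Deliberately not a transport engine.  Parallel axial
  beams (default gantry angles 0/90/180/270°) with the aperture set to the
  PTV projection plus a 5 mm margin; HU → relative electron density via a
  piecewise-linear calibration (−1000→0.001, 0→1.0, 1000→1.6); primary
  dose ∝ exp(−μ_eff × radiological depth) with μ_eff = 0.005/mm; Gaussian
  lateral scatter (σ = 3 mm); dose grid 2.5 mm isotropic; the sum scaled so
  the PTV mean equals the prescription exactly.  In **medium** mode the
  local deposition is additionally multiplied by a factor rising linearly
  from 1.00 at relative electron density 1.05 to 1.11 at 1.6 — the analog
  of dose-to-medium vs dose-to-water reporting, whose difference reaches
  ~11% in cortical bone.  Only the two properties the evaluation needs are
  modeled: dose sensitivity to HU along beam paths, and a reporting-mode
  switch that makes bone (real or mislabeled) run hot.
* **Cohort.** Per case, a target true-bone fraction of the PTV is drawn
  from an even spread over 0.02–0.48 and the PTV (volume ~45–400 cm³,
  shrinking as the bone fraction grows — large targets cannot be half
  bone) is pushed along a seeded direction by bisection until the target
  fraction is met.  Prescriptions are drawn from 40–60 Gy.  The severity
  link sets the interface mislabel probability to 0.08 + 1.4 × bone
  fraction (capped at 0.85), encoding the observation that sCT errors
  concentrate near bone; the case with the highest bone fraction receives
  the implant plate (the worst-case analog).  Everything is deterministic
  under a fixed seed, including per-case sub-seeds.

**What passing tests do and do not show.**  The phantoms exercise every
metric under controlled, analytically known conditions, and the cohort
reproduces the qualitative clinical findings: medium-mode (dose-to-medium)
gamma rates fall below water-mode rates, and BVR correlates strongly and
negatively with the 1%/1 mm PTV rate.  They do not contain real anatomy,
registration error, scanner artifacts, VMAT fluence modulation, or a
transport-grade dose engine, so absolute passing rates and p-values are
properties of the simulation, not clinical estimates.

## Problem sizes and runtime choices

Default study size is 20 cases, matching the emulated cohort.  The
robustness check of the predictor correlation repeats the full
generate-and-evaluate loop over 20 independent cohort seeds.  The gamma
oracle cross-check uses 50 random dose pairs on grids up to 10³ voxels —
large enough to exercise every code path while keeping the exhaustive
search (≈10⁵ candidates per voxel) tractable on one CPU.

## Known limitations

* The dose model's PTV-mean normalization forces the PTV Dmean difference
  between paired plans to zero by construction; Dmean rows in the
  difference table are therefore degenerate for synthetic cohorts (they are
  meaningful for imported file-based dose pairs).
* Water-mode dose differences respond only to attenuation changes along
  beam paths and are typically much smaller than in clinical
  convolution-superposition engines; water-mode passing rates are
  correspondingly optimistic.
* Skull DSC of the calibrated corruption (~0.94) sits slightly above
  clinically reported values (~0.87): the phantom's smooth shell geometry
  offers fewer thin-bone regions to corrupt than real anatomy.
* The bisection placement clamps when a target bone fraction is
  geometrically unreachable for a drawn PTV size/direction; the cohort
  span test guards the realized distribution.
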