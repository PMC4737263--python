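# Methods

## Overview

`svdmap` reproduces, as tested code over synthetic data, a lesion-mapping
analysis for cerebral small vessel disease: per-subject lesion
segmentation, affine normalization of binary masks into a common
template space, voxel-wise probability-density (PD) mapping per lesion
class, regional sampling on a subcortical atlas, and rank-based
comparison of the spatial distributions of the acute symptomatic lesion
(recent small subcortical infarct) against the covert lesions (WMH and
lacunes).

## Synthetic cohort

The generator emulates the *statistical and spatial structure the
analysis assumes*, not MRI physics.

**Template and atlas.** A scaled-down 1-mm isotropic brain: nested
ellipsoids give a cortical grey shell and deep white matter; left/right
lateral ventricles (CSF); left/right caudate, lentiform and thalamic
nuclei (grey); a periventricular rim (the 3-voxel distance shell of the
ventricles); and a left/right deep "tract" — a tube of radius 0.03·nx
around an inferior→superior curve running between the nuclei, standing
in for the corticospinal tract / posterior limb of the internal capsule.
Intensities are per-tissue class means per sequence (FLAIR-like:
CSF 40 < white 100 < grey 120; T1-like: CSF 40 < grey 100 < white 140,
arbitrary units) plus i.i.d. Gaussian noise (default SD 4) inside the
head. The default 64³ grid holds a ≈ 80 ml brain; the geometry is
proportional, not absolute, so ROI and lesion logic carry over.

**Lesions.** Each subject receives exactly one infarct: a sphere of
diameter 6–14 mm (axial-diameter cap 20 mm enforced) centred on a
randomly chosen tract voxel — emulating the concentration of symptomatic
lesions in the motor/sensory pathways. WMH are multifocal unions of
3–9 mm spheres, 1 + Poisson(7) per subject, seeded in the
periventricular rim with probability 0.7 (else anywhere in white
matter); they are FLAIR-hyperintense (mean 200) and slightly T1-hypointense
(mean 90). Lacunes occur in a Bernoulli(0.465) fraction of subjects
(echoing a cohort with 87/187 affected), 1 + Poisson(0.3) per affected
subject, spherical, at CSF intensity on both sequences; planted
diameters are drawn from 4–10 mm inside the detector's 3–15 mm
definition band, clear of ventricles and the brain edge so that a
correct detector can find them. Lesion classes are kept disjoint;
lesions replace tissue intensity with their class mean (no
partial-volume modelling — sufficient for testing threshold and
quantization logic, and a known simplification).

**Misalignment and volumetrics.** Each subject is resampled through a
random small affine — rotations ≤ 5° per axis, translations ≤ 5 mm,
per-axis scales 0.97–1.03 — recorded as the subject's `true_affine`
(the template-world → subject-world pull-back a registration should
recover). Volumetric features (intracranial, brain, ventricular, WMH
volume, ml) are measured from the generated subject-space volumes; the
WMH entry is exactly voxel count × voxel volume. Per-subject RNG
streams are seeded from `(master_seed, subject_index)` so any subject is
reproducible independently of cohort size or generation order.

**What passing tests do not show.** No bias fields, partial volume,
motion or k-space artifacts; one shared modality pair; lesion intensity
distributions are clean Gaussians. Success here demonstrates the
*pipeline logic* (denominators, geometry, determinism, statistics), not
clinical segmentation performance.

## WMH segmentation

Two co-registered sequences are fused into RGB (FLAIR → red, T1 → green,
blue 0), each percentile-clipped and min-max rescaled to [0, 255] over
the brain mask. The clip is wide (0.5/99.9): lesions are often well
under 1% of brain voxels, and a 99th-percentile ceiling would land
inside the grey-matter intensity range and erase the lesion–tissue
contrast the quantizer needs.

Minimum-variance quantization partitions the colour cloud into K
clusters minimising total within-cluster squared distance. It operates
on distinct colours weighted by voxel counts, so cost is independent of
image size. Determinism, with no random initialisation: for small
colour sets (≤ 32 distinct colours and ≤ 4000 K-subsets) Lloyd
refinement is restarted from every K-subset of distinct colours and the
best objective kept — in practice the global optimum; larger clouds use
a divisive scheme (split the largest-SSE cluster along its principal
colour axis at the weighted mean, then refine) with assignment ties
broken to the lowest cluster index and empty clusters re-seeded at the
worst-fit point. Convergence: objective change < 1e-9 or 100
iterations. K defaults to 5 (CSF, grey, white, lesion, mixed/boundary);
clusters are relabelled in increasing centroid-red order for stability.

The WMH class is the cluster(s) whose centroid red (FLAIR-hyperintense
channel) reaches a configurable percentile of centroid reds (default
100: the reddest cluster). Voxels inside the supplied acute-infarct
mask are excluded so the symptomatic lesion, which is delineated
separately, is not counted as WMH. If no cluster passes the rule the
result is an empty mask with a warning, not an error. Known limitation:
when the hyperintense population is tiny *and* noise is high (contrast
to noise ≲ 10 at the defaults' lesion load), the variance budget may not
justify a separate lesion cluster and the reddest cluster degrades to a
tissue cluster; raising K or pre-smoothing the sequences mitigates this.

## Lacune detection

FLAIR is thresholded below a CSF cutoff (midpoint of CSF and grey means
when known, otherwise Otsu over brain voxels; global, not per-slice).
26-connected components are discarded if they overlap the ventricles or
touch the brain-mask boundary (sulcal/peripheral CSF); survivors must
have an equivalent sphere diameter `(6V/π)^(1/3)` within 3–15 mm and
sphericity ≥ 0.3. Sphericity is `π^(1/3)(6V)^(2/3) / A` with `A` the
exposed-voxel-face surface area — a crude digital estimator under which
an ideal digital sphere scores ≈ 0.6–0.7 rather than 1; the 0.3 default
is calibrated to that estimator and simply encodes "round or ovoid".
The 15 mm ceiling is a package convention (the lesion definition is
open-ended above 3 mm); both bounds are parameters.

## Spatial normalization

**Representative subject.** The population-representative brain is the
subject whose four volumetric features are jointly closest to the
component-wise cohort median under the Mahalanobis distance with the
cohort sample covariance (n−1 denominator, raw volumes, ridge
1e-8·trace/4 on the diagonal for conditioning). Ties break to the
lowest index. Even-n medians are the standard lower-midpoint average.

**Registration.** Intensity mean-squared error over a 3-level pyramid
(downsampling factors 4/2/1 after Gaussian smoothing with σ = factor/2),
minimised by Powell's method — deterministic and derivative-free — from
identity, with rotation/scaling parametrised about the fixed-image
centre (translations in mm, rotations in degrees, scales/shears in
percent, so unit steps are commensurate). A 12-dof fit runs a rigid
stage first at the coarsest level. Iteration caps (20/8/2 per level)
put almost all work at coarse levels; the finest level is a short
polish. A fixed-step gradient scheme was tried conceptually and
rejected in favour of Powell: with MSE and this parametrisation the
search is bounded, deterministic and robust across the generator's
transform ranges (median recovery error ≈ 0.1 voxel; the contract is
< 1 voxel). Cost not decreasing over the schedule logs a
registration-quality warning (the transform is still returned); in the
pipeline such subjects are excluded from PD denominators and listed in
the manifest. The cost assumes a shared modality — true for the
synthetic cohort; cross-modal metrics are out of scope.

Transforms are world-to-world pull-back maps (fixed-frame point →
moving-frame point), serialized as plain-text 4×4 matrices, composable,
and used directly for resampling. Masks are resampled trilinearly and
re-binarised at 0.5 — volume-preserving in expectation and exact under
integer-voxel translations.

By default each subject is registered straight to the template (12 dof);
a `two_step` option reproduces the chain subject → representative
(affine) composed with representative → template (rigid), which is how a
real cohort with a study-specific representative brain is processed.
With one shared synthetic modality the two routes coincide up to
optimisation error, so the direct route is the default.

## PD maps, ROIs, subtraction

PD maps are integer count volumes divided by a recorded denominator:
all contributing subjects for infarct and WMH; only subjects with a
non-empty mask for lacunes ("affected-only"), so lacune PDs are not
diluted by lacune-free subjects. Voxel values are exact multiples of
1/N; Σ PD·N equals the total lesioned voxel count exactly.

Regional sampling uses one cubic ROI per atlas structure, 2 voxels
(2 mm) on a side, anchored at the structure's mass centre (snapped into
the structure if the centroid falls outside, clipped in-grid). The ROI
summary is the mean PD over the 8 voxels (max available by flag) — a
"2-mm ROI" by the cube-side reading, since a literal 2 mm³ region is
sub-resolution at 1 mm sampling. Reported tables are rounded half-up to
3 decimals; full precision is kept internally.

Subtraction maps are voxel-wise differences of two group PD maps, with
an overlap summary: the fraction of voxels positive in both maps among
voxels positive in either (NaN when neither has support).

## Regional statistics

Friedman's two-way ANOVA by ranks with midranks within blocks and the
standard tie-corrected statistic

    χ²_F = (k−1) Σ_j (R_j − n(k+1)/2)² / (Σ_ij r_ij² − nk(k+1)²/4),

df = k−1. Blocks are regions; treatments are lesion classes; left and
right values of paired regions are averaged into one block by default
(keeping sides as separate blocks is an option — the blocking is a
package choice, made explicit rather than implicit). The p-value is an
exact permutation p (all within-block orderings, enumerated as a
distribution over column-sum vectors) whenever (k!)ⁿ ≤ 2×10⁶, else the
χ² asymptotic; the reported method is always labelled. All-constant
data yield statistic 0 with a degenerate-data warning. The pipeline
emits the two planned comparisons (infarct vs WMH, infarct vs lacune);
no multiplicity correction is applied, matching the single-planned-
comparison design.

## Reproducibility

Every stage is deterministic given the configuration and master seed;
per-subject streams are hashed from `(seed, index)`. The run manifest
echoes config, seeds and versions and certifies outputs with SHA-256
hashes of array content (shape + dtype + bytes), deliberately not of
container files, so compression timestamps cannot break the
identical-config ⇒ identical-hash contract. Demo problem sizes
(12 subjects at 48³ for the end-to-end run, 64³ for single-subject
fixtures, 20 subjects for registration validation, 500 small-grid
subjects for the prevalence check) were chosen to keep the full chain
in the minutes range on a single CPU while leaving every contract
non-trivially exercised.

## Known limitations

- Affine-only normalization; no nonlinear refinement, skull stripping
  or cross-modal cost.
- The quantizer's cluster budget can starve tiny lesion loads at high
  noise (see above).
- The sphericity estimator is biased low on digital spheres; thresholds
  are calibrated to it, not to analytic sphericity.
- Synthetic lesion placement weights (WMH periventricular fraction,
  counts, diameters) are plausible free parameters, not estimates of
  any real cohort.
- The lacune "affected-only" denominator makes lacune PDs incomparable
  to the other classes' PDs in absolute terms; the rank-based regional
  comparison is unaffected by such monotone rescaling.
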