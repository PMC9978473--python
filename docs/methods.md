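# Methods

## The level model

Head-and-neck nodal clinical target volumes are assembled from 20 lymph
node levels: the midline levels Ia, VIa, VIb and VIIa and the bilateral
levels Ib, II, III, IVa, IVb, V, VIIb and VIII, giving 21 prediction
classes including background. The package encodes this as a taxonomy:
`(name, label value, laterality)` entries, left/right mirror pairs, and
*exclusivity chains* — ordered cranial→caudal lists of levels that are by
definition stacked on top of each other and therefore mutually exclusive on
any single CT slice. The shipped default maps the levels to contiguous
labels 1–20 (background 0), pairs each left level with its right
counterpart, and declares one chain per side, II → III → IVa → IVb. The
exact set of craniocaudally adjacent level pairs is a clinical convention
rather than a published constant, so the chains are plain data in the
taxonomy JSON and fully user-configurable; everything downstream consumes
whatever chains the taxonomy declares.

Volumes carry their voxel spacing in mm and two axis conventions: the slice
axis (cranial→caudal with increasing index, default: last array axis) and
the left-right axis (default: first). Coordinates are 0-based voxel
indices; physical distances always go through the spacing. Spacing is held
at 32-bit float precision, which is the precision of the NIfTI-1 header, so
write-then-read round trips are bitwise exact on both NIfTI (via nibabel)
and NRRD (via SimpleITK).

## Slice-plane adjustment

Raw 3D CNN predictions violate slice-plane consistency near level
interfaces: a slice near the II/III boundary typically contains voxels of
both. The adjustment runs in two steps, conflict resolution then boundary
trimming; the order is fixed for reproducibility (resolution only relabels
foreground, so it does not change the per-slice foreground counts that
trimming inspects — either order yields the same trim decisions).

**Conflict resolution.** Slice by slice, cranial to caudal: if two or more
members of one chain co-occur on a slice, the member covering the most
voxels on that slice wins and the others' voxels are relabeled to it.
"Area" is voxel count per slice; with uniform in-plane spacing this is
equivalent to physical mm². Equal counts go to the more cranial chain
member — a deterministic tie-break independent of label numbering. The
operation conserves total foreground and touches nothing outside the
conflicting chain members on the conflicting slices.

**Boundary trimming.** Per-slice foreground counts are taken on the input.
Working inward from each end of the foreground extent, a slice is cleared
to background when (a) its count is at most `min_foreground_voxels`
(default 10), or (b) its count is at most `1 − drop_fraction` (default
0.8, i.e. a drop of 80% or more) times the count of its neighbour towards
the volume centre, while every slice further out is already background.
The run stops at the first slice that triggers neither rule; interior
slices are never modified, because the rule exists to regularize the
cranial boundary of the topmost and the caudal boundary of the bottommost
levels, not to punch holes mid-structure. Evaluating the "outward is
empty" condition on the working state (slices cleared earlier in the same
run count as empty) makes the composed operation idempotent in general —
with a strictly input-state reading, a steep interior slope could be
trimmed only on a second application, which would make the postprocessing
depend on how often it is run. The ≥-boundary of the drop rule ("80% or
more") is guarded with a 1e-9 epsilon because 0.2 is not representable in
binary floating point.

**Component cleanup.** Nodal levels are single connected structures, so for
each class all but the largest 26-connected 3D component are set to
background. A size tie keeps the component containing the lexicographically
smallest voxel index (C order) — deterministic and orientation-independent
at phantom scale. 26-connectivity is the most permissive standard choice
and matches common segmentation-cleanup practice.

## Mirroring augmentation

Left-right mirroring is performed offline (one new file per training
sample) because pipelines that mirror on the fly cannot swap label values:
a flipped left level II is anatomically a right level II. The operation
reverses the array along the left-right axis and applies the taxonomy's
mirror permutation to label values; midline labels and background are fixed
points. It is an involution, conserves per-class counts under the
left↔right permutation, and leaves the slice-inconsistency count invariant
(chains come in mirror-symmetric pairs). The affine/header of the mirrored
file is left unchanged: the output is a training sample, not a clinically
oriented image — this is stated here deliberately because silently flipped
orientation metadata is a classic failure mode.

## Foreground masking

The body mask is computed as: clip intensities to the
`[p, 1−p]` percentile range (`p = otsu_percentile_threshold`, default
0.01); compute the Otsu threshold over a 256-bin histogram; multiply it by
`threshold_correction_factor` (default 0.3) — the multiplicative reading
pulls the cut towards the low end so faint tissue survives; binarize; close
with a cubic element of width `closing_size` (default 9); keep the largest
26-connected component (this is the step that actually discards detached
mask/holder fragments, which typically lie *above* the corrected
threshold); dilate by `dilate_size` (default 2, 26-neighbourhood
iterations, i.e. Chebyshev radius). This is a documented re-implementation
of the ROIAuto-style procedure with its conventional parameter names and
defaults; voxel-level agreement with any particular GUI implementation is
out of scope. The mask is a single connected component before dilation, and
dilation is monotone in its radius — both are tested properties. Constant
input is rejected as degenerate rather than silently thresholded.

## Geometric metrics

Volumetric Dice is `2|A∩B|/(|A|+|B|)` over voxel sets. Surface Dice at
tolerance τ is `(|{a ∈ ∂A : d(a, ∂B) ≤ τ}| + |{b ∈ ∂B : d(b, ∂A) ≤ τ}|) /
(|∂A| + |∂B|)`; maximum Hausdorff distance is
`max(max_a d(a, ∂B), max_b d(b, ∂A))` in mm. Surfaces are boundary voxels
(mask minus its 6-connected erosion, with the grid border counting as
outside) and distances are Euclidean distances between boundary-voxel
centers under the physical spacing, computed with exact Euclidean distance
transforms. The voxel-center approximation weights every boundary voxel
equally rather than by surfel area, which is the comparability caveat
against surfel-area implementations; the distances themselves are exact and
the package's values agree with brute-force pairwise enumeration on small
grids to machine precision (tested). Distances exactly equal to the
tolerance are matched, with a 1e-7 relative epsilon: under the one-voxel
rule a one-voxel shift produces distances exactly equal to a spacing
component, and float rounding must not drop them.

The "one voxel" tolerance under anisotropic spacing is resolved as the
**maximum** spacing component (3.0 mm for 1.14 × 1.14 × 3 mm voxels), so a
one-voxel shift along any axis is within tolerance; an explicit tolerance
in mm is available when a different convention is needed. Empty-vs-nonempty
Dice is 0 (an absent level is a real error); empty-vs-empty is undefined
and excluded from case means (a level absent from both volumes carries no
information and must not inflate the mean). Hausdorff is undefined when
either mask is empty. Union metrics pool all selected levels into one
binary mask — the union view approximates a nodal CTV, where boundaries
between individual levels are irrelevant. This produces the central
dissociation the toolkit demonstrates at phantom scale: corruption that
only swaps labels across level interfaces leaves the union mask bitwise
unchanged (union Dice exactly 1.0, Hausdorff 0.0) while per-level Dice
degrades, and slice-plane adjustment changes the label map visibly while
moving mean per-level Dice by ≲ 0.01 — overlap metrics are nearly blind to
the consistency property.

## Statistics

Case-level contour comparisons are paired (same cases, two conditions) with
small n, so the protocol is nonparametric throughout.

- **Signed-rank test**: differences of zero are dropped (Wilcoxon's
  convention, matching common package defaults); absolute differences are
  midranked; the reported statistic is W⁺ − W⁻ (antisymmetric under
  condition swap). For n ≤ 25 effective pairs the null distribution of W⁺
  is enumerated exactly by a shift-polynomial convolution over doubled
  midranks (doubling makes tied half-ranks integral), so ties are handled
  exactly rather than approximately; two-sided p = 2·min(P(≤), P(≥)) capped
  at 1. Beyond 25, a normal approximation with the standard tie correction
  (−Σ(t³−t)/48 on the variance) is used. The exact path agrees with full
  2ⁿ sign enumeration for all n ≤ 12 and with scipy's exact method on
  tie-free samples (tested), and its empirical type-I error at α = 0.05
  under a simulated null (n = 20) is ≈ 0.046 — the attainable size of the
  discrete test just below 0.05.
- **Rank-sum test**: delegated to `scipy.stats.mannwhitneyu` (exact for
  tie-free samples with m + n ≤ 20, tie-corrected asymptotic otherwise);
  the statistic is re-expressed as the classic rank sum W = U + m(m+1)/2.
- **Paired dispersion test**: the cited paired Levene / extended
  Brown-Forsythe approach is not specified by a formula in the source
  literature available here, so the package adopts one published reading:
  per-case absolute deviations from each condition's median are formed and
  their paired differences tested with the signed-rank procedure; the
  reported statistic is the mean deviation difference. A pure location
  shift yields identical deviations and a degenerate p = 1, which is the
  defining sanity property of any dispersion-only test.
- No multiple-testing correction is applied; p-values are reported
  unadjusted and conventionally compared against 0.05.

**Blinded manifests.** Each rater receives every (case, contour set)
combination exactly once in an independently shuffled order; contour-set
identities are replaced by neutral aliases (the alias key stays with the
study coordinator). Ratings use a continuous 0–100 scale with four guidance
categories (0–25 complete recontouring, 26–50 major editing, 51–75 minor
editing, >75 clinically usable). With 3 raters, 20 cases, 20 levels and 3
contour sets the design yields 3600 rating slots. Summaries use case-level
mean ratings as the unit of analysis (mean/median/IQR across cases per
set), with pairwise signed-rank comparisons between sets.

## Synthetic phantom

The phantom reproduces the *data regime*, not the anatomy: anisotropic
voxels (default 1.14 × 1.14 × 3 mm — typical planning-CT pixel spacing and
slice thickness), a craniocaudal stack of level structures, and the three
defect classes that slice-plane postprocessing targets. Geometry: two
lateral columns of stacked elliptical slabs following each side's chain
(II → III → IVa → IVb) plus a midline column holding the four midline
levels, mirror-symmetric by construction so the label-swapping mirror maps
the ground truth onto itself. Defaults: 12 slices (36 mm) per level —
a realistic craniocaudal level extent at 3 mm slices — and ~150 in-plane
voxels per slab slice, safely above the 10-voxel trimming threshold.

Corruption defaults model moderate network misbehaviour: boundary jitter
probability 0.15 (that fraction of voxels on each side of every within-chain
interface flips to the adjacent level, so defects concentrate on the 2
slices around each interface), 2 spurious islands of 4 voxels placed in
background at least 4 voxels (Chebyshev) from any structure and inside the
foreground slice range, and 2 fringe slices of 6 voxels beyond each
craniocaudal end, sampled from the footprint of the adjacent true end
slice. Jitter only relabels foreground (never touches background), which is
what makes the union-Dice invariance exact. Because the jitter probability
is below 0.5, the per-slice majority is expected to remain the true level,
so adjustment restores the interface; islands land either as isolated
components (removed by the component cleanup) or as within-chain conflicts
(absorbed by resolution, then removed); fringe counts sit at or below the
10-voxel rule. Fringe/island-only corruption is therefore *exactly*
invertible by adjust + largest-component — the recovery property the test
suite asserts bitwise.

What the phantom does **not** emulate: real CNN error structure (spatially
correlated, intensity-driven), inter-level boundary ambiguity in soft
tissue, contrast effects, patient-to-patient anatomical variation, or
imperfect ground truth. Passing the phantom suites shows the algorithms
implement their specified behaviour exactly; it does not certify clinical
accuracy numbers, which require a trained model and clinical data.

The intensity phantom is a bright body ellipsoid (~1000, arbitrary
nonnegative units, not HU) on a dark noisy background with a thin detached
dorsal plate (~300) imitating an immobilization-mask holder; the gap
between plate and body exceeds the default closing width so the
largest-component step, not the threshold, is what removes it — the same
division of labour as on real data.

## Numerical choices and degenerate inputs

- Exact-boundary guards: 1e-9 absolute on the 80%-drop rule, 1e-7 relative
  on the surface-Dice tolerance; both protect decisions made exactly at a
  threshold from binary rounding, and both are orders of magnitude below
  any physically meaningful difference.
- Ties: per-slice conflict ties go to the more cranial level; component
  size ties to the lexicographically first component; midranks in the
  signed-rank test are exact via rank doubling.
- Degenerate inputs raise typed errors rather than returning silently:
  constant intensities (Otsu), all-zero paired differences (flagged
  degenerate with p = 1), empty masks (undefined metrics as `None`).
- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator output is bitwise reproducible from its spec + seed.

## Problem sizes

The default phantom grid is 64 × 44 × 56 voxels (≈160k voxels, ≈170 mm
craniocaudal extent), chosen so property suites over tens of seeded
phantoms and the 10,000-replicate signed-rank calibration complete in
seconds while every structure stays comfortably above the algorithmic
thresholds being exercised. Metric oracle tests use 7 × 6 × 5 grids where
exhaustive pairwise surface-distance enumeration is feasible.

## Known limitations

- The exclusivity-chain default covers only the II–IV chains per side;
  institutions that treat further level pairs as craniocaudally exclusive
  must extend the taxonomy JSON (supported, tested path).
- Surface metrics use the voxel-center approximation (see above); absolute
  surface-Dice values are comparable between candidates evaluated with this
  package but may differ in the second decimal from surfel-area
  implementations.
- The dispersion test is one defensible formulation of a paired robust
  dispersion comparison, not the only one.
- No DICOM / DICOM-RT support; convert to NIfTI or NRRD first.
- The foreground masking approximates, but does not bit-match, GUI
  implementations of the same parameterized procedure.
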