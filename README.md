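# levelpost

A post-model toolkit for deep-learning autosegmentation of head-and-neck
lymph node levels on planning CT. Neural networks segment the 20 nodal
levels (midline Ia, VIa, VIb, VIIa and bilateral Ib, II, III, IVa, IVb, V,
VIIb, VIII; 21 classes with background) well in bulk-overlap terms, but
their raw 3D predictions violate a convention that radiation oncologists
apply strictly: craniocaudally adjacent levels (e.g. level II above level
III) must meet exactly *between* CT slices, never mix on one slice.
`levelpost` provides everything around the network needed to train,
postprocess and evaluate such models without shipping the network itself:

- **Slice-plane adjustment postprocessing** — on every CT slice, mutually
  exclusive levels from the same craniocaudal chain are resolved in favour
  of the level predicted for the most voxels; cranial/caudal fringe slices
  with ≤ 10 foreground voxels, or whose foreground count dropped by ≥ 80%
  relative to the neighbouring slice towards the volume centre while
  everything further out is background, are cleared. Plus the standard
  largest-connected-component cleanup (levels are single structures).
- **Mirroring augmentation with label adaption** — offline left-right
  flipping that simultaneously swaps left/right level labels so anatomical
  sidedness stays correct (plain mirroring would mislabel every lateral level).
- **Foreground masking** — percentile clip → Otsu threshold × correction
  factor → morphological closing → largest component → dilation, with the
  conventional parameters (`otsuPercentileThreshold 0.01`,
  `thresholdCorrectionFactor 0.3`, `closingSize 9`, `ROIAutoDilateSize 2`),
  removing immobilization-mask remnants from the CT.
- **Geometric metrics** — per-level and union volumetric Dice
  `2|A∩B|/(|A|+|B|)`, surface Dice at one-voxel tolerance, and maximum
  Hausdorff distance in mm, on anisotropic voxel grids.
- **Statistics** — paired Wilcoxon signed-rank (exact null enumeration up to
  n = 25, midranks included), Wilcoxon rank-sum, a paired robust dispersion
  test, and summaries of 0–100 expert ratings.
- **Blinded-evaluation design** — seeded, per-rater randomized presentation
  manifests with aliased contour sets.
- **Synthetic phantom** — seeded ground-truth level maps plus corrupted
  "raw prediction" maps with exactly the defect classes the postprocessing
  targets (cross-boundary jitter, spurious islands, low-count fringe
  slices), and CT-like intensity phantoms for the masking pipeline. The
  whole toolkit is testable end to end without clinical data.

I/O covers NIfTI (`.nii`, `.nii.gz`) and NRRD label/intensity volumes with
voxel spacing; a JSON taxonomy file defines level names, label values,
lateralities, mirror pairs and exclusivity chains (a validated 20-level
default ships with the package).

## Worked example

```python
import levelpost as lp

tax = lp.load_taxonomy()                      # shipped 20-level taxonomy
spec = lp.PhantomSpec(seed=1)                 # 1.14 x 1.14 x 3 mm voxels
gt = lp.generate_ground_truth(spec, tax)      # slice-plane consistent
pred = lp.corrupt(gt, lp.CorruptionSpec(seed=2), tax)   # jitter + islands + fringe

print(lp.count_slice_inconsistencies(pred, tax))        # 14
adjusted, report = lp.slice_plane_adjust(pred, tax)
cleaned = lp.keep_largest_component(adjusted, tax)
print(report.relabeled_voxels, report.trimmed_slices)   # 315 4
print(lp.count_slice_inconsistencies(cleaned, tax))     # 0

raw = lp.evaluate_pair(pred, gt, tax)
fixed = lp.evaluate_pair(cleaned, gt, tax)
print(round(raw.case_mean_volumetric_dice, 3))          # 0.986
print(round(raw.union.volumetric_dice, 3))              # 0.999
print(fixed.case_mean_volumetric_dice)                  # 1.0
```

The corrupted prediction has 14 slices where two craniocaudally exclusive
levels co-occur; adjustment relabels 315 voxels and trims 4 fringe slices,
after which the phantom ground truth is recovered exactly. Note the
dissociation the toolkit is built to expose: the raw prediction's *union*
Dice (0.999) barely registers defects that per-slice consistency checking
sees immediately — bulk-overlap metrics are nearly blind to the slice-plane
property that raters care about.

The same operations are available from a shell:

```
levelpost phantom --out-dir demo --seed 1 --corrupt jitter=0.3,islands=2,fringe=2
levelpost adjust demo/pred.nii.gz demo/fixed.nii.gz --largest-component --report report.json
levelpost evaluate demo/fixed.nii.gz demo/gt.nii.gz --out metrics.csv
levelpost mirror demo/gt.nii.gz demo/gt_mirrored.nii.gz
levelpost mask-foreground demo/ct.nii.gz demo/mask.nii.gz
levelpost manifest --cases c1,c2 --sets expert,dl --raters 3 --seed 7 --out manifest.csv
```

## Layout

- `src/levelpost/taxonomy.py`, `volume.py` — level model, containers, I/O
- `src/levelpost/postproc.py` — slice-plane adjustment, component cleanup
- `src/levelpost/augment.py` — label-aware mirroring
- `src/levelpost/preprocess.py` — foreground masking, cropping
- `src/levelpost/metrics.py` — Dice / surface Dice / Hausdorff
- `src/levelpost/stats.py` — paired tests, manifests, rating summaries
- `src/levelpost/phantom.py` — synthetic data
- `src/levelpost/cli.py` — `levelpost` entry point
- `docs/methods.md` — models, parameters, numerical choices, limitations
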