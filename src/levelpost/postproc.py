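"""CT slice-plane adjustment postprocessing and connected-component cleanup.

Lymph node level boundaries are defined not only by anatomical landmarks but
by the orientation of the CT slice planes: craniocaudally adjacent levels
(e.g. II above III) must meet exactly between slices, so no single slice may
contain voxels of two levels from the same craniocaudal chain. A 3D
segmentation model does not know this, and its raw predictions typically
violate it near level interfaces.

``slice_plane_adjust`` enforces the property in two steps:

1. ``resolve_slice_conflicts`` — slice by slice (cranial to caudal), if two
   or more members of one exclusivity chain co-occur, the member predicted
   for the most voxels on that slice wins and the others are relabeled to it.
   This only relabels foreground voxels; the total foreground count is
   conserved.
2. ``trim_boundary_slices`` — cranial and caudal fringe slices with at most
   ``min_foreground_voxels`` foreground voxels (default 10), or whose
   foreground count dropped by at least ``drop_fraction`` (default 80%)
   relative to their inner neighbour while everything further out is already
   background, are replaced entirely by background. Trimming works inward
   from both ends of the foreground extent and never touches interior
   slices.

``keep_largest_component`` implements the standard connected-component
cleanup: levels are by definition single connected structures, so for each
class only the largest 26-connected 3D component keeps its label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .taxonomy import LevelTaxonomy
from .volume import LabelVolume

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class AdjustmentParams:
    """Thresholds governing boundary-slice trimming.

    min_foreground_voxels: a boundary slice with this many or fewer
    foreground voxels becomes background (default 10).
    drop_fraction: a boundary slice whose foreground count fell by at least
    this fraction relative to its inner neighbour (and with only background
    further out) becomes background (default 0.8).
    """

    min_foreground_voxels: int = 10
    drop_fraction: float = 0.8
    apply_boundary_trim: bool = True

    def __post_init__(self) -> None:
        if self.min_foreground_voxels < 0:
            raise ValidationError("min_foreground_voxels must be >= 0")
        if not (0.0 < self.drop_fraction <= 1.0):
            raise ValidationError("drop_fraction must be in (0, 1]")


@dataclass(frozen=True)
class AdjustmentReport:
    """Bookkeeping from one slice-plane adjustment run."""

    relabeled_voxels: int
    trimmed_slices: int
    conflicts_before: int


def _slices_iter(arr: np.ndarray, axis: int):
    """Yield (index, 2D slice view) along ``axis``, cranial to caudal."""
    moved = np.moveaxis(arr, axis, 0)
    for k in range(moved.shape[0]):
        yield k, moved[k]


def resolve_slice_conflicts(
    volume: LabelVolume, taxonomy: LevelTaxonomy
) -> tuple[LabelVolume, int]:
    """Resolve within-chain label co-occurrence on every CT slice.

    Returns the adjusted volume and the number of voxels relabeled. For each
    slice and chain, the chain member covering the most voxels on that slice
    absorbs the voxels of all other members present there. Equal counts are
    broken in favour of the more cranial chain member, which makes the
    outcome deterministic and independent of label numbering.
    """
    volume.validate(taxonomy)
    out = volume.array.copy()
    chains = taxonomy.chains_as_labels()
    relabeled = 0
    for _, sl in _slices_iter(out, volume.slice_axis):
        for chain in chains:
            counts = [(int(np.count_nonzero(sl == lab)), lab) for lab in chain]
            present = [(c, lab) for c, lab in counts if c > 0]
            if len(present) < 2:
                continue
            # max count; ties go to the member earliest in the chain, i.e.
            # the more cranial level
            winner = max(present, key=lambda cl: cl[0])[1]
            for c, lab in present:
                if lab != winner:
                    sl[sl == lab] = winner
                    relabeled += c
    return volume.with_array(out), relabeled


def trim_boundary_slices(
    volume: LabelVolume, params: AdjustmentParams | None = None
) -> tuple[LabelVolume, int]:
    """Replace low-count cranial/caudal boundary slices by background.

    Returns the trimmed volume and the number of slices set to background.
    Working inward from each end of the foreground extent, a slice is
    cleared when (a) its foreground count is at most
    ``min_foreground_voxels``, or (b) its count is at most
    ``(1 - drop_fraction)`` times the count of its inner neighbour and every
    slice further out is already background. The run stops at the first
    slice that triggers neither rule; interior slices are never modified.
    """
    params = params or AdjustmentParams()
    arr = volume.array
    axis = volume.slice_axis
    bg = 0
    counts = np.count_nonzero(np.moveaxis(arr != bg, axis, 0), axis=(1, 2))
    fg = np.flatnonzero(counts)
    if fg.size == 0:
        return volume, 0

    lo, hi = int(fg[0]), int(fg[-1])
    n = counts.size
    # "dropped by >= drop_fraction" includes the exact boundary (e.g. 100 ->
    # 20 at 0.8); epsilon guards the inexact binary representation of the
    # fraction
    keep_drop = (1.0 - params.drop_fraction) + 1e-9
    trimmed: set[int] = set()

    def run(indices: list[int], inner_of) -> None:
        # every slice outward of s is background: either beyond the original
        # foreground extent or trimmed earlier in this run (we stop at the
        # first kept slice, so the run is always contiguous from the end)
        for s in indices:
            inner = inner_of(s)
            small = counts[s] <= params.min_foreground_voxels
            dropped = (
                0 <= inner < n
                and counts[inner] > 0
                and counts[s] <= keep_drop * counts[inner]
            )
            if small or dropped:
                trimmed.add(s)
            else:
                break

    run(list(range(lo, hi + 1)), lambda s: s + 1)  # cranial end, inward
    run(list(range(hi, lo - 1, -1)), lambda s: s - 1)  # caudal end, inward

    if not trimmed:
        return volume, 0
    out = arr.copy()
    moved = np.moveaxis(out, axis, 0)
    for s in trimmed:
        moved[s] = bg
    return volume.with_array(out), len(trimmed)


def slice_plane_adjust(
    volume: LabelVolume,
    taxonomy: LevelTaxonomy,
    params: AdjustmentParams | None = None,
) -> tuple[LabelVolume, AdjustmentReport]:
    """Full slice-plane adjustment: conflict resolution, then boundary trimming.

    The composed operation is idempotent and leaves a volume with zero
    within-chain slice inconsistencies.
    """
    params = params or AdjustmentParams()
    conflicts = count_slice_inconsistencies(volume, taxonomy)
    resolved, relabeled = resolve_slice_conflicts(volume, taxonomy)
    if params.apply_boundary_trim:
        trimmed_vol, n_trimmed = trim_boundary_slices(resolved, params)
    else:
        trimmed_vol, n_trimmed = resolved, 0
    return trimmed_vol, AdjustmentReport(
        relabeled_voxels=relabeled, trimmed_slices=n_trimmed, conflicts_before=conflicts
    )


def count_slice_inconsistencies(volume: LabelVolume, taxonomy: LevelTaxonomy) -> int:
    """Number of (slice, chain) pairs where two or more chain members co-occur.

    Zero if and only if the volume is slice-plane consistent with respect to
    the taxonomy's exclusivity chains.
    """
    chains = taxonomy.chains_as_labels()
    total = 0
    for _, sl in _slices_iter(volume.array, volume.slice_axis):
        present = set(np.unique(sl))
        for chain in chains:
            if len(present.intersection(chain)) >= 2:
                total += 1
    return total


def keep_largest_component(
    volume: LabelVolume,
    taxonomy: LevelTaxonomy,
    classes: list[str] | None = None,
) -> LabelVolume:
    """For each class keep only the largest 26-connected 3D component.

    Other components of that class become background. A size tie is broken
    by the component containing the lexicographically smallest voxel index.
    ``classes`` selects a subset of level names; default is all levels.
    """
    volume.validate(taxonomy)
    names = classes if classes is not None else list(taxonomy.names)
    labels = [taxonomy.label_for(nm) for nm in names]
    out = volume.array.copy()
    for lab in labels:
        mask = out == lab
        if not mask.any():
            continue
        comp, n = ndimage.label(mask, structure=_CONN26)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        best_size = sizes.max()
        candidates = np.flatnonzero(sizes == best_size) + 1
        if len(candidates) == 1:
            keep = int(candidates[0])
        else:
            # tie: keep the component whose smallest voxel index comes first
            # in C order (lexicographic over (axis0, axis1, axis2))
            flat = comp.ravel(order="C")
            first_index = {
                int(c): int(np.flatnonzero(flat == c)[0]) for c in candidates
            }
            keep = min(first_index, key=first_index.get)
        out[mask & (comp != keep)] = taxonomy.background_value
    return volume.with_array(out)
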