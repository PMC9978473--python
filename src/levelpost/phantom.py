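"""Synthetic neck phantom: ground-truth level maps, corrupted "raw
prediction" maps, and CT-like intensity volumes.

The phantom emulates the data regime of planning CT for head-and-neck nodal
levels — anisotropic voxels (default 1.14 x 1.14 mm in-plane, 3 mm slices)
and a craniocaudal stack of level structures — without any anatomical
realism. It consists of two lateral columns (patient left and right) of
stacked elliptical slabs following each side's exclusivity chain cranial to
caudal (II, III, IVa, IVb), plus an optional midline column of the midline
levels (Ia, VIa, VIb, VIIa). The construction is mirror-symmetric, so the
label-swapping mirror augmentation maps the ground truth onto itself, and
slice-plane consistent by construction.

``corrupt`` injects exactly the defect classes the postprocessing targets:

- boundary jitter: on the two slices either side of each within-chain level
  interface, voxels flip to the adjacent chain member with a given
  probability, producing within-chain co-occurrence on those slices;
- spurious islands: small isolated components of a level's label placed in
  background away from the true structures;
- fringe slices: a few slices beyond the cranial/caudal foreground ends
  containing only a handful of foreground voxels (the <= 10-voxel defect
  that boundary trimming removes).

All generation is seed-deterministic: identical spec + seed give bitwise
identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .taxonomy import LevelTaxonomy
from .volume import IntensityVolume, LabelVolume

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic neck phantom.

    Defaults give three non-overlapping columns (left, midline, right) of
    elliptical slabs with ~150 in-plane voxels per level slice and 12 slices
    (36 mm) per level.
    """

    grid_shape: tuple[int, int, int] = (64, 44, 56)
    spacing: tuple[float, float, float] = (1.14, 1.14, 3.0)
    slices_per_level: int = 12
    inplane_radius_voxels: int = 7
    lateral_offset_voxels: int = 16
    midline_levels_present: bool = True
    cranial_margin_slices: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slices_per_level < 2:
            raise ValidationError("slices_per_level must be >= 2")
        if any(n < 8 for n in self.grid_shape):
            raise ValidationError("grid_shape axes must be >= 8")


@dataclass(frozen=True)
class CorruptionSpec:
    """Parameters of the synthetic defect model applied to a ground truth."""

    boundary_jitter_prob: float = 0.15
    island_count: int = 2
    island_size_voxels: int = 4
    fringe_slices: int = 2
    fringe_voxels: int = 6
    island_level: str | None = None  # default: seeded choice among present levels
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.boundary_jitter_prob <= 1.0):
            raise ValidationError("boundary_jitter_prob must be in [0, 1]")
        for nm in ("island_count", "island_size_voxels", "fringe_slices", "fringe_voxels"):
            if getattr(self, nm) < 0:
                raise ValidationError(f"{nm} must be >= 0")


def _ellipse_mask(nx: int, ny: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return ((ii - cx) / rx) ** 2 + ((jj - cy) / ry) ** 2 <= 1.0


def generate_ground_truth(spec: PhantomSpec, taxonomy: LevelTaxonomy) -> LabelVolume:
    """Build the slice-plane-consistent ground-truth label volume.

    Axis convention: axis 0 is left-right (increasing index = patient left),
    axis 2 is the slice axis (cranial to caudal).
    """
    nx, ny, nz = spec.grid_shape
    r = spec.inplane_radius_voxels
    off = spec.lateral_offset_voxels
    cx_mid = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    if cx_mid + off + r >= nx - 1 or cx_mid - off - r <= 0:
        raise ValidationError("lateral columns exceed the grid; enlarge grid_shape")
    if off <= 2 * r:
        raise ValidationError("lateral_offset_voxels too small; columns would overlap")

    chains = taxonomy.chains_as_labels()
    left_chain = right_chain = None
    for chain, names in zip(chains, taxonomy.exclusivity_chains):
        lat = {taxonomy.entry(nm).laterality for nm in names}
        if lat == {"left"}:
            left_chain = chain
        elif lat == {"right"}:
            right_chain = chain
    if left_chain is None or right_chain is None:
        raise ValidationError("taxonomy must declare one all-left and one all-right chain")

    n_levels = len(left_chain)
    span = n_levels * spec.slices_per_level
    z0 = spec.cranial_margin_slices
    if z0 + span + spec.cranial_margin_slices > nz:
        raise ValidationError("level stack exceeds the grid along the slice axis")

    midline_labels = [
        e.label_value for e in taxonomy.entries if e.laterality == "midline"
    ] if spec.midline_levels_present else []
    # midline levels share the same craniocaudal span, split evenly
    mid_slabs: list[tuple[int, int, int]] = []
    if midline_labels:
        per = span // len(midline_labels)
        for k, lab in enumerate(midline_labels):
            top = z0 + k * per
            bottom = z0 + (k + 1) * per if k < len(midline_labels) - 1 else z0 + span
            mid_slabs.append((lab, top, bottom))

    arr = np.zeros(spec.grid_shape, dtype=np.int16)
    ell_left = _ellipse_mask(nx, ny, cx_mid + off, cy, r, r)
    ell_right = _ellipse_mask(nx, ny, cx_mid - off, cy, r, r)
    ell_mid = _ellipse_mask(nx, ny, cx_mid, cy, r, r)

    for k in range(n_levels):
        zs = slice(z0 + k * spec.slices_per_level, z0 + (k + 1) * spec.slices_per_level)
        arr[:, :, zs][ell_left] = left_chain[k]
        arr[:, :, zs][ell_right] = right_chain[k]
    for lab, top, bottom in mid_slabs:
        arr[:, :, top:bottom][ell_mid] = lab

    return LabelVolume(arr, spec.spacing, slice_axis=2, lr_axis=0)


def _level_slice_range(arr: np.ndarray, label: int, axis: int) -> tuple[int, int] | None:
    present = np.flatnonzero(np.moveaxis(arr == label, axis, 0).any(axis=(1, 2)))
    if present.size == 0:
        return None
    return int(present[0]), int(present[-1])


def corrupt(gt: LabelVolume, cspec: CorruptionSpec, taxonomy: LevelTaxonomy) -> LabelVolume:
    """Apply the seeded corruption model to a ground-truth volume."""
    gt.validate(taxonomy)
    rng = np.random.default_rng(cspec.seed)
    arr = gt.array.copy()
    axis = gt.slice_axis
    moved = np.moveaxis(arr, axis, 0)  # view; slices index first

    # --- boundary jitter across within-chain interfaces
    if cspec.boundary_jitter_prob > 0:
        for chain in taxonomy.chains_as_labels():
            for upper, lower in zip(chain[:-1], chain[1:]):
                ru = _level_slice_range(arr, upper, axis)
                rl = _level_slice_range(arr, lower, axis)
                if ru is None or rl is None or rl[0] != ru[1] + 1:
                    continue
                for s, src, dst in ((ru[1], upper, lower), (rl[0], lower, upper)):
                    sl = moved[s]
                    sel = sl == src
                    flips = sel & (rng.random(sl.shape) < cspec.boundary_jitter_prob)
                    sl[flips] = dst

    fg_slices = np.flatnonzero((moved != 0).any(axis=(1, 2)))
    lo, hi = int(fg_slices[0]), int(fg_slices[-1])

    # --- spurious islands in background, away from true structures
    if cspec.island_count > 0 and cspec.island_size_voxels > 0:
        present = sorted(int(v) for v in np.unique(arr) if v != taxonomy.background_value)
        if not present:
            raise ValidationError("cannot place islands in an empty volume")
        if cspec.island_level is not None:
            island_label = taxonomy.label_for(cspec.island_level)
        else:
            island_label = int(rng.choice(present))
        forbidden = ndimage.binary_dilation(arr != 0, structure=_CONN26, iterations=3)
        side = int(np.ceil(cspec.island_size_voxels ** (1.0 / 3.0)))
        shape = arr.shape
        placed = 0
        for _ in range(2000):
            if placed == cspec.island_count:
                break
            corner = [int(rng.integers(0, shape[i] - side + 1)) for i in range(3)]
            # keep islands inside the foreground slice range so boundary
            # trimming decisions are unaffected
            z_index = corner[axis]
            if not (lo <= z_index and z_index + side - 1 <= hi):
                continue
            region = tuple(slice(c, c + side) for c in corner)
            if forbidden[region].any():
                continue
            block = np.zeros(side**3, dtype=bool)
            block[: cspec.island_size_voxels] = True
            arr[region][block.reshape((side,) * 3)] = island_label
            forbidden[
                tuple(
                    slice(max(c - 3, 0), min(c + side + 3, shape[i]))
                    for i, c in enumerate(corner)
                )
            ] = True
            placed += 1
        if placed < cspec.island_count:
            raise ValidationError("no background room to place all islands")

    # --- fringe slices beyond the cranial/caudal foreground ends
    if cspec.fringe_slices > 0 and cspec.fringe_voxels > 0:
        for end, step in ((lo, -1), (hi, +1)):
            template = moved[end]
            fg = np.argwhere(template != 0)
            if fg.shape[0] < cspec.fringe_voxels:
                raise ValidationError("fringe_voxels exceeds the end-slice footprint")
            for k in range(1, cspec.fringe_slices + 1):
                s = end + step * k
                if not (0 <= s < moved.shape[0]):
                    raise ValidationError("fringe slices exceed the grid; enlarge it")
                pick = fg[rng.choice(fg.shape[0], size=cspec.fringe_voxels, replace=False)]
                for i, j in pick:
                    moved[s, i, j] = template[i, j]

    return gt.with_array(arr)


def make_intensity_phantom(spec: PhantomSpec) -> IntensityVolume:
    """CT-like intensity phantom: a bright body ellipsoid on dark background
    plus detached thin arcs imitating immobilization-mask remnants.

    Intensities are arbitrary nonnegative units (not HU): background ~0,
    arcs ~300, body ~1000, with mild seeded Gaussian noise.
    """
    nx, ny, nz = spec.grid_shape
    rng = np.random.default_rng(spec.seed)
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ax, ay, az = 0.32 * nx, 0.25 * ny, 0.45 * nz
    body = ((ii - cx) / ax) ** 2 + ((jj - cy) / ay) ** 2 + ((kk - cz) / az) ** 2 <= 1.0

    # thin detached plate behind the body (dorsal), a few slices thick,
    # imitating the immobilization mask holder; the gap to the body exceeds
    # the default closing width so morphological closing cannot bridge it
    z_lo = int(0.3 * nz)
    arc = (
        (jj >= ny - 2)
        & (jj < ny - 1)
        & (np.abs(ii - cx) < 0.3 * nx)
        & (kk >= z_lo)
        & (kk < z_lo + 4)
    )
    arc &= ~ndimage.binary_dilation(body, structure=_CONN26, iterations=2)

    arr = rng.normal(0.0, 5.0, size=spec.grid_shape)
    arr[body] = rng.normal(1000.0, 20.0, size=int(body.sum()))
    arr[arc] = rng.normal(300.0, 10.0, size=int(arc.sum()))
    return IntensityVolume(arr.astype(np.float32), spec.spacing, lr_axis=0)
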