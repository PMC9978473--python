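"""Offline left-right mirroring augmentation with adaption of label values.

Flipping a training volume across the patient midline turns every left-side
level into its right-side counterpart, so a plain geometric mirror would
produce anatomically mislabeled training data. The augmentation therefore
flips the voxel array along the left-right axis and simultaneously applies
the taxonomy's mirror-pair label permutation (left values become the paired
right values and vice versa; midline levels and background are unchanged).

This runs offline — it produces a new training sample file per input — and
the mirrored file keeps the original affine/header; it is a training sample,
not a clinically oriented image.
"""

from __future__ import annotations

import numpy as np

from .taxonomy import LevelTaxonomy
from .volume import IntensityVolume, LabelVolume


def mirror_augment(volume: LabelVolume, taxonomy: LevelTaxonomy) -> LabelVolume:
    """Mirror a label volume along its left-right axis, swapping lateral labels.

    Every lateral label present in the volume must belong to a mirror pair;
    the taxonomy type enforces this at construction, and the volume is
    re-validated here so unknown labels fail with ``ValidationError``.
    """
    volume.validate(taxonomy)
    mapping = taxonomy.mirror_label_map()
    flipped = np.flip(volume.array, axis=volume.lr_axis)
    lut = np.arange(int(max(mapping)) + 1, dtype=volume.array.dtype)
    for src, dst in mapping.items():
        lut[src] = dst
    return volume.with_array(lut[flipped])


def mirror_intensity(volume: IntensityVolume) -> IntensityVolume:
    """Mirror an intensity volume along its left-right axis (spacing unchanged)."""
    return IntensityVolume(
        np.flip(volume.array, axis=volume.lr_axis).copy(),
        volume.spacing,
        lr_axis=volume.lr_axis,
    )
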