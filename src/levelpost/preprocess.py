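"""Foreground masking for planning CT volumes.

Planning CTs of the head and neck routinely contain a thermoplastic
immobilization mask and its holder. These high-contrast external structures
carry no anatomical information and vary between institutions, so they are
removed before training or inference. The procedure mirrors the classic
ROIAuto-style pipeline:

    percentile clip -> Otsu threshold -> scale threshold by a correction
    factor -> binarize -> morphological closing -> keep largest connected
    component -> dilate

with the conventional parameter set ``otsu_percentile_threshold = 0.01``,
``threshold_correction_factor = 0.3``, ``closing_size = 9`` and
``dilate_size = 2``. The correction factor is applied multiplicatively to
the Otsu threshold, pulling it toward the low end so faint body tissue is
retained; the largest-component step is what actually discards detached
mask/holder fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, ValidationError
from .volume import IntensityVolume, LabelVolume

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_OTSU_BINS = 256


@dataclass(frozen=True)
class PreprocessParams:
    otsu_percentile_threshold: float = 0.01
    threshold_correction_factor: float = 0.3
    closing_size: int = 9
    dilate_size: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.otsu_percentile_threshold < 0.5):
            raise ValidationError("otsu_percentile_threshold must be in [0, 0.5)")
        if self.threshold_correction_factor <= 0:
            raise ValidationError("threshold_correction_factor must be positive")
        if self.closing_size < 1:
            raise ValidationError("closing_size must be >= 1")
        if self.dilate_size < 0:
            raise ValidationError("dilate_size must be >= 0")


def otsu_threshold(intensities: np.ndarray) -> float:
    """Otsu threshold over a 256-bin histogram of a 1D intensity sample.

    Returns the threshold maximizing between-class variance; deterministic.
    Raises ``DegenerateInputError`` for constant input (no two classes to
    separate).
    """
    values = np.asarray(intensities, dtype=np.float64).ravel()
    if values.size < 2 or np.min(values) == np.max(values):
        raise DegenerateInputError("Otsu threshold undefined for constant input")
    return float(threshold_otsu(values, nbins=_OTSU_BINS))


def foreground_mask(volume: IntensityVolume, params: PreprocessParams | None = None) -> LabelVolume:
    """Compute the binary body mask of a CT-like volume.

    Pipeline: clip intensities to the [p, 1-p] percentile range, threshold
    with Otsu scaled by the correction factor, close with a cubic element,
    keep the largest 26-connected component, then dilate. The result is a
    binary label volume (1 = body) on the same grid.
    """
    params = params or PreprocessParams()
    arr = np.asarray(volume.array, dtype=np.float64)
    if arr.min() == arr.max():
        raise DegenerateInputError("foreground masking undefined for constant volume")

    p = params.otsu_percentile_threshold
    lo, hi = np.quantile(arr, [p, 1.0 - p])
    clipped = np.clip(arr, lo, hi)
    thr = otsu_threshold(clipped.ravel()) * params.threshold_correction_factor
    mask = clipped > thr

    if mask.any():
        size = int(params.closing_size)
        if size > 1:
            mask = ndimage.binary_closing(mask, structure=np.ones((size,) * 3, dtype=bool))
        comp, n = ndimage.label(mask, structure=_CONN26)
        if n > 1:
            sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
            mask = comp == (int(np.argmax(sizes)) + 1)
        if params.dilate_size > 0:
            mask = ndimage.binary_dilation(mask, structure=_CONN26, iterations=params.dilate_size)

    return LabelVolume(
        mask.astype(np.int16),
        spacing=volume.spacing,
        slice_axis=2 if volume.lr_axis != 2 else 1,
        lr_axis=volume.lr_axis,
    )


def apply_mask(image: IntensityVolume, mask: LabelVolume, fill_value: float) -> IntensityVolume:
    """Replace voxels outside the mask by ``fill_value``."""
    if image.array.shape != mask.array.shape:
        raise ValidationError(
            f"image grid {image.array.shape} does not match mask grid {mask.array.shape}"
        )
    out = np.asarray(image.array, dtype=np.float32).copy()
    out[mask.array == 0] = fill_value
    return IntensityVolume(out, image.spacing, lr_axis=image.lr_axis)


def crop_index_range(
    volume: IntensityVolume | LabelVolume,
    ranges: tuple[tuple[int, int], tuple[int, int], tuple[int, int]],
):
    """Crop a volume to half-open voxel index ranges per axis.

    Stand-in for the manual cubic region-of-interest fitting against
    anatomical landmarks (skull base, carina, humeral heads), which requires
    a human and is exposed only as an explicit index crop.
    """
    (a0, b0), (a1, b1), (a2, b2) = ranges
    shape = volume.array.shape
    for (a, b), n in zip(ranges, shape):
        if not (0 <= a < b <= n):
            raise ValidationError(f"crop range {(a, b)} invalid for axis of length {n}")
    arr = volume.array[a0:b0, a1:b1, a2:b2].copy()
    if isinstance(volume, LabelVolume):
        return volume.with_array(arr)
    return IntensityVolume(arr, volume.spacing, lr_axis=volume.lr_axis)
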