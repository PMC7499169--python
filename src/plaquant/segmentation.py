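"""Dental-area segmentation from UV photographs.

Under ultraviolet light with fluorescein disclosure, clean enamel
fluoresces bright blue and plaque fluoresces green, while gingiva and
background stay comparatively dark.  The dental area is therefore
recovered from brightness alone: the blue and red channels are summed,
the darkest ``background_fraction`` of pixels is declared background,
near-white specular artifacts and isolated pixels are removed, and the
remaining connected components are filtered by size and solidity to
discard non-dental regions (lips, mirror edges, gingival highlights).

Stages, in order:

1. optional rectangular crop
2. B+R quantile threshold (default: darkest 75% = background)
3. bright-artifact removal (min-channel floor, default 240)
4. isolated-pixel removal (8-neighborhood)
5. connected-component filtering by size (> 2000 px) and solidity (> 0.5)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .data_model import ProcessingParams, UVImage
from .errors import DegenerateImageWarning, EmptyDentalAreaError, ValidationError

__all__ = [
    "DentalMask",
    "brightness_threshold",
    "remove_bright_artifacts",
    "remove_isolated_pixels",
    "filter_components",
    "segment_dental_area",
]

#: 3x3 eight-neighborhood kernel (center excluded)
_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


@dataclass
class DentalMask:
    """Segmented dental area.

    ``mask`` marks dental pixels; ``component_ids`` labels each surviving
    connected component 1..K (0 = non-dental).
    """

    mask: np.ndarray
    component_ids: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.component_ids.max())

    @property
    def pixel_count(self) -> int:
        return int(np.count_nonzero(self.mask))


def brightness_threshold(image: UVImage, background_fraction: float = 0.75) -> int:
    """Background/foreground threshold on the per-pixel B+R sum.

    Returns the value at rank ``ceil(background_fraction * N)`` of the
    sorted B+R sums (range 0-510).  Pixels strictly above the threshold
    are foreground; ties at the threshold go to the background, so exactly
    the stated fraction of the darkest pixels (or slightly more, under
    ties) is discarded.

    A constant image leaves no pixel above its own threshold; a
    :class:`DegenerateImageWarning` is emitted and the foreground is empty.
    """
    if not 0.0 < background_fraction < 1.0:
        raise ValidationError("background_fraction must lie in (0, 1)")
    px = image.pixels
    br = px[..., 2].astype(np.int32) + px[..., 0].astype(np.int32)
    flat = np.sort(br, axis=None)
    rank = math.ceil(background_fraction * flat.size)  # 1-based
    threshold = int(flat[rank - 1])
    if threshold == int(flat[-1]):
        warnings.warn(
            "image has no intensity spread above the background threshold; "
            "foreground is empty",
            DegenerateImageWarning,
            stacklevel=2,
        )
    return threshold


def foreground_mask(image: UVImage, background_fraction: float = 0.75) -> np.ndarray:
    """Boolean raster of pixels strictly brighter (B+R) than the threshold."""
    px = image.pixels
    br = px[..., 2].astype(np.int32) + px[..., 0].astype(np.int32)
    return br > brightness_threshold(image, background_fraction)


def remove_bright_artifacts(mask: np.ndarray, image: UVImage,
                            artifact_intensity_floor: int = 240) -> np.ndarray:
    """Drop near-white specular highlights from the mask.

    A pixel whose *minimum* channel is at or above the floor is bright in
    every channel simultaneously — a specular reflection of the UV lamp,
    not fluorescence (pure blue or green signal is bright in one channel
    only and survives).
    """
    px = image.pixels
    artifact = px.min(axis=2) >= artifact_intensity_floor
    return mask & ~artifact


def remove_isolated_pixels(mask: np.ndarray) -> np.ndarray:
    """Clear every true pixel with zero true 8-neighbors; leave the rest."""
    mask = np.asarray(mask, dtype=bool)
    neighbors = ndimage.convolve(mask.astype(np.uint8), _NEIGHBOR_KERNEL,
                                 mode="constant", cval=0)
    return mask & (neighbors > 0)


def filter_components(mask: np.ndarray, min_region_size: int = 2000,
                      min_solidity: float = 0.5) -> DentalMask:
    """Keep 8-connected components with area > ``min_region_size`` and
    solidity (area / convex-hull area) > ``min_solidity``.

    Survivors are relabeled 1..K in scan order.  Raises
    :class:`EmptyDentalAreaError` when nothing survives.
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    keep: list[int] = []
    for prop in measure.regionprops(labels):
        if prop.area > min_region_size and prop.solidity > min_solidity:
            keep.append(prop.label)
    if not keep:
        raise EmptyDentalAreaError(
            "no connected component survives the size/solidity filters"
        )
    component_ids = np.zeros_like(labels)
    for new_id, old_id in enumerate(keep, start=1):
        component_ids[labels == old_id] = new_id
    return DentalMask(mask=component_ids > 0, component_ids=component_ids)


def segment_dental_area(image: UVImage, params: ProcessingParams | None = None,
                        crop: tuple[int, int, int, int] | None = None) -> DentalMask:
    """Full segmentation pipeline; deterministic for fixed inputs.

    ``crop`` overrides ``params.crop`` for this image.  The returned mask
    has the (possibly cropped) image's shape.
    """
    params = params or ProcessingParams()
    image = image.cropped(crop if crop is not None else params.crop)
    fg = foreground_mask(image, params.background_fraction)
    fg = remove_bright_artifacts(fg, image, params.artifact_intensity_floor)
    fg = remove_isolated_pixels(fg)
    return filter_components(fg, params.min_region_size, params.min_solidity)
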