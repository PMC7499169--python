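"""Pixel classification of the dental area by green-blue channel difference.

Fluorescein-stained plaque fluoresces green while clean enamel fluoresces
blue, so the signed difference G-B separates *visible plaque* (G-B > 0)
from the rest of the dental area.  The non-positive side is split further
by two thresholds into risk levels of *non-visible plaque*:

- VISIBLE:    G-B > 0
- NV1:        delta <= G-B <= 0   (risk of becoming plaque within hours)
- NV2:        l <= G-B < delta    (risk within days)
- NONPLAQUE:  G-B < l             (no risk in the medium term)

with l <= delta <= 0.  Both thresholds can be resolved automatically:
``delta`` as minus the absolute difference of the mean blue and mean green
channels over the dental area, and ``l`` by comparing the non-visible
plaque histogram of the current image against the reference moment's —
the first (most negative) G-B value where the current count exceeds the
reference count.  Dental pixels with a zero green or blue channel carry no
fluorescence signal and are excluded from the risk classes (NONPLAQUE).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .data_model import UVImage
from .errors import DegenerateSegmentationError, ParameterError
from .segmentation import DentalMask

__all__ = [
    "Label",
    "GBMap",
    "GBHistogram",
    "RegionLabels",
    "gb_map",
    "gb_histogram",
    "nonvisible_histogram",
    "auto_delta",
    "auto_l",
    "classify",
]

#: G-B values run from -255 to 255 inclusive: 511 unit-width bins.
GB_MIN, GB_MAX = -255, 255
N_BINS = GB_MAX - GB_MIN + 1


class Label(IntEnum):
    """Per-pixel category of the labeled raster."""

    OUTSIDE = 0
    VISIBLE = 1
    NV1 = 2
    NV2 = 3
    NONPLAQUE = 4


@dataclass
class GBMap:
    """Signed per-pixel G-B difference over the dental area.

    ``values`` is an int16 raster (range [-255, 255]); entries outside the
    dental mask are 0 and meaningless — consult ``mask``.
    """

    values: np.ndarray
    mask: np.ndarray

    def dental_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class GBHistogram:
    """Integer counts per G-B value, indexed from -255 to 255."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {self.counts.shape}")

    def count(self, gb_value: int) -> int:
        return int(self.counts[gb_value - GB_MIN])

    @property
    def values(self) -> np.ndarray:
        return np.arange(GB_MIN, GB_MAX + 1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class RegionLabels:
    """Categorical raster over the five classes plus the thresholds used."""

    labels: np.ndarray
    delta_used: float
    l_used: float

    def count(self, label: Label) -> int:
        return int(np.count_nonzero(self.labels == label))

    @property
    def dental_pixels(self) -> int:
        return int(np.count_nonzero(self.labels != Label.OUTSIDE))


def gb_map(image: UVImage, mask: DentalMask | np.ndarray) -> GBMap:
    """Signed G-B difference on dental pixels."""
    m = mask.mask if isinstance(mask, DentalMask) else np.asarray(mask, dtype=bool)
    if m.shape != image.shape:
        raise ValueError("mask shape does not match image shape")
    px = image.pixels
    values = px[..., 1].astype(np.int16) - px[..., 2].astype(np.int16)
    values[~m] = 0
    return GBMap(values=values, mask=m)


def gb_histogram(gb: GBMap) -> GBHistogram:
    """Unit-width histogram of G-B over the dental area; the counts sum to
    the dental pixel count."""
    vals = gb.dental_values()
    counts = np.bincount((vals.astype(np.int64) - GB_MIN), minlength=N_BINS)
    return GBHistogram(counts)


def nonvisible_histogram(image: UVImage, gb: GBMap) -> GBHistogram:
    """Histogram restricted to first-approximation non-visible plaque pixels
    (G-B <= 0 with G > 0 and B > 0); used to resolve ``l``."""
    px = image.pixels
    sel = gb.mask & (gb.values <= 0) & (px[..., 1] > 0) & (px[..., 2] > 0)
    vals = gb.values[sel]
    counts = np.bincount((vals.astype(np.int64) - GB_MIN), minlength=N_BINS)
    return GBHistogram(counts)


def auto_delta(image: UVImage, mask: DentalMask | np.ndarray) -> float:
    """Automatic delta: -|mean(B) - mean(G)| over the dental area.

    Stored non-positive so it thresholds the G-B <= 0 side directly.
    """
    m = mask.mask if isinstance(mask, DentalMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise DegenerateSegmentationError("auto delta requires a non-empty dental mask")
    px = image.pixels
    mean_g = float(px[..., 1][m].mean())
    mean_b = float(px[..., 2][m].mean())
    return -abs(mean_b - mean_g)


def auto_l(current_hist: GBHistogram, reference_hist: GBHistogram,
           delta: float) -> float:
    """Automatic l from current vs. reference non-visible plaque histograms.

    Scanning G-B values upward from -255 to 0, returns the first value
    where the current image's count strictly exceeds the reference
    image's.  If no value qualifies (e.g. the histograms are identical),
    falls back to ``delta``, which empties the NV2 class.
    """
    cur = current_hist.counts[: -GB_MIN + 1]   # bins for -255..0
    ref = reference_hist.counts[: -GB_MIN + 1]
    exceeds = np.nonzero(cur > ref)[0]
    if exceeds.size == 0:
        return float(delta)
    return float(exceeds[0] + GB_MIN)


def classify(gb: GBMap, image: UVImage, mask: DentalMask | np.ndarray,
             delta: float, l: float) -> RegionLabels:
    """Partition the dental area into the four plaque classes.

    Boundary semantics (l <= delta <= 0): VISIBLE takes G-B > 0; NV1 takes
    delta <= G-B <= 0 (both ends inclusive); NV2 takes l <= G-B < delta;
    NONPLAQUE takes G-B < l.  Dental pixels with G == 0 or B == 0 are
    NONPLAQUE regardless of thresholds.  Idempotent and deterministic.
    """
    if l > delta:
        raise ParameterError(f"l ({l}) must be <= delta ({delta})")
    if delta > 0:
        raise ParameterError(f"delta ({delta}) must be <= 0")
    m = mask.mask if isinstance(mask, DentalMask) else np.asarray(mask, dtype=bool)
    px = image.pixels
    v = gb.values

    labels = np.full(m.shape, Label.OUTSIDE, dtype=np.uint8)
    guard = (px[..., 1] > 0) & (px[..., 2] > 0)

    labels[m] = Label.NONPLAQUE
    labels[m & (v <= 0) & guard & (v >= delta)] = Label.NV1
    labels[m & (v <= 0) & guard & (v < delta) & (v >= l)] = Label.NV2
    labels[m & (v > 0)] = Label.VISIBLE
    return RegionLabels(labels=labels, delta_used=float(delta), l_used=float(l))
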