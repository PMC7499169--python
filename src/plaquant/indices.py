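"""Clinical plaque indices computed from the labeled dental area.

Three planimetric indices summarize each image:

- **API index** ("area per intensity", 0-100): the visible-plaque area
  fraction weighted by the mean stain intensity of that area,
  ``API = area_fraction * (mean G-B over VISIBLE / 255) * 100``.
  It is 0 with no visible plaque and 100 only when the whole dental area
  is visible plaque at saturated intensity.  The exact functional form is
  a reconstruction: the index is specified only by its name, its 0-100
  range and its monotonicity in both area and intensity; this is the
  simplest product with those properties (see docs/methods.md).
- **Area growth index** (% area per hour): plaque-area change since the
  reference moment divided by the elapsed hours.
- **Area time index** (days): linear extrapolation of the time left until
  the plaque area covers 100% of the dental area at the current growth
  rate.

"Total" variants pool visible plaque with both non-visible plaque levels.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .classification import GBMap, Label, RegionLabels
from .data_model import MomentMeasurements
from .errors import DegenerateSegmentationError, ParameterError

__all__ = [
    "area_percent",
    "mean_visible_intensity",
    "api_index",
    "area_growth_index",
    "area_time_index",
    "measure_moment",
]


def area_percent(labels: RegionLabels, cls: Label) -> float:
    """Percentage of the dental area carrying class ``cls``."""
    dental = labels.dental_pixels
    if dental == 0:
        raise DegenerateSegmentationError("empty dental area")
    return 100.0 * labels.count(cls) / dental


def mean_visible_intensity(labels: RegionLabels, gb: GBMap) -> float:
    """Mean G-B over VISIBLE pixels, 8-bit units; 0 when VISIBLE is empty."""
    sel = labels.labels == Label.VISIBLE
    if not sel.any():
        return 0.0
    return float(gb.values[sel].mean())


def api_index(labels: RegionLabels, gb: GBMap) -> float:
    """Area-per-intensity plaque index in [0, 100]."""
    dental = labels.dental_pixels
    if dental == 0:
        raise DegenerateSegmentationError("empty dental area")
    n_visible = labels.count(Label.VISIBLE)
    if n_visible == 0:
        return 0.0
    area_fraction = n_visible / dental
    intensity = mean_visible_intensity(labels, gb) / 255.0
    return area_fraction * intensity * 100.0


def area_growth_index(area_now: float, area_ref: float,
                      elapsed_hours: float) -> float:
    """Plaque-area growth rate, percentage points of dental area per hour.

    Negative growth (area decreased) is allowed and returned as a negative
    rate.  Undefined for the reference moment itself (elapsed time 0).
    """
    if elapsed_hours <= 0:
        raise ParameterError(
            "growth index is undefined for the reference moment (elapsed <= 0)"
        )
    return (area_now - area_ref) / elapsed_hours


def area_time_index(area_now: float, growth_rate: float) -> Optional[float]:
    """Days until the plaque area reaches 100% of the dental area, assuming
    the current constant growth rate.

    Returns 0 when the area is already at (or beyond) 100%, and ``None``
    (not computable) for zero or negative growth.
    """
    if area_now >= 100.0:
        return 0.0
    if growth_rate <= 0:
        return None
    return (100.0 - area_now) / growth_rate / 24.0


def _total_percent(labels: RegionLabels) -> float:
    """Pooled VISIBLE + NV1 + NV2 percentage of the dental area."""
    return (area_percent(labels, Label.VISIBLE)
            + area_percent(labels, Label.NV1)
            + area_percent(labels, Label.NV2))


def measure_moment(
    current_labels: RegionLabels,
    current_gb: GBMap,
    reference_labels: Optional[RegionLabels] = None,
    elapsed_hours: Optional[float] = None,
    *,
    patient_id: str = "",
    moment_label: str = "",
    image_index: int = 0,
    image_path: str = "",
    timestamp=None,
    normalization: float = 1.0,
) -> MomentMeasurements:
    """Assemble the full per-image measurement record.

    Absolute indices (class areas, mean intensity, API) come from the
    current image alone.  Relative indices (growth and area-time, visible
    and total) need the reference moment's labels and a positive elapsed
    time; they are left ``None`` for the reference moment itself.
    """
    is_reference = reference_labels is None or not elapsed_hours

    counts = {cls: current_labels.count(cls)
              for cls in (Label.VISIBLE, Label.NV1, Label.NV2, Label.NONPLAQUE)}
    percents = {cls: area_percent(current_labels, cls) for cls in counts}

    rec = MomentMeasurements(
        patient_id=patient_id,
        moment_label=moment_label,
        image_index=image_index,
        image_path=image_path,
        timestamp=timestamp,
        is_reference=is_reference,
        dental_pixels=current_labels.dental_pixels,
        pixel_count_visible=counts[Label.VISIBLE],
        pixel_count_nv1=counts[Label.NV1],
        pixel_count_nv2=counts[Label.NV2],
        pixel_count_nonplaque=counts[Label.NONPLAQUE],
        area_percent_visible=percents[Label.VISIBLE],
        area_percent_nv1=percents[Label.NV1],
        area_percent_nv2=percents[Label.NV2],
        area_percent_nonplaque=percents[Label.NONPLAQUE],
        mean_visible_intensity=mean_visible_intensity(current_labels, current_gb),
        api_index=api_index(current_labels, current_gb),
        delta_used=current_labels.delta_used,
        l_used=current_labels.l_used,
        normalization_factor=normalization,
    )
    if is_reference:
        return rec

    rec.elapsed_hours = float(elapsed_hours)
    ref_visible = area_percent(reference_labels, Label.VISIBLE)
    ref_total = _total_percent(reference_labels)
    cur_total = _total_percent(current_labels)

    rec.growth_index_visible = area_growth_index(
        percents[Label.VISIBLE], ref_visible, rec.elapsed_hours)
    rec.growth_index_total = area_growth_index(
        cur_total, ref_total, rec.elapsed_hours)
    rec.area_time_visible = area_time_index(
        percents[Label.VISIBLE], rec.growth_index_visible)
    rec.area_time_total = area_time_index(cur_total, rec.growth_index_total)
    return rec
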