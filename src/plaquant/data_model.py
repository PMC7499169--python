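"""Domain model: images, plaque moments, experiments, parameters, measurements.

A *plaque moment* is the set of photographs (frontal view first, optional
lateral views) taken from one patient at one timepoint.  One moment per
patient is the *reference moment* ("moment 0", typically after professional
dental cleaning); every growth index is measured against it.

Cross-moment comparisons are carried out on area percentages, which are
invariant to the number of pixels in the dental area; the ratio of
reference to current dental pixel counts is recorded alongside as
``normalization_factor`` so that absolute pixel counts remain comparable.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import (
    ConfigurationError,
    DegenerateSegmentationError,
    UnreadableImageError,
    ValidationError,
)

#: Sentinel for parameters resolved automatically from the image data.
AUTO = "auto"


# ---------------------------------------------------------------------------
# Images


@dataclass
class UVImage:
    """8-bit RGB photograph of fluorescein-dyed dentition under UV light.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
        R, G, B channels.  Clean enamel fluoresces bright blue (high B),
        plaque deposits fluoresce green (G > B), gingiva appears dim/reddish
        and the background is near black.
    source_path : str
        Where the raster came from ("<synthetic>" for generated scenes).
    timestamp : datetime
        Acquisition time (timezone-naive; elapsed times are computed in
        fractional hours).
    """

    pixels: np.ndarray
    source_path: str = "<memory>"
    timestamp: Optional[datetime] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(
                f"UVImage requires an HxWx3 raster, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def nbytes(self) -> int:
        return int(self.pixels.nbytes)

    def cropped(self, rect: Optional[Sequence[int]]) -> "UVImage":
        """Return the axis-aligned crop ``(top, left, bottom, right)``,
        half-open, 0-based, row-major.  ``None`` returns self unchanged."""
        if rect is None:
            return self
        top, left, bottom, right = (int(v) for v in rect)
        h, w = self.shape
        if not (0 <= top < bottom <= h and 0 <= left < right <= w):
            raise ValidationError(f"crop rectangle {rect!r} outside image {h}x{w}")
        return UVImage(self.pixels[top:bottom, left:right].copy(),
                       self.source_path, self.timestamp)

    def downscaled_to_bytes(self, max_bytes: int) -> "UVImage":
        """Decimate by the smallest integer factor bringing the raster under
        ``max_bytes`` (aspect ratio preserved; 8-bit values untouched)."""
        if self.nbytes <= max_bytes:
            return self
        h, w = self.shape
        k = 2
        while (math.ceil(h / k) * math.ceil(w / k) * 3) > max_bytes:
            k += 1
        return UVImage(self.pixels[::k, ::k].copy(), self.source_path, self.timestamp)

    @classmethod
    def from_file(cls, path: str | Path, timestamp: Optional[datetime] = None,
                  max_bytes: Optional[int] = None) -> "UVImage":
        """Read a PNG/JPEG/TIFF file (8-bit per channel)."""
        import imageio.v3 as iio

        try:
            arr = iio.imread(path)
        except (FileNotFoundError, OSError, ValueError) as exc:
            raise UnreadableImageError(f"cannot read image {path}: {exc}") from exc
        arr = np.asarray(arr)
        if arr.ndim == 2:  # greyscale: replicate
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.dtype != np.uint8:
            raise UnreadableImageError(
                f"{path}: expected 8-bit channels, got dtype {arr.dtype}"
            )
        img = cls(arr, source_path=str(path), timestamp=timestamp)
        if max_bytes is not None:
            img = img.downscaled_to_bytes(max_bytes)
        return img


# ---------------------------------------------------------------------------
# Processing parameters


@dataclass
class ProcessingParams:
    """Tunable parameters of the image-processing pipeline.

    ``delta`` is the threshold separating level-1 from level-2 non-visible
    plaque on the G-B axis.  It acts on the non-positive side of G-B, so a
    user-supplied value must be <= 0; the default ``AUTO`` resolves it per
    image as minus the absolute difference between the mean blue and mean
    green channel over the dental area.
    """

    background_fraction: float = 0.75
    min_region_size: int = 2000
    min_solidity: float = 0.5
    delta: float | str = AUTO
    artifact_intensity_floor: int = 240
    max_image_bytes: int = 5_000_000
    crop: Optional[tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.background_fraction < 1.0:
            raise ValidationError("background_fraction must lie in (0, 1)")
        if self.min_region_size < 1:
            raise ValidationError("min_region_size must be >= 1")
        if not 0.0 < self.min_solidity <= 1.0:
            raise ValidationError("min_solidity must lie in (0, 1]")
        if self.delta != AUTO:
            self.delta = float(self.delta)
            if self.delta > 0:
                raise ValidationError(
                    "delta thresholds the non-positive side of G-B and must be <= 0"
                )
        if not 0 <= self.artifact_intensity_floor <= 255:
            raise ValidationError("artifact_intensity_floor must be an 8-bit value")
        if self.max_image_bytes < 3:
            raise ValidationError("max_image_bytes too small for any image")
        if self.crop is not None:
            self.crop = tuple(int(v) for v in self.crop)
            if len(self.crop) != 4:
                raise ValidationError("crop must be (top, left, bottom, right)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["crop"] is not None:
            d["crop"] = list(d["crop"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProcessingParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown processing parameters: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# Moments and experiments


@dataclass
class PlaqueMoment:
    """All views captured from one patient at one timepoint."""

    patient_id: str
    timestamp: datetime
    images: list[UVImage]
    label: str = ""
    is_reference: bool = False
    #: per-image crop rectangles (parallel to ``images``; None = no crop)
    crops: Optional[list[Optional[tuple[int, int, int, int]]]] = None

    def __post_init__(self) -> None:
        if not self.images:
            raise ValidationError("a plaque moment requires at least one image")
        if self.crops is not None and len(self.crops) != len(self.images):
            raise ValidationError("crops must parallel images")

    @property
    def frontal(self) -> UVImage:
        return self.images[0]


@dataclass
class Experiment:
    """A set of plaque moments selected for processing, plus parameters.

    ``registry`` optionally holds the full pool of known moments per
    patient; selecting a non-reference moment auto-includes that patient's
    reference moment from the pool, mirroring how an operator picks
    moments from a patient database.
    """

    name: str = "experiment"
    params: ProcessingParams = field(default_factory=ProcessingParams)
    moments: list[PlaqueMoment] = field(default_factory=list)
    registry: list[PlaqueMoment] = field(default_factory=list)

    def reference_for(self, patient_id: str) -> Optional[PlaqueMoment]:
        for m in self.moments:
            if m.patient_id == patient_id and m.is_reference:
                return m
        return None

    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.moments:
            seen.setdefault(m.patient_id, None)
        return list(seen)

    def validate(self) -> None:
        """Check reference uniqueness, presence, and timestamp ordering."""
        for pid in self.patients():
            refs = [m for m in self.moments
                    if m.patient_id == pid and m.is_reference]
            if len(refs) > 1:
                raise ValidationError(
                    f"patient {pid!r} has {len(refs)} reference moments; exactly one allowed"
                )
            if not refs:
                raise ConfigurationError(
                    f"patient {pid!r} has selected moments but no reference moment"
                )
            ref = refs[0]
            for m in self.moments:
                if m.patient_id == pid and not m.is_reference \
                        and m.timestamp < ref.timestamp:
                    raise ValidationError(
                        f"moment {m.label!r} of patient {pid!r} predates the reference moment"
                    )


def attach_moment(experiment: Experiment, moment: PlaqueMoment) -> Experiment:
    """Attach ``moment`` to the experiment's selection.

    Attaching a non-reference moment automatically includes the patient's
    reference moment (from the experiment's registry if not yet selected).
    Attaching a second reference moment for a patient raises
    :class:`ValidationError`; a non-reference moment whose reference exists
    nowhere raises :class:`ConfigurationError`.
    """
    existing_ref = experiment.reference_for(moment.patient_id)
    if moment.is_reference:
        if existing_ref is not None and existing_ref is not moment:
            raise ValidationError(
                f"patient {moment.patient_id!r} already has a reference moment"
            )
        if moment not in experiment.moments:
            experiment.moments.append(moment)
        return experiment

    if moment not in experiment.moments:
        experiment.moments.append(moment)
    if existing_ref is None:
        pool_ref = next(
            (m for m in experiment.registry
             if m.patient_id == moment.patient_id and m.is_reference),
            None,
        )
        if pool_ref is None:
            raise ConfigurationError(
                f"no reference moment known for patient {moment.patient_id!r}"
            )
        experiment.moments.append(pool_ref)
    return experiment


def normalization_factor(current_dental_pixels: int | np.ndarray,
                         reference_dental_pixels: int | np.ndarray) -> float:
    """Pixel-count normalization between a moment and the reference moment.

    Accepts either boolean dental masks or plain pixel counts; returns
    ``reference count / current count`` so that
    ``factor * current count == reference count``.  Downstream comparisons
    use area percentages (scale-invariant); this factor is recorded so
    absolute pixel counts stay comparable across moments.
    """
    def _count(x) -> int:
        arr = np.asarray(x)
        if arr.ndim == 0:
            return int(arr)
        return int(np.count_nonzero(arr))

    cur, ref = _count(current_dental_pixels), _count(reference_dental_pixels)
    if cur <= 0 or ref <= 0:
        raise DegenerateSegmentationError(
            "normalization requires non-empty dental masks"
        )
    return ref / cur


# ---------------------------------------------------------------------------
# Measurements


@dataclass
class MomentMeasurements:
    """Per-image absolute indices plus indices relative to the reference moment.

    Class areas are percentages of the dental area and sum to 100.
    ``mean_visible_intensity`` is the mean G-B over VISIBLE pixels in 8-bit
    units.  Relative fields (growth, area-time, elapsed hours) are ``None``
    for the reference moment itself.
    """

    patient_id: str
    moment_label: str
    image_index: int
    image_path: str
    timestamp: Optional[datetime]
    is_reference: bool
    dental_pixels: int
    pixel_count_visible: int
    pixel_count_nv1: int
    pixel_count_nv2: int
    pixel_count_nonplaque: int
    area_percent_visible: float
    area_percent_nv1: float
    area_percent_nv2: float
    area_percent_nonplaque: float
    mean_visible_intensity: float
    api_index: float
    delta_used: float
    l_used: float
    normalization_factor: float
    elapsed_hours: Optional[float] = None
    growth_index_visible: Optional[float] = None
    growth_index_total: Optional[float] = None
    area_time_visible: Optional[float] = None
    area_time_total: Optional[float] = None

    #: column order of the CSV export
    CSV_COLUMNS = (
        "patient_id", "moment_label", "image_index", "image_path", "timestamp",
        "is_reference", "elapsed_hours", "dental_pixels",
        "pixel_count_visible", "pixel_count_nv1", "pixel_count_nv2",
        "pixel_count_nonplaque",
        "area_percent_visible", "area_percent_nv1", "area_percent_nv2",
        "area_percent_nonplaque",
        "mean_visible_intensity", "api_index",
        "growth_index_visible", "growth_index_total",
        "area_time_visible", "area_time_total",
        "delta_used", "l_used", "normalization_factor",
    )

    def to_row(self) -> dict:
        row = {c: getattr(self, c) for c in self.CSV_COLUMNS}
        if isinstance(row["timestamp"], datetime):
            row["timestamp"] = row["timestamp"].isoformat()
        return row


# ---------------------------------------------------------------------------
# Config serialization (YAML)


def _moment_to_dict(m: PlaqueMoment, paths: list[str]) -> dict:
    d: dict = {
        "label": m.label,
        "timestamp": m.timestamp.isoformat(),
        "is_reference": bool(m.is_reference),
        "images": [],
    }
    for i, p in enumerate(paths):
        entry: dict = {"path": p}
        if m.crops is not None and m.crops[i] is not None:
            entry["crop"] = list(m.crops[i])
        d["images"].append(entry)
    return d


def save_config(experiment: Experiment, path: str | Path) -> None:
    """Write the experiment (patients, moments, parameters) as YAML.

    Image pixel data is referenced by each image's ``source_path``.
    """
    doc: dict = {
        "name": experiment.name,
        "params": experiment.params.to_dict(),
        "patients": [],
    }
    for pid in experiment.patients():
        pdoc: dict = {"id": pid, "moments": []}
        for m in experiment.moments:
            if m.patient_id != pid:
                continue
            pdoc["moments"].append(
                _moment_to_dict(m, [img.source_path for img in m.images]))
        doc["patients"].append(pdoc)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> Experiment:
    """Load an experiment configuration; image files are read eagerly."""
    p = Path(path)
    try:
        doc = yaml.safe_load(p.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config {path} is not a mapping")

    params = ProcessingParams.from_dict(doc.get("params", {}) or {})
    exp = Experiment(name=doc.get("name", p.stem), params=params)
    base = p.parent
    for pdoc in doc.get("patients", []) or []:
        pid = str(pdoc.get("id"))
        for mdoc in pdoc.get("moments", []) or []:
            ts = mdoc.get("timestamp")
            if isinstance(ts, str):
                ts = datetime.fromisoformat(ts)
            if not isinstance(ts, datetime):
                raise ConfigurationError(
                    f"moment {mdoc.get('label')!r} of patient {pid!r}: "
                    "timestamp must be ISO-8601"
                )
            images, crops = [], []
            for entry in mdoc.get("images", []) or []:
                if isinstance(entry, str):
                    entry = {"path": entry}
                img_path = Path(entry["path"])
                if not img_path.is_absolute():
                    img_path = base / img_path
                images.append(UVImage.from_file(
                    img_path, timestamp=ts, max_bytes=params.max_image_bytes))
                crops.append(tuple(entry["crop"]) if "crop" in entry else None)
            moment = PlaqueMoment(
                patient_id=pid, timestamp=ts, images=images,
                label=str(mdoc.get("label", "")),
                is_reference=bool(mdoc.get("is_reference", False)),
                crops=crops if any(c is not None for c in crops) else None,
            )
            exp.moments.append(moment)
    exp.validate()
    return exp


def elapsed_hours(moment: PlaqueMoment, reference: PlaqueMoment) -> float:
    """Elapsed time since the reference moment, in fractional hours."""
    return (moment.timestamp - reference.timestamp).total_seconds() / 3600.0
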