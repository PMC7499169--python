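"""Synthetic UV dentition scenes with ground truth.

Clinical fluorescein/UV photographs cannot be redistributed, so every
pipeline stage is exercised on rendered scenes that reproduce the color
structure the segmentation and classification stages rely on:

- near-black background (the oral cavity outside the lit field),
- a dim reddish gingiva band whose B+R brightness sits between background
  and teeth — excluded by the brightness threshold, as in real images,
- bright blue elliptical teeth (B well above G),
- green plaque patches (G above B by a programmable margin) grown
  contiguously from a per-tooth anchor to an exact coverage fraction,
- optional near-white specular discs (lamp reflections),
- i.i.d. Gaussian channel noise.

Rendering is fully deterministic for a fixed seed.  ``render_series``
produces a time series of plaque moments whose coverage grows linearly at
a programmed rate (percent of dental area per hour), with a mild upward
drift of G-B on clean enamel mimicking early, sub-visible accumulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .data_model import Experiment, PlaqueMoment, ProcessingParams, UVImage
from .errors import ValidationError

__all__ = [
    "ToothSpec",
    "PlaquePatchSpec",
    "GingivaSpec",
    "ArtifactSpec",
    "SceneSpec",
    "default_scene",
    "render_scene",
    "render_series",
    "write_synthetic_experiment",
]


@dataclass
class ToothSpec:
    """Axis-aligned elliptical tooth blob."""

    center: tuple[float, float]          # (row, col)
    radii: tuple[float, float]           # (row radius, col radius)
    blue_mean: float = 205.0
    blue_sd: float = 8.0
    green_mean: float = 60.0
    green_sd: float = 6.0
    red_mean: float = 25.0


@dataclass
class PlaquePatchSpec:
    """Plaque patch on one tooth, covering a fraction of its area."""

    tooth: int                           # index into SceneSpec.teeth
    coverage: float                      # fraction of the tooth area, [0, 1]
    gb_mean: float = 70.0                # programmed G-B margin of plaque
    gb_sd: float = 10.0
    blue_mean: float = 120.0             # plaque blue level (keeps B+R bright)
    blue_sd: float = 8.0
    red_mean: float = 30.0


@dataclass
class GingivaSpec:
    """Horizontal gingiva band across the top of the canvas."""

    height_fraction: float = 0.16
    red_mean: float = 70.0
    green_mean: float = 30.0
    blue_mean: float = 10.0


@dataclass
class ArtifactSpec:
    """Small near-white specular disc."""

    center: tuple[float, float]
    radius: float
    intensity: float = 250.0


@dataclass
class SceneSpec:
    """Complete description of one synthetic scene."""

    height: int = 400
    width: int = 520
    teeth: list[ToothSpec] = field(default_factory=list)
    plaque: list[PlaquePatchSpec] = field(default_factory=list)
    gingiva: Optional[GingivaSpec] = field(default_factory=GingivaSpec)
    artifacts: list[ArtifactSpec] = field(default_factory=list)
    background_mean: tuple[float, float, float] = (8.0, 6.0, 10.0)
    noise_sd: float = 5.0
    seed: int = 0
    #: seed controlling plaque-anchor placement; kept fixed across a time
    #: series so patches grow from stable anchors. Defaults to ``seed``.
    anchor_seed: Optional[int] = None


def default_scene(seed: int = 0, n_teeth: int = 4,
                  coverage: float = 0.0, height: int = 400,
                  width: int = 520, noise_sd: float = 5.0,
                  with_artifacts: bool = False) -> SceneSpec:
    """A frontal-view-like scene: ``n_teeth`` teeth in a row under a
    gingiva band, each optionally carrying a plaque patch of the given
    coverage fraction."""
    teeth: list[ToothSpec] = []
    plaque: list[PlaquePatchSpec] = []
    margin = width / (n_teeth + 1)
    ry = height * 0.22
    rx = min(margin * 0.44, width * 0.12)
    for i in range(n_teeth):
        cy = height * 0.52
        cx = margin * (i + 1)
        teeth.append(ToothSpec(center=(cy, cx), radii=(ry, rx)))
        if coverage > 0:
            plaque.append(PlaquePatchSpec(tooth=i, coverage=coverage))
    artifacts = []
    if with_artifacts:
        artifacts = [ArtifactSpec(center=(height * 0.45, margin * 1.0), radius=4.0)]
    return SceneSpec(height=height, width=width, teeth=teeth, plaque=plaque,
                     artifacts=artifacts, noise_sd=noise_sd, seed=seed)


def _ellipse_mask(h: int, w: int, center: tuple[float, float],
                  radii: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = center
    ry, rx = radii
    if ry <= 0 or rx <= 0:
        return np.zeros((h, w), dtype=bool)
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _patch_mask(tooth_mask: np.ndarray, anchor: tuple[int, int],
                coverage: float) -> np.ndarray:
    """The ``coverage`` fraction of tooth pixels nearest the anchor —
    a contiguous blob growing outward from the anchor as coverage rises."""
    n_target = int(round(coverage * np.count_nonzero(tooth_mask)))
    patch = np.zeros_like(tooth_mask)
    if n_target <= 0:
        return patch
    ys, xs = np.nonzero(tooth_mask)
    d2 = (ys - anchor[0]) ** 2 + (xs - anchor[1]) ** 2
    order = np.argsort(d2, kind="stable")[:n_target]
    patch[ys[order], xs[order]] = True
    return patch


def render_scene(spec: SceneSpec) -> tuple[UVImage, np.ndarray, np.ndarray]:
    """Render a scene; returns (image, dental mask, plaque mask).

    The plaque mask is a subset of the dental mask.  Identical specs give
    bit-identical outputs.  Out-of-canvas blobs are clipped; overlapping
    teeth merge into their union.
    """
    h, w = int(spec.height), int(spec.width)
    if h < 1 or w < 1:
        raise ValidationError("canvas must be at least 1x1")
    rng = np.random.default_rng(spec.seed)
    anchor_rng = np.random.default_rng(
        spec.seed if spec.anchor_seed is None else spec.anchor_seed)

    img = np.empty((h, w, 3), dtype=np.float64)
    for c, mean in enumerate(spec.background_mean):
        img[..., c] = mean

    if spec.gingiva is not None:
        gh = int(round(spec.gingiva.height_fraction * h))
        img[:gh, :, 0] = spec.gingiva.red_mean
        img[:gh, :, 1] = spec.gingiva.green_mean
        img[:gh, :, 2] = spec.gingiva.blue_mean

    tooth_masks = [
        _ellipse_mask(h, w, t.center, t.radii) for t in spec.teeth
    ]
    dental = np.zeros((h, w), dtype=bool)
    for t, m in zip(spec.teeth, tooth_masks):
        dental |= m
        n = int(np.count_nonzero(m))
        if n == 0:
            continue
        img[m, 0] = t.red_mean
        img[m, 1] = rng.normal(t.green_mean, t.green_sd, size=n)
        img[m, 2] = rng.normal(t.blue_mean, t.blue_sd, size=n)

    # anchors are drawn per tooth from anchor_rng regardless of coverage,
    # so a series with growing coverage keeps its anchors fixed
    anchors: list[Optional[tuple[int, int]]] = []
    for m in tooth_masks:
        ys, xs = np.nonzero(m)
        if ys.size == 0:
            anchors.append(None)
            continue
        k = int(anchor_rng.integers(ys.size))
        anchors.append((int(ys[k]), int(xs[k])))

    plaque = np.zeros((h, w), dtype=bool)
    for p in spec.plaque:
        if not 0 <= p.tooth < len(tooth_masks):
            raise ValidationError(f"plaque patch references missing tooth {p.tooth}")
        anchor = anchors[p.tooth]
        if anchor is None:
            continue
        pm = _patch_mask(tooth_masks[p.tooth], anchor, p.coverage)
        plaque |= pm
        n = int(np.count_nonzero(pm))
        if n == 0:
            continue
        b = rng.normal(p.blue_mean, p.blue_sd, size=n)
        gb = rng.normal(p.gb_mean, p.gb_sd, size=n)
        img[pm, 0] = p.red_mean
        img[pm, 1] = b + gb
        img[pm, 2] = b

    for a in spec.artifacts:
        am = _ellipse_mask(h, w, a.center, (a.radius, a.radius))
        img[am] = a.intensity

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return UVImage(pixels, source_path="<synthetic>"), dental, plaque


def render_series(
    spec: SceneSpec,
    rate: float,
    timestamps: list[datetime],
    patient_id: str = "synthetic",
    drift_per_hour: float = 0.12,
) -> list[tuple[PlaqueMoment, dict]]:
    """Render a longitudinal series with linear plaque growth.

    ``rate`` is the programmed visible-plaque growth in percent of the
    dental area per hour; coverage at time t is ``min(100, rate * hours)``
    percent, applied uniformly across teeth.  The first timestamp is the
    reference moment and carries zero plaque.  Clean-enamel green drifts
    upward by ``drift_per_hour`` intensity units per hour, flattening the
    negative G-B histogram lobe over time the way real series do.

    Returns one ``(PlaqueMoment, ground_truth)`` pair per timestamp;
    ground truth holds the dental mask, plaque mask and programmed
    coverage fraction.
    """
    if sorted(timestamps) != list(timestamps):
        raise ValidationError("timestamps must be increasing")
    base_anchor = spec.seed if spec.anchor_seed is None else spec.anchor_seed
    out: list[tuple[PlaqueMoment, dict]] = []
    t0 = timestamps[0]
    for i, ts in enumerate(timestamps):
        hours = (ts - t0).total_seconds() / 3600.0
        coverage = min(100.0, rate * hours) / 100.0
        teeth = [
            dataclasses.replace(t, green_mean=t.green_mean + drift_per_hour * hours)
            for t in spec.teeth
        ]
        plaque = ([] if coverage <= 0 else
                  [PlaquePatchSpec(tooth=j, coverage=coverage)
                   for j in range(len(spec.teeth))])
        child_seed = int(
            np.random.SeedSequence([spec.seed, i]).generate_state(1)[0] % (2 ** 31))
        mspec = dataclasses.replace(
            spec, teeth=teeth, plaque=plaque, seed=child_seed,
            anchor_seed=base_anchor)
        image, dental, plaque_mask = render_scene(mspec)
        image = UVImage(image.pixels, source_path=f"<synthetic:m{i}>", timestamp=ts)
        moment = PlaqueMoment(
            patient_id=patient_id, timestamp=ts, images=[image],
            label=f"M{i}", is_reference=(i == 0),
        )
        out.append((moment, {
            "dental_mask": dental,
            "plaque_mask": plaque_mask,
            "coverage": coverage,
            "hours": hours,
        }))
    return out


def write_synthetic_experiment(
    out_dir: str | Path,
    seed: int = 0,
    rate: float = 0.75,
    n_moments: int = 5,
    hours_step: float = 24.0,
    n_teeth: int = 4,
    noise_sd: float = 5.0,
    start: Optional[datetime] = None,
    params: Optional[ProcessingParams] = None,
) -> Path:
    """Write a complete synthetic experiment (PNG images + config YAML +
    ground-truth masks) ready for ``plaquant run``.  Returns the config
    path."""
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    start = start or datetime(2025, 1, 6, 9, 0, 0)
    timestamps = [start + timedelta(hours=hours_step * i) for i in range(n_moments)]
    spec = default_scene(seed=seed, n_teeth=n_teeth, noise_sd=noise_sd)
    series = render_series(spec, rate=rate, timestamps=timestamps)

    params = params or ProcessingParams()
    doc: dict = {
        "name": f"synthetic-{seed}",
        "params": params.to_dict(),
        "patients": [{"id": "synthetic", "moments": []}],
    }
    for i, (moment, truth) in enumerate(series):
        img_rel = f"images/m{i}.png"
        iio.imwrite(out / img_rel, moment.images[0].pixels)
        iio.imwrite(out / f"truth/m{i}_dental.png",
                    (truth["dental_mask"] * np.uint8(255)))
        iio.imwrite(out / f"truth/m{i}_plaque.png",
                    (truth["plaque_mask"] * np.uint8(255)))
        doc["patients"][0]["moments"].append({
            "label": moment.label,
            "timestamp": moment.timestamp.isoformat(),
            "is_reference": bool(moment.is_reference),
            "images": [{"path": img_rel}],
        })
    config_path = out / "experiment.yaml"
    config_path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return config_path


def series_experiment(seed: int = 0, rate: float = 0.75, n_moments: int = 5,
                      hours_step: float = 24.0, n_teeth: int = 4,
                      noise_sd: float = 5.0,
                      params: Optional[ProcessingParams] = None,
                      ) -> tuple[Experiment, list[dict]]:
    """In-memory convenience: a ready-to-process Experiment plus ground truth."""
    start = datetime(2025, 1, 6, 9, 0, 0)
    timestamps = [start + timedelta(hours=hours_step * i) for i in range(n_moments)]
    spec = default_scene(seed=seed, n_teeth=n_teeth, noise_sd=noise_sd)
    series = render_series(spec, rate=rate, timestamps=timestamps)
    exp = Experiment(name=f"synthetic-{seed}", params=params or ProcessingParams())
    truths = []
    for moment, truth in series:
        exp.moments.append(moment)
        truths.append(truth)
    exp.validate()
    return exp, truths
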