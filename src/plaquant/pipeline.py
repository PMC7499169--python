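"""End-to-end experiment processing.

For every patient the reference moment's frontal image is processed
first; its non-visible plaque histogram and dental pixel count anchor the
automatic ``l`` threshold, the pixel-count normalization factor and the
growth baselines for every other image of that patient.  Each image then
yields one measurement record (per-image reporting; views are never
pooled).

Per-image failures (unreadable file, empty dental area) are logged and
abort only that image; a missing or duplicate reference moment aborts the
whole experiment, because nothing relative can be computed without it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .classification import (
    auto_delta,
    auto_l,
    classify,
    gb_histogram,
    gb_map,
    nonvisible_histogram,
)
from .data_model import (
    AUTO,
    Experiment,
    MomentMeasurements,
    PlaqueMoment,
    UVImage,
    elapsed_hours,
    normalization_factor,
)
from .errors import PlaquantError
from .indices import measure_moment
from .segmentation import segment_dental_area

logger = logging.getLogger("plaquant")

__all__ = ["ImageResult", "ExperimentResult", "process_image", "process_experiment"]


@dataclass
class ImageResult:
    """Everything computed for one image."""

    measurement: MomentMeasurements
    labels: object
    gb: object
    mask: object
    histogram: object
    nonvisible_hist: object


@dataclass
class ExperimentResult:
    measurements: list[MomentMeasurements] = field(default_factory=list)
    images: list[ImageResult] = field(default_factory=list)
    errors: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def process_image(
    image: UVImage,
    experiment: Experiment,
    moment: PlaqueMoment,
    image_index: int,
    reference: Optional[ImageResult],
    crop=None,
) -> ImageResult:
    """Segment, classify and measure a single view.

    ``reference`` is the processed reference frontal image of the same
    patient (``None`` while processing that image itself).
    """
    params = experiment.params
    image = image.cropped(crop if crop is not None else params.crop)
    mask = segment_dental_area(image, params)
    gb = gb_map(image, mask)
    delta = auto_delta(image, mask) if params.delta == AUTO else float(params.delta)
    nv_hist = nonvisible_histogram(image, gb)
    ref_hist = reference.nonvisible_hist if reference is not None else nv_hist
    l = auto_l(nv_hist, ref_hist, delta)
    labels = classify(gb, image, mask, delta, l)

    if reference is not None:
        norm = normalization_factor(mask.pixel_count,
                                    reference.mask.pixel_count)
        hours = elapsed_hours(moment, _ref_moment(experiment, moment.patient_id))
        ref_labels = reference.labels if hours > 0 else None
    else:
        norm, hours, ref_labels = 1.0, None, None

    measurement = measure_moment(
        labels, gb,
        reference_labels=ref_labels,
        elapsed_hours=hours,
        patient_id=moment.patient_id,
        moment_label=moment.label,
        image_index=image_index,
        image_path=image.source_path,
        timestamp=moment.timestamp,
        normalization=norm,
    )
    return ImageResult(measurement=measurement, labels=labels, gb=gb,
                       mask=mask, histogram=gb_histogram(gb),
                       nonvisible_hist=nv_hist)


def _ref_moment(experiment: Experiment, patient_id: str) -> PlaqueMoment:
    ref = experiment.reference_for(patient_id)
    assert ref is not None  # validate() ran before processing
    return ref


def process_experiment(experiment: Experiment,
                       out_dir: Optional[str | Path] = None,
                       write_images: bool = True) -> ExperimentResult:
    """Process every image of every moment of every patient.

    When ``out_dir`` is given, writes per image: dental-mask PNG, labeled
    PNG, G-B histogram CSV and plot, pie/bar class charts; per experiment:
    ``measurements.csv`` and ``manifest.json``.
    """
    experiment.validate()
    result = ExperimentResult()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "experiment": experiment.name,
        "version": __version__,
        "params": experiment.params.to_dict(),
        "resolved": [],
        "outputs": [],
        "errors": [],
        "warnings": [],
    }

    for pid in experiment.patients():
        ref_moment = experiment.reference_for(pid)
        moments = sorted(
            (m for m in experiment.moments if m.patient_id == pid),
            key=lambda m: (not m.is_reference, m.timestamp),
        )
        ref_result: Optional[ImageResult] = None
        for moment in moments:
            for i, image in enumerate(moment.images):
                crop = moment.crops[i] if moment.crops is not None else None
                tag = f"{pid}/{moment.label or moment.timestamp.isoformat()}[{i}]"
                if moment is not ref_moment and ref_result is None:
                    entry = {"image": tag, "path": image.source_path,
                             "error": "ReferenceUnavailable",
                             "message": "reference image failed to process; "
                                        "relative indices impossible"}
                    result.errors.append(entry)
                    manifest["errors"].append(entry)
                    continue
                try:
                    with warnings.catch_warnings(record=True) as caught:
                        warnings.simplefilter("always")
                        is_ref_frontal = moment is ref_moment and i == 0
                        res = process_image(
                            image, experiment, moment, i,
                            None if is_ref_frontal else ref_result, crop)
                    for wmsg in caught:
                        text = f"{tag}: {wmsg.message}"
                        logger.warning(text)
                        result.warnings.append(text)
                        manifest["warnings"].append(text)
                except PlaquantError as exc:
                    msg = f"{tag}: {type(exc).__name__}: {exc}"
                    logger.error(msg)
                    entry = {"image": tag, "path": image.source_path,
                             "error": type(exc).__name__, "message": str(exc)}
                    result.errors.append(entry)
                    manifest["errors"].append(entry)
                    continue
                if moment is ref_moment and i == 0:
                    ref_result = res
                result.images.append(res)
                result.measurements.append(res.measurement)
                manifest["resolved"].append({
                    "image": tag,
                    "delta": res.labels.delta_used,
                    "l": res.labels.l_used,
                })
                if out is not None and write_images:
                    stem = f"{pid}_{moment.label or 'moment'}_{i}"
                    _write_image_outputs(res, out, stem, manifest)

    if out is not None:
        from .report import write_manifest, write_measurements_csv

        csv_path = out / "measurements.csv"
        write_measurements_csv(result.measurements, csv_path)
        manifest["outputs"].append(str(csv_path))
        write_manifest(manifest, out / "manifest.json")
    result.manifest = manifest
    return result


def _write_image_outputs(res: ImageResult, out: Path, stem: str,
                         manifest: dict) -> None:
    from .report import (
        histogram_to_csv,
        plot_class_charts,
        plot_histogram,
        save_labeled_png,
        save_mask_png,
    )

    paths = {
        "mask": out / f"{stem}_mask.png",
        "labeled": out / f"{stem}_labeled.png",
        "histogram_csv": out / f"{stem}_histogram.csv",
        "histogram_png": out / f"{stem}_histogram.png",
        "pie": out / f"{stem}_pie.png",
        "bar": out / f"{stem}_bar.png",
    }
    save_mask_png(res.mask.mask, paths["mask"])
    save_labeled_png(res.labels, paths["labeled"])
    histogram_to_csv(res.histogram, paths["histogram_csv"])
    plot_histogram(res.histogram, paths["histogram_png"], title=stem,
                   delta=res.labels.delta_used, l=res.labels.l_used)
    plot_class_charts(res.measurement, paths["pie"], paths["bar"])
    manifest["outputs"].extend(str(p) for p in paths.values())
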