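"""Report artifacts: labeled images, histograms, charts, CSV/JSON export."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import matplotlib

matplotlib.use("Agg")

import imageio.v3 as iio
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classification import GBHistogram, Label, RegionLabels
from .data_model import MomentMeasurements

__all__ = [
    "DEFAULT_PALETTE",
    "labeled_image",
    "save_labeled_png",
    "save_mask_png",
    "histogram_to_csv",
    "plot_histogram",
    "plot_class_charts",
    "write_measurements_csv",
    "write_manifest",
]

#: label → RGB. Blue: non-plaque, green: visible plaque, red: level-1
#: non-visible plaque, orange: level-2, black: outside the dental area.
DEFAULT_PALETTE: Mapping[Label, tuple[int, int, int]] = {
    Label.OUTSIDE: (0, 0, 0),
    Label.NONPLAQUE: (0, 0, 255),
    Label.VISIBLE: (0, 255, 0),
    Label.NV1: (255, 0, 0),
    Label.NV2: (255, 165, 0),
}

_CLASS_NAMES = {
    Label.VISIBLE: "visible",
    Label.NV1: "non-visible L1",
    Label.NV2: "non-visible L2",
    Label.NONPLAQUE: "non-plaque",
}


def labeled_image(labels: RegionLabels,
                  palette: Optional[Mapping[Label, tuple[int, int, int]]] = None,
                  ) -> np.ndarray:
    palette = palette or DEFAULT_PALETTE
    out = np.zeros(labels.labels.shape + (3,), dtype=np.uint8)
    for label, rgb in palette.items():
        out[labels.labels == label] = rgb
    return out


def save_labeled_png(labels: RegionLabels, path: str | Path,
                     palette=None) -> None:
    iio.imwrite(Path(path), labeled_image(labels, palette))


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(mask, dtype=bool).astype(np.uint8) * 255)


def histogram_to_csv(hist: GBHistogram, path: str | Path) -> None:
    pd.DataFrame({"gb_value": hist.values, "count": hist.counts}).to_csv(
        path, index=False)


def plot_histogram(hist: GBHistogram, path: str | Path, title: str = "",
                   delta: Optional[float] = None,
                   l: Optional[float] = None) -> None:
    """G-B histogram with the conventional vertical marker at G-B = 0 and,
    when given, the delta and l thresholds."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(hist.values, hist.counts, lw=1.0, color="tab:blue")
    ax.axvline(0, color="black", lw=1.0)
    if delta is not None:
        ax.axvline(delta, color="tab:red", lw=0.8, ls="--", label="delta")
    if l is not None:
        ax.axvline(l, color="tab:orange", lw=0.8, ls="--", label="l")
    if delta is not None or l is not None:
        ax.legend(fontsize=8)
    ax.set_xlabel("G - B")
    ax.set_ylabel("pixels")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_class_charts(measurement: MomentMeasurements, pie_path: str | Path,
                      bar_path: str | Path) -> None:
    """Pie and bar charts of the four class percentages for one image."""
    percents = [
        measurement.area_percent_visible,
        measurement.area_percent_nv1,
        measurement.area_percent_nv2,
        measurement.area_percent_nonplaque,
    ]
    names = [_CLASS_NAMES[c] for c in
             (Label.VISIBLE, Label.NV1, Label.NV2, Label.NONPLAQUE)]
    colors = ["#00c000", "#e02020", "#ff9900", "#2050e0"]

    fig, ax = plt.subplots(figsize=(4, 4))
    shown = [(p, n, c) for p, n, c in zip(percents, names, colors) if p > 0]
    if shown:
        ax.pie([s[0] for s in shown], labels=[s[1] for s in shown],
               colors=[s[2] for s in shown], autopct="%.1f%%",
               textprops={"fontsize": 8})
    fig.tight_layout()
    fig.savefig(pie_path, dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.bar(names, percents, color=colors)
    ax.set_ylabel("% of dental area")
    ax.tick_params(axis="x", labelsize=8)
    fig.tight_layout()
    fig.savefig(bar_path, dpi=110)
    plt.close(fig)


def write_measurements_csv(records: Iterable[MomentMeasurements],
                           path: str | Path) -> pd.DataFrame:
    """One CSV row per image per moment; floats at full precision so users
    can build their own statistics downstream."""
    df = pd.DataFrame([r.to_row() for r in records],
                      columns=list(MomentMeasurements.CSV_COLUMNS))
    df.to_csv(path, index=False)
    return df


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str) + "\n")
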