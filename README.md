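# plaquant

Automated quantification of dental plaque from photographs of
fluorescein-disclosed dentition taken under ultraviolet light.

Dental plaque is the bacterial biofilm behind caries and periodontal
disease. Disclosed with fluorescein and photographed under UV light,
plaque fluoresces **green** while clean enamel fluoresces **bright
blue**, which makes plaque extent measurable planimetrically instead of
by subjective visual scoring. `plaquant` is aimed at dental researchers
running longitudinal plaque-growth or hygiene-intervention studies: it
turns a set of timestamped UV photographs per patient into per-image
plaque maps, histograms and clinical indices, exported as CSV for
downstream statistics.

## Method

For each image the pipeline:

1. **Segments the dental area.** The per-pixel sum B + R is thresholded
   at the quantile `background_fraction` (default 0.75: the darkest 75%
   of pixels is background). Near-white specular reflections
   (min(R,G,B) ≥ 240) and isolated pixels are removed, and 8-connected
   components are kept only if their size exceeds 2000 px and their
   solidity (area / convex-hull area) exceeds 0.5 — discarding gingiva
   highlights, lips and other non-dental structures.
2. **Classifies every dental pixel** by the signed channel difference
   G − B, with thresholds l ≤ δ ≤ 0:

   | class | condition | meaning |
   |---|---|---|
   | VISIBLE | G − B > 0 | visible plaque |
   | NV1 | δ ≤ G − B ≤ 0 | non-visible plaque, short-term risk |
   | NV2 | l ≤ G − B < δ | non-visible plaque, medium-term risk |
   | NONPLAQUE | G − B < l | no risk in the medium term |

   Dental pixels with G = 0 or B = 0 carry no fluorescence signal and
   fall to NONPLAQUE. δ defaults to **auto**: −|mean(B) − mean(G)| over
   the dental area. l is derived automatically from the non-visible
   plaque histograms of the current and reference images: the first
   (most negative) G − B value where the current count exceeds the
   reference count (falling back to l = δ when no such value exists).
3. **Computes clinical indices**, per image and relative to the
   patient's *reference moment* (the baseline after perfect dental
   cleaning):
   - class areas as % of the dental area;
   - **API index** (0–100) = visible-area fraction × mean(G − B over
     visible)/255 × 100 — plaque extent weighted by stain intensity;
   - **area growth index** (%/h) = (area − reference area) / elapsed
     hours;
   - **area time index** (days) = (100 − area) / growth rate / 24, the
     linear extrapolation of the time left until plaque covers the
     whole dental area. Both growth indices come in a *visible* and a
     *total* (visible + NV1 + NV2) variant.

Since clinical photographs cannot be shipped, the package includes a
deterministic synthetic-scene generator (`plaquant.synth`) that renders
UV-like dentition images — dark background, dim reddish gingiva, bright
blue elliptical teeth, coherently growing green plaque patches, optional
specular artifacts — together with ground-truth masks and programmable
linear plaque growth, so the entire pipeline is testable end to end.

## Worked example

Generate a synthetic 96-hour experiment (5 moments, 24 h apart,
programmed visible-plaque growth of 0.75% of the dental area per hour)
and process it:

```sh
plaquant synth --out exp --seed 7 --moments 5
plaquant run exp/experiment.yaml --out results
```

`results/measurements.csv` then contains one row per image; the key
columns are:

```
moment_label  elapsed_hours  area_percent_visible  api_index  growth_index_visible  area_time_visible  delta_used   l_used
          M0            NaN                 0.000      0.000                   NaN                NaN    -145.030 -145.030
          M1         24.000                18.002      4.949                 0.750              4.555    -103.900 -193.000
          M2         48.000                35.996      9.879                 0.750              3.556     -63.950 -189.000
          M3         72.000                53.998     14.807                 0.750              2.556     -24.985 -126.000
          M4         96.000                72.000     19.755                 0.750              1.556     -12.995 -122.000
```

Reading M4: after 96 h, visible plaque covers 72.0% of the dental area;
the recovered growth index is 0.750 %/h, exactly the programmed rate;
at that rate the remaining 28% would be covered in
(100 − 72)/0.75/24 ≈ 1.56 days (`area_time_visible`); the API index of
19.8 combines the 72% extent with the moderate mean stain intensity.
The reference moment M0 has no relative indices, and its automatic
δ (−145.0) reflects the large blue-green separation of clean enamel;
δ rises toward 0 as plaque accumulates. The output directory also holds,
per image, the dental-mask PNG, the labeled map (green = visible plaque,
red = NV1, orange = NV2, blue = non-plaque, black = outside), the G − B
histogram (CSV + plot with the conventional marker at G − B = 0) and
pie/bar charts, plus `manifest.json` recording the resolved δ and l of
every image.

Real experiments use the same YAML config format that
`plaquant synth` writes: patients, moments (image paths, ISO-8601
timestamps, `is_reference` flags, optional crop rectangles) and a
processing-parameter block. `plaquant segment <image>` runs the
segmentation stage alone for debugging.

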