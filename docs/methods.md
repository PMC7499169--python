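# Methods

## Imaging model and assumptions

Input images are 8-bit RGB photographs of fluorescein-disclosed
dentition under ultraviolet light. The method assumes the standard
fluorescence signature: plaque fluoresces green (G > B), clean enamel
fluoresces blue (B ≫ G), gingiva and background are comparatively dark.
All decisions are per-pixel color rules plus connected-component
geometry; there is no learned model, so results are deterministic and
fully reproducible from the configuration file.

Images larger than `max_image_bytes` (default 5 MB of raw raster) are
decimated by the smallest integer factor that brings them under the
limit. Integer decimation keeps 8-bit values untouched instead of
interpolating, which would smooth the G−B histogram.

## Dental-area segmentation

1. Optional axis-aligned crop (configured per image; replaces manual
   cropping in an interactive tool).
2. **Brightness threshold.** The per-pixel B+R sum (0–510) is sorted
   and the value at rank ⌈`background_fraction`·N⌉ becomes the
   threshold; pixels strictly above it are foreground. Ties at the
   threshold value go to the background — the "darkest fraction" is
   read inclusively. The fraction is a *percentile of pixels*, not of
   the intensity range. A constant image yields an empty foreground and
   a `DegenerateImageWarning`.
3. **Bright-artifact removal.** Specular reflections of the lamp are
   bright in *every* channel, unlike fluorescence which is bright in
   one; pixels with min(R,G,B) ≥ `artifact_intensity_floor`
   (default 240) are dropped. This is a single documented heuristic
   with one parameter; real acquisition setups may need the floor
   adjusted.
4. **Isolated-pixel removal.** Foreground pixels with zero true
   neighbors in their 8-neighborhood are cleared.
5. **Component filtering.** 8-connected components are kept when
   area > `min_region_size` (default 2000 px) *and*
   solidity > `min_solidity` (default 0.5), where solidity is the
   standard regionprops ratio of component area to convex-hull area.
   Survivors are relabeled 1..K. Nothing surviving raises
   `EmptyDentalAreaError`.

8-connectivity is used throughout (both for isolated-pixel removal and
labeling): it avoids splitting thin enamel ridges and matches common
imaging practice. Note that `min_region_size` is a pixel count and
therefore resolution-dependent: at half the linear resolution the same
anatomy has a quarter of the pixels, so the parameter should be scaled
by the area factor when image sizes change.

## Pixel classification

The signed difference G−B is computed on dental pixels (int16, range
[−255, 255]). With thresholds l ≤ δ ≤ 0:

- VISIBLE: G−B > 0
- NV1: δ ≤ G−B ≤ 0 (both ends inclusive — δ itself is NV1)
- NV2: l ≤ G−B < δ (l itself is NV2)
- NONPLAQUE: G−B < l

Dental pixels with G = 0 or B = 0 are excluded from the risk classes
and labeled NONPLAQUE: a zero channel means no fluorescence signal,
so risk grading would be meaningless there. The four classes partition
the dental area exactly for any l ≤ δ ≤ 0.

**δ (auto).** Minus the absolute difference between the mean blue and
mean green channel over the dental area of the *current* image. Stored
non-positive by convention so it can be compared to G−B directly; on
clean dentition it is strongly negative (large blue-green separation)
and rises toward 0 as plaque accumulates. Making δ more negative can
only grow NV1 at the expense of NV2; VISIBLE and NONPLAQUE are
unaffected.

**l (auto).** Computed from the *non-visible plaque histograms*
(unit-width bins over G−B ≤ 0, restricted to pixels with G > 0 and
B > 0) of the current image and of the patient's reference image:
scanning from −255 upward to 0, l is the first value where the current
count strictly exceeds the reference count. The restriction to
risk-eligible pixels keeps signal-free pixels out of the comparison;
the alternative (all non-positive pixels) was considered and rejected
for that reason. When no bin qualifies — in particular when current and
reference are the same image — l falls back to δ and NV2 is empty.
This fallback is a design choice for the otherwise-undefined case; it
makes the reference moment itself carry no NV2 by construction.

## Clinical indices

- **area_percent(class)** = 100 · pixels(class) / dental pixels.
- **API index** = (visible fraction) · (mean G−B over VISIBLE / 255) ·
  100. The index is specified in the literature only as an
  "area-per-intensity" value bounded to [0, 100]; the product form here
  is a *reconstruction* — the simplest expression that attains the
  bounds and is monotone both in plaque extent and in mean stain
  intensity. Intensity is the mean G−B of visible pixels (the quantity
  the visible-plaque rule is defined on), not raw G. API = 0 when no
  pixel is visible plaque.
- **Area growth index** (%/h) = (area% now − area% at reference) /
  elapsed hours, always measured against the reference moment (not
  between consecutive moments), since the reference is the defined
  baseline after perfect cleaning. Negative growth is allowed.
- **Area time index** (days) = (100 − area%) / growth rate / 24 —
  linear extrapolation at constant rate; 0 when the area is already at
  100%, not computable (empty field) when the rate is ≤ 0. The "100%"
  refers to the whole dental area. Exactly:
  area% + 24 · rate · area_time = 100.
- Both growth and area-time have *visible* and *total*
  (VISIBLE+NV1+NV2) variants. Total can extrapolate slower than
  visible when the reference moment already carries a large NV1 region
  (its total baseline is high), which is common: clean enamel
  concentrates near δ.

Every image yields its own measurement row; frontal and lateral views
are never averaged. Cross-moment comparability relies on percentages,
which are invariant to the dental-area pixel count; the ratio
(reference dental pixels / current dental pixels) is recorded as
`normalization_factor` rather than resampling images, since resampling
would perturb the G−B histogram that l depends on.

Elapsed time is computed in fractional hours from timezone-naive
timestamps; reported times are in hours (growth) and days (area time).

## Synthetic scenes

`plaquant.synth` renders what the pipeline needs to be true of real
images, and nothing more: near-black background, a dim reddish gingiva
band whose B+R brightness sits between background and teeth (so the
default 75% threshold excludes it, as in real photographs), bright blue
elliptical teeth (B ≈ 205, G ≈ 60), green plaque patches with a
programmable G−B margin (default +70 ± 10), optional near-white
specular discs, and i.i.d. Gaussian channel noise (default σ = 5).
Plaque patches grow contiguously outward from a per-tooth anchor to an
exact coverage fraction, so connected-component logic sees realistic
shapes and a series' patches nest as coverage rises. A time series
grows coverage linearly at a programmed rate (default 0.75% of the
dental area per hour over 5 moments spaced 24 h — a typical no-hygiene
growth design) and drifts clean-enamel green mildly upward
(0.12 intensity/h), flattening the negative histogram lobe the way real
series do. The enamel B−G margin (≈ 140) exceeds 3× the noise σ by
construction, so the G−B > 0 rule cannot misfire from noise alone.

What the generator does **not** model: photorealistic texture,
fluorescein photobleaching, camera optics and vignetting, uneven
illumination, saliva specularity beyond circular discs,
tooth-boundary partial-volume pixels, or inter-patient anatomical
variation. Passing tests therefore demonstrate correctness of the
*algorithms* under the stated color contract, not clinical performance
on patient photographs.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give bit-identical images,
and per-moment seeds are derived with `SeedSequence` while the
plaque-anchor seed stays fixed across a series.

## Numerical choices and degenerate inputs

- The quantile threshold uses strict `>` for foreground; threshold-value
  ties are background.
- G−B is exact integer arithmetic; δ and l are floats compared against
  integers, so boundary semantics are exact.
- Histograms use integer bins of width 1 (511 bins, −255..255).
- Degenerate cases: constant image → warning + empty foreground; no
  surviving component → per-image error (the batch continues); empty
  dental mask in any downstream computation → error; elapsed time 0 →
  relative indices undefined; growth ≤ 0 → area time not computable.
- Problem sizes in the test-suite and acceptance script (520×400
  canvases, 5-moment series, 20–50 scenes, 100 random 256×256 oracle
  images) were chosen to exercise every code path at full statistical
  contrast while completing in well under a minute each.

## Known limitations

- The bright-artifact rule and the API formula are single documented
  reconstructions of behavior that interactive tools expose only
  qualitatively; both are parameterized/flagged so they can be revised
  against clinical ground truth.
- The l fallback (l = δ) for non-crossing histograms is a convention.
- Indices assume the dental area is comparable across moments for the
  same patient (similar pose and framing); there is no registration
  step.
- No group-level statistics: the CSV export is the interface for
  downstream analysis.
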