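# Methods

## Scope and data model

All pipelines operate on calibrated 2-D multi-channel images
(`MultiChannelImage`): a `(channels, height, width)` array with named
channels and a pixel size in µm/px. Pixel values are used exactly as loaded
— no rescaling or histogram stretching — because acquisition is assumed to
use identical illumination across conditions and any normalization is a
pipeline decision, not a loader side effect. Coordinates are (row, col),
0-based, origin top-left; conversion to micrometres happens only when a
length is reported. The pixel size is always an explicit input: typical
confocal sampling of ~0.1 µm/px is used as the *generator* default, but no
acquisition value is assumed for real data.

## Thresholding

Otsu's threshold is computed on a 256-bin histogram spanning the observed
min–max of the pooled values, for every bit depth, so 8- and 16-bit inputs
behave identically. Foreground is strictly `value > threshold`. Constant
input raises a degenerate-input error rather than returning an arbitrary
cut. On histograms with an empty valley the between-class variance ties
exactly over many candidate splits; any tied candidate is a valid Otsu
threshold, and the tests therefore check that the returned threshold
*attains* the exact maximum (verified in rational arithmetic) rather than
comparing threshold values.

Three entry points:

- `channel_mask` — per-channel Otsu followed by morphological closing
  (disk, default radius 1 px; radius 0 disables closing). Closing bridges
  1–2 px gaps from shot noise without inflating object outlines.
- `combined_channel_mask` — for dual-channel JC-1 images; default is the
  *union* of the per-channel masks so mitochondria visible in only one JC-1
  form (monomer-only at collapsed potential, aggregate-only at high
  potential) are retained. An Otsu-on-channel-sum mode exists
  (`mode="sum"`) for users who prefer a single joint threshold.
- `global_otsu` — one threshold from the pooled histogram of an entire
  batch, applied unchanged to every image. Per-image Otsu is invariant to
  gain, so it would silently equalize a dim and a bright condition; the
  pooled threshold preserves such differences. It is permutation-invariant
  and invariant to how the same pixels are split across images.

Connected components default to 8-connectivity for foreground.

## Colocalization

Given two channels, the pipeline builds both Otsu+closing masks, their
union, and an optimized scan line, then reports:

- **pixel-wise PCC** over the union mask;
- **line PCC** on the two bilinear intensity profiles along the scan line;
- **Manders M1/M2** in the classical thresholded form: each channel's own
  mask is its domain, the other channel's mask the colocalization
  criterion;
- **ICQ** over the union mask, excluding pixels whose mean-deviation
  product is exactly zero from both numerator and denominator (masked
  zeros would otherwise bias the count).

The scan line is the full-image chord through the union-mask centroid at
the orientation (among `n_orientations` = 36 evenly spaced in [0, π))
maximizing the summed product of the two channels' bilinear samples
(step 0.5 px, endpoint-inclusive). Ties break deterministically to the
smallest orientation index. The objective is deliberately parameter-light
and pluggable; other optimization criteria would select different lines,
so line-PCC values are comparable only within a fixed criterion.

A statistic that is undefined on an image (constant channel, empty union,
all-zero products) is reported as missing with its reason — never as 0.
Values are reported per image; no cross-cell aggregation rule is imposed.

## JC-1 membrane-potential profiling

Objects come from the combined red/green mask and connected-component
labeling. For each object with at least 2 px:

1. the principal axis is the leading eigenvector of the intensity-weighted
   (red+green) covariance of pixel coordinates — weighting suppresses the
   influence of dilated mask halos; an unweighted mode is available. The
   direction sign is fixed (row component ≥ 0) and objects with an
   eigenvalue ratio < 1.2 are flagged near-isotropic, since their axis is
   arbitrary;
2. both channels are sampled along the axis by bilinear interpolation
   (default step 0.25 px) across the object's projection extent;
3. each profile is normalized to its own maximum ("per-profile" reading of
   normalization to respective maxima; a per-image mode is available).
   All-zero profiles are reported raw with a flag instead of divided;
4. the red/green ratio is computed where the normalized green exceeds 0.05
   (configurable) to avoid division blow-ups, and the within-object
   pixel-wise red–green PCC ("pix PCC") plus the variance of the ratio
   along the axis (the mosaic readout) are reported.

JC-1 objects are *not* passed through the 1–20 µm morphometry filter by
default; the two analyses are independent.

## Morphometry

Per image, tubeness is the maximum over scales σ ∈ {1, 2, 3, 4} px of the
Frangi vesselness for bright ridges with β = 0.5. The structureness scale γ
is set to half the maximum structureness per scale; in batch runs the
maximum is pooled over *all* images (`batch_tubeness`). The pooled-γ choice
matters: γ normalized per image rescales every response to that image's own
strongest ridge, which amplifies noise-only images to full scale and erases
the inter-condition differences the batch-global threshold exists to
preserve. With pooled γ the response is invariant to an additive offset and
to a gain applied to the whole batch, while relative differences between
images survive.

Segmentation applies one `global_otsu` threshold to all tubeness maps
(scope = the whole manifest; a per-condition override exists but defaults
off), then labels 8-connected components. Per object:

- **skeleton length** — topological thinning, pruning of spur branches
  shorter than 2 px (suppresses digitization spurs on thick tubes), then a
  weighted step sum over adjacent skeleton pixels, skipping diagonal steps
  that already have an axial 2-step path. Default weights are Kulpa's
  corrected chain-code weights (0.948 axial, 1.343 diagonal), which are
  unbiased for digital straight lines of random orientation; the naive
  (1, √2) weights overestimate oblique lines by ~5–8 % and are available as
  `step_weights="plain"`. An optional endpoint-completion term (the
  distance-transform radius at each skeleton tip) exists for blunt-ended
  masks but is off by default: thinning of the round-capped masks produced
  by tubular fluorescence ends at the centerline endpoints already, and on
  such masks the correction would double-count the caps.
- **aspect ratio** — major/minor axis of the unweighted second-moment
  ellipse, minor axis floored at 1 px so 1-px-thin lines get a finite,
  large value; always ≥ 1.
- the 1–20 µm filter is a closed interval on skeleton length (a
  major-axis-length metric is available by config). Objects below 1 µm are
  counted as noise, above 20 µm as fused networks; both counts are
  reported since network-dominant cells are scored separately from
  per-object statistics. Border-touching objects are measured and flagged
  but kept.

Summaries report mean, median, SD of length, mean/median aspect ratio and
n per condition.

## Synthetic fields

The generator emulates the statistical structure the pipelines assume:

- **tube fields** — centerlines are random-walk polylines with equal 2-px
  segments and a curvature cap (0.2 rad per step), so the true length is
  the analytic polyline length (quantized to 0.2 µm at the default
  0.1 µm/px). Tubes render as `amp · exp(−d²/2σ²)` of the distance to the
  rasterized centerline; "width" in the API is the visible full width at
  half maximum, σ = width/2.355, matching mitochondrial diameters of
  0.2–0.5 µm at confocal sampling. Placement enforces a minimum centerline
  separation with a retry budget (density error on failure).
- **colocalization fields** — isotropic Gaussian spots; `round(f·n)` spots
  are exact duplicates (same position and amplitude) in both channels, the
  remainder disjoint, all centers ≥ 4σ apart. Truth records the designed
  `f` and the realized intensity-weighted overlap.
- **JC-1 fields** — dual-channel tubes whose red/green amplitude follows
  the normalized arclength: `uniform`, `half-half` (red dominates s < 0.5,
  with a 12 % floor in the dominated channel so masks stay contiguous), or
  `gradient` (linear crossover).
- **noise** — Poisson shot noise (mean = clean × `poisson_scale`, divided
  back), additive Gaussian read noise (sd 50), a smooth background
  (level 300, ±20 % low-frequency modulation), clipping at 0 and 16-bit
  quantization. Default tube amplitudes are 6000–9000 (±20 % about 7500 on
  the 16-bit scale), emulating uniform dye loading under identical
  illumination; peak SNR is ≈ 60. Everything is bit-reproducible from the
  seed.

What the generator does **not** emulate: a realistic PSF (the Gaussian
cross-section stands in for lateral blur; there is no Airy structure),
out-of-focus light from 3-D structure, spectral bleed-through between
channels, intensity-dependent photobleaching, or touching/crossing
organelles (placement forbids overlap). Passing tests therefore validate
the estimators under clean, well-separated geometry; on real images,
crossing mitochondria merge into single labeled objects (no watershed
splitting is attempted) and bleed-through would bias colocalization
statistics upward.

## Numerical choices and degenerate inputs

- Bilinear sampling is exact at integer pixel centers and on linear ramps;
  out-of-bounds samples clamp to the border value.
- Profile/line sampling is endpoint-inclusive with the largest step ≤ the
  requested one that divides the segment evenly.
- Undefined statistics (zero variance, zero denominators, empty masks,
  single-pixel objects) raise typed errors at the function level and are
  skipped-and-counted or reported as missing at the pipeline level.
- Output tables are byte-identical across reruns with the same inputs and
  config; timestamps appear only in the provenance JSON.

## Known limitations

- Frangi response amplitude scales with ridge contrast and inversely with
  tube width, so under one global threshold, dim *and* wide tubes are the
  first to fragment when within-field brightness varies by more than
  roughly two-fold.
- A batch containing **only** background/noise images still produces
  spurious supra-threshold ridges (γ then normalizes to the noise's own
  structureness); the empty-result guarantee holds only for background
  images inside a batch anchored by real signal.
- Skeleton-length accuracy (≤ 10 % for ≥ 10 px tubes) degrades below ~1 µm
  at 0.1 µm/px, where tip effects dominate; the 1 µm filter floor removes
  that regime from reported statistics.
- The scan-line objective (summed joint intensity) is one reasonable
  choice among several; line-PCC values are tied to it.

## Problem sizes in the validation suite

The test and acceptance runs use 192–512 px fields, 5–10 objects per field,
10–20 seeds per condition and 100-seed batches for rate estimates — sizes
chosen so the full validation completes in minutes on one CPU while keeping
Monte-Carlo standard errors well inside the asserted tolerances.
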