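# Methods

## Model and assumptions

The scorer treats an eye image as a noisy rendering of a point pattern:
one centroid per ommatidium, arranged in the wild type as a triangular
(hexagonally packed) lattice. Disorder is measured purely on the
centroid pattern — intensities and facet shapes influence detection but
not the indices. The method assumes one eye per image, ommatidia that
appear as roughly circular blobs at a single characteristic scale, and
enough of the lattice in view that a median nearest-neighbor distance is
meaningful.

For each detected centroid the six nearest detections define a vector
fan. A detection is *stable*, and eligible for a fan, only if all six
of those neighbors lie strictly within 2.0 × the image-wide median
nearest-neighbor distance. This removes border ommatidia and isolated
detections, whose "six nearest" would span holes in the pattern and
carry no geometric meaning. The strictness of the inequality matters in
degenerate configurations: on a seven-point regular hexagon, the rim
points' sixth neighbor sits exactly at twice the spacing, and only the
central point should be scored.

Per-fan disorder is distance spread (sum of the five longest vector
lengths minus five times the shortest) plus angle spread (the analogous
sum over the six consecutive angular gaps, in degrees). The two are
summed without weighting; pixels and degrees are deliberately mixed, so
the local ordering key `odi_local = odi_d + odi_a` — and therefore which
ommatidia count as "most ordered" — depends on the image scale. This is
a property of the index as defined, not an implementation accident; a
consequence is that the eye-level scaling law (ODI_D linear in scale,
ODI_A invariant) is exact per fan, and exact at eye level only when the
requested N saturates the stable count.

The severity score is P = (ODI / n_used) · (N / Z) with N the requested
count (default 200) and Z all detections (not only stable ones): mean
disorder of the selected ommatidia, inflated when the eye offers fewer
ommatidia than requested, since fused or missing facets are themselves
part of severity. With zero detections, or no stable fan, P is
undefined and reported as `NA`.

## Detection

1. **Contrast normalization.** Affine stretch from the 0.5th intensity
   percentile to the image maximum. The ceiling is the true maximum, not
   a percentile: saturating peak tops would bias sub-pixel centroids.
   The stretch is global rather than tile-based; tile-based equalization
   would make detection depend on where the eye sits in the frame,
   breaking translation equivariance.
2. **Polarity.** SEM images (shaded domes: dark facet centers on a
   bright field) are inverted so both modalities present bright spots.
   The SEM preset also uses a larger structuring element (12 px vs 9 px);
   the presets are configuration data on one code path.
3. **White top-hat** with a disk structuring element (radius 9 px by
   default, which must exceed the facet radius and is rejected if it
   exceeds a quarter of the image side). This removes smooth
   illumination exactly (a linear ramp is reproduced by its morphological
   opening away from borders) while preserving spot-scale structure.
4. **Peak finding** on a lightly smoothed (σ = 1 px) copy, at a
   threshold relative to the brightest peak (0.25 by default), with a
   minimum separation of one spot diameter — two maxima closer than
   2 × the minimum spot radius cannot be two ommatidia. Peaks within
   one structuring radius of the border are not accepted; the top-hat is
   unreliable there.
5. **Sub-pixel refinement.** Each integer peak is refined by a
   background-subtracted intensity centroid over a circular window on
   the *unsmoothed* top-hat, with one recentering pass. The window
   radius is 0.49 × the median nearest-neighbor spacing of the integer
   peaks, so a window never reaches into a neighboring facet; the
   background is the median of the window's outer ring. On clean
   synthetic renders this localizes centers to ~1e-6 px; under default
   sensor noise, to ~0.1 px.
6. **Radius and filtering.** Each spot's radius is the equivalent radius
   of its above-half-peak area, falling back to half the lattice spacing
   when that fit is degenerate; detections outside the configured radius
   bounds are dropped. Duplicates are merged greedily, brightest first
   (ties by (cy, cx)), enforcing the configured minimum separation
   (default = minimum spot radius). Output is sorted by (cy, cx); the
   list length is Z.

All tie-breaks are deterministic, and nothing draws randomness, so a
fixed image and configuration give bit-identical output — which is what
makes the serial/parallel batch contract testable as byte equality.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `structuring_radius_px` | 9 (SEM: 12) | px | top-hat scale; > facet radius, ≪ eye size |
| `min_spot_radius_px` / `max_spot_radius_px` | 1.5 / 12 | px | plausible facet radius band |
| `peak_threshold` | 0.25 | relative | peak acceptance vs brightest peak |
| `merge_distance_px` | = min radius | px | one circle per ommatidium |
| `smoothing_sigma_px` | 1.0 | px | peak-finding smoothing only |
| `n_requested` (`-n`) | 200 | count | most-ordered ommatidia totalled into ODI |

The bright-field defaults are calibrated to the synthetic generator's
facet scale (~4 px spot radius at ~14 px spacing) and validated only
against it; real micrographs at other magnifications need the radii and
structuring element rescaled accordingly.

## Synthetic ground truth

The generator lays out a rows × cols triangular lattice (odd rows offset
by half the spacing, vertical pitch spacing × √3/2), applies isotropic
Gaussian jitter, removes floor(fraction × count) points without
replacement, and renders each point as a cosine²-windowed Gaussian spot
(σ = radius/2, compact support 1.5 × radius) with optional linear
illumination gradient, additive Gaussian noise, and an SEM variant that
inverts polarity under a radial dome shading. Spot amplitude is 0.65 so
a 30% gradient plus noise cannot saturate the canvas. Margins of twice
the spacing guarantee no spot is clipped. All randomness derives from
the integer seed.

Defaults — 16 × 17 lattice (272 points, comfortably above N = 200 so a
clean eye's selection draws only interior fans), 14 px spacing, 4 px
spots — model a typical adult-eye micrograph at working resolution.

The smooth compact spot profile is deliberate: a C¹ profile sampled on
the pixel grid carries essentially no aliasing, so intensity centroids
of clean renders recover the true centers to ~1e-6 px and the
zero-disorder baseline can be verified through the full image pipeline,
not just on exact coordinates. What the generator does *not* emulate:
eye curvature and the resulting foreshortening, specular pseudopupils,
inter-ommatidial bristles, facet-to-facet brightness variation, blur,
and compression artifacts. Passing tests therefore demonstrate the
geometry and the pipeline plumbing, not robustness to everything real
optics does; the detection presets are the tunable surface for real
data.

## Numerical choices

- "Exact zero" disorder on a perfect lattice is exact only in real
  arithmetic: lattice y-coordinates are irrational multiples of the
  spacing, so computed neighbor lengths agree to ~1e-12 and eye-level
  indices to ~1e-10. Tests assert < 1e-9, the same tolerance used for
  rigid-motion invariance.
- Bearings are degrees in [0, 360), sorted ascending; gaps are cyclic
  consecutive differences and sum to 360 within 1e-6. Consecutive gaps
  are the only convention that yields six angles from six vectors.
- The `-h` orientation flag rotates 90° counter-clockwise. The indices
  are rotation-invariant, so the direction is a convention fixed for
  reproducibility, not a scientific choice.
- Intensity canonicalization divides by the dtype ceiling (255 or
  65535); color inputs use BT.601 luminance weights.
- Degenerate inputs: rasters under 64 × 64 are rejected on load;
  a blank image scores Z = 0 with undefined P; fewer than seven
  detections yield no fans, hence ODI = 0 and undefined P.
- Batches run on threads; images are independent, records are collected
  by input index, and equality across worker counts is asserted at the
  byte level in CSV output.

## Problem sizes

The validation suite runs clean-lattice recovery over 20 seeds
(~5,400 facets), jitter monotonicity over 30 seeds × 3 jitter levels on
exact centroid sets, brute-force neighbor verification on up to 300
random points × 20 seeds, and a 20-image parallel batch — a few seconds
each, chosen to give stable Monte-Carlo means while keeping the whole
suite around ten seconds.

## Known limitations

- One eye per image; no eye-region segmentation distinct from spot
  detection.
- The severity formula P = (ODI/n_used)·(N/Z) is this package's
  definition of "computed from ODI and Z"; other tools in this space
  may scale differently, so compare P values only within one tool.
- ODI mixes pixels and degrees unweighted; comparisons across
  magnifications require rescaling images, not just reinterpreting
  scores.
- SEM handling (inversion + dome shading robustness) is validated on
  the synthetic dome model only.
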