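# Methods

## Model and assumptions

`findwormz` treats worm detection as a brightfield segmentation problem and
fluorescence quantification as mask transfer. The assumptions are:

1. **Worms do not touch.** Animals are pushed apart before imaging. No
   watershed or learned splitting is attempted; two touching worms become
   one elongated component whose worminess usually exceeds the band's upper
   bound, so they are rejected rather than mis-measured.
2. **Worms are dark on a brighter backlit background** after illumination
   correction. A polarity switch covers the opposite optics.
3. **Fluorescence is measured raw.** Contrast, illumination and blur apply
   only to the brightfield channel used for locating worms; the measured
   channel is never rescaled, so means are in acquisition units.
4. **One background per image.** The background is the mean fluorescence of
   every pixel outside the *step-2* foreground mask — the cleaned threshold
   output *before* the worminess/size filters. Debris detected at
   thresholding is therefore excluded from the background even though it
   never enters the measurements. Background-subtracted means may be
   negative and are reported as-is; clamping would bias condition means
   that sit near background.

## The worminess score

For a labeled component with perimeter *P* and pixel area *A*,
`W = P / (4 sqrt(A))`. The score is scale-invariant; its continuous floor is
a circle at `sqrt(pi)/2 ≈ 0.8862` (0.89 at two decimals) and a square scores
exactly 1. Straight tubes of length *L* and width *w* (capsules) score
`(2L + pi w − 2w) / (4 sqrt(Lw − w² + pi w²/4))`, ≈ 1.54–1.84 for aspect
ratios 8–12, which is why the default acceptance band is [1.5, 2.1]
(inclusive at both ends). Mutant morphologies may need the band moved.

**Perimeter estimator.** Perimeter uses the 4-direction Crofton formula
(`skimage.measure.regionprops.perimeter_crofton`), recorded in metadata as
`crofton-4dir`. Naive boundary-pixel counting inflates diagonal runs by
11–27%, which would push worm scores out of the band; Crofton is nearly
unbiased on the smooth boundaries that matter here (rasterized disk of
radius 100 px: 0.889 vs 0.886 continuous; seeded capsule suite: within
discretization of the closed form). Its known weakness is axis-aligned
straight edges, which it reads ≈ 5.7% short (a 50-px square measures 0.942
rather than 1.0); this does not affect worm-shaped or round objects but is
asserted with widened tolerances in the rectangle tests.

## Pipeline stages and defaults

Fixed order: contrast → illumination → blur → threshold → clean → label →
measure shapes → worminess filter → size filter → background → measure
fluorescence → overlay.

| parameter | default | units | why |
|---|---|---|---|
| `contrast_low_pct` / `contrast_high_pct` | 1 / 99 | percentile | robust linear stretch to [0, 1]; immune to hot/dead pixels |
| `illum_sigma` | shorter side / 8 | px | illumination varies on the field scale, worms on a much finer one |
| `illum_mode` | divide | — | brightfield shading is multiplicative; subtract mode available |
| `blur_sigma` | 2 | px | evens out intra-worm light/dark patches enough for one global threshold |
| threshold | Otsu | — | maximizes between-class variance; exact distinct-value histogram for quantized images; `fixed(t)` mode available |
| polarity | dark_foreground | — | worms read darker than the backlit background |
| `max_hole_area` | 100 | px² | holes ≤ this inside objects are filled (bright gut granules etc.) |
| `min_speck_area` | 20 | px² | foreground islands < this are dropped before labeling |
| connectivity | 8 | — | 1-px diagonal worm sections must not fragment |
| band | [1.5, 2.1] | — | capsule scores for aspect 8–12 worms, see above |
| `min_area` | 200 | px² | below any plausible worm at the working magnification; magnification-dependent |
| `exclude_border` | false | — | border-touching worms are kept but flagged `touches_border` |

All convolutions use reflective padding so image borders do not acquire
dark rims that would segment as objects. Otsu on a constant image is
undefined and yields an empty mask with a warning. Standard deviations are
population (divide by *n*). Output rows are sorted by (pair_id,
worm_number) and numbering matches the overlay, so reruns are
byte-identical.

## Synthetic plates

The generator renders what the pipeline needs to see, not photorealism:

* **Worms**: filled tubes of width *w* around a sinusoidal midline of arc
  length *L* (defaults L = 120 px, w ∈ [10, 15] px, bend amplitude up to
  0.2 L), rasterized via a distance transform; uniform dark gray on the
  brightfield (an optional *mottled* mode adds intra-worm light/dark
  banding to exercise the blur step).
* **Placement**: uniformly random rotation/position with a minimum
  clearance between objects (default 12 px). The clearance must exceed the
  blur kernel's bridging distance: animals a pixel or two apart are
  "touching" at the method's working resolution and would merge into one
  rejected component.
* **Debris and specks**: round disks (worminess ≈ 0.89, rejected by the
  band) and 4-px specks (removed by cleanup). Debris emits no fluorescence —
  it occludes the background glow, reading ≈ 0 in the fluorescence channel —
  which is what makes the background-rule regression informative; a flag
  makes debris bright instead for QC stress tests.
* **Signal**: fluorescence = planted background (default 1000) everywhere,
  planted per-worm mean on worm pixels, Gaussian noise (default sd 300,
  ≈ 0.5% of the 16-bit range, small enough that clipping at zero is
  negligible). Brightfield = bright field × multiplicative ramp
  (0.85–1.15) with worms/debris dark, plus 1% noise.
* **Determinism**: all draws flow from the single spec seed; placement and
  noise use separate streams so adding debris to a scene moves neither the
  worms nor the noise realization.

What the plates do **not** emulate: real worm texture (gut granules,
embryos), eggs and larvae, out-of-focus blur, vignetting beyond a linear
ramp, or touching animals. Passing the synthetic suite therefore shows the
pipeline's logic and numerics are correct under the stated model; it does
not certify segmentation quality on any particular microscope's output,
which is what the color-coded QC overlay is for.

## Verification at a glance

The test suite checks, among others: exact Otsu agreement with an
exhaustive between-class-variance search; hole-fill/speck-removal pixel
accounting and idempotence; worminess scale invariance and the 0.85
discrete floor over 1,000 random convex blobs; recovery of planted
per-worm means under true masks to within 2·sd/sqrt(area); and, end to end
over 20 seeds of a 4-condition suite (20 worms per condition, debris and
specks present), perfect recall and precision at IoU ≥ 0.6 with planted
condition ordering preserved and min–max-scaled recovered vs planted means
correlating > 0.99.

The background regression pins the threshold (`fixed`, t = 0.6) when
comparing a plate with and without debris: under Otsu, injected dark pixels
shift the global threshold slightly, moving every worm boundary a fraction
of a pixel, and that halo effect (~0.5% of background) would mask the
quantity under test — the step-2-mask rule itself, which holds to < 0.1%
while a deliberately wrong post-filter background shifts by > 1%.

## Known limitations

* Touching or overlapping worms are rejected, not split.
* The worminess band assumes wild-type adult proportions; dumpy or long
  mutants need the band adjusted.
* Border-truncated worms are measured over their visible pixels only
  (flagged, optionally excluded).
* The Crofton perimeter slightly underestimates rectilinear outlines; only
  relevant if the filter is reused for non-biological shapes.
* A single global threshold assumes blur can unify intra-worm contrast; at
  extreme transparency the mask may split one animal into pieces that the
  size filter then drops.
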