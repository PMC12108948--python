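# Methods

## Model and assumptions

The segmenter assumes a bitewing's decisive structure is geometric: two
rows of radiopaque crowns separated by a radiolucent occlusal band, with
radiolucent interdental gaps between neighboring crowns. Everything else —
exposure, restorations, braces, noise — is handled by per-image adaptive
binarization rather than fixed thresholds. Three assumptions matter:

1. the occlusal band is roughly straight, so a single global rotation can
   level it;
2. when leveled, at least one row of the binarized image inside the middle
   third crosses only background, so the masked horizontal-projection
   trough is a sharp function of angle;
3. interdental gaps produce vertical-projection valleys deeper than 10% of
   the profile maximum (after vertical erosion removes thin bridges).

Assumption 2 fails on severely overlapping dentitions; see Limitations.

## Pipeline and parameters

| stage | parameter | default | why |
|---|---|---|---|
| smoothing | `sigma` (px) | 1.5 | suppress sensor noise without erasing interdental gaps (~8 px wide) |
| binarization | — | per-image Otsu, 256 levels | exposure varies per image; no fixed threshold survives that |
| horizontal erosion | `erode_h` (px, odd) | max(3, width/50) | scale with width so oblique band edges don't bridge the trough row |
| vertical erosion | `erode_v` (px, odd) | max(3, row_height/20) | remove thin vertical bridges across interdental gaps |
| coarse search | `coarse_range`, `coarse_step` | ±15°, 5° | tilt in acquisition practice stays within ±15° |
| fine search | `fine_step`, `fine_halfwidth` | 1°, 4° | 1° matches the search's integer-angle resolution; ±4° covers the coarse step's bracketing error |
| valley detection | `min_prominence_frac` | 0.10 | ignores texture dips; real gaps reach near zero |
| valley spacing | `min_separation` (px) | width/16 | at most 8 teeth per row in a bitewing |
| half split | — | box midline, extra column to the right | fixed, arbitrary; anatomical axes are out of scope |

Binarization computes Otsu's threshold by an exhaustive scan over the 256
quantized levels and takes *foreground = level ≥ t* with the smallest
maximizing t on ties. This keeps the threshold convention exact and
deterministic; bin-center estimates (as some library implementations
return) can flip pixels lying exactly at a class edge.

Rotation uses bilinear interpolation about the canvas center, canvas size
preserved, exposed corners filled with background (0). Binarization is
recomputed after every rotation; binary masks are never rotated, avoiding
nearest-neighbor stair-stepping in the profiles.

Tie-breaking in all argmin searches: smaller trough first, then smaller
|angle|, then smaller signed angle — fixed so results are reproducible.

All boxes are reported in the angle-corrected frame with the applied
rotation recorded in the sidecar; `box_to_original_frame` maps corners
back when overlays on the raw image are needed.

## Enhancement operators

IAM maps `clip((I − P_low)/(P_high − P_low), 0, 1)^γ` with percentile
anchors (defaults 1/99, γ = 1). HISTEQ evaluates the normalized cumulative
256-bin histogram at each pixel's bin, so a constant image maps to 1.0 and
the lowest occupied bin maps to its own mass, not 0. AHE is
contrast-limited adaptive equalization (default 8×8 tiles, clip 0.01)
delegated to scikit-image; note its per-tile CDF is renormalized so the
lowest occupied bin maps to 0 — single-tile, unclipped AHE therefore
matches HISTEQ only up to that affine renormalization (within two
bin-widths in tests). Chains apply operators strictly left-to-right;
"A+B" presets mean "A then B".

## Evaluation statistics

Accuracy, precision and recall come from the confusion counts with zero
denominators reported as explicitly undefined, never silently zero.
Percentages render at two decimals, rounding half away from zero. AP uses
all-point interpolation with greedy score-ordered one-to-one matching at
IoU ≥ 0.5; mAP is the mean of per-class APs. The paired t statistic on two
IoU samples is computed from its definition (see README); only the t CDF
comes from scipy. Zero-variance differences raise instead of returning an
infinite statistic. The two-sided p-value convention was chosen because no
direction is privileged when comparing two segmenters.

## The phantom: what it emulates, what it does not

The generator draws, in a canonical axis-aligned frame: dark background
(0.10), two rows of bright crowns (per-tooth intensity ~ N(0.75, 0.05²)),
a nominal 30 px occlusal band, 8 px interdental gaps, optional bright
restoration caps (0.95) and small dark proximal caries notches (0.15),
then adds Gaussian noise (sd 0.02) and rotates by the requested angle g.
Ground truth (angle, jaw-split row, exact per-tooth boxes, lesion flags)
is recorded in the canonical frame.

Crowns carry rounded cusp bulges reaching 33–43% of the occlusal band from
each side, so the fully clear band is 14–34% of the nominal gap. This is
deliberate: with flat crown edges a 30 px clear band yields a zero trough
across ~±2° of tilt, leaving the argmin ill-posed; cusped crowns narrow
the clear band to roughly the height a 1° tilt sweeps across a 600 px
canvas, making 1°-accurate recovery a meaningful target. Default canvas
600×400, 4 teeth per jaw; restoration/caries probabilities 0.3 each.

The phantom does **not** emulate: anatomy (roots, pulp, bone), cervical
burnout, braces hardware, scatter or beam-hardening, vignetting, tooth
contact/overlap, or non-rigid distortion. Passing phantom tests therefore
demonstrates the geometric logic (rotation recovery, jaw split, gap
detection, bookkeeping) under controlled contrast and noise — not clinical
performance on real bitewings.

Test problem sizes: recovery suites run 20 seeds per generator angle in
{−10, −5, 0, 5, 10} on the 600×400 default phantom, which exercises the
full two-stage search (~15 angle evaluations per image) at comfortable
desk scale.

## Degenerate inputs and numerical choices

* Constant image: binarizes to all background; IAM maps to 0; HISTEQ to 1;
  AHE returns it unchanged.
* Gaussian smoothing with sigma 0 and rotation by 0° are exact identities.
* Erosion lengths must be odd so structuring elements are centered;
  out-of-image neighborhoods count as background.
* Profile troughs and valley selection break ties toward the smallest
  index; angle searches toward the smaller |angle|.
* 8-bit PNG output quantizes by rounding; round trips are exact to 1/255.

## Limitations

* Only integer angles are searched; sub-degree tilt is not corrected.
* One global rotation cannot fix a curved occlusal plane.
* Touching teeth with no radiolucent gap produce no valley and merge into
  one segment unless an expected tooth count forces a (possibly wrong)
  split elsewhere.
* The jaw split is a single horizontal line; teeth crossing it (severe
  overbite in the frame) are truncated.
* Half-tooth splitting uses the box midline, not an anatomical axis.
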