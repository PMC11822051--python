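# Methods

This note documents the models, estimators, parameter choices, and known
limitations behind `collmig`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic wounded monolayer

The generator is a Vicsek-style active-particle model, chosen because it is
the minimal model producing the three kinematic signatures the pipeline
measures: tunable velocity alignment between neighbours, angular noise, and
directed invasion of a cell-free stripe. It encodes no claim about the
biology that produces those signatures in real monolayers (membrane
tension, lipid signalling, cytoskeletal mechanics are all outside the
model); it exists so that every estimator can be tested against known
ground truth.

Each cell carries a position `(x, y)` (µm) and a heading `θ` (rad). Per
step of duration `dt`:

1. **Hard-core exclusion** — pairs closer than 5 µm (or `min_spacing`, if
   larger) are pushed apart symmetrically along their center line. This is
   the simplest volume-exclusion surrogate; it prevents degenerate stacking
   without simulating contact mechanics.
2. **Alignment** — the heading vector is blended with the mean neighbour
   heading within `interaction_radius`:
   `h' = (1−α)·h + α·mean(h_neighbours)`, with `α = alignment_strength`.
3. **Wound bias** — cells within a fixed 60 µm band outside the stripe, and
   cells already inside it, have their heading blended with the inward
   wound normal (toward the stripe midline) with weight `wound_bias`. The
   60 µm band mirrors the front-cell band used in the wound analysis
   (about three nuclear diameters). The band is anchored to the initial
   stripe geometry.
4. **Noise** — Gaussian angular noise of std `heading_noise` is added.
5. **Advance** — the cell moves `speed_v0 · dt` along its heading;
   box boundaries are reflective (positions and headings reflect), keeping
   the wound geometry meaningful in a bounded field of view (periodic
   boundaries would let the two wound fronts interact across the seam).

A single `numpy` Generator seeded from the config drives every stochastic
step, so identical configs give bit-identical trajectories.

**Default conditions.** 600 cells in a 600 × 400 µm box with a 200 µm
vertical cell-free stripe; `speed_v0 = 5 nm/s` (the middle of the 2–7 nm/s
single-cell speed range the pipeline reports), `dt = 10 min`, 96 steps
(16 h of imaging at the standard wound-assay interval);
`interaction_radius = 30 µm` (roughly first-neighbour distance at
confluence), `heading_noise = 0.8 rad`, `wound_bias = 0.3`. The noise and
bias defaults were fixed once at values where directed invasion is present
but does not overwhelm the alignment effect: with a very strong edge bias
the front band alone fills the wound regardless of coupling, which is not
the regime of interest. `alignment_strength` is the experimental knob and
has no privileged default beyond 0.6.

An optional `initial_heading` gives every cell the same starting heading;
with `α = 1` and zero noise the model then reduces to rigid parallel
translation, the closed-form case used to validate the track metrics.

**Rendering.** Nuclei are Gaussian spots (`nucleus_sigma`, default 2 µm)
plus additive Gaussian noise, quantized to 8 or 16 bits. The
phase-contrast-like channel draws each cell as a 12 µm-radius disk of
speckle texture that is frozen at cell creation and rigidly translated
(bilinear sub-pixel shifts) with the cell — re-randomizing the texture per
frame would destroy the frame-to-frame correlation PIV depends on.
Overlapping disks combine by maximum so local variance stays bounded. The
cell-free stripe is therefore plain low-variance background, which is what
makes variance-based wound segmentation applicable. No fluorescence
photophysics beyond this is modelled.

**What the generator does not emulate.** Proliferation (cell number is
conserved, so a fully closing wound eventually thins the sheet elsewhere —
late-phase area series can level off or rebound for this reason and
analyses fit closure rates over the early phase), leader-cell fingering,
cell shape and deformation, imaging artifacts beyond additive Gaussian
noise, and any biochemical dynamics. Passing tests demonstrate estimator
correctness on translating textures and point nuclei, not robustness to
real phase-contrast halos, debris, or segmentation-quality variation.

## PIV

Interrogation windows (default 32 px, 50% overlap — standard for
cell-scale imaging at ~1 µm/px) are mean-subtracted and cross-correlated
via zero-padded FFT. The raw linear correlation carries a triangular
overlap envelope; the envelope is divided out locally at the three points
used for sub-pixel interpolation (three-point Gaussian fit, parabolic
fallback when a neighbouring value is non-positive). A second pass
re-correlates the pair at the integer offset found in the first pass,
which removes the loss-of-pairs asymmetry that otherwise limits accuracy
to ~0.1–0.3 px; near the frame border the reference window shifts
oppositely so the full offset is always realized. Flat (zero-variance)
windows are flagged invalid rather than NaN-propagated. Equal correlation
peaks are broken toward the smaller displacement, deterministically.

Validation is the normalized-median test on the 3×3 neighbourhood
(threshold 2.0, regularization 0.1 px/frame); failing vectors are replaced
by the neighbourhood median and flagged `interpolated`, and both invalid
and interpolated vectors are excluded from all downstream statistics.

Coordinates: origin top-left, x rightward, y downward, window centers at
`offset + window/2` px; public outputs in µm and µm/h (1 µm/h =
0.2778 nm/s).

## Correlation length

The profile is `C(r) = Σ δv_i·δv_j / normalization` over vector pairs at
lag ~r, with `δv` the per-frame mean-subtracted velocities, pooled over
frames by accumulating pair sums (weighting bins by evidence rather than
averaging per-frame profiles). `C(0) = 1` by construction; the zero lag is
its own bin. On a rectangular grid the exact all-pairs sums are computed by
FFT autocorrelation of the masked component images — identical to the
naive O(N²) pair loop, but fast enough for grids large relative to the
correlation length, which matters because subtracting the sample mean
biases `C` downward by roughly the integral of the true correlation over
the field of view (≈ 2πλ²/L² for an exponential profile); fields should be
several λ across.

The correlation length is the first crossing of `1/e`, linearly
interpolated between bracketing bins; profiles that never cross within the
maximum lag return the maximum lag flagged censored. A least-squares fit of
`exp(−r/λ)` over bins with `C > 0.05` is provided as a cross-check. The
literature uses several inequivalent definitions of a monolayer
"correlation length"; the mean-subtracted vector dot-product
autocorrelation with the 1/e crossing is this package's primary definition
and is stated wherever numbers are reported. (A component-wise definition
changes nothing: the components enter the dot product additively.)

Angle conventions everywhere follow image coordinates (y down): 0° is the
inward wound normal, +90° points down the image. Rose histogram bins are
half-open `(lo, hi]` over `(−180°, 180°]`.

## Wound analysis

Segmentation: 7×7 local standard deviation → Otsu threshold on
`log(1 + std)` (the sheet's variance spread would otherwise dominate the
split) → morphological closing (disk 3) → dilation by half the std window
(the filter sees texture up to that distance past the true boundary) →
largest connected low-variance component. Two guards make degenerate
frames explicit: a frame whose "wound" variance is not well below the
sheet's (median ratio > 0.3) reports `closed` — on a confluent frame Otsu
merely splits noise — and a featureless frame reports the whole frame as
wound. Components below 1% of the image also report `closed`.

The closure rate is the negative least-squares slope of area vs time —
robust to single-frame segmentation errors, unlike an endpoint difference —
reported in µm²/h and, normalized to the t = 0 area, in %/h. The time axis
is zeroed at the frame closest to a configurable post-wounding offset
(default 4 h, the usual guard against seeding-density transients).

Front cells are those whose center lies strictly within 60 µm of the wound
edge (distance to the boundary pixels of the cleaned mask); exactly 60 µm
is rear. A `straight_edge` option measures distance to the mean vertical
edge lines instead, for consistency with track-analysis conventions that
treat the wound edge as a straight vertical line.

## Tracking and track metrics

Detection is scale-normalized LoG at the nuclear scale with per-axis
parabolic sub-pixel refinement (a 3×3 intensity centroid undershoots badly
for multi-pixel spots). Linking is greedy ascending-distance assignment
between consecutive frames with a hard displacement gate, no gap closing,
and index-ordered tie-breaks — a deterministic simplification of LAP
tracking that is adequate when inter-nucleus spacing exceeds the per-frame
displacement (the regime of nuclear imaging at 10-min intervals), and
degrades gracefully as density rises.

Filters: optional truncation before opposing wound fronts touch, then
removal of tracks with fewer than four displacement steps (exactly four is
kept, i.e. five detections minimum).

Metrics per track: straightness = net displacement / total path length
(undefined for zero path length; such cells are excluded from aggregates),
median step speed converted to nm/s, and the signed orientation angle of
the net displacement against the inward wound normal, with a folded
(absolute) variant for rose plots that ignore the sign.

## Generalized polarization

`GP = (I445 − G·I525)/(I445 + G·I525)` per pixel, with pixels whose
denominator falls below an intensity floor (default 1% of the bit-depth
maximum; dim pixels would otherwise contribute pure noise ratios) masked
invalid. The correction factor is derived from a solvent (DMSO) reference
measurement `G_m` via
`G = (G_ref + G_ref·G_m − G_m − 1)/(G_m + G_ref·G_m − G_ref − 1)`,
`G_ref = 0.207`; algebraically this factors as
`(G_ref−1)(1+G_m) / ((1+G_ref)(G_m−1))`, which shows the valid domain is
`−1 < G_m < 1` and that applying the corrected ratio to the solvent pair
returns `G_ref` exactly (a property the tests assert).

Interface time courses take the mean valid GP inside a supplied ROI mask
per time point and normalize to the initial value by subtraction (default:
GP is already a bounded difference ratio, so a GP *change* is the natural
report) with division available as an option. Boundary/interface detection
itself is out of scope; masks come from the generator or external
segmentation. Per-pixel GP noise at moderate SNR is substantial
(≈ √2·σ/T at GP ≈ 0), so quantitative statements are made about ROI or map
means, which average it down.

## Morphometry

The punctum pipeline: min-max normalization to [0, 1] (which makes the
whole chain exactly invariant to affine intensity rescaling) → rolling-ball
background subtraction (radius 50 px) → CLAHE (tile 64 px, clip 0.01) →
`(exp(x) − 1)/(e − 1)` remap (suppresses mid-level background relative to
bright structures) → percentile contrast stretch (0.1% saturation — the
saturation fraction must stay below the punctum pixel fraction, or the
stretch maps background noise to full range) → Otsu within the cell mask →
8-connected components → strict area filter (> 0.5 µm²) → per-cell counts
and areas, assigning each punctum to the cell label at its centroid. A
guard declares zero puncta when Otsu labels more than 25% of the cell as
foreground: puncta are sparse, and on a punctum-free image Otsu simply
splits the background noise distribution. All parameters are exposed.

Nuclear/cytoplasmic ratio: mean intensity inside the nuclear mask over the
mean in cell-minus-nucleus; requires the nucleus inside the cell and a
nonempty cytoplasm. Spreading area: pixel count × pixel area. Cell and
nuclear masks are always inputs — segmentation models are out of scope.

## Expression

`ΔCt = Ct_target − Ct_housekeeping` per sample; `ΔΔCt` subtracts the
arithmetic mean control `ΔCt` (equivalently, normalizes by the geometric
mean control fold change, making the control group's geometric mean
exactly 1); fold change `2^(−ΔΔCt)`. No amplification-efficiency
correction. Samples lacking a housekeeping measurement are excluded with a
warning rather than silently imputed.

## Problem sizes and numerical choices

The shipped analyses and tests use a 600 × 400 µm field at 2 µm/px and up
to 48 steps, 10–20 replicate seeds for stochastic claims, and
200×200-vector synthetic fields for correlation-length recovery — sizes at
which every stage's estimator is well-conditioned while the whole chain
runs on a laptop in minutes. Tolerances asserted in tests derive from the
estimators themselves: machine precision where an operation is exact
(straightness extremes, GP inversion, integer-shift PIV on periodic
speckle), sampling-noise bounds (3/√n) for null correlations, and
15%/5%/2% recovery bands where an estimator has known finite-sample bias
(correlation length under mean subtraction, segmentation pixelization,
regression on noisy series). Ties are broken deterministically throughout;
there is no hidden global RNG state.

## Known limitations

- Single-pass + discrete-offset PIV; no window deformation or optical
  flow, so strong shear within a window biases vectors.
- Greedy linking is not globally optimal; at densities where per-frame
  displacement approaches nucleus spacing, identity switches rise (tested
  as a trend, not hidden).
- Variance-based wound segmentation assumes a texture-free wound; debris
  or floating cells inside a real wound would be misclassified.
- Conserved cell number means long simulations cannot keep a closing sheet
  confluent; late-phase wound areas are less trustworthy than early-phase
  rates.
- The correlation-length estimate is censored at the maximum lag and
  biased low when the field of view is not large relative to the true
  length; both conditions are reported, not silently absorbed.
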