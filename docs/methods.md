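# Methods

## The identification problem

Eukaryotic flagella share the conserved '9+2' axoneme, which gives the
organelle an approximately constant diameter along its whole length. At
typical optical-microscopy resolution this remains true even when
accessory structures (a paraflagellar rod, outer dense fibres) thicken
the filament. The cell body, by contrast, has a varied visible width.
`flagtrace` exploits this contrast to isolate the flagellum of a
free-swimming cell from videomicroscopy with no user input — no seed
point, no tuned per-experiment heuristic.

The per-frame procedure is:

1. **Preprocess** the raw frame into a binary mask of the whole cell
   (temporal-median background subtraction over the stack, automatic
   Otsu threshold, polarity chosen so the cell is the minority phase
   touching fewer border pixels, small-object removal, hole filling,
   largest-component selection).
2. **Medial axis transform (MAT)**: the pixel-wise product of an exact
   Euclidean distance map and a connectivity-preserving skeletonization.
   The result is zero off the medial line and equals the local
   *half-width* in pixels along it. A disk maps to (nearly) a single
   point carrying its radius; an annulus to a closed loop of constant
   value; a cell-plus-flagellum to a curve whose value profile shows a
   long plateau (the flagellum) and a broad hump (the body).
3. **Width analysis** isolates the flagellar region from the MAT:
   - *Modal analysis* (default): histogram the MAT values on the
     skeleton (1 px bins), take the modal width — the long
     constant-width flagellum dominates the distribution — and use it
     as a simple threshold: keep skeleton pixels with width at most
     `mode + tolerance`, then select the largest 8-connected region.
     The cut is deliberately one-sided. The flagellum is the *thin*
     structure: its tip may taper below the mode (markedly so after
     optical blur), while anything wider than the mode by more than the
     tolerance is body. The attachment point is the region endpoint
     whose skeleton neighbourhood beyond the region is wider (the body
     side).
   - *Derivative analysis* (alternative): order the width-profile from
     the flagellar tip, approximate dw/ds by a `step`-sample forward
     difference (default 3), and flag the first derivative that is an
     outlier against the running median + k·MAD (k = 3) of the previous
     derivatives; that position is the attachment, where the width
     starts climbing into the body.
4. **Tracing** orders the selected pixels from attachment to tip, with
   two refinements for visually-overlapping flagella: *linear
   stitching* (re-join isolated thresholded segments whose endpoint gap
   is within about a flagellum width — by default 2x the modal
   half-width) and *tangent-preserving branch resolution* (at a
   skeleton junction, take the outgoing branch whose initial direction,
   averaged over a 5 px window, best matches the incoming tangent).

Frames are processed independently; there is no temporal prior, so one
bad frame never contaminates its neighbours, and memory stays bounded
when streaming a long stack from disk (the background is estimated from
at most 64 evenly-spaced frames).

## Why modal analysis is the default

The modal route has no parameter whose miscalibration silently breaks
it: the mode is found from the data, the tolerance only absorbs
rasterization jitter, and the selection is independent of skeleton
topology and arclength (crossings do not confuse it). The derivative
route is sensitive to the forward-difference step and to the outlier
rule; on these phantoms both methods saturate at 100% frame success, so
the comparison harness asserts the orderings (modal ≥ derivative;
3-step ≥ 2-step) rather than a separation.

## Evaluation metrics

Given a test pixel set and a baseline set, the **missed detection rate
(MDR)** is the percentage of baseline pixels farther than `d` pixels
from the test set, and the **false detection rate (FDR)** the
percentage of test pixels farther than `d` from the baseline;
`d = 3 px` throughout, reduced to 2 for 2x-downsampled images.
Distances are exact Euclidean (KD-tree nearest neighbour), and both
rates are reported pooled over frames as well as per frame. Because
"successful segmentation" is classically a by-eye judgement, it is
operationalized here as a frame with MDR ≤ 10% *and* FDR ≤ 10% against
ground truth (both ceilings are config keys).

## The phantom generator

The generator provides ground truth the real datasets cannot: an
ellipse body (semi-axes `a = 12, b = 7 px`; optionally tapered) joined
at its vertex to a flagellar tube of constant half-width `h = 2 px`
(visible width 3 px, at the lower end of what the method is intended
for) and axial extent 70 px. In the body frame the centerline is

    y(x, t) = A · g(x) · sin(2πx/λ − 2πf t),   g(x) = clip(x / ramp, 0, 1)

with defaults A = 6 px, λ = 40 px, f = 29 Hz sampled at 200 fps. The
ramp `g` (default λ/4) pins the base to the attachment point — a pure
sine base would detach the filament from the body whenever A exceeds
the half-width. The cell drifts at (0.25, 1.2) px/frame, obliquely to
the flagellar axis as real swimmers move; at a nominal 0.1 µm/px this
is ≈25 µm/s. The motion is essential, not decorative: the
temporal-median background estimate is only valid if no pixel is
foreground in most frames, and a purely axial drift would leave a
stationary corridor along the beat envelope that breaks this under
blur. Rasterization is centre-in-region with the open region (distance
strictly below the half-width). Frames are 8-bit, foreground 60 on
background 200 (dark cell on bright field).

Degradations mirror common acquisition limits, applied one at a time to
each raw frame before any processing: block-average downsampling (2x or
4x, emulating sensor binning), additive Gaussian noise of sd 10 on the
0-255 scale (clipped, emulating high-framerate shot noise), isotropic
Gaussian blur of radius 2 (defocus), and pixel-wise multiplication by a
black-to-white horizontal ramp (non-uniform illumination).

What the phantom does *not* emulate: phase-contrast halos and shade-off,
intensity variation along the cell, out-of-plane excursions of the
flagellum, body rotation, shape irregularity of a real promastigote
body, and multi-cell scenes. Passing the phantom suite therefore
demonstrates the geometric/algorithmic correctness of the method under
controlled optics, not performance on any particular instrument.

## Parameters that matter

| parameter | default | unit | role |
|---|---|---|---|
| `bin_width_px` | 1.0 | px | width-histogram bin; 1 px matches the discrete MAT values |
| `modal_tolerance_px` | 1.0 | px | one-sided margin above the mode; absorbs √2 rasterization jitter |
| `min_region_px` | 5 | px | rejects speckle modal regions |
| `derivative_step` | 3 | samples | forward-difference span; 2 is noise-dominated, large steps smear the attachment |
| `outlier_k` | 3.0 | — | MAD multiplier of the outlier rule |
| `mad_floor` | 0.05 | px/px | keeps the outlier threshold meaningful on perfectly flat profiles (MAD = 0) |
| `stitch_radius_factor` | 2.0 | — | stitch radius = factor × modal half-width ≈ the full flagellum width |
| `tangent_window` | 5 | px | tangent averaging at junctions; trades noise robustness against curvature |
| `d_px` | 3.0 | px | MDR/FDR distance tolerance (2 under 2x downsampling) |
| `success_mdr_max`, `success_fdr_max` | 10.0 | % | per-frame success operationalization |
| `min_object_area_px`, `fill_hole_area_px` | 9 | px² | mask cleanup |

## Kinematic estimators

Beat parameters are defined operationally so that they exactly invert
the generator's wave model on noiseless data:

- traces are aligned to a body frame (origin at the attachment, x-axis
  along the mean attachment→tip direction);
- **frequency**: peak of the Hann-windowed periodogram of the
  transverse displacement interpolated at the flagellar midpoint
  (x = L/2), DC excluded — resolution is `frame_rate / n_frames`;
- **amplitude**: √2 × RMS of that midpoint signal;
- **wavelength**: least-squares fit of `A sin(kx − 2πft + φ)` to the
  pooled body-frame samples at the estimated frequency (linear in the
  two harmonic coefficients at fixed k; k refined by bounded scalar
  minimization after a coarse scan). The proximal quarter of the
  filament is excluded, where base-anchored amplitude growth departs
  from the constant-amplitude model;
- **length**: mean trace arclength × pixel size.

Estimates are flagged low-confidence when the midpoint amplitude is
below 0.5 px, the spectral peak does not rise at least 5x above the
median non-peak power, or fewer than two beat periods are covered.

## Numerical choices and degenerate inputs

- Exact Euclidean distance transform (no chamfer approximation); on all
  test masks the skeleton MAT values equal a brute-force
  nearest-background scan bit-for-bit.
- Skeletonization by homotopic thinning (connectivity of each component
  is preserved exactly, holes survive), followed by a crossing-number
  pass that deletes removable pixels from residual 2x2 blocks. On
  speckle masks a 2x2 block can be irreducible (no simple pixel);
  topology wins over strict unit width in that case.
- Thinning retracts skeleton endpoints from rounded tips by roughly the
  local half-width; the shape-coverage guarantee is therefore
  "every foreground pixel within (MAT value + 3) px of some skeleton
  pixel", not the ~1.5 px of a true medial axis.
- Ties: equal histogram bins resolve toward the smaller width (the
  flagellum is the thin structure); equal-size candidate regions toward
  the one containing the lexicographically smallest pixel; equal stitch
  gaps lexicographically by endpoint.
- Degenerate inputs fail loudly but recoverably: a constant or
  implausibly thresholded frame raises a segmentation failure, a
  profile with no body raises an identification failure, and the
  pipeline converts these into per-frame `failed` statuses without
  stopping the run. A free filament with no body yields a deterministic
  low-confidence attachment, never an error.
- All randomness (noise degradations, test mask generation) is
  seeded; reruns are bit-identical including CSV outputs.
  `PhantomParams.rng_seed` is carried in the parameter record for
  provenance, but the generator itself is deterministic.

## Problem sizes

The standard study conditions used by the test suite and the
reproduction script are 100-frame stacks of 130x280 px frames (about
14 beat periods at 29 Hz / 200 fps), a five-lane degradation benchmark
on the same stack, and a 3x3 grid of (amplitude, wavelength) ∈
{4, 6, 8} × {40, 50, 60} px for kinematic recovery — the grid brackets
the beat geometry reported for *Leishmania*-like swimmers (λ/L ≈
0.6–0.9, A/λ ≈ 0.1–0.2) scaled to the 70 px phantom. The full suite
runs in well under a minute on one CPU.

## Known limitations

- Amplitude recovery degrades when the crest curvature radius
  `1/(Ak²)` approaches the tube half-width: pixel-level skeletons cut
  the crests, biasing amplitude low (≈12% at λ = 30, A = 8 px). The
  supported regime is gentler beats, matching the organisms the method
  targets.
- Approximately tangential filament crossings can double the apparent
  width over an extended stretch; stitching bridges transverse
  crossings but tangential ones remain unreliable, and very
  high-curvature junctions can defeat the windowed tangent rule.
- The method needs the flagellum sharply resolved at ≥ 2–3 px visible
  width; 4x downsampling of the standard phantom (flagellum < 1 px)
  sits at the edge of feasibility, and real low-resolution data should
  be expected to fail there.
- A flagellar *mid-section* of distinctly different width (e.g. a
  sperm midpiece) is identified as a separate width class and excluded
  from the modal region; segmenting such sections would require
  repeated modal analysis, which is not implemented.
- Everything is 2-D: out-of-plane beating violates the constant-width
  assumption where the filament tilts away from the focal plane.
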