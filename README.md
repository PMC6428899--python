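# flagtrace

Fully-automated identification and tracing of eukaryotic flagella from
videomicroscopy, via the medial axis transform.

Quantifying a flagellar beat normally requires isolating the flagellum
in every frame of a video — a step that typically needs manual seeding
or an experiment-specific heuristic, because simple thresholding cannot
separate a flagellum from the cell body it is attached to.
`flagtrace` automates this for free-swimming cells with a single
flagellum (e.g. *Leishmania* promastigotes, spermatozoa), using the one
morphological fact that is conserved across eukaryotes: the '9+2'
axoneme gives the flagellum an approximately **constant visible
width**, in contrast to the varied width of the cell body.

## Method

For a binary cell mask *B*, the medial axis transform is the pixel-wise
product of an exact Euclidean distance map and a
connectivity-preserving skeletonization,

&nbsp;&nbsp;&nbsp;&nbsp;MAT(x) = skel(B)(x) · dist(x, ∁B),

so the transform is nonzero only on the medial line, where it encodes
the local half-width w(s) in pixels. Read along the skeleton arclength
s, the flagellum appears as a long plateau in w(s) and hence as the
mode of the width distribution. The flagellum is isolated as the
largest connected skeleton region with w ≤ mode + 1 px (the mode used
as a simple threshold), the attachment point is the region endpoint on
the wider (body) side, and the region is traced from attachment to tip.
An alternative derivative analysis walks w(s) from the tip and flags
the first outlier of a 3-step forward difference (running median +
3·MAD) as the attachment. Segmentations are scored by the missed and
false detection rates at d = 3 px:

&nbsp;&nbsp;&nbsp;&nbsp;MDR = % of baseline pixels farther than d from the test set,
&nbsp;&nbsp;&nbsp;&nbsp;FDR = % of test pixels farther than d from the baseline.

A synthetic phantom generator (swimming ellipse body + travelling-wave
flagellum with exact per-frame centerline ground truth, plus the four
standard image degradations) makes the whole pipeline testable without
any experimental data. See `docs/methods.md` for the full model,
parameter table and limitations.

## Worked example

```python
from flagtrace import (PhantomParams, make_phantom, binarize, medial_axis_transform,
                       modal_segment, attachment_from_modal, trace_flagellum)

frames, truth = make_phantom(PhantomParams(n_frames=1))
mask = binarize(frames[0].astype(float))
mat = medial_axis_transform(mask)
result = modal_segment(mat)
attachment = attachment_from_modal(result, mat)
trace = trace_flagellum(result, attachment, mat)
```

Running `python examples/identify_and_trace.py` (which is this code
plus printing) gives:

```
binary mask:     587 foreground px (one connected cell)
skeleton:        87 px, half-widths 1.0-7.1 px
modal width:     2.15 px  (the flagellar half-width)
modal region:    73 px of 1 candidate region(s)
attachment:      (50, 40)  (2.0 px from ground truth)
trace:           73 points, arclength 89.0 px
```

The modal width 2.15 px recovers the phantom's 2 px tube half-width
(the ~0.5 px excess is rasterization); the attachment lands 2 px from
the true body junction; the 73-point trace runs the full filament,
whose arclength exceeds its 70 px axial extent because it is curved.

`examples/degradation_benchmark.py` runs the full pipeline over a
100-frame beating phantom, clean and degraded, and prints:

```
   degradation  mdr_percent  fdr_percent  success_rate_percent  d_px  n_failed
          none         0.02         0.03                100.00  3.00         0
 downsample_2x         0.00         0.03                100.00  2.00         0
 downsample_4x         0.00         6.11                 97.00  3.00         0
gaussian_noise         0.02         0.03                100.00  3.00         0
 gaussian_blur         0.02         0.00                100.00  3.00         0
gradient_blend         1.05         0.22                 99.00  3.00         0
```

i.e. essentially perfect centerline recovery except under aggressive
4x downsampling, where the flagellum falls below 1 px of visible width.
The other examples cover phantom generation, beat-parameter recovery
(frequency/wavelength/amplitude/length) and tracing through filament
crossings.

## Command line

A thin CLI wraps the library for shell use:

```bash
flagtrace phantom --out phantom/ --n-frames 100        # synthetic stack + truth
flagtrace run phantom/frames.tif --out results/        # trace every frame
flagtrace benchmark phantom/                           # degradation table
flagtrace kinematics results/traces.csv --pixel-size-um 0.1 --frame-rate-hz 200
flagtrace eval results/traces.csv phantom/centerline.csv
```

`run` accepts multi-page TIFF or a glob of per-frame images, streams
frames with bounded memory, and writes `traces.csv`,
`attachments.csv`, an `overlay.tif` with the centerline highlighted in
white, and a `manifest.json` echoing the configuration.

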