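# Methods

This note documents the models, parameters, and design choices behind
`paperecg`: what each stage assumes, which constants matter, what the
synthetic generator does and does not emulate, and the known limits.

## Pipeline model and assumptions

The pipeline assumes a flatbed-style scan of a printed 12-lead ECG:
rows of near-horizontal traces on a millimetre grid, printed at
25 mm/s and 10 mm/mV, with lead names printed at the start of each
lead's segment and (optionally) a black redaction header at the top of
the page. It does not attempt de-skewing beyond the ±2.5° Hough
tolerance, perspective rectification of photographs, shadow correction,
or detection of the 1 mV calibration pulse.

**Redaction stripping.** A row is "black" when its mean intensity is
below 1/255 — anti-aliased scans never produce exact zeros, so a strict
zero test would never fire. Only the maximal run of black rows touching
the top edge is removed, because the redaction area is a header; black
bands elsewhere are treated as content. A fully black page is an error.

**Grid removal.** The red channel is saturated to 1 and the image
converted to grey with the standard luminance weights (0.299 R, 0.587 G,
0.114 B); pixels with grey ≤ 0.94 are ink (the comparison is inclusive:
exactly 0.94 is ink). Red saturation lifts reddish pixels toward white
so the grid clears the threshold while black ink stays far below it.
Limitation: a *saturated dark* red grid (low green/blue channels) or a
grid printed in black does not clear 0.94 under luminance weighting and
will leak into the ink image; pale red/pink grids — the common case on
clinical printouts — are removed cleanly. Greyscale scans are accepted
by treating the single channel as all three, which makes red saturation
a no-op rather than an error.

**Baseline Hough.** Discretisation: angle step 0.5° over [−2.5°, +2.5°],
intercept step 1 px, intercept measured at the page's horizontal centre
so a tilted row accumulates in one cell. For each accumulator peak the
supporting pixels' column coverage is merged along the line (gaps ≤ 15 %
of width), and the line survives only if the merged span is ≥ 80 % of
width — this is segment merging along the line's direction, not vertical
clustering. Duplicate lines from 2 px-thick traces are collapsed by
strongest-first non-maximum suppression; the NMS window is 0.3 × the
median inter-line spacing, bootstrapped from a first pass with a 5 px
window (the median spacing is unknown until some lines are accepted).

**Layout inference.** The row count is the primary signal (12 → 12×1),
with names per row disambiguating the rest: 4 rows with multi-name rows
→ 3×4 + rhythm strip; 3 rows with multiple names → 3×4; 3 rows with one
name each → 3×1; 6 rows with two → 6×2. Partial name detection must not
break layout inference, so the multi-name thresholds require only ≥ 2
found names per row; missing names are repaired afterwards. "Unknown"
is a valid outcome and is still digitised row by row with whatever names
were found.

**Vertical anchors.** Each row's band is baseline ± 0.7 × d where d is
the distance to the *nearer* neighbouring baseline (not the average):
edge rows reuse their single neighbour's distance, a single-row page
uses half the image height, and bands clamp at the borders. Total crop
height is therefore 1.4 × d with the baseline centred.

**Lead names.** Candidate objects are connected components (8-connected;
glyph and trace staircases are corner-connected) of the ink image after
a 3×3 dilation-then-erosion pass, with letters grouped into words when
their boxes are ≤ 6 px apart horizontally and overlap vertically by at
least half the smaller height — thin inter-letter bridges created by
dilation do not survive the erosion, so letters of one label arrive as
separate components. Objects are rejected when either side is < 5 px or
> 500 px or the side ratio exceeds 5 (ratio taken as max/min, which also
rejects tall QRS fragments). Before all this, ink within ±1 px of every
baseline is cleared in a working copy: names printed against the
isoelectric line otherwise merge with the trace into one oversized
component that the filter rejects. The original ink image is untouched.

The recogniser contract is `(patch) -> (best vocabulary match,
confidence)`. The default is normalised cross-correlation against
templates of the 12 label strings rendered from two packaged bitmap
faces ("block" and "sans"); a third face ("round") exists so fixtures
can use a font absent from the template set, keeping recognition tests
honest. Patches and templates are trimmed to content, padded with a
2 px background border (so solid glyphs retain variance) and resized to
the template's shape before correlating. The confidence threshold
defaults to 0.6. False labels are worse than missing ones — missing
names are reconstructed by placing the expected grid cell at the median
x of the same column in other rows, or failing that by extrapolating
the row's median column pitch; box size and height above the baseline
come from the found boxes' medians. The rhythm-strip row's identity is
read from its printed label, falling back to lead II with a warning.

**Cropping.** A lead spans from the end of its own name box to the start
of the next name in its row. Rightmost leads of multi-column rows extend
by the maximum span observed among the row-interior leads; whole-row
strips (rhythm, 12×1, 3×1 rows) extend to the right page margin.

**Trace isolation and collapse.** A horizontal 1×5 dilation bridges
breaks in the trace before labelling; components are sized by their
*pre-dilation* ink count and only ink under the largest survives (ties:
larger count, then leftmost bounding box — ties are measure-zero but
tests need determinism). Each remaining ink column collapses to its
median row; with an even count the *lower* median is taken, keeping the
output on the pixel lattice. Columns with no ink are filled later by
linear interpolation — the dilation is expected to have closed most
gaps first.

**Calibration.** `time_res = 10 000 ms / W` where `W` is the x-pixel
span of the rhythm (or longest) strip scaled by its row's column count
(a 6×2 page's longest strip covers only 5 s of the record, so its width
is doubled before the division). `volt_res = time_res × 0.0025 mV/ms`
exactly, by construction, for every signal. Voltage is measured from the
detected Hough baseline of the row (not the per-crop ink median), with
y growing downward and voltage upward. On multi-column pages column k's
leads are offset by k × 2.5 s (3×4) or k × 5 s (6×2); each lead's own
time axis starts at zero at its first ink column.

**Output.** The CSV has exactly 13 columns — time in ms, then the 12
leads in standard order, in mV, 6 significant digits, comma separator,
LF endings. On multi-column pages a lead has samples only inside its own
window; other cells are empty. A 3×1 page genuinely carries only leads
I, II and V1, so its record holds those three signals and its CSV leaves
the other nine columns empty. An optional uniform resampling (e.g.
500 Hz) is available because the native per-pixel rate varies with scan
width.

## Validation metrics

Pearson r, RMSE (mV) and a two-sided p-value are computed on the
overlap of the two time spans after resampling the digitised lead onto
the reference grid. Crop anchors are pixel-quantised, which introduces
a small constant latency between the recovered and reference time axes;
a bounded integer-lag search (multiples of the reference step within
±40 ms, chosen by maximum |r|, ties toward zero lag) absorbs it before
the statistics are computed. Identity therefore reports r = 1, RMSE = 0
at lag 0, and an inverted signal reports r = −1. p-values are reported,
never thresholded.

## Synthetic generator

The generator emulates what the pipeline must cope with, not cardiac
physiology. Each beat is a sum of five Gaussians (defaults: P 0.15 mV
at 200 ms σ25, Q −0.10 at 340 σ10, R 1.00 at 360 σ15, S −0.20 at 385
σ10, T 0.30 at 600 σ60) tiled at 60 bpm over 10 s at 500 Hz; every lead
is the same train scaled by a per-lead factor between 0.4 and 1.0 (aVR
−0.5, inverted as on real tracings). Seeded uniform jitter (±8 % heart
rate, ±10 % wave amplitude) differentiates records; both jitters can be
zeroed for closed-form tests (a lone R wave's maximum equals its
amplitude analytically).

Rendering: 250 dpi (9.84 px/mm), 25 mm/s, 10 mm/mV, so 10 s spans
2461 px; traces are 2 px polylines of near-black ink over a pale pink
grid (RGB 1.0, 0.93, 0.93 — chosen so the grid's post-saturation grey
is ≈ 0.951, just above the 0.94 threshold, while remaining visibly
pink); 1 mm grid pitch; a 100 px pure-black redaction header; printed
lead names 40 px above each baseline; salt-and-pepper density 5 × 10⁻⁴
by default (validation batches pass 0). The row pitch is 40 mm: the
no-overlap guarantee requires the maximum ink excursion (≈ 11 mm for a
1.1 mV R wave) to stay outside neighbouring rows' 0.7 × pitch bands,
which forces pitch > excursion / 0.3. `overlap_factor` multiplies drawn
amplitudes by (1 + factor) to force inter-row overlap for stress tests.
`names_on_baseline` drops each label onto its row's isoelectric line
(with a short ink run-in joining it to the trace) to reproduce the
recognition failure that baseline clearing repairs; that mode is a
detection stress test, not an accuracy fixture.

What the generator does **not** emulate — and what passing tests
therefore do not show — includes: photographed (perspective-distorted,
shadowed) pages, skew beyond ±2.5°, thermal-paper fading and wrinkles,
black or saturated-red grids, proportional text fonts with serifs at
arbitrary sizes, calibration pulses, and real ECG morphology
(arrhythmias, baseline wander, muscle noise). Accuracy on real scans
with overlapping large-amplitude leads will be lower, as overlapping
traces are the method's known failure mode.

## Numerical choices and degenerate inputs

Boxes are half-open (x0, y0, x1, y1), origin top-left, x rightward,
y downward, everywhere. Duration of a digitised strip is
`n_samples × time_res`, so the rhythm strip's reconstructed duration is
10 s to within float rounding by construction. Empty crops, blank ink
images, pages with no surviving Hough line, and pages where no lead
name is recognised anywhere all raise typed errors carrying the failing
stage; an empty ink image from grid removal is legal output, and
"unknown" layout is a valid, digitisable outcome.

## Problem sizes

The validation batches are 20 seeded 3×4+rhythm pages and 10 pages each
of 12×1 and 3×1, all zero-noise and zero-overlap at 250 dpi — sizes
chosen to keep a full closed-loop run in the low minutes on one core
while averaging over the generator's seeded jitter. The property suite
checks row-count recovery over 4 layouts × 20 seeds.
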