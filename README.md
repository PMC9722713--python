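# paperecg

Fully-automated digitisation of scanned 12-lead paper ECGs: from a raster
image of a printed ECG to twelve calibrated voltage–time signals, with no
manual segmentation or user input.

Huge archives of clinical ECGs exist only on paper. Machine-learning work
on ECGs needs digital signals, so those archives are unusable until each
page is converted back into voltage–time series. `paperecg` is aimed at
researchers who hold scanned printouts (typically 250 dpi, 25 mm/s paper
speed, 10 mm/mV gain) in any of the common printed layouts — 3×4 with a
lead II rhythm strip, 6×2, 12×1, or 3×1 — and want a reproducible,
scriptable conversion to a 13-column spreadsheet (time + 12 leads).

## Method

The pipeline is a chain of classical image-processing stages:

1. **Pre-processing.** The black redaction header (anonymised patient
   data) is stripped: every maximal top-anchored run of rows with mean
   intensity ≈ 0 is removed. The millimetre grid is suppressed by
   saturating the red channel to 1, converting to grey, and keeping only
   pixels with grey value ≤ 0.94 as candidate ink (signal traces and
   printed lead names survive; the red/pink grid does not).
2. **Baseline detection.** Each lead row's isoelectric line is found with
   a Hough transform restricted to |θ| ≤ 2.5° about the horizontal.
   Collinear segments separated by gaps ≤ 15 % of the page width are
   merged; lines spanning < 80 % of the width are discarded. The row
   count determines the printed configuration.
3. **Anchor points and cropping.** Vertical anchors: each row's band
   extends 0.7 × the distance to the neighbouring baseline above and
   below (crop height 1.4 × that distance, baseline centred). Horizontal
   anchors come from lead-name localisation: connected ink components
   after a dilation–erosion pass, filtered by size (5–500 px sides) and
   aspect ratio (≤ 5), are scored against the 12-name vocabulary
   (I, II, III, avr, avl, avf, v1…v6) by a pluggable recogniser (the
   default is a deterministic normalised-cross-correlation template
   matcher; any OCR engine can be dropped in). Missing names are
   reconstructed from the spacing of the names that were found. Each
   lead's crop runs from the end of its own name to the start of the
   next.
4. **Signal extraction and calibration.** Inside each crop a horizontal
   dilation bridges drawing gaps, the largest connected object is kept as
   the trace (noise specks and encroaching neighbours are discarded), and
   each ink column collapses to its median row. With the rhythm (or
   longest) strip spanning 10 s, the time resolution is
   `10 000 ms / width_px`, and the voltage resolution follows from the
   fixed ratio of 25 mm/s, 10 mm/mV paper:
   `0.1 mV / 40 ms = 0.0025 mV/ms`.

A companion synthetic renderer draws ground-truthed paper ECGs —
sum-of-Gaussians P-QRS-T beats, pink millimetre grid, printed names,
redaction band, salt-and-pepper noise — so the whole pipeline is
validated closed-loop (render → digitise → compare, Pearson r and RMSE
per lead) without any clinical data.

## Worked example

```bash
python examples/digitise_synthetic.py
```

```
rendered page: 2940 x 1874 px at 250 dpi
detected layout: 3x4_rhythm, rhythm strip: lead II (10 s)
 lead        r  RMSE (mV)
    I   0.9993     0.0044
   II   0.9994     0.0064
  ...
   v6   0.9995     0.0037
```

Each line compares one digitised lead with the waveform that was printed:
r is the Pearson correlation after alignment and RMSE is in millivolts —
0.004–0.006 mV is well under the 0.1 mV height of one small grid square,
i.e. the recovered trace is visually indistinguishable from the original.
`examples/export_csv.py` shows the 13-column CSV output and
`examples/layout_survey.py` runs all four printed layouts.

From the shell, the same pipeline is available as:

```bash
paperecg digitise scan.png --out scan.csv
paperecg validate scan.png --truth truth.csv --report report.json
paperecg fixtures --out fixtures/ --seeds 1,2,3 --layouts 3x4_rhythm,12x1
```

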