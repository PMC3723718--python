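# serialrhythm

Serial section analysis of long biological-rhythm time series.

A long uniformly sampled record (motor activity counts, temperature, ...)
is cut into successive sections of length `l` samples, displaced by a step
of `s` samples, each analyzed in the circadian range with a period `T`.
The per-section results form a new series Z whose evolution over days,
weeks or months is the object of the analysis.  The package provides:

- **core** — time-series container, segmentation, Sidak/Bonferroni
  multiplicity correction for overlapping sections, serial driver, and
  phase tracking that wraps per-section phase changes into ±T/2 of a
  regression-extrapolated expectation.
- **filters** — moving average and running median (edge-shrinking, missing
  aware), the analytic moving-average transfer function H(f), normalized
  frequency ↔ period conversions, dichotomization.
- **serial_metrics** — per-section scalar descriptors (mean, median,
  percentiles, SD, ...), intradaily variability (IV), relative amplitude
  (RA from M10/L5 of the average daily profile), entrainment fraction.
- **phase** — acrophase, linear and circular center of gravity, activity
  onset/offset detection by Heaviside and circular square-wave template
  regression, threshold-crossing markers, alpha duration.
- **harmonics** — least-squares harmonic decomposition, power spectra,
  serial-spectrum graphic matrices, and the joint two-close-periods model.
- **periodograms** — Sokolove-Bushell and Lomb-Scargle (standard and
  generalized floating-mean) periodograms with significance thresholds,
  percent-variance scaling, serial heatmaps and per-section peak tracking.
- **wavelet** — convolution with a Gaussian-modulated sine kernel for
  per-cycle onset/middle/offset markers, plus the Rayleigh test for group
  phase homogeneity.
- **io / viz / synth** — CSV and plain-text I/O, actograms (single, double,
  triple plotted) and graphic-matrix heatmaps, and a fully seeded
  synthetic-rhythm generator (sinusoids, square patterns, phase/period
  programs, shape morphs, two-component series, white/pink noise, Poisson
  counts) so every method is testable without external recordings.

## CLI

Everything is reachable through a single entry point:

```sh
serialrhythm simulate --kind sinusoid --duration 14400 --dt 15 --period 1440 --out series.txt
serialrhythm filter series.txt --method median --window 5 --dt 15
serialrhythm serial stat series.txt --dt 15 --stat p95 --length 96 --step 96 --period 96
serialrhythm serial phase series.txt --dt 15 --method acrophase --length 96 --step 96 --period 96
serialrhythm serial spectrum series.txt --dt 15 --harmonics 12 --length 96 --step 96 --period 96
serialrhythm periodogram series.txt --dt 15 --method lsp-float --pmin 960 --pmax 1800
serialrhythm indices series.txt --dt 15
serialrhythm wavelet a1.txt a2.txt --dt 15 --period 1440
serialrhythm plot series.txt --dt 15 --period 1440 --plot-factor 2
```

Common flags: `--config <yaml>`, `--seed`, `--out-dir`, `--log-level`.
Plots are written as PNG + SVG with their underlying arrays dumped as CSV.

## Conventions

- Sampling intervals and durations are minutes; section lengths, steps and
  analysis periods are samples unless a CLI flag says otherwise.
- Normalized frequency f = 1 denotes the Nyquist frequency (period of two
  sampling intervals): T = 2·dt/f.
- Within-cycle sample positions are reported 1-based (sample i ↔ angle
  2πi/n); internal indexing is 0-based half-open.
- Missing values are NaN; per-section statistics track the missing fraction
  and yield a flagged NaN above a configurable cap (default 20%).
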