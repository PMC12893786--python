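# sousapam

Passive acoustic monitoring (PAM) toolkit for the vocalizations of
Indo-Pacific humpback dolphins (*Sousa chinensis*): detection and
measurement of echolocation **clicks**, extraction and classification of
tonal **whistles**, and a nonparametric **two-group comparison** between
recording sub-regions — together with a seeded synthetic-scene generator so
every stage can be validated against exact ground truth without field data.

It is written for bioacousticians processing high-rate (576 kHz) hydrophone
recordings of shallow-water odontocete populations, and for anyone who needs
a tested, reproducible reference implementation of the TKEO/FDR click
detector and the connected-component whistle extractor.

## Methods at a glance

**Clicks.** The waveform (high-passed at 5 kHz) is transformed by the
Teager–Kaiser energy operator, Ψ[xₙ] = xₙ² − xₙ₋₁xₙ₊₁, then smoothed by a
Gaussian kernel (FWHM = 0.10 ms) and a rectangular kernel of identical gain
and length. The Filter Difference Ratio

&nbsp;&nbsp;&nbsp;&nbsp;FDR[n] = (h₁[n] − h₂[n]) / h₁[n]

(h₁, h₂ the Gaussian- and rectangular-smoothed TKEO) is ≈ 0 on stationary
noise and spikes at impulsive events; samples with FDR > 0.7 become click
candidates, which a pluggable classifier separates from snapping-shrimp
impulses. Each click window is measured for peak frequency f_p, −3/−6/−10 dB
bandwidths, 95%-energy duration τ95, and peak-to-peak sound pressure level
SPLpp = 20·log₁₀(p_pp / 1 μPa).

**Whistles.** Frames of 65,792 samples (overlap 13,824) are transformed with
a Hanning-1024 STFT, P[m, f] = 20·log₁₀|F[m, f]|, enhanced by a 3×3 median
filter plus the offset 3·std(P) − mean(P), and binarized by an adaptive
threshold (mean over a radius-15 circular neighborhood). 8-connected
components at least 11 columns wide with peak value ≥ 10 become whistle
candidates; a per-column intensity-weighted ridge gives the contour, from
which duration, beginning/ending/minimum/maximum frequency and frequency
range are measured and the shape is classified as constant, upsweep,
downsweep, concave, convex or sinusoidal.

**Statistics.** Normality gating (Shapiro–Wilk for n ≤ 50, else
Kolmogorov–Smirnov), then a two-tailed Mann–Whitney U test at α = 0.05
compares any parameter between the West (24.30°–24.57° N, 117.94°–118.16° E)
and East (24.45°–24.63° N, 118.22°–118.50° E) sub-regions.

Design choices, parameter defaults and limitations are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from sousapam import synth, detect, measure, whistles
from sousapam.audio import highpass

# one 2-second synthetic scene: 8 clicks, 1 whistle, snapping shrimp
rng = np.random.default_rng(0)
clicks = synth.sample_click_specs(rng, 8, onsets_s=0.2 + 0.2 * np.arange(8))
cfg = synth.SceneConfig(
    duration_s=2.0, ambient_spl_db=95.0, snap_rate_per_s=2.0, clicks=clicks,
    whistles=[synth.WhistleSynthSpec("upsweep", 400.0, (5.0, 9.0),
                                     snr_db=20.0, onset_s=0.8)],
    seed=0)
segment, truth = synth.render_scene(cfg)

# click pipeline: detect -> classify -> measure
cands = detect.detect_candidates(highpass(segment))
detect.train_and_classify(cands, training_scenes=synth.training_scenes(seed=11),
                          sample_rate=segment.sample_rate, seed=0)
clicks_only = [c for c in cands if c.label == "click"]
print(f"{len(cands)} candidates, {len(clicks_only)} classified as clicks")
print(measure.summarize_metrics(
    [measure.measure_click(c.window, segment.sample_rate) for c in clicks_only]))

# whistle pipeline
w = max(whistles.extract_whistles(segment), key=lambda w: w.metrics.duration_ms)
m = w.metrics
print(f"longest whistle: {w.shape}, {m.duration_ms:.1f} ms, "
      f"{m.bf_khz:.2f} -> {m.ef_khz:.2f} kHz (range {m.range_khz:.2f} kHz)")
```

prints

```
9 candidates, 8 classified as clicks
              mean    sd    min    max
fp_khz        87.6  16.1   63.1  108.8
bw3_khz       36.3  12.0   23.7   61.6
bw6_khz       51.3  17.0   33.5   86.9
bw10_khz      66.2  21.9   43.2  112.0
duration_us   21.9   6.1   11.9   31.4
spl_pp_db    169.1   9.7  150.8  177.2

longest whistle: upsweep, 392.9 ms, 5.03 -> 8.92 kHz (range 3.97 kHz)
```

All 8 synthesized clicks are found and labeled (the 9th candidate is a snap
the classifier rejects); the per-click table is the mean ± SD / range layout
used in field reports, in kHz, μs and dB re 1 μPa. The 400 ms upsweep is
recovered with its shape, duration and 5 → 9 kHz extent (the ~4 ms shortfall
and ±0.1 kHz endpoint error reflect spectrogram column/bin quantization).

A thin CLI wraps the same functions for WAV files:

```bash
sousapam detect-clicks   --in rec.wav --out clicks.csv
sousapam detect-whistles --in rec.wav --out whistles.csv
sousapam compare --clicks clicks.csv --whistles whistles.csv --out report/
```

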