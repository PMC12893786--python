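# Methods

`sousapam` re-implements, as a tested pipeline, a passive-acoustic-monitoring
workflow for Indo-Pacific humpback dolphin (*Sousa chinensis*) vocalizations:
detection and measurement of echolocation clicks, extraction and
classification of tonal whistles, and a nonparametric West/East two-group
comparison. Because field recordings are not required, a synthetic-scene
generator supplies ground-truthed test signals whose parameter distributions
follow the descriptive statistics reported for the Xiamen Bay population
(`sousapam.populations`). This note records the models, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not establish.

## Signal chain and calibration

All in-memory audio is calibrated sound pressure in μPa. WAV samples (ADC
fractions of full scale) are converted through full-scale voltage, gain, and
hydrophone sensitivity. Defaults — sensitivity −176 dB re 1 V/μPa, gain
0 dB, 1 V full scale — are typical autonomous-recorder values, not measured
constants; every SPL the package reports inherits whatever calibration the
caller supplies. Levels follow field convention: peak-to-peak dB re 1 μPa
for transients, RMS for noise.

Click analysis is preceded by a 5 kHz high-pass. The filter family and
order are not dictated by the workflow being reproduced; we fix a 4th-order
Butterworth applied forward-backward (`sosfiltfilt`), which is zero-phase and
therefore cannot shift click peaks — the detector's timing and the
peak-referenced windowing depend on that.

## Click detection (TKEO / FDR)

The Teager–Kaiser energy operator Ψ[x_n] = x_n² − x_{n−1}x_{n+1} converts
the waveform to an instantaneous-energy series in which a tens-of-μs click
is a sharp spike. The series is smoothed twice: by a Gaussian kernel with
FWHM = 0.10 ms (σ_G = FWHM / (2√(2 ln 2)); the standard FWHM relation), and
by a rectangular kernel of identical length whose taps all equal the mean
Gaussian tap, so both filters have exactly the same gain. The Filter
Difference Ratio FDR = (h₁ − h₂)/h₁ is ≈ 0 on stationary noise (equal
gains), and approaches 1 − mean/max tap at an impulse. Samples with
FDR > 0.7 are grouped into runs; runs closer than a 1 ms refractory interval
merge; each run yields one candidate at its TKEO maximum.

**Kernel span.** The kernel half-width is N = 4·FWHM·f_s samples (total span
≈ 8×FWHM). The span sets the detector's ceiling, 1 − mean/max tap: at
≈ 4×FWHM the ceiling is 0.734, leaving almost no headroom over the fixed 0.7
threshold, and clicks at moderate SNR (25 dB peak-amplitude SNR, the
recovery studies' operating point) with low carrier frequencies fall under
threshold; at ≈ 8×FWHM the ceiling is 0.867 and the same clicks sit at
FDR ≈ 0.83. The longer rectangular window also averages noise harder, so
false runs become rarer. Both kernels still satisfy the matched-gain and
FWHM constraints.

**Windowing.** Each candidate's waveform window grows symmetrically from the
Hilbert-envelope peak until the envelope stays below −20 dB of the peak for
10 consecutive samples per side, capped at ±150 μs; windows cut by the
segment edge are flagged, not dropped. An optional reverberation screen
rejects candidates with a secondary envelope lobe above −10 dB after the
main lobe (off by default; it emulates a quality-selection step without
claiming fidelity to any particular field protocol).

**Classifier.** Snapping-shrimp-like impulses trip the FDR just as clicks
do, so candidates are scored by a pluggable classifier. The default is a
StandardScaler + single-hidden-layer MLP (32 units) over six
level-independent features (τ95 duration, peak frequency, −3 dB bandwidth,
spectral centroid, crest factor, energy fraction above 100 kHz), trained on
synthetic click and snap scenes with a fixed seed; label = click iff
score ≥ 0.5. Any callable `scorer(features) → [0, 1]` may substitute. The
synthetic populations are separable by spectral centroid, so held-out
accuracy is high by construction; no claim is made about performance on
field data or about reproducing any published classifier.

## Click parameters

Measured on the window's magnitude spectrum, zero-padded to ≥ 4096 points
(≈ 140 Hz resolution at 576 kHz): peak frequency f_p = argmax; BW_x = width
of the contiguous interval around f_p where power ≥ peak − x dB, with linear
interpolation at the crossings (detached sidelobes excluded — nesting
BW₃ ≤ BW₆ ≤ BW₁₀ then holds structurally). SPLpp = 20·log₁₀(max − min).

**Duration.** τ95 — the central 2.5%→97.5% interval of cumulative energy —
is computed on the *squared Hilbert envelope*, restricted to the click's
principal lobe (the contiguous interval around the envelope peak where the
envelope stays within 20 dB of its maximum). Two reasons: (i) with only ~2
carrier cycles per envelope, τ95 on raw squared pressure depends on carrier
phase by ±10%, while the envelope-based value equals the Gaussian closed
form 2.772σ; (ii) the principal-lobe restriction keeps the extracted
window's pure-noise skirts out of the cumulative sum, which would otherwise
inflate τ95 by ≈ 2 μs at 25 dB SNR. A −10 dB envelope-threshold duration is
available via `duration_mode="envelope"`.

Closed-form checks (BW₃ = √(ln 2)/(πσ), τ95 = 2.772σ) are asserted at a
144 kHz carrier: at low carrier × small σ (e.g. 90 kHz, 3 μs) the
negative-frequency image overlaps the main lobe and genuinely widens the
measured bandwidth by ~4% — a property of real spectra, not a measurement
error, and outside the closed forms' validity domain.

## Whistle extraction

Recordings are framed (65,792 samples, 13,824 overlap) and each frame is
transformed with a 1024-point Hanning STFT at hop 512 (bin 562.5 Hz, column
step 0.889 ms), log-scaled (20·log₁₀|F|, floor −120 dB), and restricted to a
0–30 kHz analysis band (whistle fundamentals are 2–16 kHz; the full 288 kHz
band adds only noise components and ~10× compute; configurable).

Enhancement is a 3×3 median filter plus the global scalar offset
3·std(P) − mean(P), applied literally as specified by the source method;
the offset preserves pixel ordering and interacts only with the
intensity-based component filter below. The adaptive threshold retains
pixels strictly exceeding the mean of their enhanced neighborhood over a
Euclidean disk of radius 15 pixels (edge disks clipped). 8-connected
components are kept if they span ≥ 11 time columns (≈ 9.8 ms — below the
shortest whistle the method is meant for) and their maximum enhanced value
is ≥ 10.

On calibrated μPa spectrograms the enhanced values are O(100 dB), so the
"maximum value ≥ 10" rule never rejects anything end-to-end; it is honored
and unit-tested on crafted matrices. A plausible alternative reading of the
enhancement offset (P − mean − 3·std, making the rule a
"10 dB above mean + 3σ" criterion) is noted here but not implemented as the
default. Consequently the extractor *does* emit noise components alongside
genuine whistles — the original workflow dealt with these by manual
inspection, which this package replaces with a review export
(`whistles.export_review`) rather than an algorithm; downstream consumers
must match contours to events of interest (as the recovery harness does) or
review them.

**Ridge rule** (the underlying method leaves it unstated; this is the
package's choice): per occupied column, the intensity-weighted centroid —
linear power weights — of the *vertically contiguous pixel run containing
the column's strongest pixel*. At realistic SNR, noise pixels become
8-connected to a whistle region through chance bridges; an unrestricted
column centroid lets them drag the ridge by entire bins, corrupting
MinF/MaxF by 1–5 kHz in roughly a third of 20 dB SNR scenes. The ridge is
median-smoothed over 5 columns (edge-replicated, not zero-padded — zero
padding biases the endpoints that define BF/EF). Column gaps are linearly
interpolated and flagged.

**Cross-frame stitching.** A 114 ms frame is shorter than a typical whistle,
so per-frame contour pieces must be joined: only pieces from *different*
frames may merge, they must abut within 5 ms (overlap included), and their
ridges must agree within 0.5 kHz over the entire shared interval — frames
overlap by 24 ms, so genuine continuations always share a verifiable
stretch. Finally, contours are edge-trimmed: leading/trailing columns whose
ridge-peak intensity falls more than 20 dB below the contour's median peak
are dropped (those columns' analysis windows barely overlap the sound and
their ridge is noise-driven; they are what corrupts begin/end/min/max
frequencies otherwise).

Metrics: duration = (n − 1)·column step; BF/EF = first/last ridge values;
MinF/MaxF = extrema; range = MaxF − MinF. Shape classification uses
δ-hysteresis turning points on the smoothed ridge with
δ = max(0.25 kHz, 5% of mean frequency): excursion < 2δ ⇒ constant; 0 turns
⇒ up/downsweep by sign; 1 turn ⇒ convex/concave by direction; ≥ 2 ⇒
sinusoidal.

## Statistics

Normality: Shapiro–Wilk for n ≤ 50, else one-sample Kolmogorov–Smirnov
against a normal with the sample's estimated mean/SD (the common applied
reading; a Lilliefors correction is deliberately not applied — with
estimated parameters the KS test is conservative, which the size test in the
suite reflects). Group comparison: two-tailed Mann–Whitney U at α = 0.05,
no multiplicity correction. The reported U is for the west group
(U_east = n_w·n_e − U_west). When min(n) ≤ 8 and the labeling count is
tractable (≤ 5·10⁵ combinations) the p-value is computed by full
enumeration with midranks, two-tailed as 2·min(P(U ≤ u), P(U ≥ u)) capped
at 1; otherwise the tie-corrected normal approximation with continuity
correction is used. Identical constant samples short-circuit to p = 1 with
a degeneracy flag.

## Synthetic scenes: what they emulate, and what they do not

Scenes are mono, 576 kHz, Gaussian ambient noise at a configurable RMS
level (95 dB re 1 μPa default), optional low-pass vessel noise, Poisson
snapping, and placed click/whistle events. Conventions chosen once:

- Clicks: linearly chirped Gaussian-envelope pulses over ±4σ. The chirp
  decouples duration from bandwidth so the reported marginals of both can be
  matched; `solve_chirp_rate` inverts the bandwidth measurement numerically
  (the field source does not publish a click waveform model — this is the
  package's model).
- Click SNR = 20·log₁₀(peak envelope amplitude / broadband noise RMS);
  whistle SNR = 20·log₁₀(tone RMS / noise RMS).
- Snaps: instant-attack exponential decay (τ = 3–8 μs) on a 180–250 kHz
  carrier. A plain exponential has a Lorentzian spectrum whose centroid
  (~50–65 kHz at these τ) sits *below* the click population's; the
  high-frequency carrier gives snaps the higher centroid and >150 kHz
  energy that make the click/snap contrast learnable and documented.
- Whistles: phase-continuous FM tones; archetype tracks are flat, linear or
  pchip (sweeps), quadratic (concave/convex), or half-cosine segments
  between alternating anchors (sinusoidal); harmonics optional at −6
  dB/harmonic (off in recovery studies to keep the ridge unambiguous);
  5 ms raised-cosine edge tapers.
- Event parameters are drawn from the reported tables: truncated normals
  with far physical floors for click parameters (f_p floor 20 kHz, duration
  6 μs, BW₃ 15 kHz), plain normal for SPLpp, moment-matched lognormals for
  whistle duration and frequencies (CV > 0.3). Draws use stratified
  inverse-CDF sampling (1-D Latin hypercube): marginals are exactly the
  prescribed distributions, while the Monte Carlo variance of the
  population mean collapses, so recovery studies measure pipeline bias
  rather than draw luck — with iid draws, the whistle-duration sample mean
  alone (CV ≈ 0.7) would fluctuate by ±5.5 ms SEM at n = 1000.

Not modeled: propagation (absorption, multipath), directionality and beam
pattern, animal movement, non-Gaussian ambient statistics, overlapping
whistles, real vessel-traffic structure. Passing recovery tests therefore
shows that the pipeline measures what it claims under calibrated, known
conditions — not that field performance matches any published figure. In
particular the default classifier's accuracy on separable synthetic
populations says nothing about any published network's 90%-level field
accuracy, which is explicitly not a target.

## Problem sizes and determinism

Recovery studies use 2,000 clicks (batched 200 per scene, 8 ms spacing,
ambient 95 dB) and 1,000 single-whistle scenes per parameter; the property
suite uses a 60 s standard scene (50 clicks at 160 dB SPLpp, snapping at
1/s, one 6 kHz whistle) and 300 single-archetype scenes — sizes chosen so
the whole validation runs on a laptop-class single core in minutes. Every
random choice flows from an explicit integer seed through
`numpy.random.default_rng`; a fixed seed reproduces scenes byte-for-byte.

## Known limitations

- The whistle extractor reports noise components by design (see above); its
  output is a candidate list, not a final catalog.
- Whistle frequency metrics are quantized by the 562.5 Hz bin (sub-bin
  accuracy comes only from the centroid); steep sweeps near the band edge
  can lose edge columns to the trimming rule.
- The exact Mann–Whitney branch is limited to small groups; large-sample
  inference relies on the tie-corrected normal approximation.
- PCM-24 writing is supported, but reading maps 24-bit data through scipy's
  int32 container; sub-LSB round-trips are only exact for float-32.
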