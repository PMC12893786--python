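"""Seeded synthetic 576 kHz underwater acoustic scenes with exact ground truth.

The generator emulates the recording setting of a shallow-bay passive
acoustic survey: broadband echolocation clicks modelled as linearly chirped
Gaussian-envelope (Gabor-like) pulses, frequency-modulated tonal whistles in
six contour archetypes, snapping-shrimp-like impulses, optional low-frequency
vessel noise and Gaussian ambient noise.  Event parameter distributions
default to the field-reported population statistics in
:mod:`sousapam.populations`, so downstream detectors and measurement code can
be scored against known truth at realistic operating points.

Scale conventions: waveforms are sound pressure in μPa; levels are dB re
1 μPa (peak-to-peak for transients, RMS for noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.signal import butter, sosfiltfilt

from . import measure
from .audio import AudioSegment, Calibration, write_wav
from .populations import CLICKS, WHISTLES

__all__ = [
    "ClickSynthSpec",
    "WhistleSynthSpec",
    "SnapSpec",
    "SceneConfig",
    "SceneEvent",
    "SceneAnnotation",
    "make_click_pulse",
    "solve_chirp_rate",
    "make_whistle_waveform",
    "make_snap",
    "render_scene",
    "gabor_bw3_khz",
    "gabor_sigma_for_bandwidth_us",
    "duration_to_sigma_us",
    "draw_truncated_normal",
    "draw_lognormal",
    "sample_click_specs",
    "sample_whistle_spec",
    "standard_scene",
    "training_scenes",
    "WHISTLE_SHAPES",
]

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 576_000.0
WHISTLE_SHAPES = ("constant", "upsweep", "downsweep", "concave", "convex", "sinusoidal")

#: τ95 of a Gaussian-envelope pulse = 2.772·σ (σ = envelope std).
ENERGY_DURATION_FACTOR = measure.ENERGY_DURATION_FACTOR


def gabor_bw3_khz(sigma_us: float) -> float:
    """−3 dB bandwidth (kHz) of an unchirped Gaussian-envelope pulse:
    BW₃ = √(ln 2)/(π σ)."""
    return np.sqrt(np.log(2.0)) / (np.pi * sigma_us * 1e-6) / 1e3


def gabor_sigma_for_bandwidth_us(bw3_khz: float) -> float:
    """Envelope std σ (μs) giving a target −3 dB bandwidth for an unchirped
    pulse (inverse of :func:`gabor_bw3_khz`)."""
    return np.sqrt(np.log(2.0)) / (np.pi * bw3_khz * 1e3) * 1e6


def duration_to_sigma_us(duration_us: float) -> float:
    """Envelope std σ (μs) giving a target 95%-energy duration."""
    return duration_us / ENERGY_DURATION_FACTOR


# ---------------------------------------------------------------------------
# event specs


@dataclass
class ClickSynthSpec:
    """Linearly chirped Gaussian-envelope click.

    ``carrier_khz`` is the instantaneous frequency at the envelope peak,
    ``sigma_us`` the Gaussian envelope standard deviation, ``chirp_khz_per_us``
    the linear instantaneous-frequency slope (0 = pure Gabor pulse), and
    ``spl_pp_db`` the peak-to-peak level in dB re 1 μPa.
    """

    carrier_khz: float
    sigma_us: float
    chirp_khz_per_us: float = 0.0
    spl_pp_db: float = 160.0
    onset_s: float = 0.0

    def validate(self, sample_rate: float) -> None:
        nyq_khz = sample_rate / 2e3
        if self.carrier_khz <= 0 or self.carrier_khz >= nyq_khz:
            raise ValueError(f"carrier {self.carrier_khz} kHz outside (0, {nyq_khz}) kHz")
        if self.sigma_us <= 0:
            raise ValueError("envelope sigma must be positive")
        span = 4.0 * self.sigma_us
        for t in (-span, span):
            f = self.carrier_khz + self.chirp_khz_per_us * t
            if f <= 0 or f >= nyq_khz:
                raise ValueError(
                    f"instantaneous frequency {f:.1f} kHz leaves (0, {nyq_khz:.1f}) kHz "
                    f"over the ±4σ support"
                )


@dataclass
class WhistleSynthSpec:
    """Frequency-modulated tonal whistle.

    ``anchors_khz`` are contour control values: a single value for constant,
    (start, end) for sweeps, (start, extremum, end) for concave/convex, and
    ≥3 alternating values for sinusoidal.  ``snr_db`` is tone RMS over
    broadband ambient-noise RMS.
    """

    shape: str
    duration_ms: float
    anchors_khz: Tuple[float, ...]
    n_harmonics: int = 1
    snr_db: float = 20.0
    onset_s: float = 0.0

    def validate(self, sample_rate: float) -> None:
        if self.shape not in WHISTLE_SHAPES:
            raise ValueError(f"unknown whistle shape {self.shape!r}")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        a = np.asarray(self.anchors_khz, dtype=float)
        nyq_khz = sample_rate / 2e3
        if np.any(a <= 0) or np.any(a >= nyq_khz):
            raise ValueError("anchor frequencies must lie in (0, Nyquist)")
        d = np.diff(a)
        if self.shape == "constant":
            if a.size < 1 or (a.size > 1 and np.ptp(a) > 0.01 * a.mean()):
                raise ValueError("constant shape needs a single (or flat) anchor value")
        elif self.shape == "upsweep":
            if a.size < 2 or np.any(d <= 0):
                raise ValueError("upsweep anchors must be strictly increasing")
        elif self.shape == "downsweep":
            if a.size < 2 or np.any(d >= 0):
                raise ValueError("downsweep anchors must be strictly decreasing")
        elif self.shape in ("concave", "convex"):
            if a.size != 3:
                raise ValueError(f"{self.shape} needs exactly 3 anchors")
            interior_ok = a[1] < min(a[0], a[2]) if self.shape == "concave" else a[1] > max(a[0], a[2])
            if not interior_ok:
                raise ValueError(f"{self.shape} interior anchor must be the extremum")
        else:  # sinusoidal
            if a.size < 3 or np.any(d == 0) or np.any(np.sign(d[1:]) == np.sign(d[:-1])):
                raise ValueError("sinusoidal anchors must alternate (≥2 reversals)")


@dataclass
class SnapSpec:
    """Snapping-shrimp-like impulse: instant attack, exponential decay."""

    onset_s: float = 0.0
    level_db: float = 160.0
    tau_us: float = 5.0
    center_khz: float = 220.0

    def validate(self, sample_rate: float) -> None:
        if self.level_db >= 220.0:
            raise ValueError("snap level must be physically plausible (< 220 dB)")
        if self.tau_us <= 0:
            raise ValueError("decay time constant must be positive")
        if not (0 < self.center_khz < sample_rate / 2e3):
            raise ValueError("snap center frequency outside (0, Nyquist)")


@dataclass
class SceneConfig:
    """Full scene description; a fixed seed yields a byte-identical scene."""

    duration_s: float
    sample_rate: float = DEFAULT_SAMPLE_RATE
    ambient_spl_db: float = 95.0
    vessel_noise: bool = False
    vessel_corner_hz: float = 2000.0
    vessel_level_db: float = 110.0
    snap_rate_per_s: float = 0.0
    clicks: List[ClickSynthSpec] = field(default_factory=list)
    whistles: List[WhistleSynthSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("scene duration must be positive")
        for c in self.clicks:
            c.validate(self.sample_rate)
        for w in self.whistles:
            w.validate(self.sample_rate)


@dataclass
class SceneEvent:
    event_class: str  # "click" | "whistle" | "snap"
    onset_s: float
    offset_s: float
    spec: object


@dataclass
class SceneAnnotation:
    """Ground-truth event list for detector scoring."""

    events: List[SceneEvent]

    def of_class(self, event_class: str) -> List[SceneEvent]:
        return [e for e in self.events if e.event_class == event_class]

    def to_dataframe(self) -> pd.DataFrame:
        import json

        rows = []
        for e in self.events:
            rows.append(
                {
                    "event_class": e.event_class,
                    "onset_s": e.onset_s,
                    "offset_s": e.offset_s,
                    "param_json": json.dumps(
                        {k: v for k, v in e.spec.__dict__.items() if not isinstance(v, np.ndarray)}
                    ),
                }
            )
        return pd.DataFrame(rows, columns=["event_class", "onset_s", "offset_s", "param_json"])

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# waveform primitives


def make_click_pulse(
    spec: ClickSynthSpec, sample_rate: float = DEFAULT_SAMPLE_RATE, phase: float = 0.0
) -> np.ndarray:
    """Synthesize one click: g(t) = A·exp(−t²/2σ²)·cos(2π(f_c t + ½ c t²) + φ)
    over ±4σ, scaled so the peak-to-peak pressure matches ``spl_pp_db``."""
    spec.validate(sample_rate)
    sigma_s = spec.sigma_us * 1e-6
    half = max(int(round(4.0 * sigma_s * sample_rate)), 2)
    t = np.arange(-half, half + 1) / sample_rate
    fc = spec.carrier_khz * 1e3
    chirp = spec.chirp_khz_per_us * 1e9  # Hz per second
    w = np.exp(-(t**2) / (2.0 * sigma_s**2)) * np.cos(
        2.0 * np.pi * (fc * t + 0.5 * chirp * t**2) + phase
    )
    pp_target = 10.0 ** (spec.spl_pp_db / 20.0)
    return w * (pp_target / (w.max() - w.min()))


def solve_chirp_rate(
    target_bw3_khz: float,
    sigma_us: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    tol: float = 0.005,
) -> float:
    """Chirp rate c ≥ 0 (kHz/μs) whose noise-free pulse measures the target
    −3 dB bandwidth; bisection against the spectral measurement itself.

    The unchirped pulse sets a lower bound BW₃ = √(ln2)/(πσ); targets below
    it are rejected.
    """
    bound = gabor_bw3_khz(sigma_us)
    if target_bw3_khz < bound * (1.0 - 1e-9):
        raise ValueError(
            f"target −3 dB bandwidth {target_bw3_khz:.2f} kHz is below the unchirped "
            f"Gabor bound √(ln2)/(πσ) = {bound:.2f} kHz for σ = {sigma_us} μs"
        )

    nyq_khz = sample_rate / 2e3
    carrier = nyq_khz / 2.0  # keeps the chirped IF inside (0, Nyquist)

    def measured(c: float) -> float:
        pulse = make_click_pulse(
            ClickSynthSpec(carrier, sigma_us, c, spl_pp_db=120.0), sample_rate
        )
        return measure.measure_click(pulse, sample_rate).bw3_khz

    if target_bw3_khz <= bound * (1.0 + tol):
        return 0.0
    c_max = (carrier - 1.0) / (4.0 * sigma_us) * 0.99  # IF stays positive at −4σ
    c_hi = min(target_bw3_khz / (2.0 * sigma_us), c_max)
    while measured(c_hi) < target_bw3_khz:
        if c_hi >= c_max:
            raise ValueError(
                f"target bandwidth {target_bw3_khz} kHz unreachable within the "
                f"(0, Nyquist) instantaneous-frequency constraint"
            )
        c_hi = min(2.0 * c_hi, c_max)
    return float(brentq(lambda c: measured(c) - target_bw3_khz, 0.0, c_hi, xtol=1e-4 * c_hi))


def _frequency_track(spec: WhistleSynthSpec, n: int) -> np.ndarray:
    """Instantaneous-frequency track (Hz) realizing the shape archetype."""
    a = np.asarray(spec.anchors_khz, dtype=float) * 1e3
    u = np.linspace(0.0, 1.0, n)
    if spec.shape == "constant":
        return np.full(n, a.mean())
    if spec.shape in ("upsweep", "downsweep"):
        if a.size == 2:
            return a[0] + (a[1] - a[0]) * u
        knots = np.linspace(0.0, 1.0, a.size)
        return PchipInterpolator(knots, a)(u)
    if spec.shape in ("concave", "convex"):
        # quadratic through (0, a0), (1/2, a1), (1, a2): single interior extremum
        coeffs = np.polyfit([0.0, 0.5, 1.0], a, 2)
        return np.polyval(coeffs, u)
    # sinusoidal: half-cosine segments between successive anchors; zero slope
    # at each anchor gives a turning point at every interior anchor
    knots = np.linspace(0.0, 1.0, a.size)
    seg = np.clip(np.searchsorted(knots, u, side="right") - 1, 0, a.size - 2)
    local = (u - knots[seg]) * (a.size - 1)
    return a[seg] + (a[seg + 1] - a[seg]) * 0.5 * (1.0 - np.cos(np.pi * local))


def make_whistle_waveform(
    spec: WhistleSynthSpec,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Phase-continuous FM tone following the shape archetype, with optional
    harmonics at −6 dB per harmonic and raised-cosine edge tapers."""
    spec.validate(sample_rate)
    n = int(round(spec.duration_ms * 1e-3 * sample_rate))
    if n < 2:
        raise ValueError("whistle too short for the sample rate")
    f = _frequency_track(spec, n)
    nyq = sample_rate / 2.0
    if f.min() <= 0 or f.max() >= nyq:
        raise ValueError("interpolated contour leaves (0, Nyquist)")
    phase = 2.0 * np.pi * np.cumsum(f) / sample_rate
    x = np.zeros(n)
    for k in range(1, spec.n_harmonics + 1):
        if k * f.max() >= nyq:
            break
        x += 10.0 ** (-6.0 * (k - 1) / 20.0) * np.sin(k * phase)
    ramp = min(int(0.005 * sample_rate), n // 10)
    if ramp > 0:
        win = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        x[:ramp] *= win
        x[-ramp:] *= win[::-1]
    return amplitude * x


def make_snap(
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    level_db: float = 160.0,
    tau_us: float = 5.0,
    center_khz: float = 220.0,
) -> np.ndarray:
    """Snapping-shrimp-like impulse: instant attack, exponential decay (time
    constant 3–8 μs typical), carried at a high center frequency so the
    population is separable from clicks by spectral centroid."""
    spec = SnapSpec(level_db=level_db, tau_us=tau_us, center_khz=center_khz)
    spec.validate(sample_rate)
    tau_s = tau_us * 1e-6
    n = max(int(round(8.0 * tau_s * sample_rate)), 4)
    t = np.arange(n) / sample_rate
    w = np.exp(-t / tau_s) * np.cos(2.0 * np.pi * center_khz * 1e3 * t)
    pp = 10.0 ** (level_db / 20.0)
    return w * (pp / (w.max() - w.min()))


# ---------------------------------------------------------------------------
# parameter draws


def _stratified_uniform(rng: np.random.Generator, size: int) -> np.ndarray:
    """One-dimensional Latin-hypercube uniforms: one draw per equal-width
    stratum of (0, 1), in shuffled order.  Each draw is marginally U(0, 1),
    but the sample covers the distribution evenly, so the Monte Carlo
    variance of a population mean collapses — population-recovery studies
    then measure pipeline bias rather than draw luck."""
    u = (rng.permutation(size) + rng.uniform(0.0, 1.0, size=size)) / size
    return np.clip(u, 1e-12, 1.0 - 1e-12)


def draw_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    """Normal(mean, sd) truncated below at ``lower`` (a far physical floor,
    so the drawn mean stays essentially unbiased), via stratified
    inverse-CDF sampling."""
    from scipy.stats import truncnorm

    a = (lower - mean) / sd
    return truncnorm.ppf(_stratified_uniform(rng, size), a, np.inf, loc=mean, scale=sd)


def draw_lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Lognormal draws moment-matched to the given arithmetic mean and SD,
    via stratified inverse-CDF sampling (heavy tails — duration CV ≈ 0.7 —
    would otherwise dominate recovered-mean error)."""
    from scipy.stats import norm

    s2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return np.exp(mu + np.sqrt(s2) * norm.ppf(_stratified_uniform(rng, size)))


def sample_click_specs(
    rng: np.random.Generator,
    n: int,
    region: str = "total",
    spl_pp_db: Optional[float] = None,
    onsets_s: Optional[Sequence[float]] = None,
    chirped: bool = True,
) -> List[ClickSynthSpec]:
    """Draw click specs matched to the reported population marginals: peak
    frequency and duration from truncated normals, −3 dB bandwidth realized
    through the chirp rate (clamped at the unchirped Gabor bound)."""
    stats = CLICKS[region]
    fp = draw_truncated_normal(rng, stats["fp_khz"].mean, stats["fp_khz"].sd, 20.0, n)
    dur = draw_truncated_normal(rng, stats["duration_us"].mean, stats["duration_us"].sd, 6.0, n)
    bw = draw_truncated_normal(rng, stats["bw3_khz"].mean, stats["bw3_khz"].sd, 15.0, n)
    if spl_pp_db is None:
        spl = rng.normal(stats["spl_pp_db"].mean, stats["spl_pp_db"].sd, size=n)
    else:
        spl = np.full(n, spl_pp_db)
    specs = []
    for i in range(n):
        sigma = duration_to_sigma_us(dur[i])
        chirp = 0.0
        if chirped and bw[i] > gabor_bw3_khz(sigma) * 1.005:
            try:
                chirp = solve_chirp_rate(bw[i], sigma)
            except ValueError:
                chirp = 0.0
        spec = ClickSynthSpec(
            carrier_khz=fp[i],
            sigma_us=sigma,
            chirp_khz_per_us=chirp,
            spl_pp_db=spl[i],
            onset_s=float(onsets_s[i]) if onsets_s is not None else 0.0,
        )
        try:
            spec.validate(DEFAULT_SAMPLE_RATE)
        except ValueError:
            spec.chirp_khz_per_us = 0.0  # drop chirp rather than the click
        specs.append(spec)
    return specs


def sample_whistle_spec(
    rng: np.random.Generator,
    shape: Optional[str] = None,
    snr_db: float = 20.0,
    onset_s: float = 0.0,
) -> WhistleSynthSpec:
    """Draw one whistle spec of the given (or random) shape archetype with
    duration and frequencies in the reported population ranges."""
    if shape is None:
        shape = WHISTLE_SHAPES[rng.integers(len(WHISTLE_SHAPES))]
    stats = WHISTLES["total"]
    duration = float(
        np.clip(draw_lognormal(rng, stats["duration_ms"].mean, stats["duration_ms"].sd, 1)[0],
                80.0, 900.0)
    )
    if shape == "constant":
        anchors = (float(rng.uniform(3.0, 10.0)),)
    elif shape == "upsweep":
        start = rng.uniform(3.0, 7.0)
        anchors = (float(start), float(start + rng.uniform(1.5, 6.0)))
    elif shape == "downsweep":
        start = rng.uniform(5.0, 11.0)
        anchors = (float(start), float(start - rng.uniform(1.5, min(6.0, start - 2.5))))
    elif shape == "concave":
        ends = rng.uniform(6.0, 10.0, size=2)
        mid = min(ends) - rng.uniform(1.5, 3.5)
        anchors = (float(ends[0]), float(max(mid, 2.2)), float(ends[1]))
    elif shape == "convex":
        ends = rng.uniform(4.0, 8.0, size=2)
        mid = max(ends) + rng.uniform(1.5, 4.0)
        anchors = (float(ends[0]), float(mid), float(ends[1]))
    else:  # sinusoidal
        base = rng.uniform(4.0, 8.0)
        amp = rng.uniform(1.0, 2.5)
        k = int(rng.integers(4, 6))
        anchors = tuple(float(base + amp * (1 if i % 2 else -1)) for i in range(k))
    return WhistleSynthSpec(
        shape=shape, duration_ms=duration, anchors_khz=anchors, snr_db=snr_db, onset_s=onset_s
    )


# ---------------------------------------------------------------------------
# scene rendering


def _add(scene: np.ndarray, pulse: np.ndarray, start: int) -> None:
    """Add a pulse into the scene at sample ``start``, clipped to bounds."""
    a, b = max(start, 0), min(start + len(pulse), len(scene))
    if b > a:
        scene[a:b] += pulse[a - start : b - start]


def render_scene(
    config: SceneConfig,
    out_wav=None,
    truth_csv=None,
    calibration: Calibration = Calibration(),
) -> Tuple[AudioSegment, SceneAnnotation]:
    """Render a scene (noise + events) and its exact annotation.

    Clicks are placed with their envelope peak at ``onset_s``; whistles span
    [onset, onset + duration]; snaps are drawn as a Poisson process at
    ``snap_rate_per_s`` with decay constants 3–8 μs.  The same seed always
    produces byte-identical output.  If ``out_wav`` is given, samples
    exceeding the calibrated full scale raise an error naming the event.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    n = int(round(config.duration_s * fs))
    scene = rng.standard_normal(n) * 10.0 ** (config.ambient_spl_db / 20.0)
    ambient_rms = 10.0 ** (config.ambient_spl_db / 20.0)
    if config.vessel_noise:
        sos = butter(2, config.vessel_corner_hz, btype="lowpass", fs=fs, output="sos")
        v = sosfiltfilt(sos, rng.standard_normal(n))
        scene += v * (10.0 ** (config.vessel_level_db / 20.0) / np.std(v))

    events: List[SceneEvent] = []
    for spec in config.clicks:
        pulse = make_click_pulse(spec, fs)
        start = int(round(spec.onset_s * fs)) - len(pulse) // 2
        _add(scene, pulse, start)
        half_span = 4.0 * spec.sigma_us * 1e-6
        events.append(SceneEvent("click", spec.onset_s - half_span, spec.onset_s + half_span, spec))

    for spec in config.whistles:
        amp = np.sqrt(2.0) * ambient_rms * 10.0 ** (spec.snr_db / 20.0)
        tone = make_whistle_waveform(spec, fs, amplitude=amp)
        _add(scene, tone, int(round(spec.onset_s * fs)))
        events.append(
            SceneEvent("whistle", spec.onset_s, spec.onset_s + spec.duration_ms * 1e-3, spec)
        )

    if config.snap_rate_per_s > 0:
        n_snaps = rng.poisson(config.snap_rate_per_s * config.duration_s)
        onsets = np.sort(rng.uniform(0.0, config.duration_s, size=n_snaps))
        taus = rng.uniform(3.0, 8.0, size=n_snaps)
        levels = rng.uniform(148.0, 172.0, size=n_snaps)
        centers = rng.uniform(180.0, 250.0, size=n_snaps)
        for onset, tau, level, center in zip(onsets, taus, levels, centers):
            snap = make_snap(fs, level_db=level, tau_us=tau, center_khz=center)
            _add(scene, snap, int(round(onset * fs)))
            spec = SnapSpec(onset_s=float(onset), level_db=float(level), tau_us=float(tau),
                            center_khz=float(center))
            events.append(SceneEvent("snap", spec.onset_s, spec.onset_s + 8 * tau * 1e-6, spec))

    events.sort(key=lambda e: e.onset_s)
    for prev, nxt in zip(events, events[1:]):
        if nxt.onset_s < prev.offset_s:
            logger.info("overlapping events at %.4f s (%s / %s)",
                        nxt.onset_s, prev.event_class, nxt.event_class)

    segment = AudioSegment(samples=scene, sample_rate=fs, calibration=calibration)
    annotation = SceneAnnotation(events)
    if out_wav is not None:
        peak_idx = int(np.argmax(np.abs(scene)))
        if np.abs(scene[peak_idx]) > calibration.full_scale_pressure:
            t_peak = peak_idx / fs
            culprit = min(events, key=lambda e: abs(e.onset_s - t_peak), default=None)
            name = f"{culprit.event_class} at {culprit.onset_s:.4f} s" if culprit else "ambient noise"
            raise ValueError(f"scene clips WAV full scale near {t_peak:.4f} s ({name})")
        write_wav(out_wav, segment, calibration)
    if truth_csv is not None:
        annotation.write_csv(truth_csv)
    return segment, annotation


# ---------------------------------------------------------------------------
# canonical scenes


def standard_scene(seed: int = 7) -> Tuple[AudioSegment, SceneAnnotation]:
    """The standard 60 s benchmark scene: 50 population-drawn clicks at
    160 dB SPLpp, ambient 95 dB, snapping at 1/s, plus one 300 ms constant
    6 kHz whistle at 20 dB SNR at t = 30 s."""
    rng = np.random.default_rng(seed)
    onsets = np.sort(rng.uniform(1.0, 59.0, size=50))
    while np.any(np.diff(onsets) < 0.05):  # keep clicks well separated
        onsets = np.sort(rng.uniform(1.0, 59.0, size=50))
    clicks = sample_click_specs(rng, 50, spl_pp_db=160.0, onsets_s=onsets)
    whistle = WhistleSynthSpec("constant", 300.0, (6.0,), snr_db=20.0, onset_s=30.0)
    config = SceneConfig(
        duration_s=60.0,
        ambient_spl_db=95.0,
        snap_rate_per_s=1.0,
        clicks=clicks,
        whistles=[whistle],
        seed=seed,
    )
    return render_scene(config)


def training_scenes(seed: int = 11) -> List[Tuple[AudioSegment, SceneAnnotation]]:
    """Labeled scenes for classifier training: one click-only scene and one
    snap-only scene, both at ambient 95 dB."""
    rng = np.random.default_rng(seed)
    onsets = 0.05 + 0.05 * np.arange(160) + rng.uniform(0, 0.02, size=160)
    clicks = sample_click_specs(rng, 160, onsets_s=onsets, chirped=False)
    click_cfg = SceneConfig(duration_s=float(onsets[-1] + 0.1), clicks=clicks, seed=seed)
    snap_cfg = SceneConfig(duration_s=8.0, snap_rate_per_s=20.0, seed=seed + 1)
    return [render_scene(click_cfg), render_scene(snap_cfg)]
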