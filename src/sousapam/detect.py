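"""Echolocation-click detection: Teager–Kaiser energy operator, matched-gain
Gaussian/rectangular smoothing, Filter Difference Ratio thresholding,
peak-referenced window extraction and a pluggable click/non-click classifier.

The TKEO Ψ[x_n] = x_n² − x_{n−1}·x_{n+1} tracks instantaneous energy; a
short transient produces a sharp TKEO peak.  Smoothing the TKEO series with a
Gaussian kernel (FWHM 0.10 ms) and a rectangular kernel of identical gain and
length yields two energy estimates whose normalized difference — the Filter
Difference Ratio, FDR = (h₁ − h₂)/h₁ — is near zero on stationary noise and
approaches 1 − mean/max kernel tap at an impulsive event.  Samples whose FDR
exceeds the 0.7 threshold are merged into candidate events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal import hilbert, oaconvolve
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .audio import AudioSegment, highpass
from .synth import SceneAnnotation

__all__ = [
    "DetectorConfig",
    "ClickCandidate",
    "tkeo",
    "build_kernels",
    "fdr_series",
    "detect_candidates",
    "extract_click_window",
    "click_features",
    "FEATURE_NAMES",
    "ClickClassifier",
    "train_classifier",
    "train_and_classify",
    "score_detections",
    "has_reverberation",
]

FEATURE_NAMES = (
    "duration95_us",
    "peak_freq_khz",
    "bw3_khz",
    "centroid_khz",
    "crest_factor",
    "hf_energy_ratio",
)


@dataclass(frozen=True)
class DetectorConfig:
    """TKEO/FDR detector settings.

    ``fwhm_ms`` is the Gaussian smoother's full width at half maximum and
    ``fdr_threshold`` the detection threshold on the Filter Difference Ratio.
    The kernel half-width N is derived from the FWHM (2N+1 spans ≈ 8×FWHM,
    keeping the impulse-response FDR ceiling well above the threshold).
    Candidates closer than ``refractory_ms`` are merged.  Window extraction
    grows from the envelope peak until the envelope stays ``window_drop_db``
    below the peak for ``window_quiet_run`` consecutive samples, capped at
    ±``window_cap_us``.
    """

    fwhm_ms: float = 0.10
    fdr_threshold: float = 0.7
    refractory_ms: float = 1.0
    window_cap_us: float = 150.0
    window_drop_db: float = 20.0
    window_quiet_run: int = 10
    echo_screen: bool = False
    echo_level_db: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.fwhm_ms <= 0:
            raise ValueError("fwhm_ms must be positive")

    def kernel_halfwidth(self, sample_rate: float) -> int:
        return int(round(4.0 * self.fwhm_ms * 1e-3 * sample_rate))

    def sigma_g_s(self) -> float:
        # standard Gaussian FWHM relation σ = FWHM / (2·sqrt(2·ln 2))
        return self.fwhm_ms * 1e-3 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ClickCandidate:
    """One detected transient, referenced to its TKEO peak sample."""

    peak_index: int
    peak_time_s: float
    fdr_at_peak: float
    window: np.ndarray
    window_start: int
    truncated: bool = False
    label: str = "unlabeled"  # "click" | "other" | "unlabeled"
    score: float = float("nan")


def tkeo(samples: np.ndarray) -> np.ndarray:
    """Teager–Kaiser energy series Ψ[n] = x[n]² − x[n−1]·x[n+1]; endpoints 0."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 3:
        raise ValueError("TKEO needs at least 3 samples")
    psi = np.zeros_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    return psi


def build_kernels(config: DetectorConfig, sample_rate: float) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian smoothing kernel and rectangular kernel of identical length
    and total gain.

    Gaussian taps are MAF₁[n] = (T_s/(σ_G·√2π))·exp(−n²T_s²/(2σ_G²)) for
    n = −N..N; each rectangular tap equals the mean Gaussian tap, so both
    kernels sum to the same gain.
    """
    ts = 1.0 / sample_rate
    sigma = config.sigma_g_s()
    n = config.kernel_halfwidth(sample_rate)
    idx = np.arange(-n, n + 1)
    gauss = ts / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(-(idx * ts) ** 2 / (2.0 * sigma**2))
    rect = np.full(2 * n + 1, gauss.sum() / (2 * n + 1))
    return gauss, rect


def fdr_series(energy: np.ndarray, kernels: Tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Filter Difference Ratio per sample: (h₁ − h₂)/h₁ with h₁, h₂ the
    Gaussian- and rectangular-smoothed TKEO (same-length zero-padded
    convolution); 0 wherever h₁ ≤ 0."""
    gauss, rect = kernels
    h1 = oaconvolve(energy, gauss, mode="same")
    h2 = oaconvolve(energy, rect, mode="same")
    out = np.zeros_like(h1)
    pos = h1 > 0
    out[pos] = (h1[pos] - h2[pos]) / h1[pos]
    return out


def _merge_runs(above: np.ndarray, gap: int) -> List[Tuple[int, int]]:
    """Contiguous True runs of ``above``, merging runs separated by < gap."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    merged = [(int(starts[0]), int(ends[0]))]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], int(e))
        else:
            merged.append((int(s), int(e)))
    return merged


def detect_candidates(
    segment: AudioSegment, config: DetectorConfig = DetectorConfig()
) -> List[ClickCandidate]:
    """Detect click candidates in a (high-passed) segment.

    FDR runs above threshold are merged within the refractory interval; each
    run yields one candidate at the TKEO maximum of the run, with its
    peak-referenced waveform window attached.
    """
    x = segment.samples
    if x.size < 3:
        return []
    energy = tkeo(x)
    fdr = fdr_series(energy, build_kernels(config, segment.sample_rate))
    gap = max(int(round(config.refractory_ms * 1e-3 * segment.sample_rate)), 1)
    candidates = []
    for s, e in _merge_runs(fdr > config.fdr_threshold, gap):
        peak = s + int(np.argmax(energy[s : e + 1]))
        window, start, truncated = extract_click_window(x, peak, segment.sample_rate, config)
        if config.echo_screen and has_reverberation(window, segment.sample_rate, config):
            continue
        candidates.append(
            ClickCandidate(
                peak_index=peak,
                peak_time_s=segment.start_time + peak / segment.sample_rate,
                fdr_at_peak=float(fdr[peak]),
                window=window,
                window_start=start,
                truncated=truncated,
            )
        )
    return candidates


def extract_click_window(
    samples: np.ndarray,
    peak_index: int,
    sample_rate: float,
    config: DetectorConfig = DetectorConfig(),
) -> Tuple[np.ndarray, int, bool]:
    """Extract the click waveform around its envelope peak.

    The window grows symmetrically until the Hilbert envelope stays below
    −``window_drop_db`` of the peak for ``window_quiet_run`` consecutive
    samples on each side, capped at ±``window_cap_us``.  Windows truncated by
    the segment edge are flagged, not dropped.
    """
    if not (0 <= peak_index < len(samples)):
        raise ValueError("peak_index outside segment")
    cap = max(int(round(config.window_cap_us * 1e-6 * sample_rate)), 4)
    pad = config.window_quiet_run + 8
    lo = max(peak_index - cap - pad, 0)
    hi = min(peak_index + cap + pad + 1, len(samples))
    env = np.abs(hilbert(samples[lo:hi]))
    center = peak_index - lo
    # re-reference to the local envelope peak
    search = slice(max(center - 8, 0), min(center + 9, len(env)))
    center = search.start + int(np.argmax(env[search]))
    thr = env[center] * 10.0 ** (-config.window_drop_db / 20.0)
    quiet = env < thr

    def _edge(direction: int) -> Tuple[int, bool]:
        run = 0
        j = center
        limit = center + direction * min(cap, (len(env) - 1 - center) if direction > 0 else center)
        while j != limit:
            j += direction
            run = run + 1 if quiet[j] else 0
            if run >= config.window_quiet_run:
                return j, False  # window keeps the quiet run it grew through
        at_segment_edge = (lo + j <= 0) or (lo + j >= len(samples) - 1)
        return j, at_segment_edge

    left, trunc_l = _edge(-1)
    right, trunc_r = _edge(+1)
    start = lo + left
    return samples[start : lo + right + 1].copy(), start, bool(trunc_l or trunc_r)


def has_reverberation(window: np.ndarray, sample_rate: float, config: DetectorConfig) -> bool:
    """Envelope-shape screen for bottom/surface reflections: a secondary
    envelope lobe above −``echo_level_db`` of the peak, separated from the
    main lobe, within the window."""
    env = np.abs(hilbert(window))
    peak = int(np.argmax(env))
    thr_echo = env[peak] * 10.0 ** (-config.echo_level_db / 20.0)
    thr_gap = env[peak] * 10.0 ** (-config.window_drop_db / 20.0)
    for side in (env[peak:], env[:peak][::-1]):
        below = np.flatnonzero(side < thr_gap)
        if below.size and np.any(side[below[0] :] > thr_echo):
            return True
    return False


def click_features(window: np.ndarray, sample_rate: float) -> np.ndarray:
    """Fixed-order, level-independent feature vector (see FEATURE_NAMES):
    95%-energy duration, peak frequency, −3 dB bandwidth, spectral centroid,
    crest factor and the energy fraction above 100 kHz."""
    from . import measure

    w = np.asarray(window, dtype=np.float64)
    if w.size < 4 or not np.any(w):
        raise ValueError("degenerate click window")
    m = measure.measure_click(w, sample_rate)
    freqs = rfftfreq(max(4096, len(w)), 1.0 / sample_rate)
    power = np.abs(rfft(w, max(4096, len(w)))) ** 2
    centroid_khz = float(np.sum(freqs * power) / np.sum(power) / 1e3)
    crest = float(np.max(np.abs(w)) / np.sqrt(np.mean(w**2)))
    hf_ratio = float(np.sum(power[freqs > 100e3]) / np.sum(power))
    return np.array([m.duration_us, m.fp_khz, m.bw3_khz, centroid_khz, crest, hf_ratio])


class ClickClassifier:
    """Single-hidden-layer feed-forward click/non-click scorer (default 32
    units, logistic output), trained on synthetic click and snap features.
    Any callable ``scorer(features) -> [0, 1]`` can substitute for it."""

    def __init__(self, hidden_units: int = 32, seed: int = 0):
        self._pipe = make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(hidden_units,),
                max_iter=2000,
                random_state=seed,
            ),
        )

    def fit(self, features: np.ndarray, labels: Sequence[int]) -> "ClickClassifier":
        y = np.asarray(labels)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both click and non-click examples")
        self._pipe.fit(np.asarray(features), y)
        return self

    def __call__(self, features: np.ndarray) -> np.ndarray:
        proba = self._pipe.predict_proba(np.atleast_2d(features))
        click_col = list(self._pipe.classes_).index(1)
        return proba[:, click_col]


def _match_times(cand_times: np.ndarray, truth_times: np.ndarray, tol_s: float):
    """Greedy one-to-one matching by time proximity; returns index pairs."""
    pairs = []
    used_c: set = set()
    used_t: set = set()
    order = []
    for i, tc in enumerate(cand_times):
        for j, tt in enumerate(truth_times):
            dt = abs(tc - tt)
            if dt <= tol_s:
                order.append((dt, i, j))
    for _, i, j in sorted(order):
        if i not in used_c and j not in used_t:
            pairs.append((i, j))
            used_c.add(i)
            used_t.add(j)
    return pairs


def train_classifier(
    scenes: Sequence[Tuple[AudioSegment, SceneAnnotation]],
    config: DetectorConfig = DetectorConfig(),
    seed: int = 0,
    tol_ms: float = 0.5,
) -> ClickClassifier:
    """Train the default classifier on ground-truth scenes: candidates are
    detected, matched to annotated click/snap events, and labeled."""
    feats, labels = [], []
    for segment, annotation in scenes:
        hp = highpass(segment)
        cands = detect_candidates(hp, config)
        cand_times = np.array([c.peak_time_s for c in cands])
        for event_class, lab in (("click", 1), ("snap", 0)):
            events = annotation.of_class(event_class)
            truth = np.array([(e.onset_s + e.offset_s) / 2.0 for e in events])
            for i, _ in _match_times(cand_times, truth, tol_ms * 1e-3):
                try:
                    feats.append(click_features(cands[i].window, segment.sample_rate))
                    labels.append(lab)
                except ValueError:
                    continue
    return ClickClassifier(seed=seed).fit(np.array(feats), labels)


def train_and_classify(
    candidates: List[ClickCandidate],
    training_scenes: Optional[Sequence[Tuple[AudioSegment, SceneAnnotation]]] = None,
    scorer: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    sample_rate: float = 576_000.0,
    config: DetectorConfig = DetectorConfig(),
    seed: int = 0,
    threshold: float = 0.5,
) -> List[ClickCandidate]:
    """Score candidates in [0, 1] and label ``click`` iff score ≥ threshold.

    Uses ``scorer`` if given, otherwise trains the default classifier on
    ``training_scenes`` (which must carry ground truth).
    """
    if scorer is None:
        if training_scenes is None:
            raise ValueError("either a scorer or training scenes are required")
        scorer = train_classifier(training_scenes, config, seed=seed)
    for cand in candidates:
        try:
            feats = click_features(cand.window, sample_rate)
        except ValueError:
            cand.score, cand.label = 0.0, "other"
            continue
        cand.score = float(np.atleast_1d(scorer(feats))[0])
        cand.label = "click" if cand.score >= threshold else "other"
    return candidates


def score_detections(
    candidates: Sequence[ClickCandidate],
    annotation: SceneAnnotation,
    tol_ms: float = 0.5,
    event_class: str = "click",
    labeled_only: bool = False,
) -> dict:
    """Precision/recall of candidates against ground truth (greedy time
    matching within ``tol_ms``)."""
    cands = [c for c in candidates if not labeled_only or c.label == "click"]
    truth = [(e.onset_s + e.offset_s) / 2.0 for e in annotation.of_class(event_class)]
    pairs = _match_times(
        np.array([c.peak_time_s for c in cands]), np.array(truth), tol_ms * 1e-3
    )
    tp = len(pairs)
    precision = tp / len(cands) if cands else 0.0
    recall = tp / len(truth) if truth else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "n_candidates": len(cands),
        "n_truth": len(truth),
        "matches": pairs,
    }
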