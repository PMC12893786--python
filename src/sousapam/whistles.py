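"""Whistle contour extraction from spectrograms by adaptive thresholding and
connected-component analysis, plus contour metrics and six-type shape
classification.

Pipeline: STFT with a 1024-sample Hanning window (hop 512) → dB spectrogram
cropped to the whistle band → broadband-transient equalization → 3×3 median
filter plus a global scalar offset (3·std − mean of the raw spectrogram) →
per-pixel adaptive threshold (mean over a circular neighborhood of radius
15) → 8-connected component labeling → filters (horizontal extent ≥ 11
columns and maximum enhanced value ≥ 10) → per-column intensity-weighted
ridge → duration/frequency metrics and shape classification into constant,
upsweep, downsweep, concave, convex and sinusoidal archetypes.

Recordings are analyzed in frames of 65,792 samples with 13,824-sample
overlap; whistles that span frames are stitched from per-frame contour
pieces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import rfft, rfftfreq
from scipy.ndimage import median_filter
from scipy.signal import fftconvolve, get_window
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk

from .audio import AudioSegment, FrameSpec, frame_stream

__all__ = [
    "Spectrogram",
    "ComponentRegion",
    "WhistleMetrics",
    "WhistleContour",
    "spectrogram",
    "enhance",
    "equalize_transients",
    "adaptive_threshold",
    "extract_regions",
    "ridge_contour",
    "measure_whistle",
    "classify_shape",
    "extract_whistles",
    "export_review",
]

DB_FLOOR = -120.0


@dataclass
class Spectrogram:
    """dB spectrogram, time-major: ``values[m, f]`` for column m, bin f."""

    values: np.ndarray
    sample_rate: float
    hop: int
    nfft: int = 1024
    start_time: float = 0.0
    bin0: int = 0  # first retained frequency bin (band crop)

    @property
    def bin_width_hz(self) -> float:
        return self.sample_rate / self.nfft

    @property
    def col_step_s(self) -> float:
        return self.hop / self.sample_rate

    def col_times(self) -> np.ndarray:
        # column time = center of its analysis window
        return self.start_time + (np.arange(self.values.shape[0]) * self.hop
                                  + (self.nfft - 1) / 2.0) / self.sample_rate

    def freqs_hz(self) -> np.ndarray:
        full = rfftfreq(self.nfft, 1.0 / self.sample_rate)
        return full[self.bin0 : self.bin0 + self.values.shape[1]]

    def crop(self, fmax_hz: float, fmin_hz: float = 0.0) -> "Spectrogram":
        """Restrict to the analysis band [fmin, fmax]; geometry is preserved
        through ``bin0``."""
        full = rfftfreq(self.nfft, 1.0 / self.sample_rate)
        keep = np.flatnonzero((full >= fmin_hz) & (full <= fmax_hz))
        return Spectrogram(self.values[:, keep[0] : keep[-1] + 1], self.sample_rate,
                           self.hop, self.nfft, self.start_time, self.bin0 + int(keep[0]))


@dataclass
class ComponentRegion:
    """8-connected set of retained spectrogram pixels."""

    rows: np.ndarray  # time-column indices
    cols: np.ndarray  # frequency-bin indices
    width: int
    max_value: float


@dataclass
class WhistleMetrics:
    duration_ms: float
    bf_khz: float
    ef_khz: float
    minf_khz: float
    maxf_khz: float
    range_khz: float


@dataclass
class WhistleContour:
    """Per-column frequency ridge of one whistle candidate."""

    times_s: np.ndarray
    freqs_khz: np.ndarray
    col_step_s: float
    interpolated: np.ndarray = field(default=None)  # per-point gap-fill flags
    peaks_db: np.ndarray = field(default=None)  # per-column ridge peak intensity
    metrics: Optional[WhistleMetrics] = None
    shape: Optional[str] = None

    def __post_init__(self) -> None:
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.times_s), dtype=bool)
        if self.peaks_db is None:
            self.peaks_db = np.zeros(len(self.times_s))


def spectrogram(
    samples: np.ndarray,
    sample_rate: float,
    hop: int = 512,
    nfft: int = 1024,
    start_time: float = 0.0,
) -> Spectrogram:
    """Log-magnitude STFT: P[m, f] = 20·log10 |F[m, f]| with Hanning-1024
    windows at the given hop; zero-magnitude bins floor at −120 dB."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size < nfft:
        raise ValueError(f"need at least one window ({nfft} samples), got {x.size}")
    win = get_window("hann", nfft, fftbins=True)
    frames = sliding_window_view(x, nfft)[::hop] * win
    mag = np.abs(rfft(frames, axis=1))
    values = 20.0 * np.log10(np.maximum(mag, 10.0 ** (DB_FLOOR / 20.0)))
    return Spectrogram(values, sample_rate, hop, nfft, start_time)


def equalize_transients(spec: Spectrogram) -> Spectrogram:
    """Broadband-transient suppression: subtract each time column's excess
    median level (over frequency) relative to the typical column.

    An echolocation click or snap spans the whole band for the 2–3 columns
    its analysis windows cover, surviving the 3×3 median filter as a
    vertical stripe that can touch and corrupt a whistle component; a
    narrowband whistle occupies a few bins and leaves its column median
    almost unchanged, so this equalization levels the stripes only."""
    p = spec.values
    col_median = np.median(p, axis=1)
    excess = np.maximum(col_median - np.median(col_median), 0.0)
    return Spectrogram(p - excess[:, None], spec.sample_rate, spec.hop,
                       spec.nfft, spec.start_time, spec.bin0)


def enhance(spec: Spectrogram) -> Spectrogram:
    """Median-filter enhancement: P′ = median₃ₓ₃(P) + 3·std(P) − mean(P),
    where the scalar offset uses the pre-median matrix.  The 3×3 median
    removes isolated (click/impulse) pixels; the offset is global and
    preserves pixel ordering."""
    p = spec.values
    if p.shape[0] < 3 or p.shape[1] < 3:
        raise ValueError("spectrogram must be at least 3×3")
    med = median_filter(p, size=3, mode="reflect")
    return Spectrogram(med + (3.0 * p.std() - p.mean()), spec.sample_rate, spec.hop,
                       spec.nfft, spec.start_time, spec.bin0)


def adaptive_threshold(spec: Spectrogram, radius: int = 15) -> np.ndarray:
    """Binary mask: pixel retained iff its enhanced value strictly exceeds
    the mean over the discrete Euclidean disk of the given radius centered on
    it (disks clipped at the edges)."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    p = spec.values
    kernel = disk(radius).astype(np.float64)
    local_sum = fftconvolve(p, kernel, mode="same")
    local_n = fftconvolve(np.ones_like(p), kernel, mode="same")
    threshold = local_sum / local_n
    return (p - threshold) > 1e-6  # tolerance absorbs FFT round-off


def extract_regions(
    mask: np.ndarray,
    spec: Spectrogram,
    min_width: int = 11,
    min_peak: float = 10.0,
) -> Tuple[List[ComponentRegion], List[Tuple[ComponentRegion, str]]]:
    """8-connected labeling of the mask; keep regions spanning ≥ ``min_width``
    time columns whose maximum enhanced value is ≥ ``min_peak``; return
    (kept, rejected-with-reason)."""
    if mask.shape != spec.values.shape:
        raise ValueError("mask and spectrogram geometry differ")
    labels = cc_label(mask, connectivity=2)
    kept, rejected = [], []
    for prop in regionprops(labels):
        rows = prop.coords[:, 0]
        cols = prop.coords[:, 1]
        region = ComponentRegion(
            rows=rows,
            cols=cols,
            width=int(rows.max() - rows.min() + 1),
            max_value=float(spec.values[rows, cols].max()),
        )
        if region.width < min_width:
            rejected.append((region, f"width {region.width} < {min_width} columns"))
        elif region.max_value < min_peak:
            rejected.append((region, f"max value {region.max_value:.1f} < {min_peak} (noise)"))
        else:
            kept.append(region)
    return kept, rejected


def ridge_contour(region: ComponentRegion, spec: Spectrogram) -> WhistleContour:
    """Per-column ridge: in each occupied column, the intensity-weighted
    centroid (linear power weights) of the vertically contiguous pixel run
    containing the column's strongest pixel — detached pixels bridged onto
    the component by noise do not pull the ridge — smoothed with a 5-point
    median.  Column gaps are linearly interpolated and flagged."""
    freqs = spec.freqs_hz()
    times = spec.col_times()
    order = np.lexsort((region.cols, region.rows))
    rows, cols = region.rows[order], region.cols[order]
    vals = spec.values[rows, cols]
    occupied_list, ridge_list, peak_list = [], [], []
    for m in np.unique(rows):
        sel = rows == m
        c, v = cols[sel], vals[sel]  # col-sorted within the column
        k = int(np.argmax(v))
        lo, hi = k, k
        while lo > 0 and c[lo - 1] == c[lo] - 1:
            lo -= 1
        while hi < len(c) - 1 and c[hi + 1] == c[hi] + 1:
            hi += 1
        w = 10.0 ** (v[lo : hi + 1] / 10.0)
        occupied_list.append(m)
        ridge_list.append(np.sum(w * freqs[c[lo : hi + 1]]) / np.sum(w))
        peak_list.append(v[k])
    occupied = np.asarray(occupied_list)
    ridge = np.asarray(ridge_list)

    full = np.arange(occupied[0], occupied[-1] + 1)
    interpolated = ~np.isin(full, occupied)
    values = np.interp(full, occupied, ridge)
    peaks = np.interp(full, occupied, np.asarray(peak_list))
    if values.size >= 5:
        values = median_filter(values, size=5, mode="nearest")
    return WhistleContour(
        times_s=times[full],
        freqs_khz=values / 1e3,
        col_step_s=spec.col_step_s,
        interpolated=interpolated,
        peaks_db=peaks,
    )


def measure_whistle(contour: WhistleContour) -> WhistleMetrics:
    """Duration and frequency metrics: duration = (n−1)·column step; BF/EF =
    first/last ridge values; MinF/MaxF = extrema; range = MaxF − MinF."""
    f = contour.freqs_khz
    if f.size < 2:
        raise ValueError("contour needs at least 2 points")
    minf, maxf = float(f.min()), float(f.max())
    return WhistleMetrics(
        duration_ms=float((contour.times_s[-1] - contour.times_s[0]) * 1e3),
        bf_khz=float(f[0]),
        ef_khz=float(f[-1]),
        minf_khz=minf,
        maxf_khz=maxf,
        range_khz=maxf - minf,
    )


def _turning_directions(f: np.ndarray, delta: float) -> List[int]:
    """Monotone run directions after δ-hysteresis (zigzag walk); the number
    of interior turning points is len(dirs) − 1."""
    dirs: List[int] = []
    direction = 0
    hi = lo = f[0]
    for value in f[1:]:
        hi = max(hi, value)
        lo = min(lo, value)
        if direction == 0:
            if value <= hi - delta:
                direction = -1
                dirs.append(-1)
                lo = value
            elif value >= lo + delta:
                direction = +1
                dirs.append(+1)
                hi = value
        elif direction == +1 and value <= hi - delta:
            direction = -1
            dirs.append(-1)
            lo = value
        elif direction == -1 and value >= lo + delta:
            direction = +1
            dirs.append(+1)
            hi = value
    return dirs


def classify_shape(contour: WhistleContour) -> str:
    """Deterministic shape rules on the smoothed ridge with tolerance
    δ = max(0.25 kHz, 5% of the mean frequency): constant if total excursion
    < 2δ; otherwise 0 δ-significant turning points ⇒ up/downsweep by the
    begin→end sign, 1 ⇒ convex (interior maximum) or concave (interior
    minimum), ≥ 2 ⇒ sinusoidal."""
    f = contour.freqs_khz
    delta = max(0.25, 0.05 * float(f.mean()))
    if f.max() - f.min() < 2.0 * delta:
        return "constant"
    dirs = _turning_directions(f, delta)
    turns = max(len(dirs) - 1, 0)
    if turns == 0:
        if not dirs:
            return "constant"
        return "upsweep" if dirs[0] > 0 else "downsweep"
    if turns == 1:
        return "convex" if dirs[0] > 0 else "concave"
    return "sinusoidal"


def _continuity_khz(cur: WhistleContour, nxt: WhistleContour) -> float:
    """Mean absolute ridge disagreement over the shared time interval (or at
    the junction point when the pieces barely overlap)."""
    t0 = max(cur.times_s[0], nxt.times_s[0])
    t1 = min(cur.times_s[-1], nxt.times_s[-1])
    if t1 - t0 >= 2.0 * cur.col_step_s:
        grid = np.arange(t0, t1, cur.col_step_s)
        f_cur = np.interp(grid, cur.times_s, cur.freqs_khz)
        f_nxt = np.interp(grid, nxt.times_s, nxt.freqs_khz)
        return float(np.mean(np.abs(f_cur - f_nxt)))
    t_join = min(max(nxt.times_s[0], cur.times_s[0]), cur.times_s[-1])
    return float(
        abs(np.interp(t_join, cur.times_s, cur.freqs_khz)
            - np.interp(t_join, nxt.times_s, nxt.freqs_khz))
    )


def _stitch(
    pieces: List[Tuple[int, WhistleContour]], max_gap_s: float, max_jump_khz: float
) -> List[WhistleContour]:
    """Merge contour pieces produced by overlapping analysis frames.

    Only pieces from *different* frames may merge (two components in the same
    frame are distinct detections), and merging requires the ridges to agree
    within ``max_jump_khz`` over their whole shared interval — a whistle
    spanning a frame boundary appears in both frames' overlap region, so
    genuine continuations always share a verifiable stretch of ridge.
    """
    if not pieces:
        return []
    pieces = sorted(pieces, key=lambda p: p[1].times_s[0])
    merged: List[WhistleContour] = []
    frames: List[set] = []  # frame indices already contributing to each contour
    for frame_idx, nxt in pieces:
        best, best_df = None, max_jump_khz
        for i, cur in enumerate(merged):
            if frame_idx in frames[i]:
                continue
            if nxt.times_s[0] - cur.times_s[-1] >= max_gap_s:
                continue
            df = _continuity_khz(cur, nxt)
            if df <= best_df:
                best, best_df = i, df
        if best is None:
            merged.append(nxt)
            frames.append({frame_idx})
            continue
        cur = merged[best]
        t = np.concatenate([cur.times_s, nxt.times_s])
        f = np.concatenate([cur.freqs_khz, nxt.freqs_khz])
        flags = np.concatenate([cur.interpolated, nxt.interpolated])
        peaks = np.concatenate([cur.peaks_db, nxt.peaks_db])
        order = np.argsort(t)
        t, f, flags, peaks = t[order], f[order], flags[order], peaks[order]
        keep = np.concatenate([[True], np.diff(t) > cur.col_step_s / 2.0])
        merged[best] = WhistleContour(t[keep], f[keep], cur.col_step_s, flags[keep], peaks[keep])
        frames[best].add(frame_idx)
    return merged


def _trim_edges(contour: WhistleContour, margin_db: float) -> Optional[WhistleContour]:
    """Drop leading/trailing columns whose ridge peak intensity falls more
    than ``margin_db`` below the contour's median peak: those columns come
    from analysis windows that barely overlap the sound, and their ridge is
    noise-driven."""
    thr = np.median(contour.peaks_db) - margin_db
    strong = np.flatnonzero(contour.peaks_db >= thr)
    if strong.size < 2:
        return None
    sl = slice(strong[0], strong[-1] + 1)
    return WhistleContour(
        contour.times_s[sl], contour.freqs_khz[sl], contour.col_step_s,
        contour.interpolated[sl], contour.peaks_db[sl],
    )


def extract_whistles(
    segment: AudioSegment,
    hop: int = 512,
    radius: int = 15,
    min_width: int = 11,
    min_peak: float = 10.0,
    band_khz: Tuple[float, float] = (0.0, 30.0),
    frame_spec: FrameSpec = FrameSpec(),
    stitch_gap_ms: float = 5.0,
    stitch_jump_khz: float = 0.5,
    edge_trim_db: float = 20.0,
) -> List[WhistleContour]:
    """Full whistle pipeline over a segment: framing, spectrogram restricted
    to the whistle analysis band (fundamentals sit at 2–16 kHz), enhancement,
    adaptive threshold, connected components, ridge extraction, cross-frame
    stitching, metrics and shape classification."""
    pieces: List[Tuple[int, WhistleContour]] = []
    for frame_idx, frame in enumerate(frame_stream(segment, frame_spec)):
        if len(frame.samples) < 1024:
            continue
        spec = spectrogram(
            frame.samples,
            segment.sample_rate,
            hop=hop,
            start_time=segment.start_time + frame.start / segment.sample_rate,
        ).crop(band_khz[1] * 1e3, band_khz[0] * 1e3)
        if spec.values.shape[0] < 3:
            continue
        enhanced = enhance(equalize_transients(spec))
        mask = adaptive_threshold(enhanced, radius=radius)
        kept, _ = extract_regions(mask, enhanced, min_width=min_width, min_peak=min_peak)
        for region in kept:
            pieces.append((frame_idx, ridge_contour(region, enhanced)))
    whistles = []
    for contour in _stitch(pieces, stitch_gap_ms * 1e-3, stitch_jump_khz):
        contour = _trim_edges(contour, edge_trim_db)
        if contour is None or contour.freqs_khz.size < max(2, min_width):
            continue
        contour.metrics = measure_whistle(contour)
        contour.shape = classify_shape(contour)
        whistles.append(contour)
    return whistles


def export_review(
    segment: AudioSegment,
    whistles: Sequence[WhistleContour],
    out_dir,
    pad_s: float = 0.1,
) -> List[str]:
    """Export per-whistle spectrogram crops (PNG) with the extracted ridge
    overlaid, for manual review in place of in-field visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, w in enumerate(whistles):
        t0 = max(w.times_s[0] - pad_s, segment.start_time)
        t1 = min(w.times_s[-1] + pad_s, segment.start_time + segment.duration)
        a = int((t0 - segment.start_time) * segment.sample_rate)
        b = int((t1 - segment.start_time) * segment.sample_rate)
        if b - a < 1024:
            continue
        spec = spectrogram(segment.samples[a:b], segment.sample_rate, start_time=t0)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(
            spec.values.T,
            origin="lower",
            aspect="auto",
            extent=[spec.col_times()[0], spec.col_times()[-1], 0,
                    spec.freqs_hz()[-1] / 1e3],
            cmap="viridis",
        )
        ax.plot(w.times_s, w.freqs_khz, "r-", lw=1)
        ax.set_ylim(0, 20)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (kHz)")
        ax.set_title(f"whistle {i}: {w.shape}, {w.metrics.duration_ms:.0f} ms")
        path = out_dir / f"whistle_{i:03d}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(str(path))
    return written
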