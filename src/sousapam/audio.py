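"""Audio I/O, hydrophone calibration, high-pass conditioning, framing and
recording-site region assignment.

All in-memory audio is held as calibrated sound pressure in micropascals
(μPa).  WAV files store ADC fractions of full scale; the :class:`Calibration`
chain (full-scale voltage, gain, hydrophone sensitivity) converts between the
two on read/write.
"""

from __future__ import annotations

import json
import wave
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Tuple

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "Calibration",
    "AudioSegment",
    "FrameSpec",
    "Frame",
    "read_wav",
    "write_wav",
    "highpass",
    "frame_stream",
    "assign_region",
    "WEST_BOX",
    "EAST_BOX",
]

#: Sub-region bounding boxes (lat_min, lat_max, lon_min, lon_max) in degrees.
WEST_BOX = (24.30, 24.57, 117.94, 118.16)
EAST_BOX = (24.45, 24.63, 118.22, 118.50)


@dataclass(frozen=True)
class Calibration:
    """Recorder calibration chain.

    Parameters
    ----------
    sensitivity_db : float
        Hydrophone sensitivity in dB re 1 V/μPa (negative).
    gain_db : float
        Recorder gain in dB.
    adc_full_scale : float
        Voltage at ADC full scale (V); must be positive.
    """

    sensitivity_db: float = -176.0
    gain_db: float = 0.0
    adc_full_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.adc_full_scale <= 0:
            raise ValueError("adc_full_scale must be positive")

    @property
    def full_scale_pressure(self) -> float:
        """Pressure (μPa) corresponding to an ADC full-scale sample."""
        return self.adc_full_scale * 10.0 ** (-(self.sensitivity_db + self.gain_db) / 20.0)

    def fraction_to_pressure(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=np.float64) * self.full_scale_pressure

    def pressure_to_fraction(self, pressure: np.ndarray) -> np.ndarray:
        return np.asarray(pressure, dtype=np.float64) / self.full_scale_pressure


@dataclass
class AudioSegment:
    """Calibrated pressure time series (μPa) with provenance."""

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0
    site: Optional[Tuple[float, float]] = None  # (lat N, lon E)
    region: Optional[str] = None  # "west" | "east" | "unassigned"
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSegment holds mono audio only")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.sample_rate


@dataclass(frozen=True)
class FrameSpec:
    """Analysis framing: frame length and overlap in samples."""

    frame_len: int = 65792
    overlap: int = 13824

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.frame_len):
            raise ValueError("require 0 <= overlap < frame_len")

    @property
    def step(self) -> int:
        return self.frame_len - self.overlap


@dataclass
class Frame:
    start: int  # sample index into the source segment
    samples: np.ndarray
    partial: bool


def read_wav(path, calibration: Calibration = Calibration()) -> AudioSegment:
    """Read a mono WAV file into a calibrated :class:`AudioSegment`.

    PCM-16, PCM-24 (zero-padded into int32 by scipy), PCM-32 and float-32/64
    encodings are accepted. Integer counts are converted to fractions of full
    scale, then through the calibration chain to μPa.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono WAV, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        frac = data / 32768.0
    elif data.dtype == np.int32:
        frac = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        frac = data.astype(np.float64)
    elif data.dtype == np.uint8:
        frac = (data.astype(np.float64) - 128.0) / 128.0
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    seg = AudioSegment(
        samples=calibration.fraction_to_pressure(frac),
        sample_rate=float(rate),
        calibration=calibration,
    )
    sidecar = Path(str(path)).with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        seg.start_time = meta.get("start_time", 0.0)
        if "site" in meta and meta["site"] is not None:
            seg.site = tuple(meta["site"])
            seg.region = assign_region(*seg.site)
    return seg


def write_wav(
    path,
    segment: AudioSegment,
    calibration: Optional[Calibration] = None,
    encoding: str = "float32",
) -> None:
    """Write a segment back to WAV (``float32``, ``pcm16`` or ``pcm24``).

    Raises ``ValueError`` if any sample exceeds the calibrated full scale
    (clipping).
    """
    cal = calibration or segment.calibration
    frac = cal.pressure_to_fraction(segment.samples)
    peak = np.max(np.abs(frac)) if len(frac) else 0.0
    if peak > 1.0:
        raise ValueError(
            f"clipping: peak pressure {peak * cal.full_scale_pressure:.3g} μPa exceeds "
            f"full scale {cal.full_scale_pressure:.3g} μPa"
        )
    rate = int(round(segment.sample_rate))
    if encoding == "float32":
        wavfile.write(str(path), rate, frac.astype(np.float32))
    elif encoding == "pcm16":
        wavfile.write(str(path), rate, np.round(frac * 32767.0).astype(np.int16))
    elif encoding == "pcm24":
        ints = np.round(frac * 8388607.0).astype("<i4")
        raw = ints.astype("<i4").tobytes()
        data24 = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 4)[:, :3].tobytes()
        with wave.open(str(path), "wb") as fh:
            fh.setnchannels(1)
            fh.setsampwidth(3)
            fh.setframerate(rate)
            fh.writeframes(data24)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")


def highpass(segment: AudioSegment, cutoff: float = 5000.0) -> AudioSegment:
    """Zero-phase 4th-order Butterworth high-pass (forward-backward).

    Removes low-frequency ocean noise while preserving click timing exactly
    (no group delay).
    """
    nyquist = segment.sample_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyquist} Hz")
    sos = butter(4, cutoff, btype="highpass", fs=segment.sample_rate, output="sos")
    return replace(segment, samples=sosfiltfilt(sos, segment.samples))


def frame_stream(segment: AudioSegment, spec: FrameSpec = FrameSpec()) -> Iterator[Frame]:
    """Split a segment into overlapping analysis frames.

    Frames start at multiples of ``frame_len - overlap``; a trailing partial
    frame is retained and flagged.
    """
    x = segment.samples
    n = len(x)
    if n < 1:
        return
    if n < spec.frame_len:
        yield Frame(0, x, partial=True)
        return
    count = int(np.ceil((n - spec.overlap) / spec.step))
    for k in range(count):
        start = k * spec.step
        end = start + spec.frame_len
        yield Frame(start, x[start:min(end, n)], partial=end > n)


def assign_region(lat: float, lon: float) -> str:
    """Assign a recording site to the West or East sub-region bounding box
    (inclusive bounds); sites outside both are ``unassigned``."""
    if not (np.isfinite(lat) and np.isfinite(lon)):
        raise ValueError("coordinates must be finite")
    for name, (lat0, lat1, lon0, lon1) in (("west", WEST_BOX), ("east", EAST_BOX)):
        if lat0 <= lat <= lat1 and lon0 <= lon <= lon1:
            return name
    return "unassigned"
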