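"""Shared fixtures: the expensive benchmark scenes are session-scoped so the
detector and classification suites reuse one rendering."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sousapam import detect, synth, whistles
from sousapam.audio import highpass

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

FS = 576_000.0


@pytest.fixture(scope="session")
def standard_scene_run():
    """Standard 60 s benchmark scene, detected and classified once."""
    segment, annotation = synth.standard_scene(seed=7)
    hp = highpass(segment)
    candidates = detect.detect_candidates(hp)
    detect.train_and_classify(
        candidates,
        training_scenes=synth.training_scenes(seed=11),
        sample_rate=segment.sample_rate,
        seed=0,
    )
    return {"segment": segment, "annotation": annotation, "candidates": candidates}


@pytest.fixture(scope="session")
def archetype_run():
    """300 seeded single-whistle scenes (50 per shape archetype) at 20 dB SNR,
    classified through the full pipeline."""
    rng = np.random.default_rng(42)
    outcomes = []
    for trial in range(300):
        shape = synth.WHISTLE_SHAPES[trial % 6]
        spec = synth.sample_whistle_spec(rng, shape=shape, snr_db=20.0, onset_s=0.12)
        config = synth.SceneConfig(
            duration_s=spec.duration_ms * 1e-3 + 0.24,
            ambient_spl_db=95.0,
            whistles=[spec],
            seed=1000 + trial,
        )
        segment, _ = synth.render_scene(config)
        found = whistles.extract_whistles(segment)
        truth_f = float(np.mean(spec.anchors_khz))
        t0 = spec.onset_s
        t1 = spec.onset_s + spec.duration_ms * 1e-3
        best, best_overlap = None, 0.0
        for w in found:
            overlap = min(t1, w.times_s[-1]) - max(t0, w.times_s[0])
            if overlap > best_overlap and abs(float(np.median(w.freqs_khz)) - truth_f) < 3.0:
                best, best_overlap = w, overlap
        outcomes.append((shape, best.shape if best is not None else "missed"))
    return outcomes
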