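"""Whistle pipeline: spectrogram, enhancement, adaptive threshold, connected
components, ridge extraction, metrics, shape rules, and end-to-end recovery."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from sousapam import synth
from sousapam.audio import AudioSegment
from sousapam.whistles import (
    Spectrogram,
    WhistleContour,
    adaptive_threshold,
    classify_shape,
    enhance,
    extract_regions,
    extract_whistles,
    measure_whistle,
    ridge_contour,
    spectrogram,
)

FS = 576_000.0
BIN_HZ = FS / 1024  # 562.5
COL_S = 512 / FS


def _tone(freq_hz, dur_s=0.3, amp=1.0):
    t = np.arange(int(dur_s * FS)) / FS
    return amp * np.sin(2 * np.pi * freq_hz * t)


class TestSpectrogram:
    def test_tone_occupies_expected_bin(self):
        spec = spectrogram(_tone(6000.0), FS)
        assert np.all(np.argmax(spec.values, axis=1) == round(6000 / BIN_HZ))

    def test_silence_floors_at_minus_120(self):
        spec = spectrogram(np.zeros(4096), FS)
        assert np.all(spec.values == -120.0)

    def test_amplitude_scaling_adds_db(self):
        a = spectrogram(_tone(6000.0), FS).values
        b = spectrogram(10.0 * _tone(6000.0), FS).values
        unfloored = a > -100.0  # leakage below the −120 dB floor is clamped
        assert np.allclose((b - a)[unfloored], 20.0, atol=1e-6)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spectrogram(np.zeros(512), FS)

    def test_band_crop_preserves_frequencies(self):
        spec = spectrogram(_tone(6000.0), FS).crop(30e3)
        assert spec.values.shape[1] == int(30e3 / BIN_HZ) + 1
        assert spec.freqs_hz()[0] == 0.0
        assert np.all(np.argmax(spec.values, axis=1) == round(6000 / BIN_HZ))


class TestEnhance:
    def _spec(self, values):
        return Spectrogram(np.asarray(values, float), FS, 512)

    def test_constant_matrix_maps_to_zero(self):
        out = enhance(self._spec(np.full((10, 10), 37.0)))
        assert np.allclose(out.values, 0.0)

    def test_isolated_impulse_removed_by_median(self):
        p = np.zeros((9, 9))
        p[4, 4] = 50.0
        out = enhance(self._spec(p))
        offset = 3 * p.std() - p.mean()
        assert out.values[4, 4] == pytest.approx(offset)  # median kills the spike

    def test_global_offset_preserves_ordering(self):
        rng = np.random.default_rng(0)
        p = rng.normal(100, 5, (40, 40))
        from scipy.ndimage import median_filter

        med = median_filter(p, size=3, mode="reflect")
        out = enhance(self._spec(p))
        rho = spearmanr(med.ravel(), out.values.ravel()).statistic
        assert rho == pytest.approx(1.0)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            enhance(self._spec(np.zeros((2, 5))))


class TestAdaptiveThreshold:
    def test_constant_image_empty_mask(self):
        spec = Spectrogram(np.full((64, 64), 25.0), FS, 512)
        assert not adaptive_threshold(spec).any()

    def test_bright_line_retained(self):
        p = np.zeros((64, 64))
        p[:, 30] = 30.0
        mask = adaptive_threshold(Spectrogram(p, FS, 512))
        assert mask[:, 30].all()
        assert not mask[:, :14].any()

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            adaptive_threshold(Spectrogram(np.zeros((8, 8)), FS, 512), radius=0)


class TestRegions:
    def _spec_like(self, mask, peak=50.0):
        return Spectrogram(np.where(mask, peak, -120.0).astype(float), FS, 512)

    def test_width_rule(self):
        mask = np.zeros((50, 40), bool)
        mask[0:10, 5] = True  # 10 columns: dropped
        mask[15:45, 20] = True  # 30 columns: kept
        kept, rejected = extract_regions(mask, self._spec_like(mask))
        assert len(kept) == 1 and kept[0].width == 30
        assert any("width" in reason for _, reason in rejected)

    def test_intensity_rule(self):
        mask = np.zeros((50, 40), bool)
        mask[5:35, 20] = True
        kept, rejected = extract_regions(mask, self._spec_like(mask, peak=9.5))
        assert kept == []
        assert any("noise" in reason for _, reason in rejected)

    def test_diagonal_blobs_are_one_region_under_8_connectivity(self):
        mask = np.zeros((40, 40), bool)
        for i in range(30):
            mask[i, 10 + (i % 2)] = True
        kept, _ = extract_regions(mask, self._spec_like(mask))
        assert len(kept) == 1


class TestRidgeAndMetrics:
    def _region_from(self, samples):
        spec = spectrogram(samples, FS).crop(30e3)
        enh = enhance(spec)
        kept, _ = extract_regions(adaptive_threshold(enh), enh)
        assert kept, "no region extracted from clean tone"
        kept.sort(key=lambda r: -len(r.rows))
        return kept[0], enh

    def test_constant_tone_ridge_within_half_bin(self):
        region, enh = self._region_from(_tone(6000.0))
        contour = ridge_contour(region, enh)
        assert np.all(np.abs(contour.freqs_khz - 6.0) < BIN_HZ / 2 / 1e3)

    def test_upsweep_ridge_monotone(self):
        sweep = synth.make_whistle_waveform(
            synth.WhistleSynthSpec("upsweep", 300.0, (5.0, 9.0)), FS
        )
        region, enh = self._region_from(sweep)
        contour = ridge_contour(region, enh)
        interior = contour.freqs_khz[3:-3]  # window-edge columns excluded
        assert np.all(np.diff(interior) > -0.05)
        assert interior[0] < 5.6 and interior[-1] > 8.4

    def test_measure_constant_contour(self):
        n = 338
        contour = WhistleContour(np.arange(n) * COL_S, np.full(n, 6.0), COL_S)
        m = measure_whistle(contour)
        assert m.bf_khz == m.ef_khz == m.minf_khz == m.maxf_khz == 6.0
        assert m.range_khz == 0.0
        assert m.duration_ms == pytest.approx(300.0, abs=1.0)

    def test_measure_upsweep_contour(self):
        f = np.linspace(5.0, 9.0, 100)
        m = measure_whistle(WhistleContour(np.arange(100) * COL_S, f, COL_S))
        assert (m.bf_khz, m.ef_khz) == (5.0, 9.0)
        assert m.range_khz == pytest.approx(4.0)

    def test_measure_convex_contour_interior_maximum(self):
        f = 5.0 + 3.0 * np.sin(np.linspace(0, np.pi, 101))
        m = measure_whistle(WhistleContour(np.arange(101) * COL_S, f, COL_S))
        assert m.maxf_khz == pytest.approx(8.0)
        assert np.argmax(f) not in (0, 100)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            measure_whistle(WhistleContour(np.array([0.0]), np.array([6.0]), COL_S))


class TestShapeRules:
    def _contour(self, f):
        f = np.asarray(f, float)
        return WhistleContour(np.arange(len(f)) * COL_S, f, COL_S)

    @pytest.mark.parametrize(
        "freqs,expected",
        [
            (np.full(60, 6.0), "constant"),
            (np.full(60, 6.0) + 0.05 * np.sin(np.arange(60)), "constant"),
            (np.linspace(5, 9, 60), "upsweep"),
            (np.linspace(9, 5, 60), "downsweep"),
            (5 + 3 * np.sin(np.linspace(0, np.pi, 61)), "convex"),
            (8 - 3 * np.sin(np.linspace(0, np.pi, 61)), "concave"),
            (6 + 1.5 * np.sin(np.linspace(0, 4 * np.pi, 121)), "sinusoidal"),
        ],
    )
    def test_archetype_rules(self, freqs, expected):
        assert classify_shape(self._contour(freqs)) == expected

    def test_sub_tolerance_wiggle_ignored(self):
        # excursions below δ-hysteresis must not create turning points
        f = np.linspace(5, 9, 80) + 0.1 * np.sin(np.arange(80))
        assert classify_shape(self._contour(f)) == "upsweep"


class TestEndToEnd:
    def test_tone_recovery_in_standard_scene(self, standard_scene_run):
        # the 300 ms, 6 kHz, 20 dB SNR whistle embedded at t = 30 s among
        # clicks, snaps and ambient noise
        segment = standard_scene_run["segment"]
        a = int(29.5 * segment.sample_rate)
        b = int(31.0 * segment.sample_rate)
        crop = AudioSegment(segment.samples[a:b], segment.sample_rate, start_time=29.5)
        found = extract_whistles(crop)
        matches = [w for w in found if abs(float(np.median(w.freqs_khz)) - 6.0) < 0.3]
        assert matches
        best = max(matches, key=lambda w: w.metrics.duration_ms)
        assert best.metrics.duration_ms == pytest.approx(300.0, abs=5.0)
        assert best.metrics.minf_khz == pytest.approx(6.0, abs=0.3)
        assert best.metrics.maxf_khz == pytest.approx(6.0, abs=0.3)
        assert best.shape == "constant"

    def test_transient_equalization_levels_click_stripes(self):
        from sousapam.whistles import equalize_transients

        p = np.full((64, 54), 100.0)
        p[30:32, :] += 25.0  # broadband stripe: a click's two columns
        p[:, 11] += 30.0  # narrowband tone
        out = equalize_transients(Spectrogram(p, FS, 512)).values
        assert np.allclose(out[30:32, 5], 100.0, atol=1e-9)  # stripe leveled
        assert np.allclose(out[:29, 11], 130.0, atol=1e-9)  # tone untouched

    def test_no_output_shorter_than_width_rule(self):
        # applies to every reported whistle, including pure-noise components
        config = synth.SceneConfig(duration_s=0.5, ambient_spl_db=95.0, seed=33)
        segment, _ = synth.render_scene(config)
        for w in extract_whistles(segment):
            assert w.metrics.duration_ms >= (11 - 1) * COL_S * 1e3 - 1e-6

    def test_archetype_identity_rate(self, archetype_run):
        correct = sum(truth == got for truth, got in archetype_run)
        assert correct / len(archetype_run) >= 0.95
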