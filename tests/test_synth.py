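"""Synthetic-scene generator: waveform closed forms, chirp solver, snap
separability, scene rendering and calibration round trips."""

import numpy as np
import pytest

from sousapam import detect, measure, synth
from sousapam.synth import (
    ClickSynthSpec,
    SceneConfig,
    WhistleSynthSpec,
    draw_lognormal,
    draw_truncated_normal,
    gabor_bw3_khz,
    make_click_pulse,
    make_snap,
    make_whistle_waveform,
    render_scene,
    solve_chirp_rate,
)

FS = 576_000.0


class TestClickPulse:
    def test_spectrum_peak_at_carrier(self):
        w = make_click_pulse(ClickSynthSpec(90.0, 5.0, 0.0, 160.0), FS)
        m = measure.measure_click(w, FS)
        assert abs(m.fp_khz - 90.0) < 0.15

    @pytest.mark.parametrize("sigma_us", [3.0, 5.0, 8.0, 12.0])
    def test_gabor_closed_forms(self, sigma_us):
        # carrier at Nyquist/2 keeps the negative-frequency image away from
        # the main spectral lobe, the closed forms' validity domain
        w = make_click_pulse(ClickSynthSpec(144.0, sigma_us, 0.0, 160.0), FS)
        m = measure.measure_click(w, FS)
        assert m.bw3_khz == pytest.approx(gabor_bw3_khz(sigma_us), rel=0.02)
        assert m.duration_us == pytest.approx(2.772 * sigma_us, rel=0.02)

    def test_peak_to_peak_scaling_exact(self):
        w = make_click_pulse(ClickSynthSpec(90.0, 5.0, 0.0, 160.0), FS)
        assert w.max() - w.min() == pytest.approx(10 ** (160 / 20), rel=1e-9)

    def test_instantaneous_frequency_bound_rejected(self):
        # chirp drives IF out of (0, Nyquist) over the ±4σ support
        with pytest.raises(ValueError, match="instantaneous frequency"):
            make_click_pulse(ClickSynthSpec(90.0, 5.0, 10.0, 160.0), FS)
        with pytest.raises(ValueError):
            make_click_pulse(ClickSynthSpec(300.0, 5.0, 0.0, 160.0), FS)


class TestChirpSolver:
    def test_target_at_bound_gives_zero(self):
        assert solve_chirp_rate(gabor_bw3_khz(5.0), 5.0) == 0.0

    def test_inverts_bandwidth_measurement(self):
        c = solve_chirp_rate(70.0, 5.0)
        w = make_click_pulse(ClickSynthSpec(144.0, 5.0, c, 160.0), FS)
        assert measure.measure_click(w, FS).bw3_khz == pytest.approx(70.0, abs=0.7)

    def test_below_bound_error_names_bound(self):
        with pytest.raises(ValueError, match="bound"):
            solve_chirp_rate(gabor_bw3_khz(5.0) * 0.99, 5.0)

    def test_monotone_in_target(self):
        rates = [solve_chirp_rate(t, 5.0) for t in (60.0, 70.0, 75.0)]
        assert rates[0] < rates[1] < rates[2]


class TestWhistleWaveform:
    def test_constant_track_flat(self):
        f = synth._frequency_track(WhistleSynthSpec("constant", 300.0, (6.0,)), 1000)
        assert np.allclose(f, 6000.0)

    def test_upsweep_endpoints_and_monotone(self):
        f = synth._frequency_track(WhistleSynthSpec("upsweep", 300.0, (5.0, 9.0)), 1000)
        assert f[0] == pytest.approx(5000.0) and f[-1] == pytest.approx(9000.0)
        assert np.all(np.diff(f) >= 0)

    def test_concave_interior_minimum(self):
        f = synth._frequency_track(WhistleSynthSpec("concave", 300.0, (8.0, 5.0, 8.0)), 1000)
        k = np.argmin(f)
        assert 0 < k < 999 and f[k] < f[0] and f[k] < f[-1]

    def test_sinusoidal_turning_points(self):
        f = synth._frequency_track(
            WhistleSynthSpec("sinusoidal", 300.0, (6.0, 8.0, 6.0, 8.0)), 2000
        )
        signs = np.sign(np.diff(f))
        reversals = np.sum(np.diff(signs[signs != 0]) != 0)
        assert reversals >= 2

    @pytest.mark.parametrize(
        "shape,anchors",
        [
            ("upsweep", (9.0, 5.0)),
            ("downsweep", (5.0, 9.0)),
            ("concave", (5.0, 8.0, 5.0)),
            ("convex", (8.0, 5.0, 8.0)),
            ("sinusoidal", (6.0, 7.0, 8.0)),
            ("constant", ()),
        ],
    )
    def test_inconsistent_anchors_rejected(self, shape, anchors):
        with pytest.raises(ValueError):
            make_whistle_waveform(WhistleSynthSpec(shape, 300.0, anchors), FS)

    def test_phase_continuity(self):
        # no sample-to-sample jumps beyond the amplitude slew of the carrier
        w = make_whistle_waveform(WhistleSynthSpec("upsweep", 100.0, (5.0, 9.0)), FS)
        assert np.max(np.abs(np.diff(w))) < 2 * np.pi * 9000.0 / FS * 1.1


class TestSnap:
    @pytest.mark.parametrize("tau_us", [3.0, 5.0, 8.0])
    def test_energy_duration_under_15us(self, tau_us):
        snap = make_snap(FS, 160.0, tau_us=tau_us)
        assert measure.measure_click(snap, FS).duration_us < 15.0

    def test_level_scaling_exact(self):
        snap = make_snap(FS, 150.0)
        assert measure.measure_click(snap, FS).spl_pp_db == pytest.approx(150.0, abs=0.1)

    def test_centroid_separates_snaps_from_clicks(self):
        rng = np.random.default_rng(0)
        click_specs = synth.sample_click_specs(rng, 20, chirped=False)
        click_centroids = [
            detect.click_features(make_click_pulse(s, FS), FS)[3] for s in click_specs
        ]
        snap_centroids = [
            detect.click_features(make_snap(FS, 160.0, tau_us=t, center_khz=c), FS)[3]
            for t, c in zip(rng.uniform(3, 8, 20), rng.uniform(180, 250, 20))
        ]
        assert min(snap_centroids) > max(click_centroids)


class TestRenderScene:
    def test_empty_scene_noise_calibration(self):
        config = SceneConfig(duration_s=1.0, ambient_spl_db=90.0, seed=3)
        segment, annotation = render_scene(config)
        assert len(annotation.events) == 0
        rms_db = 20 * np.log10(np.sqrt(np.mean(segment.samples**2)))
        assert rms_db == pytest.approx(90.0, abs=0.5)

    def test_event_bookkeeping(self):
        rng = np.random.default_rng(1)
        clicks = synth.sample_click_specs(
            rng, 10, onsets_s=0.05 + 0.05 * np.arange(10), chirped=False
        )
        _, annotation = render_scene(SceneConfig(duration_s=0.6, clicks=clicks, seed=1))
        assert len(annotation.of_class("click")) == 10
        onsets = [e.onset_s for e in annotation.events]
        assert onsets == sorted(onsets)

    def test_seed_determinism_byte_identical(self):
        config = SceneConfig(
            duration_s=0.5,
            snap_rate_per_s=5.0,
            whistles=[WhistleSynthSpec("constant", 200.0, (6.0,), onset_s=0.1)],
            seed=9,
        )
        a, _ = render_scene(config)
        b, _ = render_scene(config)
        assert a.samples.tobytes() == b.samples.tobytes()

    def test_clipping_error_names_event(self, tmp_path):
        clicks = [ClickSynthSpec(90.0, 5.0, 0.0, spl_pp_db=200.0, onset_s=0.1)]
        config = SceneConfig(duration_s=0.2, clicks=clicks, seed=0)
        with pytest.raises(ValueError, match="click"):
            render_scene(config, out_wav=tmp_path / "x.wav")

    @pytest.mark.parametrize("level_db", [120.0, 150.0, 190.0])
    def test_calibration_round_trip(self, level_db):
        w = make_click_pulse(ClickSynthSpec(90.0, 5.0, 0.0, level_db), FS)
        assert measure.measure_click(w, FS).spl_pp_db == pytest.approx(level_db, abs=0.1)


class TestParameterDraws:
    def test_truncated_normal_moments_and_floor(self):
        x = draw_truncated_normal(np.random.default_rng(0), 86.4, 19.5, 20.0, 4000)
        assert x.min() > 20.0
        assert x.mean() == pytest.approx(86.4, abs=0.5)
        assert x.std(ddof=1) == pytest.approx(19.5, rel=0.05)

    def test_lognormal_moments(self):
        x = draw_lognormal(np.random.default_rng(0), 247.6, 174.2, 4000)
        assert np.all(x > 0)
        assert x.mean() == pytest.approx(247.6, rel=0.02)
        assert x.std(ddof=1) == pytest.approx(174.2, rel=0.1)
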