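"""Generator: anatomy, midline simulation, fluorescence emission, cohorts."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

import wormcycle as wc
from wormcycle.synthgen import resolve_muscle_name, warped_wave

SYMMETRIC_COUNTS = (("DL", 24), ("DR", 24), ("VL", 24), ("VR", 24))


class TestAnatomy:
    def test_default_quadrant_counts(self, anatomy):
        assert anatomy.count("VL") == 23
        assert anatomy.count("VR") == 24
        assert anatomy.count("DL") == 24
        assert anatomy.count("DR") == 24
        assert len(anatomy) == 95

    def test_positions_increase_within_quadrant(self, anatomy):
        for q in ("DL", "DR", "VL", "VR"):
            cells = sorted(anatomy.quadrant(q), key=lambda c: c.index)
            s = [c.s for c in cells]
            assert all(0.0 < v < 1.0 for v in s)
            assert np.all(np.diff(s) > 0)

    def test_count_override(self):
        cfg = wc.SynthConfig(quadrant_counts=(("VL", 1),))
        an = wc.make_anatomy(cfg)
        assert an.count("VL") == 1
        assert an.count("DR") == 24  # unspecified quadrants keep the default

    @pytest.mark.parametrize(
        "name,expected",
        [
            ("vm21", "VL21"),
            ("vm24", "VR24"),  # VL has no 24th cell; most posterior ventral
            ("dm21", "DL21"),
            ("VR05", "VR05"),
        ],
    )
    def test_name_resolution(self, anatomy, name, expected):
        assert anatomy[name].name == expected

    def test_vm24_is_most_posterior_ventral(self, anatomy):
        ventral = anatomy.quadrant("VL") + anatomy.quadrant("VR")
        assert anatomy["vm24"].s == max(c.s for c in ventral)

    def test_bad_names_rejected(self):
        with pytest.raises(ValueError):
            resolve_muscle_name("vm")
        with pytest.raises(ValueError):
            resolve_muscle_name("xq3")


class TestWarpedWave:
    def test_extrema_and_lobes(self):
        phi = np.linspace(0, 1, 2001, endpoint=False)
        w = warped_wave(phi, f_dorsal=0.4, gain_dorsal=0.5, gain_ventral=1.0)
        assert w[0] == pytest.approx(0.5)  # dorsal max, scaled by a_d
        assert w.min() == pytest.approx(-1.0, abs=1e-4)  # ventral lobe, a_v
        # ventral extreme at phase 1 - f_D
        assert phi[np.argmin(w)] == pytest.approx(0.6, abs=1e-3)

    def test_lobe_scaling_biases_the_mean_ventrally(self):
        # brute-force integral of the lobe-scaled wave
        phi = (np.arange(200000) + 0.5) / 200000
        w = warped_wave(phi, 0.5, gain_dorsal=0.5, gain_ventral=1.0)
        assert w.mean() < -0.05

    def test_symmetric_wave_is_plain_cosine(self):
        phi = np.linspace(0, 1, 50, endpoint=False)
        np.testing.assert_allclose(
            warped_wave(phi), np.cos(2 * np.pi * phi), atol=1e-12
        )


class TestSimulateMidline:
    def test_zero_amplitude_gives_collinear_midline(self):
        cfg = wc.SynthConfig(amplitude=0.0, noise_sd=0.0)
        track, truth = wc.simulate_midline(cfg)
        assert np.all(truth.bend_ref == 0.0)
        bend = wc.bend_angle(track, -1, 0, cfg.hinge_index)
        np.testing.assert_allclose(bend.values, 0.0, atol=1e-9)

    def test_reference_bend_amplitude_matches_closed_form(self):
        cfg = wc.SynthConfig(noise_sd=0.0)
        _, truth = wc.simulate_midline(cfg)
        # oracle: the warped wave evaluated on the frame grid
        expected = cfg.amplitude * warped_wave(cfg.times / cfg.period)
        np.testing.assert_allclose(truth.bend_ref, expected, atol=1e-12)
        assert np.max(np.abs(truth.bend_ref)) == pytest.approx(45.0, abs=1e-9)

    def test_ventral_lobe_gain_biases_mean_bend(self):
        cfg = wc.SynthConfig(gain_dorsal=0.5, gain_ventral=1.0, noise_sd=0.0)
        _, truth = wc.simulate_midline(cfg)
        assert truth.bend_ref.mean() < 0.0

    def test_arc_length_constant(self):
        cfg = wc.SynthConfig(noise_sd=0.0)
        track, _ = wc.simulate_midline(cfg)
        np.testing.assert_allclose(
            track.arc_length(), cfg.um_per_body_length,
            atol=1e-6 * cfg.um_per_body_length,
        )

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError):
            wc.SynthConfig(n_points=2)

    def test_seed_determinism_bitwise(self, anatomy):
        cfg = wc.SynthConfig(seed=7, duration=4.0)
        outs = []
        for _ in range(2):
            track, truth = wc.simulate_midline(cfg)
            traces = wc.emit_fluorescence(truth, anatomy, cfg)
            outs.append((track.coords.copy(), traces.traces["DL21"].copy(),
                         traces.background.copy()))
        for x, y in zip(*outs):
            assert np.array_equal(x, y)


class TestEmitFluorescence:
    def test_emission_bounds_noise_free(self, swim_recording, anatomy):
        cfg, _, truth, traces = swim_recording
        for model in ("swim_coactive", "crawl_antiphase"):
            c = cfg.replace(emission_model=model)
            _, tr = wc.simulate_midline(c)
            ts = wc.emit_fluorescence(tr, anatomy, c)
            for name, f in ts.traces.items():
                assert np.all(f >= cfg.baseline - 1e-9)
                assert np.all(f <= cfg.baseline + cfg.gain + 1e-9)

    def test_swim_trace_hits_baseline_at_own_bend_extremum(
        self, swim_recording
    ):
        _, _, _, traces = swim_recording
        cfg = swim_recording[0]
        for f in traces.traces.values():
            # at the trace's own bend extremum 1 - |kappa|/khat == 0 exactly
            assert f.min() == pytest.approx(cfg.baseline, abs=1e-9)

    def test_crawl_opposite_side_clamped_to_baseline(self, anatomy):
        cfg = wc.SynthConfig(noise_sd=0.0, emission_model="crawl_antiphase",
                             hinge_s=anatomy["dm21"].s)
        _, truth = wc.simulate_midline(cfg)
        traces = wc.emit_fluorescence(truth, anatomy, cfg)
        # at peak ventral bend of the reference point, the colocated dorsal
        # muscle is silent
        frame = int(np.argmin(truth.bend_ref))
        assert traces.traces["DL21"][frame] == pytest.approx(cfg.baseline, abs=1e-9)

    def test_crawl_dorsal_peaks_at_dorsal_extremum(self, anatomy):
        cfg = wc.SynthConfig(noise_sd=0.0, emission_model="crawl_antiphase",
                             hinge_s=anatomy["dm21"].s)
        _, truth = wc.simulate_midline(cfg)
        traces = wc.emit_fluorescence(truth, anatomy, cfg)
        f = traces.traces["DL21"]
        peak_frames = np.flatnonzero(f == f.max())
        true_maxima = np.flatnonzero(truth.bend_ref == truth.bend_ref.max())
        assert set(peak_frames) == set(true_maxima)

    def test_swim_traces_minimal_at_dorsal_extremum(self, swim_recording):
        cfg, _, truth, traces = swim_recording
        f = traces.traces["DL21"]  # colocated with the reference vertex
        frame = int(np.argmax(truth.bend_ref))
        assert f[frame] == pytest.approx(f.min(), abs=1e-9)

    def test_gain_ratio_of_identical_waveforms(self):
        # symmetric anatomy + on-grid wavelength: vm21/vm24 waveforms are
        # circular shifts on the frame grid over 8 exact periods
        cfg = wc.SynthConfig(
            noise_sd=0.0, baseline=0.0, duration=16.0, wavelength=1.25,
            quadrant_counts=SYMMETRIC_COUNTS,
            gain_overrides=(("VL21", 40.0), ("VL24", 100.0)),
        )
        an = wc.make_anatomy(cfg)
        _, truth = wc.simulate_midline(cfg)
        traces = wc.emit_fluorescence(truth, an, cfg)
        ratio = traces.traces["VL21"].mean() / traces.traces["VL24"].mean()
        assert ratio == pytest.approx(0.4, abs=1e-9)

    def test_degenerate_bend_raises(self, anatomy):
        cfg = wc.SynthConfig(amplitude=0.0, noise_sd=0.0)
        _, truth = wc.simulate_midline(cfg)
        with pytest.raises(ValueError, match="degenerate bend"):
            wc.emit_fluorescence(truth, anatomy, cfg)

    def test_bleaching_decays_signal(self, anatomy):
        cfg = wc.SynthConfig(noise_sd=0.0, bleach_tau=5.0)
        _, truth = wc.simulate_midline(cfg)
        traces = wc.emit_fluorescence(truth, anatomy, cfg)
        f = traces.traces["DL01"]
        assert f[: len(f) // 2].max() > f[len(f) // 2 :].max()


class TestRenderFrames:
    def test_constant_trace_round_trip(self, anatomy):
        cfg = wc.SynthConfig(noise_sd=0.0, duration=2.0, n_points=17,
                             amplitude=0.0, um_per_body_length=300,
                             translation_speed=0.0)
        track, _ = wc.simulate_midline(cfg)
        c = 7.5
        n = track.n_frames
        sub = wc.RoiTraceSet(
            {"DL12": np.full(n, c)}, np.zeros(n), cfg.fps
        )
        cfg0 = cfg.replace(background_level=0.0)
        stack, masks, _ = wc.render_frames(track, sub, anatomy, cfg0,
                                           um_per_px=5.0)
        rec = wc.roi_intensity(stack, masks["DL12"])
        # oracle: direct summation of the rendered Gaussian over the disk
        blob_mean = rec[0] / c
        np.testing.assert_allclose(rec, c * blob_mean, rtol=1e-9)
        assert 0.1 < blob_mean < 1.0
        # moving worm: readout still tracks the trace to discretization error
        cfg_m = cfg.replace(amplitude=45.0)
        track_m, _ = wc.simulate_midline(cfg_m)
        stack_m, masks_m, _ = wc.render_frames(
            track_m, sub, anatomy, cfg0.replace(amplitude=45.0), um_per_px=5.0
        )
        rec_m = wc.roi_intensity(stack_m, masks_m["DL12"])
        np.testing.assert_allclose(rec_m, c * blob_mean, rtol=0.05)

    def test_zero_traces_give_background(self, anatomy):
        cfg = wc.SynthConfig(noise_sd=0.0, duration=1.0, n_points=17,
                             um_per_body_length=300, translation_speed=0.0)
        track, _ = wc.simulate_midline(cfg)
        n = track.n_frames
        sub = wc.RoiTraceSet({"DL12": np.zeros(n)}, np.zeros(n), cfg.fps)
        stack, masks, bg = wc.render_frames(track, sub, anatomy, cfg,
                                            um_per_px=5.0)
        np.testing.assert_allclose(
            wc.roi_intensity(stack, masks["DL12"]), cfg.background_level,
            atol=1e-9,
        )
        np.testing.assert_allclose(
            wc.roi_intensity(stack, bg), cfg.background_level, atol=1e-9
        )

    def test_image_too_small_raises(self, anatomy):
        cfg = wc.SynthConfig(noise_sd=0.0, duration=1.0, n_points=17)
        track, truth = wc.simulate_midline(cfg)
        traces = wc.emit_fluorescence(truth, anatomy, cfg)
        with pytest.raises(ValueError, match="too small"):
            wc.render_frames(track, traces, anatomy, cfg, um_per_px=10.0,
                             image_shape=(16, 16))

    def test_image_pipeline_matches_trace_pipeline(self, anatomy):
        """peak_phase from rendered images equals the trace-level result."""
        cfg = wc.SynthConfig(noise_sd=0.0, duration=8.0, n_points=17,
                             um_per_body_length=300, translation_speed=0.0,
                             hinge_s=anatomy["dm21"].s)
        track, truth = wc.simulate_midline(cfg)
        traces = wc.emit_fluorescence(truth, anatomy, cfg)
        sub = wc.RoiTraceSet({"DL21": traces.traces["DL21"]},
                             traces.background, cfg.fps)
        stack, masks, bg = wc.render_frames(track, sub, anatomy, cfg,
                                            um_per_px=3.0)
        bend = wc.bend_angle(track, -1, 0, cfg.hinge_index)
        cycles = wc.detect_cycles(bend)
        rec = wc.roi_intensity(stack, masks["DL21"])
        bg_trace = np.full_like(rec, cfg.background_level)
        m_img = wc.time_normalize_cycles(
            wc.normalize_background(rec, bg_trace), cycles
        )
        m_tr = wc.time_normalize_cycles(
            wc.normalize_background(
                traces.traces["DL21"],
                np.full_like(rec, cfg.background_level),
            ),
            cycles,
        )
        np.testing.assert_array_equal(wc.peak_phase(m_img), wc.peak_phase(m_tr))


class TestSimulateCohort:
    def test_byte_identical_reruns(self, tmp_path):
        cfg = wc.SynthConfig(duration=3.0, seed=5)
        digests = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            wc.simulate_cohort(cfg, 3, d)
            digests.append(
                {
                    p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(d.iterdir())
                }
            )
        assert digests[0] == digests[1]

    def test_manifest_records_overrides(self, tmp_path):
        cfg = wc.SynthConfig(duration=3.0)
        m1 = wc.simulate_cohort(cfg, 1, tmp_path / "c1",
                                overrides={"gain_overrides": (("vm21", 100.0),)})
        m2 = wc.simulate_cohort(cfg, 1, tmp_path / "c2",
                                overrides={"gain_overrides": (("vm21", 40.0),)})
        assert m1["config"]["gain_overrides"] != m2["config"]["gain_overrides"]
        assert m1["config_hash"] != m2["config_hash"]

    def test_frame_count_matches_fps_times_duration(self, tmp_path):
        import pandas as pd

        cfg = wc.SynthConfig(duration=17.0, fps=10.0)
        m = wc.simulate_cohort(cfg, 2, tmp_path)
        for entry in m["animals"]:
            df = pd.read_csv(tmp_path / entry["files"]["traces"])
            assert df["frame"].nunique() == 170

    def test_rejects_empty_cohort(self, tmp_path):
        with pytest.raises(ValueError):
            wc.simulate_cohort(wc.SynthConfig(), 0, tmp_path)
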