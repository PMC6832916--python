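"""Dipole simulator: waveform, field geometry, records, studies."""

import numpy as np
import pytest

from lans_ecg.simulate import (
    DEFAULT_TEMPLATE,
    DipoleSource,
    NoiseModel,
    SimConfig,
    WaveComponent,
    beat_waveform,
    lead_voltage,
    plant_source,
    planted_best_lead,
    simulate_square,
    simulate_study,
    square_lead_gains,
    template_qrs_span,
)

SILENT = NoiseModel(baseline=(), white_sd=0.0, powerline_amp=0.0)


class TestBeatWaveform:
    def test_zero_amplitudes_give_zero(self):
        template = [WaveComponent(w.label, 0.0, w.center, w.width) for w in DEFAULT_TEMPLATE]
        t = np.linspace(-0.4, 0.4, 200)
        assert np.all(beat_waveform(t, template) == 0)

    def test_single_gaussian_peaks_at_its_center(self):
        template = [WaveComponent("R", 1.0, 0.0, 0.012)]
        assert beat_waveform(0.0, template) == pytest.approx(1.0)

    def test_default_template_peaks_at_r_center(self):
        t = np.linspace(-0.4, 0.4, 8001)
        m = beat_waveform(t)
        assert abs(t[np.argmax(m)]) < 2e-3


class TestLeadVoltage:
    SOURCE = DipoleSource(origin=(0.0, 0.0, 5.0), axis=(1.0, 0.0, 0.0))

    def test_symmetric_electrodes_give_zero(self):
        # both electrodes on the plane normal to the axis through the origin
        v = lead_voltage(self.SOURCE, (0.0, 2.0, 0.0), (0.0, -2.0, 0.0), 0.0)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_voltage_is_linear_in_moment(self):
        a, b = (3.0, 1.0, 0.0), (-2.0, 0.5, 0.0)
        v1 = lead_voltage(self.SOURCE, a, b, 0.01)
        doubled = DipoleSource(origin=self.SOURCE.origin, axis=self.SOURCE.axis, moment_scale=2.0)
        assert lead_voltage(doubled, a, b, 0.01) == pytest.approx(2 * v1)

    def test_electrode_at_origin_rejected(self):
        with pytest.raises(ValueError):
            lead_voltage(self.SOURCE, (0.0, 0.0, 5.0), (1.0, 0.0, 0.0), 0.0)

    def test_aligned_diagonal_dominates_counter_diagonal(self, grid):
        src = plant_source(grid, "front", 13)
        gains = np.abs(square_lead_gains(grid, "front", 13, src))
        assert gains[4] > gains[5]  # channel 5 (principal) vs 6 (counter)
        assert gains[4] == np.max(gains)


class TestSimulateSquare:
    def test_zero_noise_record_equals_clean(self, grid, source):
        rec, truth = simulate_square(grid, "front", 13, source, noise=SILENT, rng=3)
        assert np.array_equal(rec.data, truth.clean)
        assert np.all(truth.noise == 0)

    def test_same_seed_reproduces_record(self, grid, source):
        r1, _ = simulate_square(grid, "front", 13, source, rng=42)
        r2, _ = simulate_square(grid, "front", 13, source, rng=42)
        assert np.array_equal(r1.data, r2.data)

    def test_beat_count_at_75_bpm(self, grid, source):
        cfg = SimConfig(duration=60.0, heart_rate=75.0, rr_jitter=0.0)
        _, truth = simulate_square(grid, "front", 13, source, config=cfg, rng=0)
        assert len(truth.r_indices) == 75

    def test_decomposition_is_exact(self, grid, source, sim_record):
        rec, truth = sim_record
        assert np.array_equal(truth.clean + truth.noise, rec.data)

    def test_record_shape_and_rate(self, grid, source, sim_record):
        rec, _ = sim_record
        assert rec.data.shape == (12000, 6)
        assert rec.fs == 200.0


class TestGroundTruthGeometry:
    def test_planted_channel_hits_target_amplitude(self, grid, source):
        span = template_qrs_span()
        amps = np.abs(square_lead_gains(grid, "front", 13, source)) * span
        assert amps[4] == pytest.approx(1.0, rel=1e-9)

    def test_amplitude_decays_along_a_row(self, grid, source):
        span = template_qrs_span()
        amp = {
            i: (np.abs(square_lead_gains(grid, "front", i, source)) * span)[4]
            for i in (11, 12, 13, 14, 15)
        }
        assert amp[13] >= amp[14] >= amp[15]
        assert amp[13] >= amp[12] >= amp[11]

    def test_back_side_is_strongly_attenuated(self, grid, source):
        span = template_qrs_span()
        front = (np.abs(square_lead_gains(grid, "front", 13, source)) * span).max()
        back = (np.abs(square_lead_gains(grid, "back", 13, source)) * span).max()
        assert back < 0.1 * front

    def test_planted_best_lead_is_the_planted_channel(self, grid, source):
        squares = [("front", i) for i in range(1, 26)]
        assert planted_best_lead(grid, squares, source) == ("front", 13, 5)

    def test_orientation_maximum_follows_the_axis(self, grid):
        # axis along the top horizontal channel of square 13
        src = plant_source(grid, "front", 13, channel=1)
        gains = np.abs(square_lead_gains(grid, "front", 13, src))
        horiz = max(gains[0], gains[1])
        assert horiz == np.max(gains)


class TestSimulateStudy:
    def test_single_subject_single_square(self, grid, source, short_config):
        study = simulate_study(grid, [("front", 13)], 1, source, config=short_config, seed=0)
        assert len(study.records) == 1
        assert study.records[(0, "front", 13)].n_channels == 6

    def test_record_and_trace_counting(self, grid, source):
        cfg = SimConfig(duration=4.0)
        squares = [("front", i) for i in (1, 3, 5, 7, 8, 9, 11, 12, 13, 14, 15, 17, 18, 19, 21, 23, 25)]
        study = simulate_study(grid, squares, 19, source, config=cfg, seed=0)
        assert len(study.records) == 19 * 17 == 323
        assert sum(r.n_channels for r in study.records.values()) == 1938

    def test_planted_best_channel_recorded(self, grid, source, short_config):
        study = simulate_study(grid, [("front", 13), ("front", 9)], 2, source,
                               config=short_config, seed=1)
        assert study.planted_best == ("front", 13, 5)
        assert study.planted_pair == (21, 28)

    def test_results_do_not_depend_on_square_order(self, grid, source, short_config):
        squares = [("front", 13), ("front", 9), ("front", 1)]
        a = simulate_study(grid, squares, 2, source, config=short_config, seed=5)
        b = simulate_study(grid, squares[::-1], 2, source, config=short_config, seed=5)
        for key in a.records:
            assert np.array_equal(a.records[key].data, b.records[key].data)

    def test_invalid_subject_count(self, grid, source, short_config):
        with pytest.raises(ValueError):
            simulate_study(grid, [("front", 1)], 0, source, config=short_config, seed=0)


class TestValidation:
    def test_axis_must_be_unit_norm(self):
        with pytest.raises(ValueError):
            DipoleSource(origin=(0, 0, 5), axis=(1.0, 1.0, 0.0))

    def test_baseline_frequency_bounds(self):
        with pytest.raises(ValueError):
            NoiseModel(baseline=((0.1, 0.7),))

    def test_duration_must_cover_two_beats(self):
        with pytest.raises(ValueError):
            SimConfig(duration=1.0, heart_rate=60.0)
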