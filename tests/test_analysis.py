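"""ROM extraction, asymmetry, compensations, summaries, session comparison."""

import numpy as np
import pytest

import cervitrack as ct
from cervitrack.analysis import SignConventionWarning


def run_rig(plane, angle):
    stream, gt = ct.simulate_rig_trial(ct.RigTrialSpec(plane=plane, angle_deg=angle))
    result = ct.analyze_stream(stream)
    return result, gt


class TestComputeRom:
    def test_flexion_rig_trial_reads_plus_34(self):
        result, gt = run_rig("flexion_extension", 34.0)
        (ep,) = result.bundle.episodes
        assert ep.rom.rom_signed_deg == pytest.approx(34.0, abs=1e-6)
        assert round(ep.rom.rom_signed_deg) == gt.goniometer_reading_deg

    def test_left_rotation_is_negative(self):
        result, _ = run_rig("rotation", -40.0)
        (ep,) = result.bundle.episodes
        assert ep.rom.label == "left_rotation"
        assert ep.rom.rom_signed_deg == pytest.approx(-40.0, abs=1e-6)

    def test_duration_is_window_length(self, clean_analysis):
        result, _ = clean_analysis
        for ep, rep in zip(result.episodes, result.bundle.episodes):
            assert rep.rom.duration_s == pytest.approx(ep.end_s - ep.start_s)

    def test_empty_window_is_an_error(self, clean_analysis):
        result, _ = clean_analysis
        from cervitrack.segmentation import MovementEpisode

        bogus = MovementEpisode(
            label="flexion", start_s=1e6, end_s=1e6 + 1,
            primary_channel="flexion_extension",
            peak_signed_deg=1.0, peak_time_s=1e6 + 0.5,
        )
        with pytest.raises(ValueError, match="empty"):
            ct.compute_rom(bogus, result.series)

    def test_noise_free_recovery_matches_ground_truth(self, clean_analysis):
        result, gt = clean_analysis
        got = {e.rom.label: e.rom.rom_signed_deg for e in result.bundle.episodes}
        for true in gt.episodes:
            assert got[true.label] == pytest.approx(true.peak_signed_deg, abs=0.01)


class TestDurationAsymmetry:
    def test_identical_mirrored_pair_is_zero(self):
        left = ct.RomResult("left_rotation", -60.0, 4.0)
        right = ct.RomResult("right_rotation", 60.0, 4.0)
        assert ct.duration_asymmetry(left, right) == (0.0, 0.0)

    def test_rom_magnitude_difference(self):
        left = ct.RomResult("left_rotation", -45.0, 4.0)
        right = ct.RomResult("right_rotation", 40.0, 4.0)
        _, rom_diff = ct.duration_asymmetry(left, right)
        assert rom_diff == pytest.approx(5.0)

    def test_asymmetric_rise_times_show_in_duration(self):
        # left rotation rises in 1.0 s, right in 1.4 s with equal peaks: the
        # episode duration difference approaches -0.8 s (rise + return)
        cfg = ct.default_protocol(seed=5, noise_sd_deg=0.0)
        for m in cfg.movements:
            if m.label == "left_rotation":
                m.rise_s = 1.0
            if m.label == "right_rotation":
                m.rise_s = 1.4
        stream, _ = ct.simulate_protocol(cfg)
        result = ct.analyze_stream(stream)
        roms = {e.rom.label: e.rom for e in result.bundle.episodes}
        ddiff, rdiff = ct.duration_asymmetry(
            roms["left_rotation"], roms["right_rotation"]
        )
        assert ddiff == pytest.approx(-0.8, abs=0.25)
        assert abs(rdiff) < 0.5

    def test_mismatched_plane_is_an_error(self):
        with pytest.raises(ValueError):
            ct.duration_asymmetry(
                ct.RomResult("flexion", 40.0, 3.0),
                ct.RomResult("left_rotation", -60.0, 4.0),
            )


class TestDetectCompensations:
    def test_pure_rig_trial_has_zero_offplane_and_no_flags(self):
        result, _ = run_rig("rotation", 45.0)
        (ep,) = result.bundle.episodes
        for peak, _ratio in ep.compensation.off_plane.values():
            assert peak == pytest.approx(0.0, abs=1e-9)
        assert ep.compensation.flags == []

    @pytest.mark.parametrize("c", [0.1, 0.2, 0.3])
    def test_injected_coupling_ratio_recovered(self, c):
        # left lateral flexion with a left-rotation co-movement: rotation
        # channel receives -c times the (positive) primary profile
        cfg = ct.default_protocol(
            seed=13, noise_sd_deg=0.5,
            couplings={"left_lateral": {"rotation": -c}},
        )
        stream, gt = ct.simulate_protocol(cfg)
        result = ct.analyze_stream(stream)
        ep = next(e for e in result.bundle.episodes if e.rom.label == "left_lateral")
        peak, ratio = ep.compensation.off_plane["rotation"]
        true_primary = next(
            g.peak_signed_deg for g in gt.episodes if g.label == "left_lateral"
        )
        assert ratio == pytest.approx(-c, abs=0.05)
        assert peak == pytest.approx(-c * true_primary, abs=1.0)
        if c * abs(true_primary) > 5.0:
            assert "co_movement:rotation" in ep.compensation.flags

    def test_norm_exceedance_flag(self, clean_analysis):
        result, _ = clean_analysis
        norms = ct.NormativeRanges({"flexion": 40.0})  # default peak is 45
        ep = result.episodes[0]
        report = ct.detect_compensations(ep, result.series, norms=norms)
        assert "norm_exceeded" in report.flags

    def test_norm_limits_must_be_positive(self):
        with pytest.raises(ValueError):
            ct.NormativeRanges({"flexion": -10.0})


class TestSummaries:
    def r(self, label, rom, dur=3.0):
        return ct.RomResult(label, rom, dur)

    def test_single_session_min_equals_max_equals_mean(self):
        s = ct.summarize_sessions([[self.r("flexion", 42.0)]])
        stats = s.movements["flexion"]
        assert stats.min_deg == stats.max_deg == stats.mean_deg == 42.0

    def test_three_session_aggregation(self):
        sessions = [[self.r("flexion", v)] for v in (30.0, 40.0, 50.0)]
        stats = ct.summarize_sessions(sessions).movements["flexion"]
        assert (stats.min_deg, stats.max_deg, stats.mean_deg) == (30.0, 50.0, 40.0)

    def test_mixed_sign_input_warns(self):
        sessions = [[self.r("flexion", 30.0)], [self.r("flexion", -30.0)]]
        with pytest.warns(SignConventionWarning):
            ct.summarize_sessions(sessions)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            ct.summarize_sessions([])

    def test_concatenated_aggregation_matches_direct(self):
        # summary of all sessions equals aggregation over the pooled results
        rng = np.random.default_rng(0)
        sessions = [
            [self.r("flexion", 40 + rng.normal(0, 3), 3 + rng.random())]
            for _ in range(5)
        ]
        pooled = [r for sess in sessions for r in sess]
        a = ct.summarize_sessions(sessions).movements["flexion"]
        roms = [r.rom_signed_deg for r in pooled]
        assert a.min_deg == pytest.approx(min(roms))
        assert a.max_deg == pytest.approx(max(roms))
        assert a.mean_deg == pytest.approx(np.mean(roms))

    def test_compare_identical_summaries_is_all_zero(self):
        s = ct.summarize_sessions([[self.r("flexion", 34.0)]])
        deltas = ct.compare_sessions(s, s)
        assert deltas["flexion"].rom_delta_deg == 0.0
        assert deltas["flexion"].duration_delta_s == 0.0

    def test_compare_reports_signed_change(self):
        a = ct.summarize_sessions([[self.r("flexion", 34.0)]])
        b = ct.summarize_sessions([[self.r("flexion", 40.0)]])
        assert ct.compare_sessions(a, b)["flexion"].rom_delta_deg == pytest.approx(6.0)

    def test_compare_movement_mismatch_is_an_error(self):
        a = ct.summarize_sessions([[self.r("flexion", 34.0)]])
        b = ct.summarize_sessions([[self.r("extension", -40.0)]])
        with pytest.raises(ValueError, match="differ"):
            ct.compare_sessions(a, b)
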