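"""Synthetic-data generator: pulse shapes, recordings, calibrations, cohorts."""

import numpy as np
import pytest
from scipy.stats import norm

from conftest import dense_grid_morphology
from icpw import simulate as sim
from icpw.diagnostics import confusion_at_cutoff, empirical_auc, pearson_r
from icpw.errors import CalibrationInfeasibleError, InvalidParameterError
from icpw.morphology import METHOD_TWO_PEAKS


class TestSimulatePulse:
    def test_single_component_degenerates_to_sub_unity_ratio(self):
        shape = sim.PulseShapeParams(
            amp1=1.0, amp2=0.0, amp3=0.0, lat1=0.12, lat2=0.30, lat3=0.55,
            width1=0.05, width2=0.09, width3=0.10, pulse_duration=0.8,
        )
        samples, morph = sim.simulate_pulse(shape, fs_hz=200)
        assert morph.p2p1 < 1
        assert morph.method != METHOD_TWO_PEAKS  # no tidal local maximum
        assert morph.p1_lat == pytest.approx(0.12, abs=0.01)
        assert len(samples) == round(200 * 0.8)

    def test_equal_components_give_unit_ratio(self):
        shape = sim.PulseShapeParams(
            amp1=1.0, amp2=1.0, amp3=0.0, lat1=0.15, lat2=0.45, lat3=0.7,
            width1=0.05, width2=0.05, width3=0.1,
        )
        _, morph = sim.simulate_pulse(shape, fs_hz=200)
        oracle = dense_grid_morphology(shape)
        assert morph.p2p1 == pytest.approx(1.0, abs=0.02)
        assert morph.p2p1 == pytest.approx(oracle["p2p1"], abs=1e-3)

    def test_three_component_shape_matches_grid_oracle(self):
        shape = sim.PulseShapeParams(
            amp1=1.0, amp2=1.3, amp3=0.6, lat1=0.12, lat2=0.30, lat3=0.55,
            width1=0.05, width2=0.09, width3=0.10, pulse_duration=0.8,
        )
        _, morph = sim.simulate_pulse(shape, fs_hz=500)
        oracle = dense_grid_morphology(shape)
        assert morph.p2p1 > 1
        assert morph.p2p1 == pytest.approx(oracle["p2p1"], abs=0.03)

    def test_non_increasing_latencies_rejected(self):
        with pytest.raises(InvalidParameterError):
            sim.PulseShapeParams(lat1=0.4, lat2=0.3, lat3=0.7)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            sim.simulate_pulse(sim.PulseShapeParams(pulse_duration=0.05), fs_hz=100)

    def test_shape_with_ratio_hits_target(self):
        for target in (0.9, 1.15, 1.3):
            shape = sim.shape_with_ratio(target)
            assert sim.achieved_morphology(shape).p2p1 == pytest.approx(target, abs=1e-3)


class TestSimulateRecording:
    def test_zero_jitter_beat_count_is_floor_of_duration_over_period(self):
        params = sim.SessionSimParams(
            heart_rate_bpm=72, hr_jitter_frac=0.0, duration_s=600, seed=1
        )
        _, gt = sim.simulate_recording(params)
        assert len(gt.onsets) == 720  # floor(600 / (60/72))

    def test_same_seed_bit_identical(self):
        params = sim.SessionSimParams(duration_s=60, seed=42)
        rec1, gt1 = sim.simulate_recording(params)
        rec2, gt2 = sim.simulate_recording(params)
        assert np.array_equal(rec1.samples, rec2.samples)
        assert np.array_equal(rec1.icp_samples, rec2.icp_samples)
        assert np.array_equal(gt1.onsets, gt2.onsets)
        assert gt1.artifact_windows == gt2.artifact_windows

    def test_ten_minute_session_has_at_least_700_beats(self):
        # 70 bpm floor of the study protocol, and the package default (72 bpm)
        _, gt_70 = sim.simulate_recording(
            sim.SessionSimParams(heart_rate_bpm=70, hr_jitter_frac=0.0, seed=0)
        )
        assert len(gt_70.onsets) == 700
        _, gt_def = sim.simulate_recording(sim.SessionSimParams(seed=0))
        assert len(gt_def.onsets) >= 700

    def test_duration_too_short_for_one_beat_rejected(self):
        with pytest.raises(InvalidParameterError):
            sim.SessionSimParams(heart_rate_bpm=30, duration_s=1.0)

    def test_icp_channel_tracks_true_mean(self):
        rec, gt = sim.simulate_recording(sim.SessionSimParams(duration_s=120, seed=9))
        assert rec.icp_samples.mean() == pytest.approx(gt.true_micp, abs=0.3)

    def test_artifact_windows_are_recorded_and_visible(self):
        params = sim.SessionSimParams(
            duration_s=120, artifact_rate_per_min=3.0, seed=5
        )
        rec, gt = sim.simulate_recording(params)
        assert len(gt.artifact_windows) > 0
        s, e = gt.artifact_windows[0]
        w = slice(int(s * rec.fs_hz), int(e * rec.fs_hz))
        # the transient dwarfs the physiologic amplitude
        assert rec.samples[w].max() > 2 * np.percentile(rec.samples, 99)


class TestCalibrateBinormal:
    def test_round_trip_on_equal_sd_pair(self):
        mu_neg, mu_pos, sd = 1.0, 1.5, 0.15
        cutoff = 1.2
        sens = float(norm.cdf((mu_pos - cutoff) / sd))
        spec = float(norm.cdf((cutoff - mu_neg) / sd))
        auc = float(norm.cdf((mu_pos - mu_neg) / (sd * np.sqrt(2))))
        p = sim.calibrate_binormal(auc, sens, spec, cutoff, sd_neg=sd)
        assert p.mu_neg == pytest.approx(mu_neg, abs=1e-6)
        assert p.mu_pos == pytest.approx(mu_pos, abs=1e-6)
        assert p.sd_pos == pytest.approx(sd, abs=1e-6)

    def test_default_calibration_solves_stated_system(self):
        p = sim.calibrate_binormal()
        # verify the three equations directly (independent of the solver)
        assert norm.sf((1.2 - p.mu_pos) / p.sd_pos) == pytest.approx(0.85, abs=1e-9)
        assert norm.cdf((1.2 - p.mu_neg) / p.sd_neg) == pytest.approx(0.77, abs=1e-9)
        assert p.auc == pytest.approx(0.88, abs=1e-9)
        # solution values cross-checked with an independent root-finder
        assert p.mu_neg == pytest.approx(1.089, abs=0.002)
        assert p.mu_pos == pytest.approx(1.88, abs=0.02)
        assert p.sd_pos == pytest.approx(0.656, abs=0.02)

    def test_boundary_auc_rejected(self):
        with pytest.raises(CalibrationInfeasibleError):
            sim.calibrate_binormal(target_auc=0.5)

    def test_calibration_closure_at_large_n(self):
        p = sim.calibrate_binormal()
        scores, labels = sim.draw_binormal_scores(p, 100_000, 0.18, seed=123)
        assert empirical_auc(scores, labels).auc == pytest.approx(0.88, abs=0.01)
        perf = confusion_at_cutoff(scores, labels, 1.2)
        assert perf.sensitivity == pytest.approx(0.85, abs=0.01)
        assert perf.specificity == pytest.approx(0.77, abs=0.01)


class TestSimulateCohort:
    def test_noiseless_link_is_perfectly_correlated(self):
        df, _ = sim.simulate_cohort(
            sim.CohortSimParams(n_patients=500, link_noise_sd=0.0, seed=3)
        )
        r, _ = pearson_r(df["micp"], df["p2p1_untruncated"])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_micp_quartiles_match_targets(self):
        df, _ = sim.simulate_cohort(sim.CohortSimParams(n_patients=2000, seed=11))
        q1, med, q3 = np.percentile(df["micp"], [25, 50, 75])
        assert med == pytest.approx(14.0, abs=1.0)
        assert q1 == pytest.approx(11.0, abs=1.5)
        assert q3 == pytest.approx(19.0, abs=1.5)

    def test_derived_residual_sd_reproduces_target_correlation(self):
        # solve the correlation identity, then confirm by simulation at n = 1e5
        mu, sigma = sim.fit_lognormal_quartiles(14.0, 11.0, 19.0)
        sigma_micp = sim.lognormal_sd(mu, sigma)
        sigma_e = sim.derive_link_noise_sd(0.02, sigma_micp, 0.49)
        assert 0.19 < sigma_e < 0.26
        rng = np.random.default_rng(7)
        micp = rng.lognormal(mu, sigma, 100_000)
        ratio = 0.82 + 0.02 * micp + rng.normal(0, sigma_e, micp.size)
        r = np.corrcoef(micp, ratio)[0, 1]
        assert r == pytest.approx(0.49, abs=0.01)

    def test_truncation_bias_below_five_points(self):
        df, info = sim.simulate_cohort(sim.CohortSimParams(n_patients=100_000, seed=2))
        r, _ = pearson_r(df["micp"], df["p2p1"])
        assert abs(r - info["target_r"]) < 0.05

    def test_infeasible_quantiles_rejected(self):
        with pytest.raises(InvalidParameterError):
            sim.CohortSimParams(micp_q1=15.0, micp_median=14.0, micp_q3=19.0)

    def test_reproducible_and_consistent(self):
        p = sim.CohortSimParams(n_patients=100, seed=8)
        df1, _ = sim.simulate_cohort(p)
        df2, _ = sim.simulate_cohort(p)
        assert df1.equals(df2)
        assert np.allclose(df1["bci"], df1["micp"] * df1["p2p1"])
        assert ((df1["micp"] > 20) == df1["iht"]).all()
        assert df1["p2p1"].between(0.4, 2.2).all()


def test_presets_order_compliance_severity():
    good = sim.preset_session("good-compliance")
    poor = sim.preset_session("poor-compliance")
    assert sim.achieved_morphology(good.shape).p2p1 < 1 < sim.achieved_morphology(poor.shape).p2p1
    assert good.micp_mmhg < poor.micp_mmhg
    with pytest.raises(InvalidParameterError):
        sim.preset_session("nope")
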