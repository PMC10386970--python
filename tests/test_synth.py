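import numpy as np
import pandas as pd
import pytest

import timebisect as tb
from timebisect.designs import DesignSpec
from timebisect.erp import extract_feature_table
from timebisect.synth import erp_template, pink_noise, read_epochs_text


class TestSimulateResponses:
    def test_logistic_at_threshold(self):
        # with no context pull and no lapse, P(long) = 0.5 at the base threshold
        assert tb.psychometric_p(800.0, 800.0, 110.0, 0.0) == pytest.approx(0.5)

    def test_full_context_pull_reproduces_ensemble_gap(self, exp1_schedules):
        params = tb.BehaviorParams(context_weight=1.0, threshold_sd_ms=0.0)
        beh = tb.simulate_responses(exp1_schedules, params, 2, 0)
        wide = beh.truth.pivot_table(index="participant", columns="context",
                                     values="threshold_ms")
        diff = (wide["NS"] - wide["PS"]).unique()
        assert diff == pytest.approx([223.71], abs=0.005)

    def test_lapse_asymptote(self):
        assert tb.psychometric_p(1e9, 800.0, 110.0, 0.04) == pytest.approx(0.98)

    def test_reproducible_and_trial_counts(self, exp1_schedules):
        a = tb.simulate_responses(exp1_schedules, tb.BehaviorParams(), 3, 9)
        b = tb.simulate_responses(exp1_schedules, tb.BehaviorParams(), 3, 9)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        assert len(a.trials) == 3 * 2 * 336
        assert set(a.trials["response"]) == {"short", "long"}

    def test_traits_shared_across_contexts(self, exp1_schedules):
        beh = tb.simulate_responses(exp1_schedules, tb.BehaviorParams(), 6, 1)
        slopes = beh.truth.pivot_table(index="participant", columns="context",
                                       values="slope_ms")
        assert np.allclose(slopes["PS"], slopes["NS"])

    def test_thresholds_stay_inside_anchor_range(self, exp1_schedules):
        params = tb.BehaviorParams(threshold_sd_ms=500.0)
        beh = tb.simulate_responses(exp1_schedules, params, 50, 2)
        assert beh.truth["threshold_ms"].between(400, 1600, inclusive="neither").all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="slope_ms"):
            tb.BehaviorParams(slope_ms=-1.0)
        with pytest.raises(ValueError, match="lapse"):
            tb.BehaviorParams(lapse=0.5)


class TestErpTemplate:
    def test_silent_before_onset(self):
        v = erp_template(800, "PS", tb.ErpParams())
        t = tb.ErpParams().times_ms
        assert np.all(v[t <= 0] == 0.0)
        assert v[np.searchsorted(t, -100.0)] == 0.0

    def test_climb_segment_slope_is_programmed_rate(self, clean_erp_params):
        p = clean_erp_params
        v = erp_template(1600, "NS", p)  # NS slope -20: plateau reached at 750 ms
        t = p.times_ms
        sl = (t >= 250) & (t <= 650)
        slope = np.polyfit(t[sl] / 1000.0, v[sl], 1)[0]
        assert slope == pytest.approx(-20.0, abs=1e-9)

    def test_returns_to_zero_at_end_of_resolution_ramp(self, clean_erp_params):
        p = clean_erp_params
        t = p.times_ms
        v = erp_template(800, "NS", p)
        post = t > 800
        first_zero = t[post][np.abs(v[post]) < 1e-12][0]
        assert first_zero == 800 + p.resolution_ramp_ms
        # strictly negative during the ramp
        ramping = (t > 800) & (t < 800 + p.resolution_ramp_ms)
        assert np.all(v[ramping] < 0)

    def test_unreachable_plateau_truncates_without_error(self):
        # |plateau| / |slope| + onset > shortest offset: ramp simply truncates
        p = tb.ErpParams(plateau_level_uv=-30.0)
        v = erp_template(400, "PS", p)
        assert np.isfinite(v).all()

    def test_duration_bounds(self):
        with pytest.raises(ValueError, match="duration"):
            erp_template(300, "PS", tb.ErpParams())

    def test_unknown_context_slope(self):
        with pytest.raises(ValueError, match="no CNV slope"):
            erp_template(800, "XX", tb.ErpParams())

    def test_lpct_amplitude_hinge(self):
        p = tb.ErpParams()
        t = p.times_ms

        def lpct_peak(d):
            v = erp_template(d, "DF", p, response_gap_ms=300.0)
            cue = d + 300.0
            sl = (t >= cue) & (t <= cue + 500)
            return v[sl].max()

        # amplitude decreases with duration below the hinge, levels off above
        assert lpct_peak(400) > lpct_peak(600) > lpct_peak(800)
        assert lpct_peak(1200) == pytest.approx(lpct_peak(1400), abs=0.2)


class TestSimulateEpochs:
    def test_zero_noise_reproduces_templates(self, exp1_schedules):
        p = tb.ErpParams(noise_sd_uv=0.0, pink_noise_sd_uv=0.0, cnv_slope_sd=0.0)
        ep = tb.simulate_epochs(exp1_schedules[:1], p, 1, 0)
        for i in (0, 5, 100):
            d = ep.metadata.loc[i, "duration_ms"]
            np.testing.assert_array_equal(
                ep.data[i], erp_template(d, "PS", p, response_gap_ms=0.0)
            )

    def test_bit_reproducible(self, exp1_schedules):
        a = tb.simulate_epochs(exp1_schedules[:1], tb.ErpParams(), 2, 3)
        b = tb.simulate_epochs(exp1_schedules[:1], tb.ErpParams(), 2, 3)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(
            a.data, tb.simulate_epochs(exp1_schedules[:1], tb.ErpParams(), 2, 4).data
        )

    def test_cue_latency_metadata(self):
        sched = tb.enumerate_trials(tb.build_design("exp2", "DF"), 1)
        p = tb.ErpParams(noise_sd_uv=0.0, pink_noise_sd_uv=0.0)
        ep = tb.simulate_epochs(sched, p, 1, 0)
        md = ep.metadata
        np.testing.assert_allclose(md["cue_latency_ms"], md["duration_ms"] + 300.0)

    def test_condition_average_within_clt_bound(self):
        # 500 noisy trials of one condition: the average tracks the template
        design = DesignSpec("exp1", "PS", (400.0, 1600.0), (500, 1))
        sched = tb.enumerate_trials(design, 2)
        p = tb.ErpParams(noise_sd_uv=3.0, pink_noise_sd_uv=0.0, cnv_slope_sd=0.0)
        ep = tb.simulate_epochs(sched, p, 1, 6)
        idx = ep.metadata.index[ep.metadata["duration_ms"] == 400.0]
        avg = ep.data[idx].mean(axis=0)
        template = erp_template(400.0, "PS", p)
        bound = 3.0 * p.noise_sd_uv / np.sqrt(len(idx))
        frac_within = np.mean(np.abs(avg - template) < bound)
        assert frac_within >= 0.99

    def test_ground_truth_records_clipped_slopes(self):
        design = DesignSpec("exp1", "PS", (400.0, 1600.0), (1, 1))
        sched = tb.enumerate_trials(design, 0)
        p = tb.ErpParams(cnv_slope_sd=20.0, noise_sd_uv=0.0, pink_noise_sd_uv=0.0)
        ep = tb.simulate_epochs(sched, p, 30, 8)
        gt = ep.ground_truth
        assert (gt["cnv_slope_uv_per_s"] <= -5.0).all()
        assert len(gt) == 30


class TestParameterRecovery:
    def test_climbing_rate_recovered_at_default_noise(self, exp1_schedules):
        ep = tb.simulate_epochs(exp1_schedules, tb.ErpParams(), 3, 17)
        feats = extract_feature_table(ep)
        agg = tb.pipeline.aggregate_climbing_rate(feats).merge(
            ep.ground_truth, on=["participant", "context"]
        )
        rel = (agg["cnv_climbing_rate_uv_per_s"] - agg["cnv_slope_uv_per_s"]) / agg[
            "cnv_slope_uv_per_s"
        ]
        assert rel.abs().max() < 0.15

    def test_peak_latency_recovered_for_pre_plateau_durations(self):
        # durations ending before the plateau is reached have an identifiable,
        # offset-locked (or onset-complex) peak; the flat plateau itself does not
        design = DesignSpec("exp1", "PS", (400.0, 504.0, 636.0, 1600.0), (96, 96, 96, 4))
        sched = tb.enumerate_trials(design, 5)
        p = tb.ErpParams(noise_sd_uv=1.0, pink_noise_sd_uv=0.0, cnv_slope_sd=0.0)
        ep = tb.simulate_epochs(sched, p, 3, 7)
        feats = extract_feature_table(ep)
        t = p.times_ms
        for d in (400.0, 504.0, 636.0):
            v = erp_template(d, "PS", p)
            v = v - v[(t >= -200) & (t <= 0)].mean()
            sl = (t >= 0) & (t <= 1600)
            truth = t[sl][np.argmin(v[sl])]
            got = feats.loc[feats["duration_ms"] == d, "cnv_peak_latency_ms"]
            assert np.abs(got - truth).max() <= 20.0


class TestNoiseAndIo:
    def test_pink_noise_unit_sd_and_reproducible(self):
        rng = np.random.default_rng(0)
        x = pink_noise(rng, (8, 2048), exponent=1.0)
        np.testing.assert_allclose(x.std(axis=-1), 1.0, atol=1e-9)
        y = pink_noise(np.random.default_rng(0), (8, 2048), exponent=1.0)
        np.testing.assert_array_equal(x, y)

    def test_pink_noise_is_low_frequency_weighted(self):
        rng = np.random.default_rng(1)
        x = pink_noise(rng, (64, 4096), exponent=2.0)
        spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2
        low = spec[:, 1:50].mean()
        high = spec[:, 500:].mean()
        assert low > 10 * high

    def test_epochset_save_load_round_trip(self, tmp_path, exp1_schedules):
        ep = tb.simulate_epochs(exp1_schedules[:1], tb.ErpParams(), 1, 0)
        ep.save(tmp_path / "epochs")
        back = tb.EpochSet.load(tmp_path / "epochs")
        np.testing.assert_array_equal(back.data, ep.data)
        np.testing.assert_array_equal(back.times_ms, ep.times_ms)
        assert len(back.metadata) == len(ep.metadata)

    def test_concat_requires_matching_grid(self, exp1_schedules):
        a = tb.simulate_epochs(exp1_schedules[:1], tb.ErpParams(), 1, 0)
        b = tb.simulate_epochs(exp1_schedules[1:], tb.ErpParams(), 1, 1)
        both = tb.EpochSet.concat([a, b])
        assert both.n_trials == a.n_trials + b.n_trials
        c = tb.simulate_epochs(exp1_schedules[:1], tb.ErpParams(tmax_ms=2500.0), 1, 0)
        with pytest.raises(ValueError, match="time grids"):
            tb.EpochSet.concat([a, c])

    def test_read_epochs_text(self, tmp_path):
        path = tmp_path / "export.txt"
        path.write_text(
            "; BrainVision-style epoch export\n"
            "[Header]\n"
            "SamplingRate=1000\n"
            "TimeStart=-2\n"
            "[Metadata]\n"
            "participant,context,duration_ms,cue_latency_ms\n"
            "0,PS,800,800\n"
            "1,PS,800,800\n"
            "[Data]\n"
            "0.0 1.0 2.0 3.0 4.0\n"
            "1.0 1.0 1.0 1.0 1.0\n"
        )
        ep = read_epochs_text(path)
        assert ep.data.shape == (2, 5)
        np.testing.assert_array_equal(ep.times_ms, [-2, -1, 0, 1, 2])
        assert list(ep.metadata["context"]) == ["PS", "PS"]
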