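import numpy as np
import pandas as pd
import pytest

import remcortex as rc
from conftest import make_preprocessed
from remcortex.remlike import (FrameCorrelationTrace, NremPeriodSpec,
                               RemLikeLabeler, compute_pc1rem,
                               detect_eye_bouts, detect_pwaves,
                               event_triggered_average, frame_cc,
                               lagged_pearson, occurrence_by_state,
                               occurrence_in_periods, sigma_crosscorr,
                               template_coefficient, theta_delta_corr)


class TestFrameCC:
    @staticmethod
    def template_and_pre(n_frames=5):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(16, 16))
        m /= np.linalg.norm(m)
        from remcortex.patterns import SpatialPattern
        tpl = SpatialPattern(map=m, coeff=np.zeros(1), explained_var=50.0,
                             rate=10.0)
        return tpl

    def test_template_frame_is_rem_like(self):
        tpl = self.template_and_pre()
        dff = np.stack([tpl.map, -tpl.map, np.zeros_like(tpl.map)])
        fct = frame_cc(make_preprocessed(dff), tpl)
        assert fct.cc[0] == pytest.approx(1.0)
        assert fct.cc[1] == pytest.approx(-1.0)
        assert fct.cc[2] == 0.0
        assert list(fct.labels) == ["REM-like", "REM-opponent", "neutral"]

    def test_threshold_is_strict(self):
        fct = FrameCorrelationTrace(cc=np.array([0.4, -0.4, 0.401, -0.401]),
                                    rate=10.0)
        assert list(fct.labels) == ["neutral", "neutral", "REM-like",
                                    "REM-opponent"]

    def test_scale_and_offset_invariance(self):
        tpl = self.template_and_pre()
        frame = 0.3 * tpl.map + 1.7
        fct = frame_cc(make_preprocessed(frame[None]), tpl)
        assert fct.cc[0] == pytest.approx(1.0, abs=1e-6)

    def test_wrong_grid_rejected(self):
        tpl = self.template_and_pre()
        with pytest.raises(ValueError):
            frame_cc(make_preprocessed(np.zeros((2, 8, 8))), tpl)


class TestPc1Rem:
    def test_requires_rem(self):
        pre = make_preprocessed(np.random.default_rng(1).normal(
            size=(20, 16, 16)))
        hyp = rc.Hypnogram(np.array(["Wake", "NREM"]))
        with pytest.raises(ValueError, match="REM"):
            compute_pc1rem(pre, hyp)

    def test_recovers_planted_occipital_map(self, pre30, session30,
                                            template30):
        cfg, rec, gt = session30
        occ = gt.pattern_maps["occipital"]
        r = np.corrcoef(template30.map.ravel(), occ.ravel())[0, 1]
        assert abs(r) > 0.9

    def test_first_component_dominates(self, pre30, session30):
        cfg, rec, gt = session30
        pre, _ = pre30
        from remcortex.patterns import run_pca
        labels = gt.hypnogram.frame_labels(pre.rate, pre.dff.shape[0])
        rem = np.flatnonzero(labels == "REM")
        pats = run_pca(pre, frame_subset=rem, downsample=1, n_components=2)
        assert pats[0].explained_var > 2 * pats[1].explained_var

    def test_retrosplenial_loading_positive(self, pre30, template30):
        pre, atlas = pre30
        rsp = atlas.region_mask("RSPd") | atlas.region_mask("RSPl")
        assert template30.map[rsp].mean() > 0

    def test_labeler_estimator_wraps_pipeline(self, pre30, session30):
        cfg, rec, gt = session30
        pre, _ = pre30
        est = RemLikeLabeler().fit(pre, gt.hypnogram)
        labels = est.predict(pre)
        assert set(np.unique(labels)) <= {"REM-like", "REM-opponent", "neutral"}


class TestOccurrence:
    def test_hand_built_counting(self):
        cc = np.zeros(10)
        cc[[2, 5, 7]] = 0.9                       # 3 REM-like of 10 frames
        fct = FrameCorrelationTrace(cc=cc, rate=1.0)   # 10 s -> 2 NREM epochs
        hyp = rc.Hypnogram(np.array(["NREM", "NREM"]))
        out = occurrence_by_state(fct, hyp)
        assert out.loc["NREM", "frac_rem_like"] == pytest.approx(0.3)
        assert np.isnan(out.loc["REM", "frac_rem_like"])

    def test_fractions_sum_to_one_with_neutral(self):
        rng = np.random.default_rng(2)
        fct = FrameCorrelationTrace(cc=rng.uniform(-1, 1, 200), rate=10.0)
        hyp = rc.Hypnogram(np.array(["Wake", "NREM", "REM", "NREM"]))
        out = occurrence_by_state(fct, hyp)
        for state in ("Wake", "NREM", "REM"):
            like = out.loc[state, "frac_rem_like"]
            opp = out.loc[state, "frac_rem_opponent"]
            labels = hyp.frame_labels(10.0, 200)
            neutral = np.mean(fct.labels[labels == state] == "neutral")
            assert like + opp + neutral == pytest.approx(1.0)

    def test_rem_like_ordering_on_synthetic_session(self, pre30, session30,
                                                    template30):
        cfg, rec, gt = session30
        pre, _ = pre30
        fct = frame_cc(pre, template30)
        out = occurrence_by_state(fct, gt.hypnogram)
        assert out.loc["REM", "frac_rem_like"] > \
            out.loc["NREM", "frac_rem_like"] > out.loc["Wake", "frac_rem_like"]


class TestPeriods:
    def test_constant_occurrence_flat_slope(self):
        hyp = rc.Hypnogram(np.array(
            ["NREM"] * 12 + ["REM"] * 4 + ["NREM"] * 12 + ["REM"] * 4))
        cc = np.full(32 * 5 * 10, 0.9)            # always REM-like
        fct = FrameCorrelationTrace(cc=cc, rate=10.0)
        out = occurrence_in_periods(fct, hyp)
        assert out.prerem_slope == pytest.approx(0.0, abs=1e-9)
        assert out.per_period.loc["preREM", "occurrence"] == pytest.approx(1.0)

    def test_planted_ramp_recovered(self, hyp3h_coeffs):
        cfg, hyp, coeffs, _ = hyp3h_coeffs
        occ, som = coeffs["occipital"], coeffs["somatomotor"]
        cc = occ / np.sqrt(occ ** 2 + som ** 2 + 0.5)
        fct = FrameCorrelationTrace(cc=cc, rate=cfg.movie_rate)
        out = occurrence_in_periods(fct, hyp)
        assert out.prerem_slope > 0
        assert out.prerem_r > 0.7

    def test_nr2_exceeds_nw2_before_rem_transitions(self, hyp3h_coeffs):
        cfg, hyp, coeffs, _ = hyp3h_coeffs
        occ, som = coeffs["occipital"], coeffs["somatomotor"]
        cc = occ / np.sqrt(occ ** 2 + som ** 2 + 0.5)
        out = occurrence_in_periods(
            FrameCorrelationTrace(cc=cc, rate=cfg.movie_rate), hyp)
        per = out.per_period
        assert per.loc["NR2", "occurrence"] > per.loc["NW2", "occurrence"]

    def test_short_bouts_skipped_and_counted(self):
        hyp = rc.Hypnogram(np.array(["NREM", "REM", "REM", "NREM"]))
        fct = FrameCorrelationTrace(cc=np.zeros(4 * 50), rate=10.0)
        out = occurrence_in_periods(fct, hyp,
                                    specs=[NremPeriodSpec("preREM")])
        assert out.skipped["preREM"] == 1          # only 5 s of NREM before REM
        assert np.isnan(out.per_period.loc["preREM", "occurrence"])

    def test_unknown_period_kind_rejected(self):
        with pytest.raises(ValueError):
            NremPeriodSpec("preWake")


class TestTriggeredAverage:
    def test_delta_bumps_recover_lag(self):
        rate = 10.0
        trace = np.zeros(6000)
        events = rc.EventSeries(np.array([100.0, 200.0, 300.0, 400.0]))
        for t in events.times_s:
            trace[int((t + 0.9) * rate)] = 1.0
        eta = event_triggered_average(trace, rate, events, window_s=2.0)
        assert eta.peak_lag_s == pytest.approx(0.9, abs=1e-9)

    def test_single_event_returns_segment(self):
        rng = np.random.default_rng(3)
        trace = rng.normal(size=500)
        ev = rc.EventSeries(np.array([25.0]))
        eta = event_triggered_average(trace, 10.0, ev, window_s=1.0)
        i = 250
        assert np.array_equal(eta.mean, trace[i - 10: i + 11])
        assert eta.n_events == 1

    def test_random_events_on_noise_average_to_zero(self):
        rng = np.random.default_rng(4)
        trace = rng.standard_normal(100_000)
        times = rng.uniform(50, 9950, size=300)
        eta = event_triggered_average(trace, 10.0, rc.EventSeries(times),
                                      window_s=2.0)
        assert np.all(np.abs(eta.mean) < 4 * np.where(eta.sem > 0, eta.sem, 1))

    def test_no_complete_window_rejected(self):
        with pytest.raises(ValueError):
            event_triggered_average(np.zeros(10), 10.0,
                                    rc.EventSeries(np.array([0.1])),
                                    window_s=5.0)


class TestPwaves:
    def test_quiet_lfp_yields_nothing(self):
        rng = np.random.default_rng(5)
        lfp = rng.standard_normal(100_000) * 0.5
        hyp = rc.Hypnogram(np.array(["REM"] * 20))
        lfp = np.clip(lfp, -1.9, 1.9)             # never beyond 4 SD
        assert len(detect_pwaves(lfp, 1000.0, hyp)) == 0

    def test_positive_spikes_ignored(self):
        lfp = np.zeros(50_000)
        lfp[[10_000, 30_000]] = 50.0
        lfp += 0.01 * np.sin(np.arange(50_000) / 500)
        hyp = rc.Hypnogram(np.array(["REM"] * 10))
        assert len(detect_pwaves(lfp, 1000.0, hyp)) == 0

    def test_planted_count_exact_on_generator_output(self, session30):
        cfg, rec, gt = session30
        ev = detect_pwaves(rec.lfp, rec.phys_rate, gt.hypnogram)
        assert len(ev) == len(gt.pwave_times)
        assert np.allclose(ev.times_s, gt.pwave_times, atol=0.05)

    def test_matches_brute_force_scan_oracle(self):
        def oracle(lfp, rate, hyp, thr=4.0, sep=0.1):
            labels = hyp.frame_labels(rate, lfp.size)
            rem = labels == "REM"
            sd = lfp[rem].std()
            neg = -lfp
            cand = [i for i in range(1, lfp.size - 1)
                    if neg[i] > thr * sd and neg[i] > neg[i - 1]
                    and neg[i] >= neg[i + 1]]
            cand.sort(key=lambda i: -neg[i])
            kept = []
            for i in cand:
                if all(abs(i - j) >= sep * rate for j in kept):
                    kept.append(i)
            return sorted(i / rate for i in kept if rem[i])

        cfg = rc.SimConfig(seed=12, duration_s=90, pwave_rate_per_min=30.0)
        cfg.state_params["Wake"]["exit"] = {"NREM": 5.0}
        cfg.state_params["NREM"] = {"mean_s": 10.0, "exit": {"REM": 1.0}}
        hyp = rc.generate_hypnogram(cfg)
        _, _, lfp, _ = rc.generate_polysomnography(hyp, cfg)
        ev = detect_pwaves(lfp, cfg.phys_rate, hyp)
        assert np.allclose(ev.times_s, oracle(lfp, cfg.phys_rate, hyp))


class TestEyeBouts:
    def test_static_eye_yields_nothing(self):
        assert len(detect_eye_bouts(np.zeros(10_000))) == 0

    def test_isolated_sharp_saccades_timed_precisely(self):
        rate = 25.0
        eye = 0.002 * np.sin(np.arange(int(300 * rate)) / 40.0)
        plants = np.arange(20.0, 280.0, 10.0)
        for t in plants:
            i = int(t * rate)
            eye[i:] += 1.0                        # step-like saccade
        bouts = detect_eye_bouts(eye, rate)
        for t in plants:
            assert np.min(np.abs(bouts.times_s - t)) <= 0.2

    def test_most_generator_saccades_recovered(self, session30):
        # bump onsets precede centers and near-simultaneous saccades merge,
        # so demand coverage rather than exact counts
        cfg, rec, gt = session30
        assert gt.eye_event_times.size > 0
        bouts = detect_eye_bouts(rec.eye, cfg.video_rate)
        near = [np.min(np.abs(bouts.times_s - t)) < 0.5
                for t in gt.eye_event_times]
        assert np.mean(near) >= 0.8

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        eye = rng.normal(size=5000)
        a = detect_eye_bouts(eye)
        b = detect_eye_bouts(eye)
        assert np.array_equal(a.times_s, b.times_s)


class TestSigmaCrossCorr:
    def test_shifted_envelope_recovers_lag(self):
        # EEG whose sigma-band amplitude follows a slow envelope; the cc
        # trace is the same envelope delayed by 5 s
        from scipy import signal as sg
        rng = np.random.default_rng(7)
        rate, dur = 1000.0, 600.0
        n = int(rate * dur)
        t = np.arange(n) / rate
        env = 1.0 + 0.8 * np.sin(2 * np.pi * 0.02 * t)
        sos = sg.butter(4, [9, 17], btype="bandpass", fs=rate, output="sos")
        carrier = sg.sosfiltfilt(sos, rng.standard_normal(n))
        eeg = env * carrier / carrier.std()
        cc_rate = 10.0
        tcc = np.arange(int(dur * cc_rate)) / cc_rate
        cc = 1.0 + 0.8 * np.sin(2 * np.pi * 0.02 * (tcc - 5.0))
        fct = FrameCorrelationTrace(cc=cc, rate=cc_rate)
        hyp = rc.Hypnogram(np.array(["NREM"] * int(dur // 5)))
        lags, rs, peak = sigma_crosscorr(eeg, rate, fct, hyp)
        assert peak == pytest.approx(5.0, abs=2.0)
        assert np.nanmax(rs) > 0.8

    def test_no_qualifying_bout_rejected(self):
        fct = FrameCorrelationTrace(cc=np.zeros(600), rate=10.0)
        hyp = rc.Hypnogram(np.array(["Wake"] * 12))
        with pytest.raises(ValueError):
            sigma_crosscorr(np.zeros(60_000), 1000.0, fct, hyp)

    def test_cophased_plants_give_positive_zero_lag(self, pre30, session30,
                                                    template30):
        cfg, rec, gt = session30
        pre, _ = pre30
        fct = frame_cc(pre, template30)
        lags, rs, peak = sigma_crosscorr(rec.eeg, cfg.phys_rate, fct,
                                         gt.hypnogram)
        assert rs[np.flatnonzero(lags == 0)[0]] > 0.2


class TestThetaDeltaCorr:
    def test_proportional_coefficient_gives_unit_r(self, session30):
        cfg, rec, gt = session30
        from remcortex.scoring import theta_delta_ratio
        ratio = theta_delta_ratio(rec.eeg, cfg.phys_rate)
        coeff = np.repeat(ratio, int(5 * cfg.movie_rate))
        r = theta_delta_corr(rec.eeg, cfg.phys_rate, coeff, cfg.movie_rate,
                             gt.hypnogram)
        assert r == pytest.approx(1.0, abs=1e-9)
        r_neg = theta_delta_corr(rec.eeg, cfg.phys_rate, -coeff,
                                 cfg.movie_rate, gt.hypnogram)
        assert r_neg == pytest.approx(-1.0, abs=1e-9)

    def test_too_few_windows_rejected(self):
        hyp = rc.Hypnogram(np.array(["REM", "Wake", "Wake", "Wake"]))
        with pytest.raises(ValueError):
            theta_delta_corr(np.random.default_rng(8).normal(
                size=20_000), 1000.0, np.zeros(200), 10.0, hyp)

    def test_coupled_plants_on_synthetic_session(self, pre30, session30,
                                                 template30):
        cfg, rec, gt = session30
        pre, _ = pre30
        coeff = template_coefficient(pre, template30)
        r = theta_delta_corr(rec.eeg, cfg.phys_rate, coeff, pre.rate,
                             gt.hypnogram)
        assert r > 0.3


def test_lagged_pearson_identifies_delay():
    rng = np.random.default_rng(9)
    x = np.convolve(rng.standard_normal(2000), np.ones(20) / 20, mode="same")
    y = np.roll(x, 30)
    lags, rs = lagged_pearson(x[100:-100], y[100:-100], 10.0, 6.0)
    assert lags[np.nanargmax(rs)] == pytest.approx(3.0, abs=0.2)
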