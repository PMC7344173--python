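"""Tests of the offline cleaning and statistical battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fmtheta import offline
from fmtheta.sim_subject import SubjectModel, generate_block


class TestKurtosisRejection:
    def test_homogeneous_channels_clean(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((16, 256 * 20))
        assert offline.reject_channels_kurtosis(data) == []

    def test_heavy_tailed_channel_flagged(self):
        """In a 64-channel montage, a channel with occasional x20 spikes
        has inflated kurtosis and must be the (only) flagged one (oracle:
        direct kurtosis values). A 5-SD z-score criterion needs a large
        ensemble: the outlier itself inflates the ensemble SD."""
        rng = np.random.default_rng(1)
        data = rng.standard_normal((64, 256 * 20))
        spikes = rng.random(data.shape[1]) < 0.002
        data[5, spikes] += 20.0 * rng.standard_normal(spikes.sum())
        flagged = offline.reject_channels_kurtosis(data)
        assert flagged == [5]
        k = stats.kurtosis(data, axis=1)
        assert np.argmax(k) == 5

    def test_threshold_respected(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((16, 256 * 20))
        data[3, ::100] += 30.0
        assert offline.reject_channels_kurtosis(data, threshold=1e6) == []

    def test_too_little_data_rejected(self):
        with pytest.raises(ValueError):
            offline.reject_channels_kurtosis(np.zeros((8, 100)))


class TestHFSegmentRejection:
    @staticmethod
    def pink(n_s, seed):
        subj = SubjectModel(sample_rate=256.0, blink_rate=0.0,
                            muscle_rate=0.0, rng_seed=seed)
        sig, _ = generate_block(subj, n_s, seed=seed)
        return sig

    @staticmethod
    def add_burst(data, start_s, dur_s, gain_db=15.0, seed=0):
        """Add a 30 Hz burst raising in-band power by ~gain_db."""
        rng = np.random.default_rng(seed)
        i0 = int(start_s * 256)
        n = int(dur_s * 256)
        t = np.arange(n) / 256.0
        freqs, psd = None, None
        from scipy.signal import periodogram

        f, p = periodogram(data[:, i0:i0 + n], fs=256.0, axis=1)
        base = p[:, (f >= 20) & (f <= 40)].sum()
        target = base * (10 ** (gain_db / 10) - 1)
        amp = np.sqrt(2 * target * 1.0 / n) * np.sqrt(256.0)
        burst = amp * np.sin(2 * np.pi * 30.0 * t)
        out = data.copy()
        out[:, i0:i0 + n] += burst
        return out

    def test_clean_recording_untouched(self):
        data = self.pink(30.0, seed=3)
        assert offline.reject_hf_segments(data) == []

    def test_two_second_burst_rejected_as_one_interval(self):
        data = self.pink(60.0, seed=4)
        dirty = self.add_burst(data, start_s=20.0, dur_s=2.0)
        intervals = offline.reject_hf_segments(dirty)
        assert len(intervals) == 1
        start, stop = intervals[0]
        assert start <= 20.0 + 0.5 and stop >= 21.5
        assert stop - start < 4.0

    def test_three_window_burst_kept(self):
        """A burst spanning only 3 contiguous windows does not satisfy the
        4-window contiguity rule."""
        data = self.pink(60.0, seed=5)
        dirty = self.add_burst(data, start_s=20.0, dur_s=1.5)
        assert offline.reject_hf_segments(dirty) == []

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            offline.reject_hf_segments(np.zeros((2, 256)))


def make_curve(amps, sid="S1", band="theta"):
    amps = np.asarray(amps, float)
    return offline.TrainingCurve(
        subject_id=sid, session_amp=amps,
        session_pct=100 * (amps / amps[0] - 1),
        baseline_amp=amps, baseline_pct=100 * (amps / amps[0] - 1),
        band=band)


class TestTrainingCurves:
    def test_arithmetic_progression_percent(self):
        curve = make_curve([10, 11, 12, 13, 14, 15, 16, 17])
        np.testing.assert_allclose(curve.session_pct,
                                   [0, 10, 20, 30, 40, 50, 60, 70])

    def test_session1_is_zero_by_construction(self):
        curve = make_curve([7.3, 9.9, 5.5])
        assert curve.session_pct[0] == 0.0

    def test_scale_invariance_of_percent(self):
        a = make_curve([4, 5, 6, 7])
        b = make_curve([8, 10, 12, 14])
        np.testing.assert_allclose(a.session_pct, b.session_pct)

    def test_from_session_logs(self):
        """Curves computed from real session logs: identical sessions give
        a flat 0% curve; missing sessions are an error."""
        from fmtheta.session import SessionPlan, run_session
        from fmtheta.sim_subject import SubjectModel

        plan = SessionPlan(start_baseline=8.0, n_blocks=2, block_len=10.0,
                           break_len=2.0, end_baseline=8.0,
                           native_rate=256.0, asr_min_baseline=6.0)
        log = run_session(SubjectModel(sample_rate=256.0, rng_seed=31),
                          plan, seed=31)
        logs = []
        for s in range(1, 4):
            logs.append(run_session(
                SubjectModel(sample_rate=256.0, rng_seed=31), plan, seed=31,
                session_index=s))
        curve = offline.training_curves(logs, n_sessions=3)
        np.testing.assert_allclose(curve.session_pct, 0.0, atol=1e-9)
        np.testing.assert_allclose(curve.baseline_pct, 0.0, atol=1e-9)
        with pytest.raises(ValueError):
            offline.training_curves(logs[:2], n_sessions=3)

    def test_band_parameterization(self):
        from fmtheta.session import SessionPlan, run_session
        from fmtheta.sim_subject import SubjectModel

        plan = SessionPlan(start_baseline=8.0, n_blocks=2, block_len=10.0,
                           break_len=2.0, end_baseline=8.0,
                           native_rate=256.0, asr_min_baseline=6.0)
        log = run_session(SubjectModel(sample_rate=256.0, rng_seed=33),
                          plan, seed=33)
        ct = offline.training_curves([log], band="theta", n_sessions=1)
        ca = offline.training_curves([log], band="alpha", n_sessions=1)
        assert ct.session_amp[0] != ca.session_amp[0]


class TestSlopes:
    def test_perfect_line_recovered_exactly(self):
        curve = make_curve(np.arange(1, 9))  # any 8 values
        curve.session_pct = 2.0 * np.arange(1, 9) + 1.0
        slope, intercept = offline.fit_subject_slope(curve)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_power_of_slope_test(self):
        """Groups with true slopes 2 vs 0 (SD 0.5, n=12) are separated by
        the one-tailed test in >=95% of 200 replicates."""
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(200):
            a = rng.normal(2.0, 0.5, 12)
            b = rng.normal(0.0, 0.5, 12)
            _, p = offline.group_slope_test(a, b)
            hits += p < 0.05
        assert hits >= 190

    def test_type_i_calibration(self):
        """Identical groups reject at ~5% (one-tailed, 1000 replicates)."""
        rng = np.random.default_rng(1)
        rejections = 0
        for _ in range(1000):
            a = rng.normal(0.0, 1.0, 12)
            b = rng.normal(0.0, 1.0, 12)
            _, p = offline.group_slope_test(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            offline.group_slope_test([], [1.0, 2.0])


class TestGroupCorrelation:
    def test_linear_curve_r2_one(self):
        curves = [make_curve(np.arange(1.0, 9.0)) for _ in range(3)]
        res = offline.group_session_correlation(curves)
        assert res["r2"] == pytest.approx(1.0)
        assert res["df"] == 6

    def test_df_convention(self):
        curves = [make_curve(np.random.default_rng(7).random(8) + 1)]
        assert offline.group_session_correlation(curves)["df"] == 6

    def test_flat_series_near_zero_r2(self):
        rng = np.random.default_rng(8)
        curves = [make_curve(10 + 0.01 * rng.standard_normal(8))
                  for _ in range(6)]
        res = offline.group_session_correlation(curves)
        assert res["p"] > 0.05 or res["r2"] < 0.5


class TestNonResponders:
    def test_homogeneous_cohort_kept(self):
        rng = np.random.default_rng(2)
        power = {f"S{i}": float(10 + rng.standard_normal())
                 for i in range(12)}
        retained, removed = offline.exclude_nonresponders(power)
        assert removed == []
        assert len(retained) == 12

    def test_constructed_outlier_removed(self):
        """One subject far outside a tight cohort of 12 is removed. (With
        n=12 the largest attainable |z| is (n-1)/sqrt(n) ~ 3.17, so the
        outlier must dominate the spread.)"""
        rng = np.random.default_rng(3)
        vals = 10 + 0.3 * rng.standard_normal(11)
        power = {f"S{i}": float(v) for i, v in enumerate(vals)}
        power["S11"] = 60.0
        retained, removed = offline.exclude_nonresponders(power)
        assert removed == ["S11"]
        assert len(retained) == 11

    def test_single_pass_not_iterated(self):
        """After removing the extreme subject the remaining spread shrinks;
        a second-pass outlier must NOT be removed."""
        power = {f"S{i}": 10.0 + 0.01 * i for i in range(10)}
        power["big"] = 300.0    # > 3 SD of the full-cohort spread
        power["mid"] = 11.0     # would be >3 SD only after removing "big"
        retained, removed = offline.exclude_nonresponders(power)
        assert removed == ["big"]
        assert "mid" in retained

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            offline.exclude_nonresponders({"a": 1.0, "b": 2.0})


class TestSpectralPermutation:
    @staticmethod
    def epochs(n, seed, boost_db=0.0):
        """4 s white-noise epochs; optionally boost the whole 4-6 Hz band
        by boost_db via spectral scaling."""
        rng = np.random.default_rng(seed)
        n_samp = 4 * 256
        eps = rng.standard_normal((n, n_samp))
        if boost_db:
            spec = np.fft.rfft(eps, axis=1)
            f = np.fft.rfftfreq(n_samp, 1 / 256.0)
            band = (f >= 4.0) & (f <= 6.0)
            spec[:, band] *= 10 ** (boost_db / 20.0)
            eps = np.fft.irfft(spec, n=n_samp, axis=1)
        return eps

    def test_planted_theta_effect_localized(self):
        """A 4-6 Hz power boost is found at the interior theta bins (the
        band-edge bins are attenuated by taper leakage) and the 20-40 Hz
        band stays clean up to the occasional false discovery that an
        FDR-controlling procedure is expected to admit."""
        detections = 0
        for seed in range(10):
            pre = self.epochs(12, seed)
            post = self.epochs(12, 100 + seed, boost_db=15.0)
            res = offline.spectral_permutation_test(
                pre, post, n_perm=1500, seed=seed)
            f = res["freqs"]
            sig = res["significant"]
            theta_interior = sig[(f >= 4.25) & (f <= 5.75)]
            high = sig[(f >= 20) & (f <= 40)]
            detections += theta_interior.all() and high.sum() <= 1
        assert detections >= 9

    def test_null_calibration(self):
        """Identical distributions: per-frequency rejection rate before FDR
        stays near alpha (500 replicates aggregated over frequencies)."""
        rng = np.random.default_rng(0)
        rej = []
        for rep in range(60):
            pre = self.epochs(8, 1000 + rep)
            post = self.epochs(8, 5000 + rep)
            res = offline.spectral_permutation_test(
                pre, post, n_perm=200, seed=rep)
            rej.append(np.mean(res["p"] <= 0.05))
        assert abs(np.mean(rej) - 0.05) < 0.02

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            offline.spectral_permutation_test(
                np.zeros((8, 256)), np.zeros((8, 256)), n_perm=0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            offline.spectral_permutation_test(
                np.zeros((8, 256)), np.zeros((8, 300)), n_perm=10)


class TestRMAnova:
    @staticmethod
    def table(n_per_group=8, n_sessions=4, group_trend=0.0, seed=0,
              cs_rho=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, gname in enumerate(("nf", "sham")):
            for s_i in range(n_per_group):
                subj_effect = rng.normal(0, 1.0)
                for sess in range(1, n_sessions + 1):
                    val = (10 + subj_effect + rng.normal(0, 1.0)
                           + (group_trend * sess if gname == "nf" else 0.0))
                    rows.append({"subject": f"{gname}{s_i}",
                                 "group": gname, "session": sess,
                                 "amplitude": val})
        return pd.DataFrame(rows)

    def test_interaction_detected_with_planted_trend(self):
        hits = 0
        for seed in range(10):
            tab = self.table(group_trend=1.0, seed=seed)
            res = offline.rm_anova(tab)
            inter = res[res["Source"] == "Interaction"]
            p = float(inter["p_unc"].iloc[0])
            hits += p < 0.05
        assert hits >= 9

    def test_null_type_i_rate(self):
        ps = []
        for seed in range(200):
            tab = self.table(seed=1000 + seed)
            res = offline.rm_anova(tab)
            inter = res[res["Source"] == "Interaction"]
            ps.append(float(inter["p_unc"].iloc[0]))
        rate = np.mean(np.asarray(ps) < 0.05)
        assert abs(rate - 0.05) <= 0.03

    def test_gg_epsilon_one_under_compound_symmetry(self):
        """Data whose empirical within-subject covariance is exactly
        compound-symmetric must give a Greenhouse-Geisser epsilon of 1."""
        rng = np.random.default_rng(5)
        n, k = 12, 4
        raw = rng.standard_normal((2 * n, k))
        # whiten empirically, then color with an exact CS covariance
        raw -= raw.mean(axis=0)
        cov = np.cov(raw.T)
        w, v = np.linalg.eigh(cov)
        white = raw @ v @ np.diag(w ** -0.5) @ v.T
        cs = 0.5 * np.ones((k, k)) + 0.5 * np.eye(k)
        wc, vc = np.linalg.eigh(cs)
        data = white @ vc @ np.diag(np.sqrt(wc)) @ vc.T
        rows = []
        for i in range(2 * n):
            for sess in range(k):
                rows.append({"subject": f"s{i}",
                             "group": "nf" if i < n else "sham",
                             "session": sess + 1,
                             "amplitude": data[i, sess]})
        res = offline.rm_anova(pd.DataFrame(rows))
        eps = float(res["eps"].dropna().iloc[0])
        assert eps == pytest.approx(1.0, abs=1e-6)

    def test_unbalanced_table_rejected(self):
        tab = self.table().iloc[:-1]
        with pytest.raises(ValueError):
            offline.rm_anova(tab)
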