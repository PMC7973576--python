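"""Beat matching, heart-rate statistics, SDE and the unpaired t-test."""

import numpy as np
import pytest
from scipy import stats

from invisible_ecg import (
    BeatSeries,
    UndefinedStatisticError,
    delta_hr,
    delta_qrs_percent,
    instantaneous_hr,
    match_rpeaks,
    signal_detection_error,
    unpaired_ttest,
)

FS = 1000.0


def beats(times_s, fs=FS):
    return BeatSeries(np.round(np.array(times_s) * fs).astype(int), fs)


class TestMatching:
    def test_identical_series_fully_matched(self):
        s = beats(np.arange(1, 11))
        m = match_rpeaks(s, s)
        assert len(m.pairs) == 10
        assert not m.unmatched_ref and not m.unmatched_exp
        assert delta_qrs_percent(s, s) == 100.0

    def test_missing_beats_counted(self):
        t = np.arange(1, 101, dtype=float)
        ref = beats(t)
        exp = beats(np.delete(t, [10, 50, 90]))
        m = match_rpeaks(ref, exp)
        assert delta_qrs_percent(ref, exp) == 97.0
        assert len(m.unmatched_ref) == 3
        assert len(m.pairs) == 97

    def test_spurious_detections_can_exceed_100_percent(self):
        t = np.arange(1, 101, dtype=float)
        ref = beats(t)
        exp = beats(np.sort(np.concatenate([t, t[:14] + 0.4])))
        assert delta_qrs_percent(ref, exp) == 114.0

    def test_each_beat_used_once_within_tolerance(self):
        ref = beats([1.0, 2.0])
        exp = beats([1.05, 1.1, 2.0])
        m = match_rpeaks(ref, exp, tolerance_ms=150)
        assert len(m.pairs) == 2
        exp_used = [j for _, j in m.pairs]
        assert len(set(exp_used)) == 2

    def test_empty_reference_raises(self):
        with pytest.raises(UndefinedStatisticError):
            match_rpeaks(beats([]), beats([1.0]))


class TestInstantaneousHr:
    def test_constant_rr_1000ms(self):
        hr, flags = instantaneous_hr(beats(np.arange(10, dtype=float)))
        assert np.allclose(hr, 60.0)
        assert not flags.any()

    def test_constant_rr_600ms(self):
        hr, _ = instantaneous_hr(beats(np.arange(10) * 0.6))
        assert np.allclose(hr, 100.0)

    def test_out_of_band_flagged_but_kept(self):
        hr, flags = instantaneous_hr(beats([0.0, 0.5]))
        assert hr[0] == pytest.approx(120.0)
        assert flags[0]

    def test_fewer_than_two_beats_empty(self):
        hr, _ = instantaneous_hr(beats([1.0]))
        assert hr.size == 0


class TestDeltaHr:
    def test_identity_is_zero(self):
        s = beats(np.arange(1, 20, dtype=float))
        m = match_rpeaks(s, s)
        mean, sd, _ = delta_hr(s, s, m)
        assert mean == 0.0 and sd == 0.0

    def test_constant_rate_shift(self):
        ref = beats(np.arange(0, 20) * 0.8)  # 75 BPM
        exp = beats(np.arange(0, 20) * 0.8 + 0.05)  # same RR, shifted in time
        m = match_rpeaks(ref, exp, tolerance_ms=150)
        mean, sd, _ = delta_hr(ref, exp, m)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_sign_convention_exp_minus_ref(self):
        ref = beats(np.arange(0, 16) * 0.8)  # 75 BPM
        exp = beats(np.arange(0, 16) * 1.0)  # 60 BPM
        m = match_rpeaks(ref, exp, tolerance_ms=250)
        mean, _, _ = delta_hr(ref, exp, m)
        assert mean < 0  # slower experimental channel -> negative difference

    def test_no_pairs_raises(self):
        ref = beats([1.0, 2.0])
        exp = beats([10.0, 11.0])
        m = match_rpeaks(ref, exp)
        with pytest.raises(UndefinedStatisticError):
            delta_hr(ref, exp, m)


class TestSde:
    def test_clean_stationary_signal_is_zero(self, rng):
        x = np.clip(rng.normal(512, 20, 60000), 1, 1022).astype(int)
        assert signal_detection_error(x, 10, FS) == 0.0

    def test_counting_clamped_run(self):
        x = np.full(100, 512)
        x[10:50] = 1023
        # 40 of 100 samples in one 400 ms run at the rail (fs = 100 Hz)
        assert signal_detection_error(x, 10, 100.0) == pytest.approx(40.0)

    def test_short_blips_not_counted(self):
        x = np.full(5000, 512)
        x[100:120] = 1023  # 20 ms < 50 ms minimum run
        assert signal_detection_error(x, 10, FS) == 0.0

    def test_synthetic_saturation_fraction(self):
        from invisible_ecg import SynthConfig, generate_pair

        cfg = SynthConfig(duration=300, seed=4, sat_rate=2.0, sat_dur=1.0)
        _, dev_b, truth = generate_pair(cfg)
        sde = signal_detection_error(dev_b.channel("A1"), 10, cfg.fs)
        f = sum(e - s for s, e in truth.sat_windows["A1"]) / cfg.duration
        assert sde == pytest.approx(100 * f, abs=0.5)

    def test_invariant_to_adding_beats(self, rng):
        from invisible_ecg import SynthConfig, generate_pair

        cfg = SynthConfig(duration=60, seed=8, sat_rate=1.0, sat_dur=1.0)
        _, dev_b, _ = generate_pair(cfg)
        sde_with_ecg = signal_detection_error(dev_b.channel("A1"), 10, cfg.fs)
        cfg2 = SynthConfig(duration=60, seed=8, sat_rate=1.0, sat_dur=1.0, ecg_amp=0.02)
        _, dev_b2, _ = generate_pair(cfg2)
        sde_small_ecg = signal_detection_error(dev_b2.channel("A1"), 10, cfg2.fs)
        assert sde_with_ecg == pytest.approx(sde_small_ecg, abs=0.5)

    def test_empty_raises(self):
        with pytest.raises(UndefinedStatisticError):
            signal_detection_error(np.array([]), 10, FS)


class TestTtest:
    def test_identical_samples_p_one(self):
        assert unpaired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_separated_samples_small_p(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(5, 1, 200)
        assert unpaired_ttest(a, b) < 1e-3

    def test_matches_scipy_welch(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0.3, 2, 60)
        assert unpaired_ttest(a, b) == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue
        )

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0, 1, 30)
            b = rng.normal(0, 1, 30)
            rejections += unpaired_ttest(a, b) < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_degenerate_samples_raise(self):
        with pytest.raises(UndefinedStatisticError):
            unpaired_ttest([1.0], [1.0, 2.0])
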