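import math

import numpy as np
import pytest

from bradyglu.episode_detection import detect_bradycardia
from bradyglu.signal_io import AnalysisConfig
from bradyglu.window_features import (
    RawWindow,
    build_feature_table,
    clean_rr_window,
    clock_features,
    frequency_domain_features,
    impute_glucose,
    nonlinear_features,
    permutation_entropy,
    sample_entropy,
    segment_windows,
    time_domain_features,
)
from oracles import (
    permutation_entropy_oracle,
    poincare_oracle,
    sample_entropy_oracle,
    spectral_oracle,
    time_domain_oracle,
)


class TestSegmentation:
    def test_one_day_yields_288_windows(self, one_day_record):
        record, _ = one_day_record
        windows = segment_windows(record)
        assert len(windows) == 288

    def test_boundary_beat_belongs_to_later_window(self, one_day_record):
        record, _ = one_day_record
        windows = segment_windows(record)
        for w in windows:
            assert np.all(w.beat_times >= w.start_s)
            assert np.all(w.beat_times < w.start_s + 300.0)

    def test_episode_spanning_boundary_flags_both_windows(self, one_day_record):
        record, truth = one_day_record
        episodes = detect_bradycardia(record.rr)
        windows = segment_windows(record, episodes)
        for ep in episodes:
            k0 = int(ep.start_s // 300)
            k1 = int(min(ep.end_s, record.rr.beat_times[-1] - 1e-9) // 300)
            for k in range(k0, k1 + 1):
                assert windows[k].contains_brady_event


class TestCleaning:
    def _window(self, rr_ms, start=0.0):
        rr_ms = np.asarray(rr_ms, dtype=float)
        times = start + np.cumsum(rr_ms) / 1000.0
        return RawWindow("p", start, np.concatenate([[start], times]), rr_ms,
                         glucose_mgdl=np.nan, contains_brady_event=False)

    def test_single_artifact_dropped_window_stays_valid(self):
        rr = [900.0] * 150 + [5000.0] + [900.0] * 150
        w = clean_rr_window(self._window(rr))
        assert w.valid
        assert w.clean_rr.size == 300
        assert np.all(w.clean_rr <= 3000)

    def test_empty_window_invalid(self):
        w = RawWindow("p", 0.0, np.empty(0), np.empty(0), np.nan, False)
        assert not clean_rr_window(w).valid

    def test_low_coverage_window_invalid(self):
        # 40% coverage: 120 s of beats in a 300-s window
        w = clean_rr_window(self._window([800.0] * 150))
        assert not w.valid


class TestTimeDomain:
    def test_constant_series(self):
        f = time_domain_features([1000.0] * 12)
        assert f["RR-sdnn"] == 0
        assert f["RR-rmssd"] == 0
        assert f["RR-pnn50"] == 0
        assert f["HR-mean"] == pytest.approx(60.0)
        assert f["HR-p2p"] == 0

    def test_alternating_series_forced_values(self):
        f = time_domain_features([1000.0, 1060.0] * 6)
        assert f["RR-pnn50"] == pytest.approx(100.0)
        assert f["RR-rmssd"] == pytest.approx(60.0)
        # sample SD of a balanced two-level series
        expected_sdnn = np.std([1000.0, 1060.0] * 6, ddof=1)
        assert f["RR-sdnn"] == pytest.approx(expected_sdnn)

    def test_matches_definition_oracle_on_random_windows(self, random_rr_windows):
        for _, _, rr in random_rr_windows:
            got = time_domain_features(rr)
            expected = time_domain_oracle(rr)
            for key, val in expected.items():
                assert got[key] == pytest.approx(val, rel=1e-9, abs=1e-12), key


class TestFrequencyDomain:
    def test_constant_rr_has_no_power(self):
        rr = np.full(300, 1000.0)
        t = np.cumsum(rr) / 1000.0
        f = frequency_domain_features(t, rr, 0.0)
        assert f["RR-total-power"] == pytest.approx(0.0, abs=1e-6)

    def test_lf_sinusoid_recovered_at_peak(self):
        # RR(t) = 1000 + 50 sin(2*pi*0.1 t): LF-band line at 0.1 Hz
        t, rr = [], []
        now = 0.0
        while now < 300.0:
            val = 1000.0 + 50.0 * math.sin(2 * math.pi * 0.1 * now)
            now += val / 1000.0
            t.append(now)
            rr.append(val)
        f = frequency_domain_features(np.array(t), np.array(rr), 0.0)
        assert abs(f["RR-lf-peak"] - 0.1) <= 1.0 / 300.0 + 1e-9
        assert f["RR-lf-norm"] > 95.0

    def test_norms_sum_to_100(self, random_rr_windows):
        for start, times, rr in random_rr_windows[:20]:
            f = frequency_domain_features(times, rr, start)
            if np.isfinite(f["RR-lf-norm"]):
                assert f["RR-lf-norm"] + f["RR-hf-norm"] == pytest.approx(100.0)

    def test_matches_dft_oracle(self, random_rr_windows):
        for start, times, rr in random_rr_windows[:30]:
            got = frequency_domain_features(times, rr, start)
            expected = spectral_oracle(times, rr, start)
            for key, val in expected.items():
                if np.isnan(val):
                    assert np.isnan(got[key]), key
                else:
                    assert got[key] == pytest.approx(val, rel=1e-9, abs=1e-12), key


class TestNonlinear:
    def test_sd1_equals_rmssd_over_sqrt2_for_zero_mean_diffs(self):
        rr = [1000.0, 1060.0] * 7 + [1000.0]  # diffs alternate +/-60, zero mean
        f = nonlinear_features(rr)
        rmssd = time_domain_features(rr)["RR-rmssd"]
        assert f["RR-sd1"] == pytest.approx(rmssd / math.sqrt(2))
        assert f["RR-sd1"] == pytest.approx(60.0 / math.sqrt(2))

    def test_monotone_series_has_zero_permutation_entropy(self):
        rr = np.arange(1000.0, 1101.0, 10.0)
        assert permutation_entropy(rr) == pytest.approx(0.0)

    def test_sample_entropy_matches_template_counting(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            x = rng.normal(1000, 40, size=50)
            r = 0.2 * float(np.std(x))
            got = sample_entropy(x, m=2, r=r)
            expected = sample_entropy_oracle(x, m=2, r=r)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_definition_oracles_on_random_windows(self, random_rr_windows):
        cfg = AnalysisConfig()
        for _, _, rr in random_rr_windows[:30]:
            got = nonlinear_features(rr, cfg)
            expected = poincare_oracle(rr)
            for key, val in expected.items():
                assert got[key] == pytest.approx(val, rel=1e-9), key
            assert got["RR-perm-ent"] == pytest.approx(
                permutation_entropy_oracle(rr), rel=1e-12
            )


class TestClockFeatures:
    @pytest.mark.parametrize(
        "hour,expected",
        [(0.0, (0.0, 1.0)), (6.0, (1.0, 0.0)), (18.0, (-1.0, 0.0)), (12.0, (0.0, -1.0))],
    )
    def test_cardinal_hours(self, hour, expected):
        s, c = clock_features(hour)
        assert s == pytest.approx(expected[0], abs=1e-12)
        assert c == pytest.approx(expected[1], abs=1e-12)

    def test_unit_circle_invariant(self):
        for h in np.linspace(0, 47.5, 96):
            s, c = clock_features(h)
            assert s * s + c * c == pytest.approx(1.0)


class TestImputation:
    def test_short_gap_interpolated_long_gap_left(self):
        g = np.array([100.0, np.nan, np.nan, 130.0, np.nan, np.nan, np.nan, np.nan, 180.0])
        out = impute_glucose(g, max_slots=3)
        np.testing.assert_allclose(out[:4], [100, 110, 120, 130])
        assert np.isnan(out[4:8]).all()


class TestBuildTable:
    def test_row_count_and_flags(self, one_day_record):
        record, truth = one_day_record
        table = build_feature_table([record])
        assert len(table) == 288
        # every injected episode flags at least its own window
        flagged = set(table.loc[table["contains_brady_event"], "window_start_s"] // 300)
        for ep in truth.episodes:
            assert ep.start_s // 300 in flagged

    def test_invalid_windows_carry_missing_features(self, one_day_record):
        record, _ = one_day_record
        table = build_feature_table([record])
        invalid = table[~table["valid"]]
        if len(invalid):
            assert invalid["RR-sdnn"].isna().all()
        valid = table[table["valid"]]
        assert valid["RR-sdnn"].notna().all()
        assert (valid["HR-min"] <= valid["HR-median"] + 1e-12).all()
        assert (valid["HR-median"] <= valid["HR-max"] + 1e-12).all()

    def test_feature_extraction_is_deterministic(self, one_day_record):
        record, _ = one_day_record
        t1 = build_feature_table([record])
        t2 = build_feature_table([record])
        assert t1.equals(t2)

    def test_patient_permutation_does_not_change_features(self, small_cohort):
        records = [r for r, _ in small_cohort]
        t_fwd = build_feature_table(records, compute_hrv=False)
        t_rev = build_feature_table(records[::-1], compute_hrv=False)
        a = t_fwd.sort_values(["patient_id", "window_start_s"]).reset_index(drop=True)
        b = t_rev.sort_values(["patient_id", "window_start_s"]).reset_index(drop=True)
        assert a.equals(b)
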