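import math

import numpy as np
import pandas as pd
import pytest

from bradyglu.assoc_stats import (
    ContingencyTable2x2,
    bootstrap_fisher_by_timeband,
    clock_hour,
    fisher_signed,
    hourly_hr_glucose_correlation,
    mannwhitney_tertile_comparison,
    per_patient_brady_freq_by_tertile,
    tertile_event_shares,
    wilcoxon_hrv_bootstrap,
)
from bradyglu.signal_io import AnalysisConfig
from bradyglu.window_features import clock_features
from oracles import fisher_exact_oracle, mannwhitney_exact_oracle


class TestFisherSigned:
    def test_balanced_table_gives_zero(self):
        assert fisher_signed(ContingencyTable2x2(5, 5, 5, 5)) == 0.0

    def test_perfectly_associated_table(self):
        stat = fisher_signed(ContingencyTable2x2(10, 0, 0, 10))
        expected_p = 2.0 / math.comb(20, 10)
        assert stat == pytest.approx(-math.log10(expected_p))
        assert stat == pytest.approx(4.9656, abs=5e-4)

    def test_transpose_preserves_magnitude(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            s1 = fisher_signed(ContingencyTable2x2(a, b, c, d))
            s2 = fisher_signed(ContingencyTable2x2(a, c, b, d))
            assert abs(s1) == pytest.approx(abs(s2), abs=1e-9)

    def test_matches_hypergeometric_enumeration_small_tables(self):
        """Exhaustive check of every non-degenerate table with total <= 24."""
        total_max = 24
        for a in range(total_max + 1):
            for b in range(total_max + 1 - a):
                for c in range(total_max + 1 - a - b):
                    for d in range(total_max + 1 - a - b - c):
                        if min(a + b, c + d, a + c, b + d) == 0 or a + b + c + d == 0:
                            continue
                        t = ContingencyTable2x2(a, b, c, d)
                        p_oracle = fisher_exact_oracle(a, b, c, d)
                        stat = fisher_signed(t)
                        expected_a = (a + b) * (a + c) / t.total
                        direction = np.sign(a - expected_a)
                        expected = (
                            0.0 if p_oracle >= 1.0
                            else -math.log10(p_oracle) * direction
                        )
                        assert stat == pytest.approx(expected, abs=1e-9), (a, b, c, d)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        res = mannwhitney_tertile_comparison(
            {"low": [1, 2, 3], "medium": [4, 5, 6], "high": [4, 5, 6]}
        )
        low_mid = res[0]
        assert low_mid.u_statistic == 0.0
        assert low_mid.p_value == pytest.approx(0.1)
        u_oracle, p_oracle = mannwhitney_exact_oracle([1, 2, 3], [4, 5, 6])
        assert low_mid.u_statistic == pytest.approx(u_oracle)
        assert low_mid.p_value == pytest.approx(p_oracle)

    def test_identical_groups_p_one(self):
        res = mannwhitney_tertile_comparison(
            {"low": [1, 2, 3], "medium": [1, 2, 3], "high": [1, 2, 3]}
        )
        assert res[0].p_value == pytest.approx(1.0, abs=1e-9)

    def test_u_complement_identity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=15)
        res1 = mannwhitney_tertile_comparison({"low": x, "medium": y, "high": y})
        res2 = mannwhitney_tertile_comparison({"low": y, "medium": x, "high": x})
        assert res1[0].u_statistic + res2[0].u_statistic == pytest.approx(12 * 15)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_tertile_comparison({"low": [1], "medium": [1, 2], "high": [1, 2]})


def synthetic_table(
    n_windows=2000,
    brady_rate=0.05,
    seed=0,
    low_enrich=1.0,
    n_patients=4,
    hr_shift_in_brady=0.0,
):
    """Window-level table with controllable tertile-bradycardia coupling."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        for i in range(n_windows // n_patients):
            start = (i * 300.0) % 86400
            hour = start / 3600.0
            tert = rng.choice(["low", "medium", "high"])
            rate = brady_rate * (low_enrich if tert == "low" else 1.0)
            brady = rng.random() < rate
            s, c = clock_features(hour)
            rows.append({
                "patient_id": f"P{p}",
                "window_start_s": i * 300.0,
                "glucose_mgdl": rng.uniform(80, 250),
                "c24_sin": s,
                "c24_cos": c,
                "contains_brady_event": brady,
                "n_beats": 300,
                "valid": True,
                "tertile": tert,
                "HR-mean": rng.normal(70, 5) + (hr_shift_in_brady if brady else 0.0),
                "HR-min": rng.normal(55, 5) + (hr_shift_in_brady if brady else 0.0),
                "RR-sdnn": rng.normal(40, 8),
            })
    return pd.DataFrame(rows)


class TestBootstrapFisher:
    def test_null_table_medians_small(self):
        table = synthetic_table(seed=3)
        res = bootstrap_fisher_by_timeband(
            table, AnalysisConfig(n_boot_fisher=50), seed=1
        )
        assert len(res) == 16
        # without coupling, at most a small minority of strata should look
        # nominally significant, and none should be extreme
        n_sig = sum(abs(r.median) > -math.log10(0.05) for r in res.values())
        assert n_sig <= 2
        for r in res.values():
            assert abs(r.median) < 2.0

    def test_low_tertile_enrichment_detected(self):
        table = synthetic_table(seed=4, brady_rate=0.08, low_enrich=5.0, n_windows=4000)
        res = bootstrap_fisher_by_timeband(
            table, AnalysisConfig(n_boot_fisher=50), seed=1
        )
        low_medians = [r.median for k, r in res.items() if k.endswith("|low")]
        assert np.median(low_medians) > 0

    def test_seeded_determinism(self):
        table = synthetic_table(seed=5)
        cfg = AnalysisConfig(n_boot_fisher=20)
        r1 = bootstrap_fisher_by_timeband(table, cfg, seed=9)
        r2 = bootstrap_fisher_by_timeband(table, cfg, seed=9)
        for k in r1:
            np.testing.assert_array_equal(r1[k].sample, r2[k].sample)

    def test_small_stratum_flagged_unreliable(self):
        table = synthetic_table(n_windows=64, seed=6)
        res = bootstrap_fisher_by_timeband(table, AnalysisConfig(n_boot_fisher=5), seed=0)
        assert any(not r.reliable for r in res.values())


class TestWilcoxonBootstrap:
    def test_shifted_feature_strongly_signed(self):
        table = synthetic_table(seed=7, brady_rate=0.15, hr_shift_in_brady=-10.0)
        cfg = AnalysisConfig(n_boot_wilcoxon=20, wilcoxon_sample_n=50)
        res = wilcoxon_hrv_bootstrap(table, cfg, seed=2, features=["HR-min", "RR-sdnn"])
        assert res["HR-min"].median < -2.0
        assert abs(res["RR-sdnn"].median) < abs(res["HR-min"].median)

    def test_null_feature_near_zero(self):
        table = synthetic_table(seed=8, brady_rate=0.15)
        cfg = AnalysisConfig(n_boot_wilcoxon=20, wilcoxon_sample_n=50)
        res = wilcoxon_hrv_bootstrap(table, cfg, seed=3, features=["RR-sdnn"])
        assert abs(res["RR-sdnn"].median) < 1.0

    def test_seeded_determinism(self):
        table = synthetic_table(seed=9, brady_rate=0.15)
        cfg = AnalysisConfig(n_boot_wilcoxon=10, wilcoxon_sample_n=40)
        r1 = wilcoxon_hrv_bootstrap(table, cfg, seed=4, features=["HR-mean"])
        r2 = wilcoxon_hrv_bootstrap(table, cfg, seed=4, features=["HR-mean"])
        np.testing.assert_array_equal(r1["HR-mean"].sample, r2["HR-mean"].sample)


class TestHourlyCorrelation:
    def test_affine_profiles_give_r_one(self):
        rows = []
        rng = np.random.default_rng(10)
        hr_profile = 70 + 8 * np.cos(2 * np.pi * (np.arange(24) - 15) / 24)
        for p in range(3):
            for h in range(24):
                s, c = clock_features(float(h))
                rows.append({
                    "patient_id": f"P{p}", "window_start_s": h * 3600.0,
                    "glucose_mgdl": 2.0 * hr_profile[h] + 10.0,
                    "c24_sin": s, "c24_cos": c, "valid": True,
                    "HR-mean": hr_profile[h],
                })
        out = hourly_hr_glucose_correlation(pd.DataFrame(rows))
        assert out["r"] == pytest.approx(1.0)
        assert len(out["profile"]) == 24

    def test_invariant_to_per_patient_affine_glucose_rescale(self):
        table = synthetic_table(seed=11, n_windows=1200)
        r1 = hourly_hr_glucose_correlation(table)["r"]
        scaled = table.copy()
        scaled["glucose_mgdl"] = scaled["glucose_mgdl"] * 3.0 + 40.0
        r2 = hourly_hr_glucose_correlation(scaled)["r"]
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_too_few_bins_rejected(self):
        table = synthetic_table(seed=12, n_windows=8)
        small = table.head(4)
        with pytest.raises(ValueError):
            hourly_hr_glucose_correlation(small.assign(valid=True))


class TestShares:
    def test_all_brady_in_low(self):
        table = synthetic_table(seed=13)
        table.loc[table["contains_brady_event"], "tertile"] = "low"
        shares = tertile_event_shares(table)
        assert shares["overall_brady"]["low"] == pytest.approx(100.0)

    def test_shares_sum_to_100(self):
        table = synthetic_table(seed=14, brady_rate=0.1)
        shares = tertile_event_shares(table)
        assert sum(shares["overall_brady"].values()) == pytest.approx(100.0)
        assert sum(shares["absolute_brady"].values()) == pytest.approx(100.0)
        for band in shares["by_band_windows"].values():
            assert sum(band.values()) == pytest.approx(100.0)

    def test_low_enriched_table_has_largest_low_share(self):
        table = synthetic_table(seed=15, brady_rate=0.08, low_enrich=3.0, n_windows=6000)
        shares = tertile_event_shares(table)["overall_brady"]
        assert shares["low"] > max(shares["medium"], shares["high"])


class TestClockHourRecovery:
    def test_round_trip_through_circadian_encoding(self):
        hours = np.arange(0, 24, 0.25)
        rows = []
        for h in hours:
            s, c = clock_features(float(h))
            rows.append({"c24_sin": s, "c24_cos": c})
        got = clock_hour(pd.DataFrame(rows))
        np.testing.assert_allclose(got, hours, atol=1e-9)


class TestPerPatientFreq:
    def test_rates_are_percentages_per_level(self):
        table = synthetic_table(seed=16, brady_rate=0.2)
        freqs = per_patient_brady_freq_by_tertile(table)
        for level, arr in freqs.items():
            assert arr.size == 4
            assert np.all((arr >= 0) & (arr <= 100))
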