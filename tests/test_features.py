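import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from glucowear.dataio import BiologicalSex, Channel
from glucowear.features import (
    BEHAVIORAL_NAMES,
    EDA_EVENT_NAMES,
    FEATURE_NAMES,
    FD_NAMES,
    HRV_NAMES,
    MANIFEST,
    NL_NAMES,
    TD_NAMES,
    behavioral_features,
    circadian_features,
    clean_features,
    demographic_feature,
    detect_scr,
    eda_decompose,
    eda_features,
    featurize_epoch,
    frequency_features,
    hrv_features,
    hrv_from_ibi,
    nonlinear_features,
    time_domain_features,
)
from glucowear.preprocess import Epoch


class TestManifest:
    def test_total_is_236(self):
        assert len(FEATURE_NAMES) == 236
        assert len(set(FEATURE_NAMES)) == 236

    def test_category_decomposition(self):
        counts = MANIFEST["category"].value_counts()
        assert counts["physiological_td"] == 2 * 31
        assert counts["physiological_fd"] == 2 * 14
        assert counts["physiological_nl"] == 2 * 42
        assert counts["hrv"] == 13
        assert counts["eda"] == 42
        assert counts["behavioral"] == 3
        assert counts["circadian"] == 3
        assert counts["demographic"] == 1

    def test_87_data_driven_per_signal(self):
        for sig in ("HR", "sTemp"):
            n = MANIFEST["feature_name"].str.contains(f"_{sig}_").sum()
            assert n == 87


class TestTimeDomain:
    def test_constant_vector(self):
        out = time_domain_features(np.full(50, 3.5))
        for name in ("std", "range", "iqr", "line_length", "variance"):
            assert out[name] == 0.0

    def test_simple_vector(self):
        out = time_domain_features(np.array([1.0, 2.0, 2.0, 3.0]))
        assert out["mean"] == 2.0
        assert out["min"] == 1.0 and out["max"] == 3.0

    def test_too_short_gives_missing(self):
        out = time_domain_features(np.array([1.0, 2.0, 3.0]))
        assert all(np.isnan(v) for v in out.values())

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.standard_normal(rng.integers(50, 400))
            got = time_domain_features(x)
            d1, d2 = np.diff(x), np.diff(x, n=2)
            c = x - x.mean()
            slope, intercept = np.polyfit(np.arange(len(x)), x, 1)
            expected = {
                "mean": np.mean(x),
                "median": np.median(x),
                "std": np.std(x),
                "variance": np.var(x),
                "min": np.min(x),
                "max": np.max(x),
                "range": np.ptp(x),
                "iqr": np.percentile(x, 75) - np.percentile(x, 25),
                "skewness": stats.skew(x),
                "kurtosis": stats.kurtosis(x),
                "rms": np.sqrt(np.mean(x**2)),
                "mad": np.mean(np.abs(c)),
                "medad": np.median(np.abs(x - np.median(x))),
                "cv": np.std(x) / np.mean(x),
                "p5": np.percentile(x, 5),
                "p90": np.percentile(x, 90),
                "diff1_meanabs": np.mean(np.abs(d1)),
                "diff1_std": np.std(d1),
                "diff2_meanabs": np.mean(np.abs(d2)),
                "slope": slope,
                "intercept": intercept,
                "energy": np.sum(x**2),
                "hjorth_activity": np.var(x),
                "line_length": np.sum(np.abs(d1)),
            }
            for k, v in expected.items():
                np.testing.assert_allclose(got[k], v, rtol=1e-8, atol=1e-10, err_msg=k)


class TestFrequencyDomain:
    def test_dominant_frequency_of_sinusoid(self):
        fs = 4.0
        t = np.arange(1200) / fs
        out = frequency_features(np.sin(2 * np.pi * 0.1 * t), fs)
        assert abs(out["dominant_freq"] - 0.1) <= fs / 256  # one bin

    def test_relative_band_powers_sum_to_one(self):
        rng = np.random.default_rng(3)
        for fs, n in [(1.0, 300), (4.0, 1200)]:
            out = frequency_features(rng.standard_normal(n), fs)
            total = sum(out[f"rel_power_{i}"] for i in range(1, 5))
            np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_white_noise_spectral_entropy_high(self):
        x = np.random.default_rng(4).standard_normal(1200)
        assert frequency_features(x, 4.0)["spectral_entropy"] > 0.9

    def test_too_short_gives_missing(self):
        out = frequency_features(np.ones(32), 4.0)
        assert all(np.isnan(v) for v in out.values())


def _brute_force_rqa_det(x: np.ndarray, m: int = 3, eps_frac: float = 0.1,
                         lmin: int = 2) -> float:
    """Independent recurrence-determinism oracle via explicit loops."""
    n = len(x) - m + 1
    emb = np.array([x[i : i + m] for i in range(n)])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.max(np.abs(emb[i] - emb[j]))
    r = d <= eps_frac * d.max()
    lengths = []
    for off in range(1, n):
        run = 0
        for i in range(n - off):
            if r[i, i + off]:
                run += 1
            else:
                if run:
                    lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    total = sum(lengths)
    if total == 0:
        return 0.0
    return sum(l for l in lengths if l >= lmin) / total


class TestNonlinear:
    def test_constant_vector_sample_entropy_is_zero(self):
        out = nonlinear_features(np.full(150, 5.0))
        assert out["sampen"] == 0.0

    def test_monotone_sequence_has_zero_permutation_entropy(self):
        out = nonlinear_features(np.arange(150, dtype=float))
        assert out["perm3"] == 0.0

    def test_determinism_sinusoid_exceeds_permutation(self):
        t = np.arange(200)
        x = np.sin(2 * np.pi * t / 25)
        x_perm = np.random.default_rng(0).permutation(x)
        det_sin = nonlinear_features(x)["rqa_det"]
        det_perm = nonlinear_features(x_perm)["rqa_det"]
        assert det_sin > det_perm
        # and both agree with an independent loop-based oracle
        np.testing.assert_allclose(det_sin, _brute_force_rqa_det(x), atol=1e-12)
        np.testing.assert_allclose(det_perm, _brute_force_rqa_det(x_perm), atol=1e-12)

    def test_rqa_det_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(120)
        got = nonlinear_features(np.tile(x, 1))  # length 120 >= 100
        np.testing.assert_allclose(got["rqa_det"], _brute_force_rqa_det(x), atol=1e-12)

    def test_sampen_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(150)
        r = 0.2 * x.std()
        m = 2
        n = len(x)
        # direct O(n^2) pair counting
        a = b = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                    b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                    a += 1
        expected = -np.log(a / b)
        np.testing.assert_allclose(nonlinear_features(x)["sampen"], expected, atol=1e-12)

    def test_short_vector_gives_missing(self):
        out = nonlinear_features(np.ones(50))
        assert all(np.isnan(v) for v in out.values())

    def test_white_noise_entropies_near_maximal(self):
        x = np.random.default_rng(8).standard_normal(300)
        out = nonlinear_features(x)
        assert out["perm3"] > 0.95
        assert out["forbidden_frac"] == 0.0

    def test_all_42_features_finite_on_noisy_signal(self):
        x = 70 + np.random.default_rng(9).standard_normal(300)
        out = nonlinear_features(x)
        assert set(out) == set(NL_NAMES)
        finite = {k for k, v in out.items() if np.isfinite(v)}
        assert len(finite) == 42


class TestHRV:
    def test_constant_rate_pulse_train(self):
        t = np.arange(0, 300, 1 / 64.0)
        bvp = -np.sin(2 * np.pi * 1.0 * t)  # one beat per second
        out = hrv_features(bvp)
        assert abs(out["meanNN"] - 1000.0) < 20
        assert out["RMSSD"] < 5.0

    def test_alternating_ibi_series(self):
        nn = np.array([800.0, 1200.0] * 5)
        out = hrv_from_ibi(nn)
        np.testing.assert_allclose(out["RMSSD"], 400.0)
        np.testing.assert_allclose(out["pNN20"], 100.0)
        np.testing.assert_allclose(out["meanNN"], 1000.0)
        np.testing.assert_allclose(out["minNN"], 800.0)
        np.testing.assert_allclose(out["maxNN"], 1200.0)

    def test_too_few_beats_gives_13_missing(self):
        out = hrv_features(np.zeros(19200))
        assert len(out) == 13
        assert all(np.isnan(v) for v in out.values())


class TestEDA:
    def test_decompose_constant(self):
        tonic, phasic = eda_decompose(np.full(1200, 4.2))
        np.testing.assert_allclose(tonic, 4.2, atol=1e-8)
        np.testing.assert_allclose(phasic, 0.0, atol=1e-8)

    def test_decompose_reconstruction_exact(self):
        x = 5 + np.random.default_rng(1).standard_normal(1200) * 0.3
        tonic, phasic = eda_decompose(x)
        np.testing.assert_allclose(tonic + phasic, x, atol=1e-10)

    def test_sharp_bump_lands_in_phasic(self):
        t = np.arange(1200) / 4.0
        bump = 0.5 * np.exp(-((t - 150) ** 2) / 0.25)  # ~0.5 s wide: well above 0.05 Hz
        x = 3 + 0.001 * t + bump
        _, phasic = eda_decompose(x)
        assert phasic.max() >= 0.8 * bump.max()

    def test_zero_phasic_has_no_events(self):
        tonic = np.full(1200, 5.0)
        out = eda_features(tonic, np.zeros(1200))
        assert out["EDA_phasic_scr_count"] == 0
        assert out["EDA_phasic_energy"] == 0.0
        assert np.isnan(out["EDA_phasic_scr_amp_mean"])

    def test_constant_tonic_statistics(self):
        out = eda_features(np.full(1200, 5.0), np.zeros(1200))
        assert out["EDA_tonic_mean"] == 5.0
        assert out["EDA_tonic_rms"] == 5.0
        assert out["EDA_tonic_std"] == 0.0

    def test_injected_scr_bumps_are_counted(self):
        fs = 4.0
        t = np.arange(1200) / fs
        phasic = np.zeros_like(t)
        for center in (60, 150, 240):
            rise = np.clip((t - center) / 2.0, 0, 1)
            decay = np.exp(-np.clip(t - center - 2.0, 0, None) / 4.0)
            phasic += 0.3 * np.where(t < center, 0.0, rise * decay)
        events = detect_scr(phasic, fs)
        assert len(events) == 3
        out = eda_features(np.full_like(phasic, 2.0), phasic, fs)
        assert out["EDA_phasic_scr_count"] == 3


class TestBehavioralCircadianDemographic:
    def test_constant_acc_window(self):
        out = behavioral_features(np.full(7200 * 32, 9.8))
        assert out == {"ACC_2h_min": 9.8, "ACC_2h_max": 9.8, "ACC_2h_mean": 9.8}

    def test_half_empty_window_is_missing(self):
        out = behavioral_features(np.full(int(0.3 * 7200 * 32), 9.8))
        assert all(np.isnan(out[n]) for n in BEHAVIORAL_NAMES)

    def test_matches_brute_force_window_scan(self):
        rng = np.random.default_rng(3)
        acc = rng.random(7200 * 32) * 20
        out = behavioral_features(acc)
        assert out["ACC_2h_min"] == acc.min()
        assert out["ACC_2h_max"] == acc.max()
        np.testing.assert_allclose(out["ACC_2h_mean"], acc.mean())

    @pytest.mark.parametrize(
        "seconds,expected",
        [
            (0.0, (0.0, 0.0, 1.0)),
            (12 * 3600.0, (720.0, 0.0, -1.0)),
            (6 * 3600.0, (360.0, 1.0, 0.0)),
        ],
    )
    def test_circadian_reference_times(self, seconds, expected):
        out = circadian_features(seconds)
        np.testing.assert_allclose(
            [out["mins_midnight"], out["mins_midnight_sin"], out["mins_midnight_cos"]],
            expected,
            atol=1e-12,
        )

    @given(st.floats(min_value=0, max_value=4e9, allow_nan=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_sin_cos_identity(self, t):
        out = circadian_features(t)
        np.testing.assert_allclose(
            out["mins_midnight_sin"] ** 2 + out["mins_midnight_cos"] ** 2,
            1.0,
            atol=1e-12,
        )
        assert 0 <= out["mins_midnight"] < 1440

    def test_demographic_mapping(self):
        assert demographic_feature(BiologicalSex.MALE) == 1
        assert demographic_feature("female") == 0
        with pytest.raises(ValueError):
            demographic_feature("other")


class TestFeaturizePurity:
    def test_same_epoch_bit_identical(self):
        rng = np.random.default_rng(0)
        channels = {
            Channel.HR: 70 + rng.standard_normal(300),
            Channel.EDA: 5 + 0.1 * rng.standard_normal(1200),
            Channel.TEMP: 33.5 + 0.1 * rng.standard_normal(1200),
            Channel.BVP: -np.sin(2 * np.pi * np.arange(19200) / 64.0) * 40,
            Channel.ACC_MAG: 9.8 + 0.1 * rng.standard_normal(9600),
        }
        ep = Epoch("S01", 300.0, 110.0, channels, {c: 0.0 for c in channels})
        r1 = featurize_epoch(ep, BiologicalSex.MALE)
        r2 = featurize_epoch(ep, BiologicalSex.MALE)
        for k in r1:
            assert (r1[k] == r2[k]) or (np.isnan(r1[k]) and np.isnan(r2[k])), k


class TestCleaning:
    def _table(self, n=100, n_feats=5, seed=0):
        rng = np.random.default_rng(seed)
        data = {
            "participant_id": ["S01"] * n,
            "glucose_time": np.arange(n) * 300.0,
            "glucose": 100 + rng.standard_normal(n),
        }
        for i in range(n_feats):
            data[f"f{i}"] = rng.standard_normal(n)
        return pd.DataFrame(data)

    def test_missing_rule_is_strictly_more_than_20pct(self):
        table = self._table(100)
        table.loc[:20, "f0"] = np.nan  # 21 of 100 = 21%
        table.loc[:19, "f1"] = np.nan  # exactly 20%
        cleaned, log = clean_features(table)
        assert "f0" not in cleaned.columns
        assert "f1" in cleaned.columns
        assert ("f0" == log.loc[log["rule"] == "missing", "name"]).any()

    def test_duplicate_keeps_earliest(self):
        table = self._table()
        table["f1"] = table["f0"]
        cleaned, log = clean_features(table)
        assert "f0" in cleaned.columns and "f1" not in cleaned.columns

    def test_low_variance_dropped(self):
        table = self._table()
        table["f2"] = 1.0 + np.random.default_rng(1).standard_normal(100) * 1e-7
        cleaned, _ = clean_features(table)
        assert "f2" not in cleaned.columns

    def test_constant_dropped(self):
        table = self._table()
        table["f3"] = 7.0
        cleaned, log = clean_features(table)
        assert "f3" not in cleaned.columns
        assert (log.loc[log["name"] == "f3", "rule"] == "constant").all()

    def test_overflow_column_dropped(self):
        table = self._table()
        table.loc[5, "f4"] = np.inf
        cleaned, log = clean_features(table)
        assert "f4" not in cleaned.columns
        assert (log.loc[log["name"] == "f4", "rule"] == "overflow").all()

    def test_overflow_drop_cell_policy(self):
        table = self._table()
        table.loc[5, "f4"] = np.inf
        cleaned, _ = clean_features(table, overflow_policy="drop_cell")
        assert "f4" in cleaned.columns
        assert np.isnan(cleaned.loc[5, "f4"])

    def test_rows_with_excess_missing_dropped(self):
        table = self._table(20, n_feats=10)
        table.loc[3, [f"f{i}" for i in range(3)]] = np.nan  # 30% of cells
        cleaned, log = clean_features(table)
        assert len(cleaned) == 19
        assert (log["kind"] == "row").sum() == 1

    def test_all_columns_removed_raises(self):
        table = self._table(50, n_feats=2)
        table["f0"] = 1.0
        table["f1"] = 2.0
        with pytest.raises(ValueError):
            clean_features(table)
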