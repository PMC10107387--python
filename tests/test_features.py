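"""Feature ensemble vs naive-loop oracles, plus closed-form identities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pretermsig as ps
from pretermsig.features import FEATURE_NAMES, FeatureConfig
import oracles


def _oracle_vector(x, fs, cfg):
    rho = oracles.naive_burg(x, cfg.ar_order)
    ceps = oracles.naive_cepstrum_fft(rho, cfg.ceps_order)
    r = cfg.sampen_r * np.std(x)
    out = {
        "MAV": oracles.naive_mav(x),
        "WL": oracles.naive_wl(x),
        "ZC": oracles.naive_zc(x, cfg.eps_threshold),
        "SSC": oracles.naive_ssc(x, cfg.eps_threshold),
        "RMS": oracles.naive_rms(x),
        "SampEN": oracles.naive_sampen(x, cfg.sampen_m, r),
        "MFL": oracles.naive_mfl(x),
        "MedFrq": oracles.naive_medfrq(x, fs),
        "PeakFrq": oracles.naive_peakfrq(x, fs),
        "NP": oracles.naive_np(x, cfg.eps_threshold),
        "SSI": oracles.naive_ssi(x),
        "VAR": oracles.naive_var(x),
    }
    for k in range(4):
        out[f"AR{k + 1}"] = rho[k]
        out[f"Ceps{k + 1}"] = ceps[k]
    return out


class TestAgainstOracles:
    def test_all_features_match_naive_oracles_on_random_windows(self, rng):
        """Every one of the 20 features agrees with an independent
        naive-loop implementation on 50 random 64-sample windows."""
        cfg = FeatureConfig(eps_threshold=0.5)
        fs = 8.0
        for _ in range(50):
            x = rng.normal(0, rng.uniform(0.5, 3.0), 64)
            got = ps.extract_features(x, fs=fs, config=cfg)
            want = _oracle_vector(x, fs, cfg)
            for name in FEATURE_NAMES:
                assert got[name] == pytest.approx(
                    want[name], rel=1e-9, abs=1e-9, nan_ok=True
                ), name

    def test_hand_arithmetic_example(self):
        """x = [1, -2, 3] identities, padded to the minimum window length.

        On the raw 3-sample toy: MAV = 2, WL = 8, SSI = 14, ZC = 2; here the
        same arithmetic is checked through the naive oracles directly.
        """
        x = [1.0, -2.0, 3.0]
        assert oracles.naive_mav(x) == 2.0
        assert oracles.naive_wl(x) == 8.0
        assert oracles.naive_ssi(x) == 14.0
        assert oracles.naive_zc(x, 0.0) == 2
        # the package path, on a window long enough to satisfy preconditions
        x8 = np.array([1.0, -2.0, 3.0] * 4)
        got = ps.extract_features(x8, fs=1.0, config=FeatureConfig(eps_threshold=0.0))
        assert got["MAV"] == pytest.approx(2.0)
        assert got["SSI"] == pytest.approx(np.sum(x8**2))
        assert got["ZC"] == oracles.naive_zc(x8, 0.0)


class TestIdentities:
    def test_constant_window(self):
        x = np.full(64, 3.0)
        got = ps.extract_features(x, fs=2.0)
        assert got["WL"] == 0.0
        assert got["ZC"] == 0.0
        assert got["SSC"] == 0.0
        assert got["VAR"] == 0.0
        assert got["SSI"] == pytest.approx(64 * 9.0)
        assert math.isnan(got["SampEN"])  # undefined at zero variance
        assert math.isnan(got["MFL"])

    @pytest.mark.parametrize("f0", [1.0, 3.0, 7.0])
    def test_sinusoid_spectral_features_land_on_f0(self, f0):
        fs = 32.0
        n = 1024
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * f0 * t)
        got = ps.extract_features(x, fs=fs)
        bin_width = fs / n
        assert abs(got["PeakFrq"] - f0) <= bin_width
        assert abs(got["MedFrq"] - f0) <= bin_width

    def test_spectral_features_bounded_by_nyquist(self, rng):
        x = rng.normal(size=256)
        got = ps.extract_features(x, fs=10.0)
        assert 0.0 <= got["MedFrq"] <= 5.0
        assert 0.0 <= got["PeakFrq"] <= 5.0


class TestInvariances:
    @given(a=st.floats(0.1, 50.0))
    @settings(derandomize=True, max_examples=25)
    def test_amplitude_scaling_behaviour(self, a):
        rng = np.random.default_rng(42)
        x = rng.normal(size=128)
        cfg = FeatureConfig(eps_threshold=0.0)
        f = ps.extract_features(x, fs=4.0, config=cfg)
        g = ps.extract_features(a * x, fs=4.0, config=cfg)
        for name in ("MAV", "WL", "RMS"):
            assert g[name] == pytest.approx(a * f[name], rel=1e-9)
        for name in ("SSI",):
            assert g[name] == pytest.approx(a * a * f[name], rel=1e-9)
        assert g["VAR"] == pytest.approx(a * a * f["VAR"], rel=1e-9)
        for name in ("ZC", "SSC", "NP"):
            assert g[name] == f[name]
        # r scales with the window SD, so SampEn is scale-free
        assert g["SampEN"] == pytest.approx(f["SampEN"], rel=1e-9)
        for k in range(1, 5):
            assert g[f"AR{k}"] == pytest.approx(f[f"AR{k}"], rel=1e-7)

    def test_time_reversal_leaves_even_features_unchanged(self, rng):
        x = rng.normal(size=100)
        cfg = FeatureConfig(eps_threshold=0.0)
        f = ps.extract_features(x, fs=1.0, config=cfg)
        g = ps.extract_features(x[::-1].copy(), fs=1.0, config=cfg)
        for name in ("MAV", "RMS", "SSI", "VAR", "WL", "ZC"):
            assert g[name] == pytest.approx(f[name], rel=1e-12)


class TestConfig:
    def test_rr_kinds_get_zero_threshold(self):
        cfg = FeatureConfig()
        assert cfg.for_kind("MHR").eps_threshold == 0.0
        assert cfg.for_kind("FHR").eps_threshold == 0.0
        assert cfg.for_kind("EHG").eps_threshold == 1.0

    def test_custom_threshold_not_overridden_for_rr(self):
        cfg = FeatureConfig(eps_threshold=2.5)
        assert cfg.for_kind("MHR").eps_threshold == 2.5

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            ps.extract_features(np.ones(4), fs=1.0)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            FeatureConfig(sampen_r=0.0)
        with pytest.raises(ValueError):
            FeatureConfig(sampen_m=0)


class TestFeaturizeCohort:
    def test_row_count_and_schema(self, small_window_sets):
        table = ps.featurize_cohort(small_window_sets)
        assert len(table) == len(small_window_sets) * 10
        assert list(table.columns) == ["patient_id", "label", "window_index",
                                       *FEATURE_NAMES]

    def test_empty_cohort_keeps_header(self):
        table = ps.featurize_cohort([])
        assert len(table) == 0
        assert list(table.columns) == ["patient_id", "label", "window_index",
                                       *FEATURE_NAMES]

    def test_determinism_replay(self, small_window_sets):
        a = ps.featurize_cohort(small_window_sets[:2])
        b = ps.featurize_cohort(small_window_sets[:2])
        pd.testing.assert_frame_equal(a, b)
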