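"""Feature registry, per-family oracles, scaling and selection."""

from importlib import resources

import numpy as np
import pandas as pd
import pytest
import pywt
import yaml
from hypothesis import given
from hypothesis import strategies as st

from remstage.errors import DataError
from remstage.features import (
    FEATURE_NAMES,
    MICROSTRUCTURE_POWER_FEATURES,
    REGISTRY,
    FeatureMatrix,
    apply_scaler,
    approximate_entropy,
    extract_epoch,
    extract_matrix,
    fit_scaler,
    hjorth_parameters,
    registry_manifest,
    teager_kaiser,
    variance_select,
    zero_crossing_rate,
)
from remstage.synthetic import DEFAULT_PROFILES, generate_epoch
from remstage.types import EpochGrid


def _tone_epoch(freq, amp=1.0, rate=256):
    t = np.arange(30 * rate) / rate
    return amp * np.sin(2 * np.pi * freq * t)


class TestRegistry:
    def test_cardinality_and_uniqueness(self):
        assert len(REGISTRY) == 164
        assert len(set(FEATURE_NAMES)) == 164

    def test_category_totals(self):
        counts = {}
        for spec in REGISTRY:
            counts[spec.category] = counts.get(spec.category, 0) + 1
        assert counts == {"time": 24, "frequency": 30, "time_frequency": 104,
                          "nonlinear": 6}

    def test_time_features_use_epoch_window(self):
        for spec in REGISTRY:
            expected = "epoch" if spec.category == "time" else "subepoch_mean"
            assert spec.window == expected, spec.name

    def test_manifest_file_matches_registry(self):
        text = (resources.files("remstage") / "data" / "feature_manifest.yaml"
                ).read_text()
        assert yaml.safe_load(text) == registry_manifest()

    def test_microstructure_subset_in_registry(self):
        assert set(MICROSTRUCTURE_POWER_FEATURES) <= set(FEATURE_NAMES)


class TestExtractEpoch:
    def test_synthetic_epoch_yields_164_finite_values(self):
        x = generate_epoch(DEFAULT_PROFILES["N2"], seed=0)
        vals = extract_epoch(x)
        assert list(vals) == list(FEATURE_NAMES)
        assert all(np.isfinite(v) for v in vals.values())

    def test_zero_signal_degenerate(self):
        vals = extract_epoch(np.zeros(7680))
        assert all(np.isfinite(v) for v in vals.values())
        for name in ("time_mean", "bp_abs_delta", "sef50", "spectral_entropy",
                     "tkeo_mean", "zcr"):
            assert vals[name] == 0.0

    def test_wrong_length_rejected(self, rng):
        with pytest.raises(DataError):
            extract_epoch(rng.standard_normal(7000))

    def test_amplitude_equivariance_classes(self):
        """Every feature responds to a 2x amplitude change as its registry
        equivariance tag says (invariant, linear or quadratic)."""
        x = generate_epoch(DEFAULT_PROFILES["REM_TONIC"], seed=3)
        base = extract_epoch(x)
        scaled = extract_epoch(2.0 * x)
        factor = {"invariant": 1.0, "linear": 2.0, "quadratic": 4.0}
        for spec in REGISTRY:
            expected = factor[spec.equivariance] * base[spec.name]
            assert scaled[spec.name] == pytest.approx(expected, rel=1e-6,
                                                      abs=1e-9), spec.name


class TestFamilyOracles:
    def test_hjorth_activity_is_variance(self, rng):
        x = rng.standard_normal(7680)
        activity, _, _ = hjorth_parameters(x)
        assert activity == pytest.approx(np.var(x))

    def test_hjorth_mobility_sinusoid_closed_form(self):
        """Mobility of a pure tone equals 2*sin(w/2), w in rad/sample."""
        for freq in (5.0, 10.0, 20.0):
            _, mobility, _ = hjorth_parameters(_tone_epoch(freq))
            w = 2 * np.pi * freq / 256
            assert mobility == pytest.approx(2 * np.sin(w / 2), rel=1e-3)

    def test_zcr_tone_crossings(self):
        # 10 Hz over 30 s: two crossings per cycle = 600 total
        zcr = zero_crossing_rate(_tone_epoch(10.0), 256)
        assert zcr * 30 == pytest.approx(600, abs=1)

    def test_coastline_of_ramp(self):
        n, s = 7680, 0.5
        ramp = np.arange(n) * s
        vals = extract_epoch(ramp - ramp.mean())
        assert vals["coastline_d1"] == pytest.approx((n - 1) * s, rel=1e-9)
        assert vals["coastline_d2"] == pytest.approx(0.0, abs=1e-6)

    def test_tkeo_constant_is_zero(self):
        assert np.all(teager_kaiser(np.full(100, 7.0)) == 0)

    def test_tkeo_sinusoid_closed_form(self):
        """psi[n] = A^2 sin^2(w) exactly, at every interior sample."""
        amp, freq = 3.0, 11.0
        w = 2 * np.pi * freq / 256
        psi = teager_kaiser(_tone_epoch(freq, amp=amp))
        np.testing.assert_allclose(psi, amp ** 2 * np.sin(w) ** 2, rtol=1e-6)

    def test_dwt_energy_conservation(self, rng):
        """Orthogonal 5-level decompositions conserve signal energy."""
        x = rng.standard_normal(256)
        for wavelet in ("db4", "haar"):
            coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=5)
            total = sum(float(np.sum(c ** 2)) for c in coeffs)
            assert total == pytest.approx(float(np.sum(x ** 2)), rel=1e-6)

    def test_approximate_entropy_matches_brute_force(self, rng):
        x = rng.standard_normal(120)

        def brute(x, m=2, rf=0.2):
            r = rf * x.std()

            def phi(mm):
                t = np.lib.stride_tricks.sliding_window_view(x, mm)
                d = np.max(np.abs(t[:, None, :] - t[None, :, :]), axis=-1)
                return float(np.mean(np.log(
                    np.count_nonzero(d <= r, axis=1) / t.shape[0])))

            return phi(m) - phi(m + 1)

        assert approximate_entropy(x) == pytest.approx(brute(x), abs=1e-12)

    def test_subepoch_mean_matches_stationary_expectation(self, rng):
        """For white noise the averaged sub-epoch relative band power equals
        the band's share of the flat spectrum."""
        x = rng.standard_normal(7680)
        vals = extract_epoch(x)
        # delta bins {1,2,3} of the 39 reference-band bins {1..39}
        assert vals["bp_rel_delta"] == pytest.approx(3 / 39, abs=0.02)


class TestScaler:
    def test_three_point_column(self):
        df = pd.DataFrame({"a": [0.0, 5.0, 10.0]})
        out = apply_scaler(df, fit_scaler(df))
        assert list(out["a"]) == [-1.0, 0.0, 1.0]

    def test_constant_column_maps_to_zero(self):
        df = pd.DataFrame({"a": [3.0, 3.0, 3.0]})
        assert list(apply_scaler(df, fit_scaler(df))["a"]) == [0.0, 0.0, 0.0]

    def test_unseen_values_not_clipped(self):
        train = pd.DataFrame({"a": [0.0, 10.0]})
        params = fit_scaler(train)
        out = apply_scaler(pd.DataFrame({"a": [12.0]}), params)
        assert out["a"].iloc[0] == pytest.approx(1.4)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_fitted_columns_attain_unit_bounds(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        out = apply_scaler(df, fit_scaler(df))
        assert np.allclose(out.min(axis=0), -1.0)
        assert np.allclose(out.max(axis=0), 1.0)


class TestVarianceSelect:
    def test_alternating_column_kept(self):
        df = pd.DataFrame({"a": [-1.0, 1.0] * 5})
        _, kept = variance_select(df)
        assert kept == ["a"]

    def test_constant_column_removed(self):
        df = pd.DataFrame({"a": [0.0] * 10, "b": [-1.0, 1.0] * 5})
        reduced, kept = variance_select(df)
        assert kept == ["b"]
        assert list(reduced.columns) == ["b"]

    def test_uniform_column_variance_one_third(self):
        # uniform on [-1, 1] has variance 1/3 >= 0.2
        df = pd.DataFrame({"a": np.linspace(-1, 1, 1001)})
        _, kept = variance_select(df)
        assert kept == ["a"]


def test_extract_matrix_roundtrip_csv(tmp_path, rng):
    grid = EpochGrid(["REM", "N2"], rng.standard_normal((2, 7680)) * 20)
    fm = extract_matrix(grid)
    path = fm.to_csv(tmp_path / "f.csv")
    back = FeatureMatrix.from_csv(path)
    assert list(back.stages) == ["REM", "N2"]
    pd.testing.assert_frame_equal(back.features, fm.features)
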