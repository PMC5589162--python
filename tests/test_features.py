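"""Feature families tested against hand values and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from jogrec.features import (
    PERCENTILE_LEVELS,
    BinSpec,
    WoETable,
    autocorr_features,
    basic_stats,
    cross_sensor_correlation,
    curvefit_features,
    extract_original_features,
    fit_bins,
    gender_features,
    histogram_features,
    lag_set,
    make_bins,
    pearson,
    percentile_features,
    power_lag_domain,
    sturges_bins,
)
from jogrec.io import ValidationError
from jogrec.names import all_series

windows = hnp.arrays(
    np.float64,
    st.integers(5, 80),
    elements=st.floats(-1e3, 1e3, allow_nan=False, width=32),
)


class TestBasicStats:
    def test_hand_oracle_1234(self):
        s = basic_stats(np.array([1.0, 2.0, 3.0, 4.0]))
        assert s["min"] == 1 and s["max"] == 4 and s["range"] == 3
        assert s["mean"] == pytest.approx(2.5)
        assert s["std"] == pytest.approx(math.sqrt(5 / 3))
        assert s["variance"] == pytest.approx(5 / 3)
        assert s["harmonic mean"] == pytest.approx(4 / (1 + 1 / 2 + 1 / 3 + 1 / 4))
        assert s["geometric mean"] == pytest.approx(24 ** 0.25)
        assert s["skewness"] == pytest.approx(0.0)
        # kurtosis m4 / s^4 with the sample (ddof=1) standard deviation
        m4 = np.mean((np.array([1, 2, 3, 4]) - 2.5) ** 4)
        assert s["kurtosis"] == pytest.approx(m4 / (5 / 3) ** 2)
        assert s["snr"] == pytest.approx(2.5 / math.sqrt(5 / 3))
        assert s["energy"] == pytest.approx(30.0)
        assert s["energy/n"] == pytest.approx(7.5)

    def test_energy_variants(self):
        x = np.array([1.0, 2.0, 3.0])
        assert basic_stats(x, energy="squared")["energy"] == 14.0
        assert basic_stats(x, energy="printed")["energy"] == 6.0

    def test_mode_tie_takes_smallest(self):
        assert basic_stats(np.array([3.0, 1.0, 1.0, 3.0, 2.0]))["mode"] == 1.0

    def test_zero_variance_window(self):
        s = basic_stats(np.full(10, 7.0))
        assert s["std"] == 0 and s["skewness"] == 0 and s["kurtosis"] == 0
        assert s["snr"] == 0

    def test_nonpositive_values_zero_means(self):
        s = basic_stats(np.array([0.0, 1.0, 2.0]))
        assert s["geometric mean"] == 0.0 and s["harmonic mean"] == 0.0

    def test_fourteen_features(self):
        assert len(basic_stats(np.arange(10.0))) == 14

    def test_stacked_matches_rowwise(self, rng):
        X = rng.normal(size=(6, 30))
        stacked = basic_stats(X)
        for i in range(6):
            row = basic_stats(X[i])
            for k, v in row.items():
                assert stacked[k][i] == pytest.approx(v)


class TestHistograms:
    def test_sturges(self):
        assert sturges_bins(60) == 7
        assert sturges_bins(180) == 9

    def test_make_bins_equal_width(self):
        spec = make_bins(np.array([0.0, 14.0]), 60)
        assert spec.h == 7
        np.testing.assert_allclose(np.diff(spec.edges), 2.0)

    def test_degenerate_range_widened(self):
        spec = make_bins(np.full(20, 5.0), 60)
        assert spec.edges[0] == 4.5 and spec.edges[-1] == 5.5

    def test_counts_against_numpy(self, rng):
        spec = make_bins(np.array([0.0, 70.0]), 60)
        x = rng.uniform(0.001, 69.999, 60)
        feats = histogram_features(x, spec)
        expected, _ = np.histogram(x, bins=np.asarray(spec.edges))
        assert [feats[lab] for lab in spec.labels()] == list(expected)

    def test_out_of_range_clips_to_terminal_bins(self):
        spec = make_bins(np.array([0.0, 7.0]), 60)
        feats = histogram_features(np.array([-5.0, -1.0, 8.0]), spec)
        labels = spec.labels()
        assert feats[labels[0]] == 2.0
        assert feats[labels[-1]] == 1.0

    @given(windows)
    def test_conservation(self, x):
        spec = make_bins(x, 60)
        feats = histogram_features(x, spec)
        assert sum(feats.values()) == x.size

    def test_binspec_validation(self):
        with pytest.raises(ValidationError):
            BinSpec("s", 2, (0.0, 1.0))  # wrong edge count
        with pytest.raises(ValidationError):
            BinSpec("s", 2, (0.0, 1.0, 1.0))  # not increasing


def percentile_oracle(x, q):
    """Textbook linear-interpolation percentile, independent of numpy."""
    s = sorted(x)
    h = (len(s) - 1) * q / 100.0
    lo = math.floor(h)
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


class TestPercentiles:
    @given(windows)
    def test_against_bruteforce_oracle(self, x):
        feats = percentile_features(x)
        for q in (25, 50, 75) + PERCENTILE_LEVELS:
            name = {25: "perc. 25", 50: "median", 75: "perc. 75"}.get(q, f"perc. {q}")
            assert feats[name] == pytest.approx(percentile_oracle(x, q), abs=1e-9)
        assert feats["IQR"] == pytest.approx(
            percentile_oracle(x, 75) - percentile_oracle(x, 25), abs=1e-9
        )

    def test_fourteen_features(self):
        assert len(percentile_features(np.arange(20.0))) == 14


class TestCorrelations:
    def test_hand_oracle(self):
        r = pearson(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
        assert r == pytest.approx(9 / math.sqrt(6 * 14))

    @given(windows, st.randoms(use_true_random=False))
    def test_against_numpy(self, x, rnd):
        y = np.array([rnd.uniform(-100, 100) for _ in x])
        r = pearson(x, y)
        if np.std(x) > 1e-9 and np.std(y) > 1e-9:
            assert r == pytest.approx(float(np.corrcoef(x, y)[0, 1]), abs=1e-8)
        assert -1.0 <= r <= 1.0

    def test_zero_variance_yields_zero(self):
        assert pearson(np.full(10, 3.0), np.arange(10.0)) == 0.0

    def test_cross_sensor_is_pearson(self, rng):
        a, b = rng.normal(size=(2, 60))
        assert cross_sensor_correlation(a, b) == pearson(a, b)


class TestAutocorrelation:
    def test_lag_sets(self):
        assert lag_set(60) == (1, 2, 4, 30)
        assert lag_set(180) == (1, 2, 4, 90)
        with pytest.raises(ValidationError):
            lag_set(90)
        assert power_lag_domain(60) == (2, 4, 8, 16, 30)

    def test_alternating_window_oracle(self):
        # x = 0,2,0,2,... (n=60): deviations are -1,+1 alternating, so the
        # classical statistic is +/- sum(dev^2 over n - tau terms) divided by
        # (n - tau) * unbiased variance = -(59/60) at lag 1, +(59/60) at lag 2
        x = np.tile([0.0, 2.0], 30)
        feats = autocorr_features(x, 60)
        assert feats["auto-corr t = 1"] == pytest.approx(-59 / 60)
        assert feats["auto-corr t = 2"] == pytest.approx(59 / 60)
        assert feats["auto-pearson t = 1"] == pytest.approx(-1.0)
        assert feats["auto-pearson t = 2"] == pytest.approx(1.0)

    def test_bruteforce_oracle(self, rng):
        x = rng.normal(size=60)
        feats = autocorr_features(x, 60)
        n, mean, var = 60, x.mean(), x.var(ddof=1)
        for tau in (1, 2, 4, 30):
            classical = sum(
                (x[i] - mean) * (x[i + tau] - mean) for i in range(n - tau)
            ) / ((n - tau) * var)
            assert feats[f"auto-corr t = {tau}"] == pytest.approx(classical)
            lagged = np.corrcoef(x[: n - tau], x[tau:])[0, 1]
            assert feats[f"auto-pearson t = {tau}"] == pytest.approx(lagged)

    def test_zero_variance_yields_zeros(self):
        feats = autocorr_features(np.full(60, 2.0), 60)
        assert all(v == 0.0 for v in feats.values())

    def test_eight_features(self):
        assert len(autocorr_features(np.arange(60.0), 60)) == 8


class TestCurveFit:
    def test_exact_polynomials(self):
        t = np.arange(30, dtype=float)
        lin = curvefit_features(5 * t + 2)
        assert lin["lin fit c1"] == pytest.approx(5.0)
        assert lin["lin fit c0"] == pytest.approx(2.0)
        quad = curvefit_features(2 * t**2 + 3 * t + 1)
        assert quad["quad fit c2"] == pytest.approx(2.0)
        assert quad["quad fit c1"] == pytest.approx(3.0)
        assert quad["quad fit c0"] == pytest.approx(1.0)

    @given(windows)
    def test_against_polyfit(self, x):
        feats = curvefit_features(x)
        t = np.arange(x.size, dtype=float)
        c1, c0 = np.polyfit(t, x, 1)
        assert feats["lin fit c1"] == pytest.approx(c1, abs=1e-6)
        assert feats["lin fit c0"] == pytest.approx(c0, abs=1e-5)
        q2, q1, q0 = np.polyfit(t, x, 2)
        assert feats["quad fit c2"] == pytest.approx(q2, abs=1e-6)
        assert feats["quad fit c1"] == pytest.approx(q1, abs=1e-5)
        assert feats["quad fit c0"] == pytest.approx(q0, abs=1e-4)


class TestWoE:
    def test_hand_oracle(self):
        gender = ["male"] * 5 + ["female"] * 5
        labels = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        woe = WoETable().fit(gender, labels)
        # jog: male 3, female 1; non: male 2, female 4; K = 2 categories
        assert woe.table["male"] == pytest.approx(math.log((3.5 / 5.0) / (2.5 / 7.0)))
        assert woe.table["female"] == pytest.approx(math.log((1.5 / 5.0) / (4.5 / 7.0)))

    def test_unseen_category_is_zero(self):
        woe = WoETable().fit(["male"] * 4, [1, 1, 0, 0])
        assert woe.transform(["female"])[0] == 0.0

    def test_smoothing_keeps_finite_on_empty_cells(self):
        woe = WoETable().fit(["male", "male", "female", "female"], [1, 1, 0, 0])
        assert np.all(np.isfinite(woe.transform(["male", "female"])))

    def test_gender_features(self):
        woe = WoETable().fit(["male", "female"], [1, 0])
        out = gender_features(["male", "female", "male"], woe)
        np.testing.assert_array_equal(out["gender is_male"], [1, 0, 1])
        np.testing.assert_array_equal(out["gender is_female"], [0, 1, 0])
        assert out["gender WoE"][0] == pytest.approx(woe.table["male"])


class TestExtraction:
    def fit(self, dataset):
        woe = WoETable().fit(dataset.gender, dataset.labels)
        return fit_bins(dataset), woe

    def test_580_columns_at_60s(self, small_dataset_60):
        ds = small_dataset_60["train"]
        bins, woe = self.fit(ds)
        m = extract_original_features(ds, bins, woe)
        assert len(m.feature_names) == 580
        for series in all_series():
            per_series = [c for c in m.feature_names if c.startswith(series + " ")]
            assert len(per_series) == 48, series

    def test_604_columns_at_180s(self, small_dataset_180):
        ds = small_dataset_180["train"]
        bins, woe = self.fit(ds)
        m = extract_original_features(ds, bins, woe)
        assert len(m.feature_names) == 604
        assert sum(c.startswith("HipAxis1 ") for c in m.feature_names) == 50

    def test_gender_and_cross_columns(self, small_dataset_60):
        ds = small_dataset_60["train"]
        bins, woe = self.fit(ds)
        m = extract_original_features(ds, bins, woe)
        assert "cross-corr HipMag AnkleMag" in m.feature_names
        assert sum(c.startswith("gender ") for c in m.feature_names) == 3

    def test_all_values_finite(self, small_dataset_60):
        # FeatureMatrix construction itself enforces finiteness; reaching
        # here without ValidationError is the assertion
        ds = small_dataset_60["validation"]
        bins, woe = self.fit(ds)
        m = extract_original_features(ds, bins, woe)
        assert np.all(np.isfinite(m.X()))
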