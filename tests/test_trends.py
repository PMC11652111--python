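import math
import warnings

import numpy as np
import pandas as pd
import pytest

from elevdiv.belts import attach_areas
from elevdiv.trends import (
    fit_gaussian,
    fit_quasipoisson,
    native_nonnative_correlation,
    nri_trend,
    peak_determinants,
    peak_elevation,
    richness_area_fit,
)

from .conftest import matrix_from_sets


def irls_oracle(x, y, tol=1e-10):
    """Independent Fisher-scoring IRLS for the log-link Poisson slope."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    beta[0] = math.log(max(np.mean(y), 1e-8))
    for _ in range(200):
        mu = np.exp(X @ beta)
        W = mu
        z = X @ beta + (y - mu) / mu
        XtW = X.T * W
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    raise RuntimeError("oracle IRLS did not converge")


class TestQuasiPoisson:
    def test_constant_response(self):
        f = fit_quasipoisson([0, 1, 2, 3], [5, 5, 5, 5])
        assert f.slope == 0.0 and f.pseudo_r2 == 0.0

    def test_noiseless_loglinear_slope_and_oracle(self):
        x = np.arange(9.0)
        y = np.round(np.exp(1 + 0.5 * x))
        f = fit_quasipoisson(x, y)
        assert abs(f.slope - 0.5) < 0.02
        beta = irls_oracle(x, y)
        assert f.slope == pytest.approx(beta[1], rel=1e-6)
        assert f.intercept == pytest.approx(beta[0], rel=1e-6)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(100)
        slopes = []
        for _ in range(50):
            x = rng.uniform(0, 4, 50)
            y = rng.poisson(np.exp(0.5 + 0.3 * x))
            slopes.append(fit_quasipoisson(x, y).slope)
        se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.3) < 2 * se + 1e-3

    def test_slope_invariant_to_count_scaling(self):
        rng = np.random.default_rng(4)
        x = np.arange(20.0)
        y = rng.poisson(np.exp(1 + 0.1 * x)) + 1
        f1 = fit_quasipoisson(x, y)
        f7 = fit_quasipoisson(x, 7 * y)
        assert f7.slope == pytest.approx(f1.slope, abs=1e-8)
        assert f7.intercept == pytest.approx(f1.intercept + math.log(7), abs=1e-8)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_quasipoisson([1, 2, 3], [0, 0, 0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_quasipoisson([1, 2], [1, 2])

    def test_nonint_warns(self):
        with pytest.warns(UserWarning, match="non-integer"):
            fit_quasipoisson([1, 2, 3, 4], [1.5, 2.5, 3.0, 4.0])


class TestRichnessArea:
    def test_requires_areas(self):
        m = matrix_from_sets([{"a"}, {"a", "b"}, {"b"}])
        with pytest.raises(ValueError, match="areas"):
            richness_area_fit(m)

    def test_constant_richness_zero_slope(self):
        m = matrix_from_sets([{"a", "b"}, {"a", "b"}, {"a", "b"}])
        areas = pd.DataFrame(
            {"mountain_id": "test", "belt_lo": [0.0, 100.0, 200.0], "area_km2": [5, 9, 3]}
        )
        f = richness_area_fit(attach_areas(m, areas))
        assert f.slope == 0.0 and f.pseudo_r2 == 0.0

    def test_richness_tracking_area_positive_significant(self):
        rng = np.random.default_rng(8)
        # hump-shaped area; richness proportional to area with Poisson noise
        areas_v = 20 + 80 * np.exp(-((np.arange(12) - 6) ** 2) / 8)
        sets = []
        for i, a in enumerate(areas_v):
            k = rng.poisson(a / 2) + 1
            sets.append({f"s{i}_{j}" for j in range(k)})
        m = matrix_from_sets(sets)
        areas = pd.DataFrame(
            {"mountain_id": "test", "belt_lo": m.grid.lower_bounds, "area_km2": areas_v}
        )
        f = richness_area_fit(attach_areas(m, areas))
        assert f.slope > 0 and f.p_value < 0.05


class TestNativeNonnative:
    def test_perfect_proportionality(self):
        sets = []
        for i, n in enumerate([10, 20, 30]):
            s = {f"nat{i}_{j}" for j in range(n)} | {f"ali{i}_{j}" for j in range(n // 10)}
            sets.append(s)
        m = matrix_from_sets(sets)
        aliens = {t for t in m.taxa if t.startswith("ali")}
        res = native_nonnative_correlation(m, aliens)
        assert res["r"] == pytest.approx(1.0)

    def test_constant_alien_richness_flagged(self):
        sets = [{"n1", "n2", "a1"}, {"n1", "a1"}, {"n1", "n2", "n3", "a1"}]
        m = matrix_from_sets(sets)
        res = native_nonnative_correlation(m, {"a1"})
        assert res["flagged"] and math.isnan(res["r"])


class TestNriTrend:
    def make_profile(self, nri_vals, evaluable=None):
        n = len(nri_vals)
        return pd.DataFrame(
            {
                "midpoint": 50.0 + 100.0 * np.arange(n),
                "nri": nri_vals,
                "evaluable": evaluable if evaluable is not None else [True] * n,
            }
        )

    def test_noiseless_line_recovered(self):
        prof = self.make_profile(list(2.0 - 0.002 * (50 + 100 * np.arange(8))))
        f = nri_trend(prof)
        assert f.slope == pytest.approx(-0.002, abs=1e-12)
        assert f.classification == "clustering_decreasing"

    def test_too_few_belts(self):
        with pytest.raises(ValueError):
            nri_trend(self.make_profile([0.1, 0.2]))

    def test_shuffled_values_usually_flat(self):
        rng = np.random.default_rng(12)
        base = 2.0 - 0.1 * np.arange(10)
        flat = 0
        for _ in range(50):
            f = nri_trend(self.make_profile(list(rng.permutation(base))))
            flat += f.p_value > 0.05
        assert flat >= 45  # >= 90% of permutations show no significant trend


class TestPeaks:
    def test_monotone_decreasing_peak_at_base(self):
        s = pd.Series([30, 20, 10], index=[50.0, 150.0, 250.0])
        assert peak_elevation(s) == 50.0

    def test_peak_in_named_belt(self):
        s = pd.Series([5, 9, 7], index=[450.0, 550.0, 650.0])
        assert peak_elevation(s) == 550.0

    def test_tie_breaks_low_and_shift_invariance(self):
        s = pd.Series([9, 9, 3], index=[50.0, 150.0, 250.0])
        assert peak_elevation(s) == 50.0
        assert peak_elevation(s + 17) == 50.0


class TestPeakDeterminants:
    def attrs(self, rel):
        return pd.DataFrame(
            {
                "mountain_id": [f"m{i}" for i in range(len(rel))],
                "relative_elevation_m": rel,
                "longitude_deg": np.linspace(108, 118, len(rel)),
                "amt_c": np.linspace(12, 18, len(rel)),
                "ap_mm": np.linspace(1200, 1900, len(rel)),
            }
        )

    def test_exact_proportionality_r2_one(self):
        rel = [1000.0, 1500.0, 2000.0, 2500.0, 3000.0]
        peaks = {f"m{i}": 0.5 * r for i, r in enumerate(rel)}
        fits = peak_determinants(peaks, self.attrs(rel), family="gaussian")
        by_pred = {f.predictor: f for f in fits}
        assert by_pred["relative_elevation_m"].pseudo_r2 == pytest.approx(1.0)
        assert by_pred["relative_elevation_m"].slope == pytest.approx(0.5)

    def test_quasipoisson_family_available(self):
        rel = [1000.0, 1500.0, 2000.0, 2500.0]
        peaks = {f"m{i}": 200 + 0.4 * r for i, r in enumerate(rel)}
        fits = peak_determinants(peaks, self.attrs(rel), family="quasipoisson")
        assert all(f.family == "quasipoisson" for f in fits) and len(fits) == 4

    def test_fewer_than_four_mountains_rejected(self):
        rel = [1000.0, 1500.0, 2000.0]
        peaks = {f"m{i}": r for i, r in enumerate(rel)}
        with pytest.raises(ValueError, match="4 mountains"):
            peak_determinants(peaks, self.attrs(rel))

    def test_permuted_attribute_explains_little_on_average(self):
        rng = np.random.default_rng(31)
        rel = np.array([800.0, 1200, 1700, 2100, 2500, 3000, 1400, 1900])
        peaks_v = 0.45 * rel
        r2s = []
        for _ in range(30):
            perm = rng.permutation(rel)
            peaks = {f"m{i}": p for i, p in enumerate(peaks_v)}
            fits = peak_determinants(peaks, self.attrs(perm), family="gaussian")
            r2s.append({f.predictor: f for f in fits}["relative_elevation_m"].pseudo_r2)
        assert np.mean(r2s) < 0.4


def test_gaussian_fit_basics():
    x = np.arange(10.0)
    f = fit_gaussian(x, 3.0 + 2.0 * x)
    assert f.slope == pytest.approx(2.0) and f.pseudo_r2 == pytest.approx(1.0)
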