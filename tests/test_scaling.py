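import numpy as np
import pandas as pd
import pytest

from conflictcascades import (DynamicalScalingFit, PowerLawFit,
                              avalanche_properties, check_exponent_relation,
                              fit_dynamical_scaling, fit_power_law)
from conflictcascades.avalanches import Avalanche
from conflictcascades.scaling import _alpha_mle_continuous
from conflictcascades.tessellation import Tessellation


def pareto(n, alpha, xmin=1.0, seed=0):
    rng = np.random.default_rng(seed)
    return xmin * (1.0 - rng.random(n)) ** (-1.0 / (alpha - 1.0))


def toy_tess(n):
    t = Tessellation(centers_lon=np.arange(n, dtype=float),
                     centers_lat=np.zeros(n), region=None, scale_b=100.0,
                     seed=0, adjacency=[set() for _ in range(n)])
    t.__dict__["cell_areas_km2"] = np.full(n, 100.0)  # fixed areas for testing
    return t


def events_at(rows):
    """rows = [(event_id, lon, lat, fatalities), ...]"""
    return pd.DataFrame({
        "event_id": [r[0] for r in rows],
        "lon": [r[1] for r in rows],
        "lat": [r[2] for r in rows],
        "fatalities": [r[3] for r in rows],
    })


class TestAvalancheProperties:
    def test_single_event_avalanche(self):
        av = Avalanche(0, {(2, 3)}, {"E0"})
        props = avalanche_properties([av], events_at([("E0", 4.0, 1.0, 7)]),
                                     toy_tess(5))
        row = props.iloc[0]
        assert (row["F"], row["R"], row["T"], row["N"], row["L"]) == (7, 1, 1, 1, 0.0)
        assert row["A"] == pytest.approx(100.0)

    def test_diameter_matches_pairwise_brute_force(self):
        from conflictcascades._geo import haversine_km

        rng = np.random.default_rng(1)
        pts = [(f"E{i}", float(rng.uniform(0, 5)), float(rng.uniform(-3, 3)), 0)
               for i in range(3)]
        av = Avalanche(0, {(0, 0)}, {p[0] for p in pts})
        props = avalanche_properties([av], events_at(pts), toy_tess(2))
        best = max(haversine_km(a[1], a[2], b[1], b[2])
                   for i, a in enumerate(pts) for b in pts[i + 1:])
        assert props.iloc[0].L == pytest.approx(best)

    def test_duration_is_inclusive_bin_span(self):
        av = Avalanche(0, {(0, 2), (0, 5)}, {"E0", "E1"})
        props = avalanche_properties([av], events_at([("E0", 1, 1, 0),
                                                      ("E1", 1, 1, 0)]), toy_tess(1))
        assert props.iloc[0]["T"] == 4


class TestPowerLawFit:
    def test_continuous_mle_matches_grid_search(self):
        x = pareto(2000, 2.4, seed=3)
        xmin = 1.0
        mle = _alpha_mle_continuous(x, xmin)
        grid = np.linspace(1.5, 4.0, 2501)
        ll = [x.size * np.log(a - 1) - a * np.sum(np.log(x / xmin)) for a in grid]
        assert abs(mle - grid[int(np.argmax(ll))]) < 1e-3

    def test_recovers_planted_continuous_exponent(self):
        x = pareto(4000, 2.5, seed=0)
        fit = fit_power_law(x, discrete=False, n_bootstrap=100, n_gof=0, rng=1)
        assert abs(fit.alpha_ - 2.5) < 3 * fit.alpha_sd_
        assert 0.5 <= fit.xmin_ <= 2.0

    def test_recovers_planted_discrete_exponent(self):
        rng = np.random.default_rng(2)
        x = rng.zipf(2.2, 5000).astype(float)
        fit = fit_power_law(x, discrete=True, n_bootstrap=50, n_gof=0, rng=1)
        assert abs(fit.alpha_ - 2.2) < max(3 * fit.alpha_sd_, 0.1)

    def test_degenerate_equal_samples_rejected(self):
        with pytest.raises(ValueError, match="degenerate|equal"):
            fit_power_law(np.full(100, 3.0))

    def test_bootstrap_sd_shrinks_like_root_n(self):
        sd = {}
        for n in (1000, 4000):
            x = pareto(n, 2.5, seed=7)
            fit = PowerLawFit(xmin=1.0, n_bootstrap=300, n_gof=0,
                              random_state=3).fit(x)
            sd[n] = fit.alpha_sd_
        assert abs(sd[1000] / sd[4000] - 2.0) / 2.0 < 0.3

    def test_sklearn_params_round_trip(self):
        fit = PowerLawFit(discrete=True, n_gof=7)
        params = fit.get_params()
        assert params["discrete"] is True and params["n_gof"] == 7
        fit.set_params(n_gof=9)
        assert fit.n_gof == 9


class TestDynamicalScaling:
    def test_exact_quadratic_recovered_to_machine_precision(self):
        T = np.geomspace(1, 300, 500)
        fit = fit_dynamical_scaling(np.column_stack([T, T**2]))
        assert fit.gamma_ == pytest.approx(2.0, abs=1e-10)

    def test_noisy_power_law_within_tolerance(self):
        rng = np.random.default_rng(5)
        T = (1 - rng.random(2000)) ** (-1.0)
        X = T**1.5 * np.exp(rng.normal(0, 0.2, T.size))
        fit = fit_dynamical_scaling(np.column_stack([T, X]))
        assert 1.4 <= fit.gamma_ <= 1.6

    def test_all_pairs_below_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            DynamicalScalingFit(t_min=100.0, x_min=100.0).fit(
                np.column_stack([np.arange(1, 10), np.arange(1, 10)]))


class TestExponentRelation:
    def test_identity_case_predicts_exactly(self):
        x = pareto(3000, 2.3, seed=1)
        fit = PowerLawFit(xmin=1.0, n_bootstrap=50, n_gof=0, random_state=0).fit(x)
        T = np.geomspace(1, 100, 200)
        dyn = fit_dynamical_scaling(np.column_stack([T, T]))  # gamma = 1
        rel = check_exponent_relation(fit, fit, dyn)
        assert rel.measured == pytest.approx(rel.predicted, abs=1e-9)
        assert rel.compatible

    def test_change_of_variables_orientation(self):
        # T ~ alpha=2 tail, F = T^2 -> P(F) tail exponent tau = 1 + (alpha-1)/2
        T = pareto(30000, 2.0, seed=4)
        F = T**2
        size_fit = PowerLawFit(xmin=1.0, n_bootstrap=60, n_gof=0,
                               random_state=0).fit(F)
        dur_fit = PowerLawFit(xmin=1.0, n_bootstrap=60, n_gof=0,
                              random_state=0).fit(T)
        dyn = fit_dynamical_scaling(np.column_stack([T, F]))
        rel = check_exponent_relation(size_fit, dur_fit, dyn)
        assert rel.compatible
        assert rel.predicted == pytest.approx(0.5, abs=0.05)

    def test_incompatible_fits_flagged(self):
        a = PowerLawFit(xmin=1.0, n_bootstrap=50, n_gof=0,
                        random_state=0).fit(pareto(5000, 3.0, seed=2))
        b = PowerLawFit(xmin=1.0, n_bootstrap=50, n_gof=0,
                        random_state=0).fit(pareto(5000, 1.5, seed=3))
        T = np.geomspace(1, 100, 200)
        dyn = fit_dynamical_scaling(np.column_stack([T, T]))
        rel = check_exponent_relation(a, b, dyn)
        assert not rel.compatible
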