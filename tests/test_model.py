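import datetime as dt

import numpy as np
import pandas as pd
import pytest

import sealight as sl
from sealight.io import Raster
from sealight.model import (ModelCandidate, build_grid, candidate_models,
                            fit_mixed_model, prepare_model_frame)


class TestSeasonOf:
    @pytest.mark.parametrize("date, season", [
        (dt.date(2002, 1, 15), "summer"),
        (dt.date(2002, 12, 1), "summer"),
        (dt.date(2002, 3, 1), "autumn"),
        (dt.date(2002, 6, 1), "winter"),
        (dt.date(2002, 8, 31), "winter"),
        (dt.date(2002, 11, 30), "spring"),
        (dt.date(2002, 9, 1), "spring"),
    ])
    def test_austral_month_mapping(self, date, season):
        assert sl.season_of(date) == season

    def test_every_month_mapped(self):
        seasons = {sl.season_of(dt.date(2002, m, 10)) for m in range(1, 13)}
        assert seasons == {"summer", "autumn", "winter", "spring"}


def noon_frame(rows):
    return pd.DataFrame(rows, columns=["seal", "date", "lat", "lon",
                                       "la250", "n_profiles"])


def flat_raster(value, lat0, lon0, n=30, res=0.1, start=None, n_days=8,
                units="mg m-3"):
    vals = np.full((n, n), value, dtype=float)
    lat = lat0 + res * (np.arange(n) + 0.5)
    lon = lon0 + res * (np.arange(n) + 0.5)
    return Raster(vals, lat, lon, units=units, time_start=start, n_days=n_days)


WINDOW = dt.date(2002, 11, 1)  # start of an 8-day window (doy 305 = 38*8+1)


def default_grids(chl=0.5, ice=0.0):
    chl_r = flat_raster(chl, -57.0, 157.0, start=WINDOW)
    ice_days = [flat_raster(ice, -57.0, 157.0, n=12, res=0.25,
                            start=WINDOW + dt.timedelta(days=i), n_days=1,
                            units="fraction")
                for i in range(8)]
    bathy = flat_raster(4200.0, -57.0, 157.0, units="m", n_days=None,
                        start=None)
    return chl_r, ice_days, bathy


class TestBuildGrid:
    def test_seal_is_part_of_the_cell_key(self):
        chl_r, ice, bathy = default_grids()
        noon = noon_frame([
            ("a", WINDOW, -56.5, 157.5, 0.3, 4),
            ("b", WINDOW, -56.5, 157.5, 0.3, 4),
        ])
        cells, ledger = build_grid(noon, [chl_r], ice, bathy)
        assert len(cells) == 2 and cells["retained"].all()
        assert ledger["cells_in"] == 2

    def test_cell_below_three_profiles_dropped(self):
        chl_r, ice, bathy = default_grids()
        noon = noon_frame([("a", WINDOW, -56.5, 157.5, 0.3, 2)])
        cells, ledger = build_grid(noon, [chl_r], ice, bathy)
        assert ledger["estimates_below_min_profiles"] == 1
        assert ledger["cells_in"] == 0

    def test_cloud_masked_cell_kept_without_chl(self):
        chl_r, ice, bathy = default_grids(chl=np.nan)
        noon = noon_frame([("a", WINDOW, -56.5, 157.5, 0.3, 4)])
        cells, ledger = build_grid(noon, [chl_r], ice, bathy)
        assert len(cells) == 1
        assert not cells["retained"].iloc[0]
        assert cells["drop_reason"].iloc[0] == "no_chl_match"
        assert np.isnan(cells["mean_log_chl"].iloc[0])

    def test_ice_covered_location_excluded(self):
        chl_r, ice, bathy = default_grids(ice=0.5)
        noon = noon_frame([("a", WINDOW, -56.5, 157.5, 0.3, 4)])
        cells, ledger = build_grid(noon, [chl_r], ice, bathy)
        assert ledger["cells_dropped_ice"] == 1

    def test_band_and_winter_exclusions(self):
        winter_window = dt.date(2002, 6, 27)  # doy 178 = 22*8+1, winter
        chl_w = flat_raster(0.5, -57.0, 157.0, start=winter_window)
        chl_n = flat_raster(0.5, -46.0, 157.0, start=WINDOW)
        ice = [flat_raster(0.0, -57.0, 157.0, n=12, res=0.25,
                           start=winter_window + dt.timedelta(days=i), n_days=1)
               for i in range(8)]
        noon = noon_frame([
            ("a", winter_window, -56.5, 157.5, 0.3, 4),   # winter
            ("a", WINDOW, -45.5, 157.5, 0.3, 4),          # north of the band
        ])
        cells, ledger = build_grid(noon, [chl_w, chl_n], ice, None)
        assert ledger["cells_dropped_band_season"] == 2
        assert ledger["cells_retained"] == 0

    def test_filter_ledger_sums_exactly(self):
        chl_r, ice, bathy = default_grids()
        noon = noon_frame([
            ("a", WINDOW, -56.5, 157.2, 0.30, 4),
            ("a", WINDOW + dt.timedelta(days=1), -56.5, 157.3, 0.32, 5),
            ("b", WINDOW, -56.5, 157.5, 0.28, 3),
            ("b", WINDOW, -45.0, 157.5, 0.28, 3),   # out of band
            ("c", WINDOW, -56.5, 157.5, 0.28, 2),   # below min profiles
        ])
        cells, ledger = build_grid(noon, [chl_r], ice, bathy)
        assert (ledger["cells_in"]
                == ledger["cells_retained"]
                + ledger["cells_dropped_few_profiles"]
                + ledger["cells_dropped_ice"]
                + ledger["cells_dropped_band_season"]
                + ledger["cells_dropped_no_chl"])
        # two same-cell days of seal a collapse into one cell
        a_cells = cells[cells["seal"] == "a"]
        assert len(a_cells) == 1 and a_cells["n_profiles"].iloc[0] == 9

    def test_mean_bathymetry_attached(self):
        chl_r, ice, bathy = default_grids()
        noon = noon_frame([("a", WINDOW, -56.5, 157.5, 0.3, 4)])
        cells, _ = build_grid(noon, [chl_r], ice, bathy)
        assert cells["mean_bathymetry"].iloc[0] == pytest.approx(4200.0)


class TestCandidateSet:
    def test_sixteen_candidates(self):
        assert len(candidate_models()) == 16

    def test_null_model_is_last(self):
        cands = candidate_models()
        assert cands[-1].terms == ()
        assert cands[-1].formula_rhs == "1"

    def test_terms_are_subsets_of_the_interaction_lattice(self):
        allowed = {"LA", "lat", "S", "LA:S", "LA:lat", "S:lat", "LA:S:lat"}
        for cand in candidate_models():
            assert set(cand.terms) <= allowed

    def test_top_candidate_matches_published_winner(self):
        assert candidate_models()[0].terms == ("LA", "lat", "S", "LA:lat", "S:lat")

    def test_labels_unique(self):
        labels = [c.label for c in candidate_models()]
        assert len(set(labels)) == 16


def simulated_cells(seed=0, n_seals=6, n_per_seal=40, beta=1.0,
                    seal_sd=0.1, noise_sd=0.2, season_effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_seals):
        intercept = rng.normal(0.0, seal_sd)
        la = rng.normal(-1.2, 0.4, n_per_seal)
        season = rng.choice(["spring", "summer"], n_per_seal)
        lat = rng.choice(np.arange(-63.5, -52.0), n_per_seal)
        y = (intercept + beta * la + season_effect * (season == "summer")
             + rng.normal(0, noise_sd, n_per_seal))
        for i in range(n_per_seal):
            rows.append({"seal": f"s{s}", "mean_log_la250": la[i],
                         "mean_log_chl": y[i], "lat_centre": lat[i],
                         "season": season[i], "retained": True})
    return pd.DataFrame(rows)


class TestMixedModelFitting:
    def test_recovers_planted_slope(self):
        cells = simulated_cells(seed=1, beta=0.8)
        fit = fit_mixed_model(cells, "LA250")
        assert fit.la_coefficient == pytest.approx(0.8, abs=3 * fit.la_se)
        assert fit.criterion == "ML" and fit.converged

    def test_ml_loglik_non_decreasing_in_nested_models(self):
        cells = simulated_cells(seed=2)
        simple = fit_mixed_model(cells, "LA250")
        fuller = fit_mixed_model(cells, "LA250+lat")
        assert fuller.loglik >= simple.loglik - 1e-6

    def test_response_shift_moves_only_the_intercept(self):
        cells = simulated_cells(seed=3)
        fit1 = fit_mixed_model(cells, "LA250+lat")
        shifted = cells.assign(mean_log_chl=cells["mean_log_chl"] + 2.5)
        fit2 = fit_mixed_model(shifted, "LA250+lat")
        assert fit2.params["Intercept"] - fit1.params["Intercept"] == pytest.approx(2.5, abs=1e-4)
        assert fit2.la_coefficient == pytest.approx(fit1.la_coefficient, abs=1e-5)

    def test_aic_definition_under_ml(self):
        fit = fit_mixed_model(simulated_cells(seed=4), "LA250")
        assert fit.aic == pytest.approx(2 * fit.df - 2 * fit.loglik)

    def test_reml_flagged_for_final_fits(self):
        fit = fit_mixed_model(simulated_cells(seed=5), "LA250", criterion="REML")
        assert fit.criterion == "REML"

    def test_needs_two_seals(self):
        cells = simulated_cells(seed=6, n_seals=1)
        with pytest.raises(ValueError, match="2 seals"):
            fit_mixed_model(cells, "LA250")


class TestSelection:
    def test_best_model_has_zero_delta_aic(self):
        sel = sl.select_model(simulated_cells(seed=7, season_effect=0.4))
        assert sel.aic_table["dAIC"].iloc[0] == 0.0
        assert sel.final.criterion == "REML"
        assert sel.final.label == sel.aic_table["model"].iloc[0]

    def test_strong_planted_effects_select_la_and_season(self):
        sel = sl.select_model(simulated_cells(seed=8, season_effect=0.6,
                                              noise_sd=0.1))
        assert "LA250" in sel.final.label and "S" in sel.final.label

    def test_pure_noise_selects_simple_models(self):
        simple = 0
        for seed in range(5):
            cells = simulated_cells(seed=100 + seed, beta=0.0, seal_sd=0.0)
            sel = sl.select_model(cells)
            best = next(c for c in candidate_models()
                        if c.label == sel.final.label)
            simple += len(best.terms) <= 1
        assert simple >= 3


class TestPredictions:
    def test_fitted_log_zero_maps_to_one(self):
        cells = simulated_cells(seed=9)
        fit = fit_mixed_model(cells, "LA250")
        pred = sl.predict_tdlr_chl(fit, cells, include_random=False)
        frame = prepare_model_frame(cells)
        manual = fit.params["Intercept"] + fit.la_coefficient * frame["la"]
        np.testing.assert_allclose(pred.to_numpy(), np.exp(manual), rtol=1e-10)

    def test_monotone_in_la_for_positive_coefficient(self):
        cells = simulated_cells(seed=10)
        fit = fit_mixed_model(cells, "LA250")
        assert fit.la_coefficient > 0
        pred = sl.predict_tdlr_chl(fit, cells, include_random=False)
        frame = prepare_model_frame(cells)
        order = np.argsort(frame["la"].to_numpy())
        assert np.all(np.diff(pred.to_numpy()[order]) >= 0)

    def test_training_predictions_track_observations(self):
        cells = simulated_cells(seed=11, noise_sd=0.05)
        fit = fit_mixed_model(cells, "LA250")
        pred = sl.predict_tdlr_chl(fit, cells)
        obs = np.exp(prepare_model_frame(cells)["mean_log_chl"])
        assert np.corrcoef(pred, obs)[0, 1] > 0.9


class TestErrorSummary:
    def test_perfect_predictions_in_central_band(self):
        obs = pd.Series([0.5, 0.8, 1.2])
        bathy = pd.Series([3500.0, 3500.0, 4500.0])
        table = sl.predictive_error_summary(obs.copy(), obs, bathy)
        assert np.allclose(table["-10..10"], 100.0)

    def test_twenty_percent_overestimate_band(self):
        obs = pd.Series([0.5, 0.8, 1.2])
        table = sl.predictive_error_summary(1.2 * obs, obs,
                                            pd.Series([4500.0] * 3))
        assert table.loc[4000, "10..30"] == pytest.approx(100.0)

    def test_band_proportions_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        obs = pd.Series(np.exp(rng.normal(0, 0.5, 200)))
        pred = obs * np.exp(rng.normal(0, 0.4, 200))
        bathy = pd.Series(rng.choice([2500.0, 3500.0, 4500.0], 200))
        table = sl.predictive_error_summary(pred, obs, bathy)
        sums = table[["<=-30", "-30..-10", "-10..10", "10..30", ">30"]].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0)


class TestCoverageAndBandMeans:
    def test_matched_never_exceeds_index_coverage(self):
        chl_r, ice, bathy = default_grids()
        noon = noon_frame([
            ("a", WINDOW, -56.5, 157.5, 0.3, 4),
            ("a", WINDOW + dt.timedelta(days=1), -56.2, 158.9, 0.3, 4),
            ("b", WINDOW, -56.6, 157.4, 0.3, 3),
        ])
        by_lat, by_month = sl.coverage_summary(noon, [chl_r])
        assert (by_lat["matched_count"] <= by_lat["index_count"]).all()
        assert by_lat["index_count"].sum() == len(noon)
        assert by_month["index_count"].sum() == len(noon)

    def test_monthly_band_means_single_obs_has_no_se(self):
        chl_r, ice, bathy = default_grids()
        noon = noon_frame([("a", WINDOW, -56.5, 157.5, 0.3, 4)])
        cells, _ = build_grid(noon, [chl_r], ice, bathy)
        fitcells = simulated_cells(seed=12)
        pred = pd.Series([0.4], index=cells.index[:1])
        out = sl.monthly_band_means(cells, pred, [chl_r], band=(-60.0, -55.0))
        assert np.isnan(out["tdlr_se"]).all()
        assert (out["tdlr_n"] == 1).all()


class TestAnalysisCellInvariants:
    def test_retained_cells_satisfy_every_filter_invariant(self):
        import sealight as sl2
        res = sl2.run_synthetic_experiment(seed=9, n_seals=3, n_days=25,
                                           fit_models=False)
        kept = res.cells[res.cells["retained"]]
        assert len(kept) > 0
        assert (kept["n_profiles"] >= 3).all()
        assert (~kept["ice_excluded"]).all()
        assert (kept["season"] != "winter").all()
        assert kept["lat_centre"].between(-64.0, -52.0).all()
        assert np.isfinite(kept["mean_log_chl"]).all()
        assert np.isfinite(kept["mean_log_la250"]).all()


class TestFixedModelCoverage:
    def test_planted_effects_within_2se_in_most_replicates(self):
        """Data simulated from the model with known coefficients: each fixed
        effect lies within 2 SE of truth in nearly all replicates."""
        hits_la = hits_season = 0
        n_rep = 20
        for seed in range(n_rep):
            cells = simulated_cells(seed=300 + seed, beta=0.8,
                                    season_effect=0.4)
            fit = fit_mixed_model(cells, "LA250+S")
            hits_la += abs(fit.la_coefficient - 0.8) <= 2 * fit.la_se
            name = [k for k in fit.params.index if "summer" in k][0]
            hits_season += abs(fit.params[name] - 0.4) <= 2 * fit.bse[name]
        assert hits_la >= int(0.85 * n_rep)
        assert hits_season >= int(0.85 * n_rep)


def interaction_cells(seed):
    """Cells with strong LA, season, latitude effects and both published
    interactions planted."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(8):
        intercept = rng.normal(0.0, 0.1)
        n = 60
        la = rng.normal(-1.2, 0.4, n)
        season = rng.choice(["spring", "summer"], n)
        lat = rng.choice(np.arange(-63.5, -52.0), n)
        lat_c = lat + 58.0
        y = (intercept + 1.0 * la + 0.4 * (season == "summer")
             + 0.1 * lat_c + 0.1 * la * lat_c
             + 0.06 * (season == "summer") * lat_c
             + rng.normal(0, 0.15, n))
        for i in range(n):
            rows.append({"seal": f"s{s}", "mean_log_la250": la[i],
                         "mean_log_chl": y[i], "lat_centre": lat[i],
                         "season": season[i], "retained": True})
    return pd.DataFrame(rows)


class TestSelectionWithPlantedInteractions:
    def test_full_winner_structure_selected_in_most_replicates(self):
        """Strong LA/season/latitude effects plus both two-way interactions:
        the ranked selection should recover the full winning structure."""
        winner = "LA250+lat+S+LA250:lat+S:lat"
        hits = 0
        for seed in range(5):
            sel = sl.select_model(interaction_cells(500 + seed))
            hits += sel.final.label == winner
        assert hits >= 4


class TestWinterCoverage:
    def test_full_winter_cloud_gives_zero_matched_coverage(self):
        winter_window = dt.date(2002, 6, 27)  # aligned 8-day window in July
        chl_nan = flat_raster(np.nan, -57.0, 157.0, start=winter_window)
        noon = noon_frame([
            ("a", winter_window + dt.timedelta(days=i), -56.5, 157.5, 0.3, 4)
            for i in range(4)
        ])
        by_lat, by_month = sl.coverage_summary(noon, [chl_nan])
        assert by_month.loc[by_month["month"] == 7, "matched_count"].sum() == 0
        assert by_month["index_count"].sum() == 4
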