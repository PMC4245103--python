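"""Gridding, filtering, and the log-log mixed-effects model relating the
light-attenuation index to satellite chlorophyll-a.

Noon index estimates are spatially averaged into 1x1-degree grid cells
keyed additionally by 8-day composite window and by seal (the random-effect
grouping), which absorbs light-geolocation position error.  Cells with
fewer than 3 dive profiles, cells in >20% sea ice, winter cells, and cells
outside the 52-64 S focal band are excluded, and only cells with a
satellite match enter the model.  Candidate fixed-effect structures combine
LA250, season (reference level autumn), centred latitude, and their
interactions; every candidate carries a random intercept, plus a random
LA250 slope by seal where LA250 is present.  Candidates are fitted by
maximum likelihood and ranked by AIC; the AIC-best structure is refitted by
REML for reporting.  Both chlorophyll and LA250 enter on the natural-log
scale.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .io import Raster, match_grid, window_start_of

FOCAL_BAND = (-64.0, -52.0)     # latitude band of the focal analysis
ICE_EXCLUSION = 0.2             # >20% sea-ice concentration excludes a location
MIN_CELL_PROFILES = 3
LAT_CENTRE = -58.0              # centring for the latitude covariate
SEASON_REFERENCE = "autumn"

_SEASON_BY_MONTH = {12: "summer", 1: "summer", 2: "summer",
                    3: "autumn", 4: "autumn", 5: "autumn",
                    6: "winter", 7: "winter", 8: "winter",
                    9: "spring", 10: "spring", 11: "spring"}


def season_of(date: dt.date) -> str:
    """Austral season: summer Dec-Feb, autumn Mar-May, winter Jun-Aug,
    spring Sep-Nov."""
    return _SEASON_BY_MONTH[date.month]


def build_grid(noon: pd.DataFrame,
               chl_rasters: list[Raster],
               ice_rasters: list[Raster],
               bathy: Raster | None = None,
               band: tuple[float, float] = FOCAL_BAND,
               exclude_winter: bool = True,
               ice_threshold: float = ICE_EXCLUSION,
               min_profiles: int = MIN_CELL_PROFILES,
               ) -> tuple[pd.DataFrame, dict]:
    """Aggregate noon estimates into (1-degree lat, 1-degree lon, 8-day
    window, seal) grid cells and apply the analysis filters.

    ``noon`` needs columns ``seal, date, lat, lon, la250, n_profiles``.
    Returns every cell (with ``retained`` flag and ``drop_reason``) plus a
    filter ledger whose cell counts sum exactly:
    cells_in = retained + dropped_few_profiles + dropped_ice +
    dropped_band_season + dropped_no_chl.
    """
    est = noon.copy()
    ledger: dict[str, int] = {"estimates_in": int(len(est))}

    bad_la = ~(est["la250"] > 0) | ~np.isfinite(est["la250"])
    ledger["estimates_nonpositive_la250"] = int(bad_la.sum())
    est = est[~bad_la]
    not_analysable = est["n_profiles"] < min_profiles
    ledger["estimates_below_min_profiles"] = int(not_analysable.sum())
    est = est[~not_analysable].copy()
    ledger["estimates_assigned"] = int(len(est))

    if len(est) == 0:
        return pd.DataFrame(), {**ledger, "cells_in": 0, "cells_retained": 0,
                                "cells_dropped_few_profiles": 0,
                                "cells_dropped_ice": 0,
                                "cells_dropped_band_season": 0,
                                "cells_dropped_no_chl": 0}

    est["lat_bin"] = np.floor(est["lat"]).astype(int)
    est["lon_bin"] = np.floor(est["lon"]).astype(int)
    est["window_start"] = est["date"].map(window_start_of)
    est["log_la250"] = np.log(est["la250"])
    ice_by_date: dict[dt.date, list[Raster]] = {}
    for r in ice_rasters:
        ice_by_date.setdefault(r.time_start, []).append(r)
    est["ice_conc"] = [
        match_grid((row.lat, row.lon), row.date,
                   ice_by_date.get(row.date, []))
        for row in est.itertuples()
    ]
    est["ice_flag"] = est["ice_conc"] > ice_threshold

    grouped = est.groupby(["lat_bin", "lon_bin", "window_start", "seal"])
    cells = grouped.agg(
        mean_log_la250=("log_la250", "mean"),
        n_profiles=("n_profiles", "sum"),
        n_locations=("la250", "size"),
        ice_excluded=("ice_flag", "any"),
    ).reset_index()
    cells["lat_centre"] = cells["lat_bin"] + 0.5
    cells["season"] = [season_of(ws + dt.timedelta(days=4))
                       for ws in cells["window_start"]]

    chl_by_window = {r.time_start: r for r in chl_rasters}
    mean_chl = np.full(len(cells), np.nan)
    for i, row in enumerate(cells.itertuples()):
        raster = chl_by_window.get(row.window_start)
        if raster is None:
            continue
        vals = raster.box_values(row.lat_bin, row.lat_bin + 1,
                                 row.lon_bin, row.lon_bin + 1)
        if vals.size and np.isfinite(vals).any():
            mean_chl[i] = np.nanmean(vals)
    cells["mean_chl"] = mean_chl
    with np.errstate(divide="ignore", invalid="ignore"):
        cells["mean_log_chl"] = np.where(mean_chl > 0, np.log(mean_chl), np.nan)

    if bathy is not None:
        cells["mean_bathymetry"] = [
            float(np.nanmean(v)) if (v := bathy.box_values(
                r.lat_bin, r.lat_bin + 1, r.lon_bin, r.lon_bin + 1)).size else np.nan
            for r in cells.itertuples()
        ]
    else:
        cells["mean_bathymetry"] = np.nan

    # filters, applied with a fixed precedence so the ledger sums exactly
    few = cells["n_profiles"] < min_profiles
    ice = cells["ice_excluded"] & ~few
    in_band = (cells["lat_centre"] >= band[0]) & (cells["lat_centre"] <= band[1])
    band_season = (~in_band | (exclude_winter & (cells["season"] == "winter"))) \
        & ~few & ~ice
    no_chl = cells["mean_log_chl"].isna() & ~few & ~ice & ~band_season
    cells["retained"] = ~(few | ice | band_season | no_chl)
    reason = np.full(len(cells), "", dtype=object)
    reason[no_chl.to_numpy()] = "no_chl_match"
    reason[band_season.to_numpy()] = "band_or_season"
    reason[ice.to_numpy()] = "ice"
    reason[few.to_numpy()] = "few_profiles"
    cells["drop_reason"] = reason

    ledger.update(
        cells_in=int(len(cells)),
        cells_retained=int(cells["retained"].sum()),
        cells_dropped_few_profiles=int(few.sum()),
        cells_dropped_ice=int(ice.sum()),
        cells_dropped_band_season=int(band_season.sum()),
        cells_dropped_no_chl=int(no_chl.sum()),
    )
    return cells, ledger


# ---------------------------------------------------------------------------
# Candidate models and fitting


@dataclass(frozen=True)
class ModelCandidate:
    label: str
    terms: tuple[str, ...]   # subset of {LA, lat, S, LA:S, LA:lat, S:lat, LA:S:lat}

    @property
    def has_la(self) -> bool:
        return "LA" in self.terms

    @property
    def formula_rhs(self) -> str:
        # season is a Categorical ordered with the reference level (autumn)
        # first, so C(season) treatment-codes against it
        mapping = {
            "LA": "la",
            "lat": "lat_c",
            "S": "C(season)",
            "LA:S": "la:C(season)",
            "LA:lat": "la:lat_c",
            "S:lat": "C(season):lat_c",
            "LA:S:lat": "la:C(season):lat_c",
        }
        if not self.terms:
            return "1"
        return " + ".join(mapping[t] for t in self.terms)


def candidate_models() -> list[ModelCandidate]:
    """The 16 candidate fixed-effect structures, in the published ranked
    order, from the full two-way-interaction model down to intercept-only."""
    rows = [
        "LA+lat+S+LA:lat+S:lat",
        "LA+lat+S+S:lat",
        "LA+lat+S+LA:S+LA:lat+S:lat",
        "LA+lat+S+LA:S+S:lat",
        "LA+lat+S+LA:S+LA:lat+S:lat+LA:S:lat",
        "LA+lat+S+LA:lat",
        "LA+lat+S",
        "LA+lat+S+LA:S+LA:lat",
        "LA+lat+S+LA:S",
        "LA+S",
        "LA",
        "LA+lat",
        "S+lat",
        "S",
        "lat",
        "1",
    ]
    out = []
    for row in rows:
        terms = () if row == "1" else tuple(row.split("+"))
        out.append(ModelCandidate(label=row.replace("LA", "LA250"), terms=terms))
    return out


@dataclass
class ModelFit:
    """A fitted linear mixed model: fixed effects, random structure, and the
    information criteria used for ranking."""

    label: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    df: int                      # fixed effects + variance components + residual
    aic: float
    criterion: str               # "ML" or "REML"
    converged: bool
    singular_fallback: bool      # random slope dropped after a singular fit
    n_obs: int
    degenerate_re: bool = False  # RE variance at the zero boundary; SEs from
                                 # the exact OLS limit
    result: object = field(repr=False, default=None)

    @property
    def la_coefficient(self) -> float | None:
        return float(self.params["la"]) if "la" in self.params else None

    @property
    def la_se(self) -> float | None:
        return float(self.bse["la"]) if "la" in self.params else None


def prepare_model_frame(cells: pd.DataFrame) -> pd.DataFrame:
    """Analysis frame for fitting: log-log responses and centred latitude."""
    data = cells[cells["retained"]] if "retained" in cells else cells
    frame = pd.DataFrame({
        "mean_log_chl": data["mean_log_chl"].to_numpy(),
        "la": data["mean_log_la250"].to_numpy(),
        "lat_c": data["lat_centre"].to_numpy() - LAT_CENTRE,
        "season": data["season"].to_numpy(),
        "seal": data["seal"].to_numpy(),
    }, index=data.index).dropna()
    # reference level (autumn) first; absent seasons are dropped so patsy
    # treatment-codes against the first level actually present
    order = [SEASON_REFERENCE] + [s for s in ("spring", "summer", "winter")
                                  if s != SEASON_REFERENCE]
    present = [s for s in order if s in set(frame["season"])]
    frame["season"] = pd.Categorical(frame["season"], categories=present)
    return frame


def _fit_once(frame: pd.DataFrame, rhs: str, re_formula: str, reml: bool,
              start_params=None, methods=("bfgs", "powell")):
    """Fit one mixed model, trying optimizers until one converges to a
    finite optimum; returns the best result found (or None)."""
    model = smf.mixedlm(f"mean_log_chl ~ {rhs}", frame,
                        groups=frame["seal"], re_formula=re_formula)

    def score(r):
        # prefer converged fits with finite SEs, then higher likelihood
        finite_bse = bool(np.all(np.isfinite(r.bse_fe)))
        return (bool(r.converged), finite_bse, r.llf)

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in methods:
            try:
                result = model.fit(reml=reml, method=method, maxiter=500,
                                   start_params=start_params)
            except (np.linalg.LinAlgError, ValueError, OverflowError):
                continue
            if not np.isfinite(result.llf):
                continue
            if best is None or score(result) > score(best):
                best = result
            if best.converged and np.all(np.isfinite(best.bse_fe)):
                break
    return best


def _usable(result) -> bool:
    return (result is not None and result.converged
            and np.isfinite(result.llf)
            and bool(np.all(np.isfinite(result.bse_fe))))


def fit_mixed_model(cells: pd.DataFrame,
                    candidate: ModelCandidate | str,
                    criterion: str = "ML") -> ModelFit:
    """Fit one candidate by ML or REML with random intercept (+ random LA250
    slope by seal when LA250 is a fixed effect).

    A singular random-slope fit (degenerate slope variance) is retried with
    a random intercept only and flagged; non-convergence is reported on the
    returned fit, never silently accepted.
    """
    if isinstance(candidate, str):
        matches = [c for c in candidate_models() if c.label == candidate]
        if not matches:
            raise ValueError(f"unknown candidate {candidate!r}")
        candidate = matches[0]
    frame = prepare_model_frame(cells)
    if frame["seal"].nunique() < 2:
        raise ValueError("need at least 2 seals for a mixed model")
    if len(frame) < 10:
        raise ValueError("need at least 10 analysis cells")
    reml = criterion.upper() == "REML"

    # The random-intercept fit is robust; the random-slope fit is kept only
    # when it converges to a finite, non-singular optimum that is at least
    # as good (the models are nested), otherwise the slope term is dropped
    # and flagged -- the boundary case of a degenerate slope variance.
    # Warm starts: the random-effect variances in well-identified data sit
    # near (or at) the zero boundary, where the profiled surface is nearly
    # flat and cold-started optimizers stall.  The intercept model starts
    # at the OLS solution; the slope model starts at the intercept optimum
    # with a small slope variance.
    from statsmodels.regression.mixed_linear_model import MixedLMParams
    singular_fallback = False
    base_start = None
    try:
        ols = smf.ols(f"mean_log_chl ~ {candidate.formula_rhs}", frame).fit()
        base_start = MixedLMParams.from_components(
            fe_params=ols.params.to_numpy(), cov_re=np.array([[1e-4]]))
    except (np.linalg.LinAlgError, ValueError):
        pass
    base = _fit_once(frame, candidate.formula_rhs, "1", reml,
                     start_params=base_start)
    result = base
    if candidate.has_la:
        start = None
        if base is not None:
            v = max(float(np.asarray(base.cov_re)[0, 0]) / base.scale, 1e-6)
            start = MixedLMParams.from_components(
                fe_params=np.asarray(base.fe_params),
                cov_re=np.array([[v, 0.0], [0.0, 1e-4]]))
        full = _fit_once(frame, candidate.formula_rhs, "1 + la", reml,
                         start_params=start,
                         methods=("lbfgs", "bfgs", "powell"))
        ok = (_usable(full)
              and np.all(np.isfinite(np.asarray(full.cov_re)))
              and (base is None or full.llf >= base.llf - 1e-6))
        if ok:
            result = full
        else:
            singular_fallback = True
    if result is None:
        raise RuntimeError(f"no optimizer produced a finite fit for "
                           f"{candidate.label!r}")

    k_fe = len(result.fe_params)
    k_vc = len(result.cov_re.values[np.tril_indices_from(result.cov_re)]) + 1
    llf = float(result.llf)
    bse = result.bse_fe
    pvalues = result.pvalues[: k_fe]
    # At the zero-variance boundary the mixed model reduces exactly to OLS,
    # but the profiled information matrix degenerates and the reported
    # fixed-effect covariance is unreliable (SEs can fall below the OLS
    # bound); take the covariance of the limiting model instead.
    degenerate_re = (
        float(np.max(np.diag(np.asarray(result.cov_re))))
        < 1e-6 * max(float(result.scale), 1e-300))
    if degenerate_re:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            limit = smf.ols(f"mean_log_chl ~ {candidate.formula_rhs}",
                            frame).fit()
        bse = limit.bse
        pvalues = limit.pvalues
    return ModelFit(
        label=candidate.label,
        params=result.fe_params,
        bse=bse,
        pvalues=pvalues,
        loglik=llf,
        df=k_fe + k_vc,
        aic=2 * (k_fe + k_vc) - 2 * llf,
        criterion="REML" if reml else "ML",
        converged=bool(result.converged),
        singular_fallback=singular_fallback,
        n_obs=len(frame),
        degenerate_re=degenerate_re,
        result=result,
    )


@dataclass
class SelectionResult:
    aic_table: pd.DataFrame
    final: ModelFit              # AIC-best structure refitted by REML
    fits: list[ModelFit]
    excluded: list[str]          # non-convergent candidates left out of ranking


def select_model(cells: pd.DataFrame,
                 candidates: list[ModelCandidate] | None = None) -> SelectionResult:
    """Fit the candidate set by ML, rank by AIC, and refit the best structure
    by REML for the final reported model."""
    if candidates is None:
        candidates = candidate_models()
    fits, excluded = [], []
    for cand in candidates:
        fit = fit_mixed_model(cells, cand, criterion="ML")
        if not fit.converged:
            excluded.append(cand.label)
            continue
        fits.append((cand, fit))
    if not fits:
        raise RuntimeError("no candidate model converged")
    table = pd.DataFrame({
        "model": [f.label for _, f in fits],
        "df": [f.df for _, f in fits],
        "AIC": [f.aic for _, f in fits],
        "logLik": [f.loglik for _, f in fits],
    }).sort_values("AIC", kind="stable").reset_index(drop=True)
    table["dAIC"] = table["AIC"] - table["AIC"].iloc[0]
    table = table[["model", "df", "AIC", "dAIC", "logLik"]]

    best_label = table["model"].iloc[0]
    best_cand = next(c for c, _ in fits if c.label == best_label)
    final = fit_mixed_model(cells, best_cand, criterion="REML")
    return SelectionResult(aic_table=table, final=final,
                           fits=[f for _, f in fits], excluded=excluded)


def predict_tdlr_chl(fit: ModelFit, cells: pd.DataFrame,
                     include_random: bool = True) -> pd.Series:
    """Light-based chlorophyll (mg m^-3): exponentiated fitted values of log
    chl-a; random effects are added for in-sample seals, population-level
    predictions are used for unseen seals."""
    frame = prepare_model_frame(cells)
    pred = np.asarray(fit.result.predict(frame), dtype=float)
    if include_random:
        re = fit.result.random_effects
        for i, seal in enumerate(frame["seal"]):
            if seal in re:
                effects = re[seal]
                pred[i] += effects.get("Group", 0.0)
                if "la" in effects:
                    pred[i] += effects["la"] * frame["la"].iloc[i]
    return pd.Series(np.exp(pred), index=frame.index, name="tdlr_chl")


ERROR_BANDS = [-np.inf, -30.0, -10.0, 10.0, 30.0, np.inf]
ERROR_BAND_LABELS = ["<=-30", "-30..-10", "-10..10", "10..30", ">30"]


def predictive_error_summary(predictions: pd.Series, observations: pd.Series,
                             bathymetry: pd.Series,
                             bathy_band_m: float = 1000.0) -> pd.DataFrame:
    """Signed percentage prediction error tabulated by bathymetry band.

    Rows are 1000-m bathymetry bands, columns the proportions (%) of cells
    in each error band (<=-30, -30..-10, -10..10, 10..30, >30%); proportions
    sum to 100 within each row.  Cells with zero observed chlorophyll are
    excluded (count returned in the ``n_excluded`` attribute column).
    """
    obs = np.asarray(observations, dtype=float)
    pred = np.asarray(predictions, dtype=float)
    bathy = np.asarray(bathymetry, dtype=float)
    ok = np.isfinite(obs) & np.isfinite(pred) & np.isfinite(bathy) & (obs != 0)
    err = 100.0 * (pred[ok] - obs[ok]) / obs[ok]
    bands = pd.cut(err, ERROR_BANDS, labels=ERROR_BAND_LABELS)
    depth_band = (np.floor(bathy[ok] / bathy_band_m) * bathy_band_m).astype(int)
    table = (pd.crosstab(depth_band, bands, normalize="index", dropna=False) * 100.0)
    table.index.name = "bathy_band_m"
    table["n_cells"] = pd.Series(depth_band).value_counts().sort_index()
    table.attrs["n_excluded"] = int((~ok).sum())
    return table


def coverage_summary(noon: pd.DataFrame, chl_rasters: list[Raster]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Data-coverage counts by 1-degree latitude bin and by calendar month.

    Three series each: analysable index estimates, estimates with a matched
    (cloud-free) satellite value at the noon position, and overall valid
    satellite pixels in the region.
    """
    est = noon[noon["n_profiles"] >= MIN_CELL_PROFILES].copy()
    est["lat_bin"] = np.floor(est["lat"]).astype(int)
    est["month"] = [d.month for d in est["date"]]
    est["matched"] = [
        np.isfinite(match_grid((r.lat, r.lon), r.date, chl_rasters))
        for r in est.itertuples()
    ]

    by_lat = est.groupby("lat_bin").agg(
        index_count=("la250", "size"), matched_count=("matched", "sum"))
    by_month = est.groupby("month").agg(
        index_count=("la250", "size"), matched_count=("matched", "sum"))

    sat_lat: dict[int, int] = {}
    sat_month: dict[int, int] = {}
    for r in chl_rasters:
        valid = np.isfinite(r.values)
        lat_bins = np.floor(r.lat).astype(int)
        for b in np.unique(lat_bins):
            sat_lat[b] = sat_lat.get(b, 0) + int(valid[lat_bins == b].sum())
        m = (r.time_start + dt.timedelta(days=(r.n_days or 8) // 2)).month
        sat_month[m] = sat_month.get(m, 0) + int(valid.sum())
    by_lat["satellite_count"] = pd.Series(sat_lat).reindex(by_lat.index).fillna(0).astype(int)
    by_month["satellite_count"] = pd.Series(sat_month).reindex(by_month.index).fillna(0).astype(int)
    return by_lat.reset_index(), by_month.reset_index()


def monthly_band_means(cells: pd.DataFrame, predictions: pd.Series,
                       chl_rasters: list[Raster],
                       band: tuple[float, float] = (-65.0, -55.0)
                       ) -> pd.DataFrame:
    """Year-month mean +/- SE series of light-based chlorophyll (model
    predictions) and satellite chlorophyll within a latitude band; months
    with no data are missing entries, and an SE needs at least 2 values."""
    data = cells[cells["retained"]].loc[predictions.index].copy()
    data["tdlr_chl"] = predictions
    in_band = (data["lat_centre"] >= band[0]) & (data["lat_centre"] <= band[1])
    data = data[in_band]
    data["month"] = [pd.Period(ws + dt.timedelta(days=4), freq="M")
                     for ws in data["window_start"]]

    def mean_se(g):
        return pd.Series({"mean": g.mean(),
                          "se": g.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else np.nan,
                          "n": len(g)})

    tdlr = data.groupby("month")["tdlr_chl"].apply(mean_se).unstack()
    tdlr.columns = [f"tdlr_{c}" for c in tdlr.columns]

    sat_rows = {}
    for r in chl_rasters:
        sel = (r.lat >= band[0]) & (r.lat <= band[1])
        vals = r.values[sel, :]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        m = pd.Period(r.time_start + dt.timedelta(days=(r.n_days or 8) // 2), freq="M")
        sat_rows.setdefault(m, []).append(vals)
    sat = pd.DataFrame({
        "sat_mean": {m: np.concatenate(v).mean() for m, v in sat_rows.items()},
        "sat_se": {m: (np.concatenate(v).std(ddof=1) / np.sqrt(len(np.concatenate(v)))
                       if len(np.concatenate(v)) > 1 else np.nan)
                   for m, v in sat_rows.items()},
    })
    out = tdlr.join(sat, how="outer").sort_index()
    out.index.name = "month"
    return out
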