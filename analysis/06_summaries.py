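"""Summary products: light-based chlorophyll predictions per cell,
predictive-error proportions by bathymetry band, data-coverage counts by
latitude and month (index vs satellite), and monthly band means of
light-based vs satellite chlorophyll in the 55-65 S band."""

import datetime as dt

import numpy as np
import pandas as pd

import sealight as sl
from sealight.io import Raster
from sealight.model import fit_mixed_model
from _common import RESULTS, SCRATCH, ensure_dirs


def main():
    ensure_dirs()
    cells = pd.read_csv(RESULTS / "grid_cells.csv",
                        parse_dates=["window_start"])
    cells["window_start"] = cells["window_start"].dt.date
    noon = pd.read_csv(RESULTS / "noon_index.csv", parse_dates=["date"])
    noon["date"] = noon["date"].dt.date
    aic = pd.read_csv(RESULTS / "aic_table.csv")
    chl = [Raster.from_netcdf(p)
           for p in sorted((SCRATCH / "rasters").glob("chl_*.nc"))]

    final = fit_mixed_model(cells, aic["model"].iloc[0], criterion="REML")
    pred = sl.predict_tdlr_chl(final, cells)
    pred.to_frame().to_csv(RESULTS / "predictions.csv")

    retained = cells[cells["retained"]].loc[pred.index]
    obs = np.exp(retained["mean_log_chl"])
    err_table = sl.predictive_error_summary(pred, obs,
                                            retained["mean_bathymetry"])
    err_table.to_csv(RESULTS / "error_by_bathymetry.csv")
    print("prediction error (%) by bathymetry band (row %):")
    print(err_table.round(1).to_string())

    by_lat, by_month = sl.coverage_summary(noon, chl)
    by_lat.to_csv(RESULTS / "coverage_by_latitude.csv", index=False)
    by_month.to_csv(RESULTS / "coverage_by_month.csv", index=False)
    frac = by_lat["matched_count"].sum() / by_lat["index_count"].sum()
    print(f"\n{by_lat['index_count'].sum()} analysable seal-days; "
          f"{100 * frac:.1f}% matched a cloud-free satellite value")

    band = sl.monthly_band_means(cells, pred, chl, band=(-65.0, -55.0))
    band.to_csv(RESULTS / "monthly_band_means.csv")
    print("\nmonthly means in the 55-65 S band "
          "(light-based vs satellite chlorophyll, mg m-3):")
    print(band.round(3).to_string())
    print(f"\ntables -> {RESULTS}/predictions.csv, error_by_bathymetry.csv, "
          f"coverage_*.csv, monthly_band_means.csv")


if __name__ == "__main__":
    main()
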