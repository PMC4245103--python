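import datetime as dt

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sealight as sl
from sealight import synthetic as syn

KM_PER_DEG = 111.32


def spec(n_days=3, seed=1, **kw):
    return sl.DeploymentSpec("sealA", dt.date(2002, 11, 1), n_days=n_days,
                             seed=seed, **kw)


class TestTrack:
    def test_single_day_stays_at_start(self, truth):
        track = sl.generate_track(spec(n_days=1), truth)
        assert len(track) == 1
        assert (track.lat[0], track.lon[0]) == (-54.58, 158.97)

    def test_daily_displacement_bounded(self, truth):
        track = sl.generate_track(spec(n_days=30), truth)
        dlat = np.diff(track.lat) * KM_PER_DEG
        dlon = np.diff(track.lon) * KM_PER_DEG * np.cos(np.radians(track.lat[:-1]))
        assert np.all(np.hypot(dlat, dlon) <= 150.0)

    def test_seeded_determinism(self, truth):
        t1 = sl.generate_track(spec(n_days=20), truth)
        t2 = sl.generate_track(spec(n_days=20), truth)
        assert t1.equals(t2)

    def test_position_noise_scale(self, truth):
        s = spec(n_days=300)
        clean = sl.generate_track(s, truth)
        noisy = sl.generate_track(s, truth, position_noise_km=(57.0, 54.0))
        lat_err_km = (noisy.lat - clean.lat) * KM_PER_DEG
        assert 30.0 < lat_err_km.std() < 80.0

    def test_latitude_bounds_respected(self, truth):
        track = sl.generate_track(spec(n_days=400), truth)
        assert track.lat.between(-68.0, -48.0).all()


class TestSolarElevation:
    def test_overhead_at_equator_equinox(self):
        assert sl.solar_elevation(0.0, 80, 12.0) == pytest.approx(90.0, abs=1.0)

    def test_austral_summer_solstice_at_60s(self):
        # 90 - |lat - decl| = 90 - |-60 + 23.44|
        assert sl.solar_elevation(-60.0, 355, 12.0) == pytest.approx(53.44, abs=0.1)

    @given(st.floats(-89, 89), st.integers(1, 365), st.floats(0.01, 11.99))
    def test_symmetric_about_solar_noon(self, lat, doy, h):
        assert sl.solar_elevation(lat, doy, 12.0 - h) == pytest.approx(
            sl.solar_elevation(lat, doy, 12.0 + h), abs=1e-9)

    @given(st.floats(-90, 90), st.integers(1, 366), st.floats(0, 23.99))
    def test_range(self, lat, doy, t):
        assert -90.0 <= sl.solar_elevation(lat, doy, t) <= 90.0


class TestDiveSeries:
    def test_level_difference_matches_constant_attenuation(self, truth):
        # pure-water column with fixed k: descent light levels fall linearly
        # with depth at 20*k/ln(10) levels per metre
        k = 0.04
        t = syn.OceanTruth(k_water=k, k_chl=0.0)
        s = spec(n_days=1)
        track = sl.generate_track(s, t)
        dep = sl.generate_dive_series(s, track, t, quantize=False)
        seg = sl.segment_dives(dep.depth, dep.time)
        # a deep near-noon dive (local noon at lon 159 is ~01:24 UTC)
        dive = max(seg.dives[:12], key=lambda d: d.max_depth)
        desc = dive.descent
        slope = np.polyfit(dep.depth[desc], dep.light_level[desc], 1)[0]
        expected = 20.0 * k / np.log(10.0)
        assert -slope == pytest.approx(expected, rel=1e-3)
        drop_250 = expected * 250.0
        assert drop_250 == pytest.approx(86.86, abs=0.01)

    def test_dives_per_day_recoverable(self, small_deployment):
        dep, _, s = small_deployment
        seg = sl.segment_dives(dep)
        per_day = len(seg.dives) / s.n_days
        assert per_day >= s.dives_per_day - 1

    def test_seeded_determinism_byte_identical(self, truth):
        s = spec(n_days=2)
        track = sl.generate_track(s, truth)
        d1 = sl.generate_dive_series(s, track, truth)
        d2 = sl.generate_dive_series(s, track, truth)
        assert d1.depth.tobytes() == d2.depth.tobytes()
        assert d1.light_level.tobytes() == d2.light_level.tobytes()
        assert d1.time.tobytes() == d2.time.tobytes()

    def test_basic_record_invariants(self, small_deployment):
        dep, _, _ = small_deployment
        assert np.all(dep.depth >= 0.0)
        assert np.all(np.diff(dep.time.astype("int64")) > 0)
        np.testing.assert_array_equal(dep.wet, dep.depth > 0)
        assert np.all((dep.light_level >= 0) & (dep.light_level <= 250))

    def test_quantization_within_half_level(self, truth):
        s = spec(n_days=1)
        track = sl.generate_track(s, truth)
        exact = sl.generate_dive_series(s, track, truth, quantize=False)
        rounded = sl.generate_dive_series(s, track, truth, quantize=True)
        assert np.max(np.abs(rounded.light_level - exact.light_level)) <= 0.5

    def test_temperature_profile_reaches_planted_t200(self, truth):
        s = spec(n_days=1)
        track = sl.generate_track(s, truth)
        dep = sl.generate_dive_series(s, track, truth)
        depth = sl.zero_offset_correct(dep.depth)
        seg = sl.segment_dives(depth, dep.time)
        dive = max(seg.dives, key=lambda d: d.max_depth)
        from sealight.hydrography import dive_t200
        got = dive_t200(dep, dive, depth=depth)
        want = float(truth.t200_field(track.lat[0]))
        assert got == pytest.approx(want, abs=0.15)

    def test_mixed_layer_option_plants_light_knee(self, truth):
        s = spec(n_days=1)
        track = sl.generate_track(s, truth)
        dep = sl.generate_dive_series(s, track, truth, quantize=False,
                                      chl_vertical="mixed_layer")
        seg = sl.segment_dives(dep.depth, dep.time)
        dive = max(seg.dives[:12], key=lambda d: d.max_depth)
        desc, asc = sl.split_phases(dive)
        got = sl.light_inflection_depth(dep.depth[desc], dep.light_level[desc],
                                        dep.depth[asc], dep.light_level[asc])
        doy = track.date[0].timetuple().tm_yday
        want = float(truth.mld(track.lat[0], doy))
        assert got == pytest.approx(want, abs=45.0)  # one 30-s sample spacing


class TestOceanTruthInvariants:
    @given(st.floats(-68, -48), st.floats(120, 200), st.integers(1, 365))
    def test_chl_positive(self, lat, lon, doy):
        assert syn.OceanTruth().chl_surface(lat, lon, doy) > 0

    @given(st.floats(-68, -48), st.integers(1, 365))
    def test_mld_in_range(self, lat, doy):
        assert 10.0 < syn.OceanTruth().mld(lat, doy) <= 350.0

    def test_t200_monotone_nonincreasing_southward(self):
        t = syn.OceanTruth()
        lats = np.linspace(-45.0, -75.0, 200)  # heading south
        vals = t.t200_field(lats)
        assert np.all(np.diff(vals) <= 1e-12)

    @given(st.floats(0.0, 3.0))
    def test_total_attenuation_at_least_clear_water(self, chl):
        t = syn.OceanTruth()
        assert t.k_total(chl) >= t.k_water > 0


class TestSatelliteProducts:
    def test_noiseless_grid_equals_window_mean_of_truth(self, truth):
        chl, _, _ = syn.generate_satellite_products(
            truth, (-60.0, -58.0), (155.0, 157.0), dt.date(2002, 11, 1), 16,
            cloud_fraction=0.0, sigma=0.0, sigma_cell=0.0, seed=0)
        r = chl[0]
        lat2, lon2 = r.lat[:, None], r.lon[None, :]
        doys = [(r.time_start + dt.timedelta(days=i)).timetuple().tm_yday
                for i in range(r.n_days)]
        want = np.mean([truth.chl_surface(lat2, lon2, d) for d in doys], axis=0)
        np.testing.assert_allclose(r.values, want, rtol=1e-12)

    def test_cloud_fraction_near_nominal(self, truth):
        chl, _, _ = syn.generate_satellite_products(
            truth, (-62.0, -52.0), (150.0, 165.0), dt.date(2002, 11, 1), 8,
            cloud_fraction=0.5, seed=3)
        values = chl[0].values
        assert values.size >= 10_000
        missing = np.isnan(values).mean()
        assert missing == pytest.approx(0.5, abs=0.03)

    def test_ice_concentration_south_of_edge(self, truth):
        _, ice, _ = syn.generate_satellite_products(
            truth, (-70.0, -55.0), (150.0, 155.0), dt.date(2002, 11, 1), 2,
            seed=0)
        day = ice[0]
        edge = float(truth.ice_edge_lat(day.time_start.timetuple().tm_yday))
        south = day.lat <= edge
        assert np.all(day.values[south, :] >= 0.5)

    def test_bathymetry_positive_depth(self, truth):
        _, _, bathy = syn.generate_satellite_products(
            truth, (-65.0, -55.0), (150.0, 170.0), dt.date(2002, 11, 1), 2,
            seed=0)
        assert np.all(bathy.values > 0)

    def test_windows_cover_period(self, truth):
        chl, ice, _ = syn.generate_satellite_products(
            truth, (-60.0, -58.0), (155.0, 157.0), dt.date(2002, 12, 20), 20,
            cloud_fraction=0.0, seed=0)
        for day_offset in range(20):
            date = dt.date(2002, 12, 20) + dt.timedelta(days=day_offset)
            assert any(r.contains(date) for r in chl)
        assert len(ice) == 20


class TestStructuralLogLogLinearity:
    def test_index_tracks_chlorophyll_with_unit_slope(self):
        # phytoplankton-dominated attenuation, noiseless sensor: the full
        # record-to-index chain must preserve log LA250 = const + log chl
        truth = syn.OceanTruth(k_water=1e-4)
        frames = []
        for i in range(3):
            s = sl.DeploymentSpec(f"s{i}", dt.date(2002, 11, 1) + dt.timedelta(days=20 * i),
                                  n_days=15, seed=5)
            track = sl.generate_track(s, truth)
            dep = sl.generate_dive_series(s, track, truth, quantize=False)
            noon = sl.process_deployment(dep, track)
            doy = np.array([d.timetuple().tm_yday for d in noon["date"]])
            chl = truth.chl_column(noon["lat"].to_numpy(),
                                   noon["lon"].to_numpy(), doy)
            frames.append((np.log(chl), np.log(noon["la250"].to_numpy())))
        x = np.concatenate([f[0] for f in frames])
        y = np.concatenate([f[1] for f in frames])
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)


class TestManifest:
    def test_manifest_records_truth_and_specs(self, tmp_path, truth):
        path = tmp_path / "manifest.json"
        sl.save_manifest(path, truth, [spec(n_days=2)])
        import json
        payload = json.loads(path.read_text())
        assert payload["ocean_truth"]["beta_true"] == truth.beta_true
        assert payload["deployments"][0]["seal_id"] == "sealA"
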