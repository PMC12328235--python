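"""Ensembles, MPA thresholds, zones, period aggregation and niche breadth."""

import math

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy import stats

from paleoniche.cube import BIOME_CLASSES
from paleoniche.projection import (
    DEFAULT_MIS_PERIODS,
    GateError,
    PeriodError,
    ZONE_CORE,
    ZONE_PERIPHERAL,
    aggregate_by_period,
    assign_periods,
    binarize_zones,
    biome_area_series,
    build_ensemble,
    cell_area_grid,
    EnsemblePrediction,
    fit_climate_pca,
    kernel_area_2d,
    modal_biome_by_period,
    mpa_threshold,
    niche_kernel_area_series,
)
from paleoniche.synthetic import generate_biome_labels, generate_climate_cube

from conftest import small_spec


def _da(arr, times=None):
    arr = np.asarray(arr, dtype=float)
    t = times if times is not None else np.arange(arr.shape[0], 0, -1) * 1000.0
    return xr.DataArray(
        arr,
        coords={
            "time": t,
            "lat": np.arange(arr.shape[1], dtype=float),
            "lon": np.arange(arr.shape[2], dtype=float),
        },
        dims=("time", "lat", "lon"),
    )


class TestEnsemble:
    def _preds(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        return {i: _da(rng.uniform(0, 1, (3, 4, 4))) for i in range(n)}

    def test_single_accepted_member_is_identity(self):
        preds = self._preds(2)
        ens = build_ensemble(
            preds, {0: 10.0, 1: 0.0}, {0: 0.9, 1: 0.9}, method="mean"
        )
        assert ens.member_ids == [0]
        np.testing.assert_array_equal(ens.suitability.values, preds[0].values)

    def test_mean_and_median_of_two(self):
        base = np.zeros((1, 1, 1))
        preds = {0: _da(base + 0.2), 1: _da(base + 0.8)}
        gates = ({0: 5.0, 1: 5.0}, {0: 0.9, 1: 0.9})
        mean = build_ensemble(preds, *gates, method="mean")
        med = build_ensemble(preds, *gates, method="median")
        assert mean.suitability.values.item() == pytest.approx(0.5)
        assert med.suitability.values.item() == pytest.approx(0.5)

    def test_gate_filter_matches_brute_force(self):
        rng = np.random.default_rng(1)
        preds = self._preds(20, seed=1)
        daic = {i: rng.uniform(-5, 10) for i in preds}
        bci = {i: rng.uniform(0, 1) for i in preds}
        ens = build_ensemble(preds, daic, bci)
        expect = sorted(
            i for i in preds if daic[i] > 2.0 and bci[i] > 0.7
        )
        assert ens.member_ids == expect

    def test_fixed_variant_uses_complementary_gate(self):
        preds = self._preds(4, seed=2)
        daic = {0: 5.0, 1: 1.0, 2: -3.0, 3: 2.5}
        ens = build_ensemble(preds, daic, {}, fixed_variant=True)
        assert ens.member_ids == [1, 2]

    def test_zero_members_raises_with_counts(self):
        preds = self._preds(3, seed=3)
        with pytest.raises(GateError, match="zero accepted members"):
            build_ensemble(
                preds, {i: 10.0 for i in preds}, {i: 0.1 for i in preds}
            )


class TestMPA:
    def test_decile_example(self):
        vals = np.arange(0.1, 1.01, 0.1)
        assert mpa_threshold(vals, 0.90) == pytest.approx(0.2)

    def test_full_coverage_is_minimum(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, 77)
        assert mpa_threshold(v, 1.0) == v.min()

    @pytest.mark.parametrize("coverage", [0.90, 0.95, 0.99])
    def test_defining_property_and_brute_force(self, coverage):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 1, 1000)
        t = mpa_threshold(v, coverage)
        achieved = np.mean(v >= t)
        n = len(v)
        assert coverage <= achieved <= coverage + 1.0 / n
        # brute force: no larger candidate threshold still covers `coverage`
        for cand in np.sort(v)[::-1]:
            if np.mean(v >= cand) >= coverage:
                assert cand == t
                break

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mpa_threshold(np.array([]), 0.9)

    def test_bad_coverage_rejected(self):
        with pytest.raises(ValueError):
            mpa_threshold(np.arange(5.0), 0.0)


class TestZones:
    def _ensemble(self, seed=0, shape=(4, 8, 8)):
        rng = np.random.default_rng(seed)
        arr = rng.uniform(0, 1, shape)
        arr[:, 0, 0] = np.nan  # a sea cell
        return EnsemblePrediction(
            method="mean", member_ids=[0], suitability=_da(arr), gates={}
        )

    def test_threshold_ordering_and_nesting(self):
        ens = self._ensemble()
        occ = np.random.default_rng(1).uniform(0.2, 1, 300)
        zc = binarize_zones(ens, occ)
        t = zc.thresholds
        assert t["t90"] >= t["t95"] >= t["t99"]
        z = zc.zones.values
        core = z == ZONE_CORE
        peri = z >= ZONE_PERIPHERAL
        total = z >= 1
        assert np.all(peri[core]) and np.all(total[peri])

    def test_zone_labels_match_per_cell_comparison(self):
        ens = self._ensemble(seed=2)
        occ = np.random.default_rng(3).uniform(0, 1, 200)
        zc = binarize_zones(ens, occ)
        arr = ens.suitability.values
        t = zc.thresholds
        z = zc.zones.values
        it = np.ndindex(arr.shape)
        for idx in it:
            v = arr[idx]
            if np.isnan(v):
                want = -1
            elif v >= t["t90"]:
                want = 3
            elif v >= t["t95"]:
                want = 2
            elif v >= t["t99"]:
                want = 1
            else:
                want = 0
            assert z[idx] == want

    def test_high_occurrence_suitability_shrinks_core(self):
        ens = self._ensemble(seed=4)
        occ = np.full(100, 1.0)
        zc = binarize_zones(ens, occ)
        assert zc.thresholds["t90"] == 1.0
        # a cell at 0.99 cannot be core
        assert not np.any(
            (ens.suitability.values < 1.0)
            & (zc.zones.values == ZONE_CORE)
        )


class TestPeriods:
    def test_default_table_partitions_study_window(self):
        times = np.arange(120_000.0, 13_999.0, -2_000.0)
        labels = assign_periods(times)
        assert len(labels) == len(times) and all(labels)

    def test_orphan_slices_rejected(self):
        with pytest.raises(PeriodError, match="outside all periods"):
            assign_periods(np.array([200_000.0]))

    def test_single_slice_period_identity(self):
        da = _da(np.random.default_rng(0).uniform(size=(2, 3, 3)),
                 times=np.array([118_000.0, 30_000.0]))
        out = aggregate_by_period(da)
        np.testing.assert_array_equal(
            out.sel(period="MIS 5e").values, da.values[0]
        )

    def test_two_slice_mean(self):
        arr = np.stack([np.full((2, 2), 0.2), np.full((2, 2), 0.4)])
        da = _da(arr, times=np.array([110_000.0, 108_000.0]))
        out = aggregate_by_period(da)
        np.testing.assert_allclose(
            out.sel(period="MIS 5d").values, 0.3
        )

    def test_modal_biome_tie_flagged_and_broken_to_drier(self):
        cube = generate_biome_labels(generate_climate_cube(small_spec(seed=41)))
        # force a two-slice cube with alternating classes on one cell
        ds = cube.data.isel(time=[0, 1]).copy()
        ids = ds["biome_id"].values.copy()
        land = np.argwhere(cube.land_mask)
        r, c = land[0]
        ids[0, r, c] = BIOME_CLASSES.index("forest")
        ids[1, r, c] = BIOME_CLASSES.index("desert")
        ds["biome_id"] = (("time", "lat", "lon"), ids)
        two = type(cube)(ds, cube.biome_class_map)
        modal, ties = modal_biome_by_period(
            two, periods=(("P", 130_000.0, 10_000.0),)
        )
        assert bool(ties.values[0, r, c])
        assert modal.values[0, r, c] == BIOME_CLASSES.index("desert")


class TestAreas:
    @pytest.fixture(scope="class")
    def world(self):
        cube = generate_biome_labels(generate_climate_cube(small_spec(seed=51)))
        return cube

    def _zones_from(self, cube, zone_value):
        arr = np.full(
            (len(cube.times), *cube.land_mask.shape), zone_value, dtype=np.int8
        )
        arr[:, ~cube.land_mask] = -1
        from paleoniche.projection import ZoneCube

        da = xr.DataArray(
            arr,
            coords={"time": cube.times, "lat": cube.lats, "lon": cube.lons},
            dims=("time", "lat", "lon"),
        )
        return ZoneCube(zones=da, thresholds={"t90": 1, "t95": 1, "t99": 1})

    def test_no_suitable_cells_zero_area(self, world):
        zc = self._zones_from(world, 0)
        series = biome_area_series(zc, world)
        assert (series["area_km2"] == 0).all()

    def test_all_suitable_sums_to_land_area(self, world):
        zc = self._zones_from(world, ZONE_CORE)
        series = biome_area_series(zc, world)
        per_slice = series.groupby("slice_time_bp")["area_km2"].sum()
        areas = cell_area_grid(world)
        land_area = areas[world.land_mask].sum()
        np.testing.assert_allclose(per_slice.values, land_area, rtol=1e-9)

    def test_matches_per_cell_loop(self, world):
        rng = np.random.default_rng(0)
        from paleoniche.climate import biome_class_grid
        from paleoniche.projection import ZoneCube

        arr = rng.integers(0, 4, (len(world.times), *world.land_mask.shape))
        arr = arr.astype(np.int8)
        arr[:, ~world.land_mask] = -1
        zc = ZoneCube(
            zones=xr.DataArray(
                arr,
                coords={"time": world.times, "lat": world.lats,
                        "lon": world.lons},
                dims=("time", "lat", "lon"),
            ),
            thresholds={"t90": 0.9, "t95": 0.8, "t99": 0.7},
        )
        series = biome_area_series(zc, world)
        areas = cell_area_grid(world)
        ti = 3
        classes = biome_class_grid(world, ti)
        for cname in BIOME_CLASSES:
            c = BIOME_CLASSES.index(cname)
            total = 0.0
            for r in range(arr.shape[1]):
                for col in range(arr.shape[2]):
                    if arr[ti, r, col] >= 2 and classes[r, col] == c:
                        total += areas[r, col]
            got = series[
                (series.slice_time_bp == world.times[ti])
                & (series.biome_class == cname)
            ]["area_km2"].iloc[0]
            assert got == pytest.approx(total)


class TestKernelArea:
    def test_standard_normal_matches_analytic_ellipse(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(5000, 2))
        area = kernel_area_2d(pts, coverage=0.99)
        analytic = math.pi * stats.chi2.ppf(0.99, 2)
        assert area == pytest.approx(analytic, rel=0.2)

    def test_duplicated_cloud_same_area(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(800, 2))
        a1 = kernel_area_2d(pts)
        a2 = kernel_area_2d(np.vstack([pts, pts]))
        assert a2 == pytest.approx(a1, rel=0.05)

    def test_scaling_law(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(3000, 2))
        a1 = kernel_area_2d(pts)
        a4 = kernel_area_2d(2 * pts)
        assert a4 / a1 == pytest.approx(4.0, rel=0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            kernel_area_2d(np.zeros((2, 2)))


class TestClimatePCA:
    def test_loadings_orthonormal_and_ordered(self):
        cube = generate_climate_cube(small_spec(seed=61))
        pca = fit_climate_pca(cube)
        gram = pca.loadings.T @ pca.loadings
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-10)
        assert pca.explained_variance[0] >= pca.explained_variance[1]

    def test_collinear_covariates_rejected(self):
        cube = generate_climate_cube(small_spec(seed=61))
        ds = cube.data.copy()
        ds["bio08"] = ds["bio10"] * 2.0  # exact collinearity
        broken = type(cube)(ds, cube.biome_class_map)
        with pytest.raises(ValueError, match="collinear|condition"):
            fit_climate_pca(broken)

    def test_kernel_series_schema_and_flags(self):
        cube = generate_biome_labels(generate_climate_cube(small_spec(seed=62)))
        rng = np.random.default_rng(3)
        from paleoniche.projection import ZoneCube

        arr = rng.choice(
            [0, ZONE_CORE], size=(len(cube.times), *cube.land_mask.shape),
            p=[0.3, 0.7],
        ).astype(np.int8)
        arr[:, ~cube.land_mask] = -1
        zc = ZoneCube(
            zones=xr.DataArray(
                arr,
                coords={"time": cube.times, "lat": cube.lats, "lon": cube.lons},
                dims=("time", "lat", "lon"),
            ),
            thresholds={"t90": 0.5, "t95": 0.4, "t99": 0.3},
        )
        series, pca = niche_kernel_area_series(cube, zc)
        assert set(series.columns) >= {
            "slice_time_bp", "biome_class", "kernel_area", "n_cells",
            "degenerate",
        }
        assert (series["kernel_area"] >= 0).all()
        assert (series.loc[series["n_cells"] < 3, "kernel_area"] == 0).all()
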