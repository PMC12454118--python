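"""Fractional-coverage zonal statistics and rankings."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from biopressure.grid import GridSpec, Layer
from biopressure.pressure import (
    CropData,
    RichnessLayer,
    compute_bp_cell,
    compute_production,
)
from biopressure.zonal import (
    CountryZones,
    country_bp,
    country_crop_metrics,
    country_sum,
    rank_entities,
)

from .conftest import make_layer
from .oracle import country_metrics_loop


def _zones_two_cells(spec):
    return CountryZones(spec, {"X": (np.array([0, 1]), np.array([1.0, 1.0]))})


class TestCountryZonesValidation:
    def test_index_out_of_grid_rejected(self, small_spec):
        with pytest.raises(ValueError, match="out of grid"):
            CountryZones(small_spec, {"X": (np.array([10**6]), np.array([1.0]))})

    def test_coverage_over_one_rejected(self, small_spec):
        with pytest.raises(ValueError, match="coverage"):
            CountryZones(small_spec, {"X": (np.array([0]), np.array([1.5]))})

    def test_summed_coverage_over_one_rejected(self, small_spec):
        with pytest.raises(ValueError, match="exceeds 1"):
            CountryZones(
                small_spec,
                {
                    "X": (np.array([0]), np.array([0.7])),
                    "Y": (np.array([0]), np.array([0.7])),
                },
            )

    def test_empty_country_rejected(self, small_spec):
        with pytest.raises(ValueError, match="no cells"):
            CountryZones(small_spec, {"X": (np.array([], dtype=int), np.array([]))})


class TestCountrySum:
    def test_full_coverage_plain_sum(self, small_spec):
        vals = np.zeros(small_spec.shape)
        vals.ravel()[0] = 3.0
        vals.ravel()[1] = 4.0
        got = country_sum(make_layer(small_spec, vals), _zones_two_cells(small_spec))
        assert got["X"] == 7.0

    def test_fractional_coverage(self, small_spec):
        vals = np.zeros(small_spec.shape)
        vals.ravel()[0] = 10.0
        zones = CountryZones(small_spec, {"X": (np.array([0]), np.array([0.5]))})
        assert country_sum(make_layer(small_spec, vals), zones)["X"] == 5.0

    def test_masked_cells_contribute_zero(self, small_spec):
        vals = np.full(small_spec.shape, 2.0)
        mask = np.zeros(small_spec.shape, bool)
        mask.ravel()[0] = True
        got = country_sum(
            make_layer(small_spec, vals, mask=mask), _zones_two_cells(small_spec)
        )
        assert got["X"] == 2.0

    def test_random_partition_matches_loop_oracle(self, rng):
        spec = GridSpec(15, 15, 1.0, origin_lon=0.0, origin_lat=15.0)
        vals = rng.normal(size=spec.shape)
        labels = rng.integers(0, 4, spec.n_cells)
        zones = CountryZones(
            spec,
            {
                f"C{k}": (np.flatnonzero(labels == k), np.ones((labels == k).sum()))
                for k in range(4)
            },
        )
        got = country_sum(make_layer(spec, vals), zones)
        flat = vals.ravel()
        for k in range(4):
            expected = sum(flat[i] for i in np.flatnonzero(labels == k))
            assert got[f"C{k}"] == pytest.approx(expected, abs=1e-12)


class TestCountryBP:
    def _bp_p_layers(self, spec, bp_cells, p_cells):
        bp_vals = np.zeros(spec.shape)
        p_vals = np.zeros(spec.shape)
        bp_vals.ravel()[: len(bp_cells)] = bp_cells
        p_vals.ravel()[: len(p_cells)] = p_cells
        mask = np.ones(spec.shape, bool)
        mask.ravel()[: len(bp_cells)] = False
        return (
            Layer(spec, bp_vals, mask, "species·ha t-1"),
            Layer(spec, p_vals, np.zeros(spec.shape, bool), "t"),
        )

    def test_equal_weights_is_plain_mean(self, small_spec):
        bp, p = self._bp_p_layers(small_spec, [1.0, 3.0], [1.0, 1.0])
        got = country_bp(bp, p, _zones_two_cells(small_spec))
        assert got["X"] == pytest.approx(2.0)

    def test_production_weighted_mean(self, small_spec):
        bp, p = self._bp_p_layers(small_spec, [1.0, 3.0], [3.0, 1.0])
        got = country_bp(bp, p, _zones_two_cells(small_spec))
        assert got["X"] == pytest.approx(1.5)

    def test_zero_production_country_is_missing_not_zero(self, small_spec):
        bp, p = self._bp_p_layers(small_spec, [1.0, 3.0], [0.0, 0.0])
        got = country_bp(bp, p, _zones_two_cells(small_spec))
        assert np.isnan(got["X"])

    def test_uniform_richness_closed_form(self, rng):
        """With SR uniform, BP_ci = SR * sum(HA) / sum(P) for every country."""
        spec = GridSpec(8, 8, 1.0, origin_lon=0.0, origin_lat=8.0)
        sr_star = 37.0
        ha = rng.uniform(0, 5, spec.shape)
        yld = rng.uniform(0.5, 4, spec.shape)
        crop = CropData(
            "c", make_layer(spec, ha, "ha"), make_layer(spec, yld, "t ha-1"), 0.0
        )
        rich = RichnessLayer(make_layer(spec, sr_star, "species"))
        p = compute_production(crop, dry=False)
        bp = compute_bp_cell(crop, rich, p)
        half = spec.n_cells // 2
        zones = CountryZones(
            spec,
            {
                "A": (np.arange(half), np.ones(half)),
                "B": (np.arange(half, spec.n_cells), np.ones(spec.n_cells - half)),
            },
        )
        got = country_bp(bp, p, zones)
        for cid, idx in (("A", np.arange(half)), ("B", np.arange(half, spec.n_cells))):
            expected = sr_star * ha.ravel()[idx].sum() / p.values.ravel()[idx].sum()
            assert got[cid] == pytest.approx(expected, rel=1e-12)


class TestMetricsTable:
    def test_matches_brute_force_oracle(self, rng):
        spec = GridSpec(15, 15, 1.0, origin_lon=0.0, origin_lat=15.0)
        ha = rng.uniform(0, 5, spec.shape) * (rng.random(spec.shape) < 0.6)
        yld = rng.uniform(0.5, 6, spec.shape)
        sr = rng.integers(0, 50, spec.shape).astype(float)
        water = 80.0
        crop = CropData(
            "c", make_layer(spec, ha, "ha"), make_layer(spec, yld, "t ha-1"), water
        )
        rich = RichnessLayer(make_layer(spec, sr, "species"))
        labels = rng.integers(0, 3, spec.n_cells)
        cov = rng.uniform(0.2, 1.0, spec.n_cells)
        zones = CountryZones(
            spec,
            {
                f"C{k}": (np.flatnonzero(labels == k), cov[labels == k])
                for k in range(3)
            },
        )
        table = country_crop_metrics([crop], rich, zones, dry=True)
        zone_cells = {
            f"C{k}": [
                (i // spec.n_cols, i % spec.n_cols, cov[i])
                for i in np.flatnonzero(labels == k)
            ]
            for k in range(3)
        }
        expected = country_metrics_loop(ha, yld, sr, water, zone_cells, dry=True)
        for _, row in table.iterrows():
            p_exp, asr_exp, bp_exp, bpp_exp = expected[row["country_id"]]
            assert row["production_total"] == pytest.approx(p_exp, rel=1e-12)
            assert row["asr_total"] == pytest.approx(asr_exp, rel=1e-12)
            assert row["bp_mean"] == pytest.approx(bp_exp, rel=1e-12)
            assert row["bp_prod"] == pytest.approx(bpp_exp, rel=1e-12)

    def test_bp_prod_equals_bp_mean_times_production(self, default_world):
        w = default_world
        table = country_crop_metrics(w.crops, w.richness, w.zones)
        ok = table.dropna(subset=["bp_mean"])
        np.testing.assert_allclose(
            ok["bp_prod"], ok["bp_mean"] * ok["production_total"], rtol=1e-9
        )

    def test_bp_mean_within_cell_bp_range(self, default_world):
        w = default_world
        crop = w.crops[0]
        p = compute_production(crop, dry=True)
        bp = compute_bp_cell(crop, w.richness, p)
        means = country_bp(bp, p, w.zones)
        flat_bp = bp.values.ravel()
        flat_ok = ~bp.mask.ravel()
        for cid, (idx, _) in w.zones.cells.items():
            cells = flat_bp[idx][flat_ok[idx]]
            if len(cells) and not np.isnan(means[cid]):
                assert cells.min() - 1e-12 <= means[cid] <= cells.max() + 1e-12

    def test_partition_additivity(self, rng, small_spec):
        """Splitting a country along cell lines preserves the union's sum
        and makes its BP the production-weighted mean of the parts."""
        vals = rng.uniform(0, 10, small_spec.shape)
        layer = make_layer(small_spec, vals)
        n = small_spec.n_cells
        idx = np.arange(n)
        union = CountryZones(small_spec, {"U": (idx, np.ones(n))})
        parts = CountryZones(
            small_spec,
            {"L": (idx[: n // 3], np.ones(n // 3)),
             "R": (idx[n // 3 :], np.ones(n - n // 3))},
        )
        su = country_sum(layer, union)
        sp = country_sum(layer, parts)
        assert su["U"] == pytest.approx(sp["L"] + sp["R"], rel=1e-12)
        p_layer = make_layer(small_spec, rng.uniform(0.1, 5, small_spec.shape), "t")
        bp_layer = make_layer(small_spec, rng.uniform(0, 3, small_spec.shape))
        bu = country_bp(bp_layer, p_layer, union)
        bparts = country_bp(bp_layer, p_layer, parts)
        pw = country_sum(p_layer, parts)
        expected = (bparts["L"] * pw["L"] + bparts["R"] * pw["R"]) / (pw["L"] + pw["R"])
        assert bu["U"] == pytest.approx(expected, rel=1e-12)

    def test_bp_scale_free_in_production_units(self, default_world):
        """Multiplying yields (hence P) by k leaves country BP unchanged."""
        w = default_world
        crop = w.crops[0]
        t1 = country_crop_metrics([crop], w.richness, w.zones)
        scaled = CropData(
            crop.crop_id,
            crop.harvested_area,
            Layer(crop.yield_.spec, crop.yield_.values * 5, units="t ha-1"),
            crop.water_pct,
        )
        t2 = country_crop_metrics([scaled], w.richness, w.zones)
        np.testing.assert_allclose(
            t2["bp_mean"], t1["bp_mean"] / 5, rtol=1e-9
        )


class TestPolygonZones:
    def test_half_cell_coverage(self):
        spec = GridSpec(2, 2, 10.0, origin_lon=0.0, origin_lat=20.0)
        # rectangle covering the west half of both west-column cells
        geoms = {"W": box(0.0, 0.0, 5.0, 20.0)}
        zones = CountryZones.from_polygons(spec, geoms)
        idx, cov = zones.cells["W"]
        assert sorted(idx) == [0, 2]
        np.testing.assert_allclose(cov, 0.5)

    def test_full_containment_gives_unit_coverage(self):
        spec = GridSpec(3, 3, 10.0, origin_lon=0.0, origin_lat=30.0)
        geoms = {"A": box(-1.0, -1.0, 31.0, 31.0)}
        zones = CountryZones.from_polygons(spec, geoms)
        _, cov = zones.cells["A"]
        np.testing.assert_allclose(cov, 1.0)

    def test_exclusion_list(self):
        spec = GridSpec(2, 2, 10.0, origin_lon=0.0, origin_lat=20.0)
        geoms = {"A": box(0, 10, 20, 20), "GRL": box(0, 0, 20, 10)}
        zones = CountryZones.from_polygons(spec, geoms, exclude=["GRL"])
        assert zones.country_ids == ["A"]


class TestRanking:
    def test_dense_ties_lexicographic(self):
        table = pd.DataFrame({"crop_id": ["a", "b", "c"], "v": [5.0, 7.0, 5.0]})
        rk = rank_entities(table, by="v")
        assert list(rk["crop_id"]) == ["b", "a", "c"]
        assert list(rk["rank"]) == [1, 2, 2]

    def test_single_entity(self):
        table = pd.DataFrame({"crop_id": ["only"], "v": [1.0]})
        assert rank_entities(table, by="v")["rank"].tolist() == [1]

    def test_matches_sort_oracle(self, rng):
        vals = rng.random(100)
        table = pd.DataFrame({"crop_id": [f"e{i:03d}" for i in range(100)], "v": vals})
        rk = rank_entities(table, by="v").set_index("crop_id")["rank"]
        order = {v: r + 1 for r, v in enumerate(sorted(set(vals), reverse=True))}
        for i, v in enumerate(vals):
            assert rk[f"e{i:03d}"] == order[v]

    def test_unknown_metric_raises(self):
        with pytest.raises(ValueError, match="unknown metric"):
            rank_entities(pd.DataFrame({"crop_id": ["a"], "v": [1.0]}), by="nope")
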