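"""Soil carbon: binning, imputation, the stock formula, both estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from atollcarbon.soil_carbon import (
    BinScheme,
    SoilSample,
    StockParams,
    assign_bin,
    averages_method,
    compare_methods,
    fit_bin_classifier,
    fit_bin_stats,
    fit_oc_regression,
    impute_organic,
    predict_soil_map,
    stock_formula,
)
from atollcarbon.spatial_core import (
    AttributedPolygon,
    CategoricalRaster,
    GridSpec,
    WATER,
)


def _sample(c_pct, community="C. nucifera", species="Cocos nucifera", bd=1.0,
            year=2016, total=None, islet="I"):
    return SoilSample(
        site_id="s", islet=islet, year=year, community=community, species=species,
        total_c_pct=total if total is not None else min(100.0, c_pct + 0.5),
        organic_c_pct=c_pct if year == 2016 else None,
        bulk_density=bd,
    )


class TestAssignBin:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (9.93, "low"),       # top of the observed low range
            (21.80, "high"),     # bottom of the observed high range
            (10.0, "medium"),    # boundary: 10-20 inclusive is medium
            (20.0, "medium"),
            (0.0, "low"),
            (100.0, "high"),
        ],
    )
    def test_bin_assignment(self, value, expected):
        assert assign_bin(value) == expected

    @given(st.floats(0, 100))
    @settings(max_examples=100, derandomize=True)
    def test_partition_is_total(self, value):
        assert assign_bin(value) in ("low", "medium", "high")

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            assign_bin(-0.1)


class TestImputation:
    def test_half_slope_regression(self):
        train = [_sample(c, total=t) for t, c in [(2, 1), (4, 2), (6, 3)]]
        reg = fit_oc_regression(train)
        assert reg.slope == pytest.approx(0.5)
        assert reg.intercept == pytest.approx(0.0, abs=1e-9)
        target = [_sample(0, year=2019, total=8.0)]
        assert impute_organic(target, reg)[0].organic_c_pct == pytest.approx(4.0)

    def test_identity_fit(self):
        train = [_sample(c, total=c) for c in (1.0, 5.0, 9.0)]
        reg = fit_oc_regression(train)
        out = impute_organic([_sample(0, year=2019, total=7.0)], reg)
        assert out[0].organic_c_pct == pytest.approx(7.0)

    def test_prediction_clamped_to_total(self):
        # steep relationship would predict organic > total; chemistry forbids it
        train = [_sample(c, total=t) for t, c in [(1, 1), (2, 2.4), (3, 4.4)]]
        reg = fit_oc_regression(train)
        out = impute_organic([_sample(0, year=2019, total=3.0)], reg)
        assert out[0].organic_c_pct == pytest.approx(3.0)

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            fit_oc_regression([_sample(1.0), _sample(2.0)])


class TestBinStats:
    def test_counts_and_low_mean(self):
        scheme = fit_bin_stats([_sample(3.0), _sample(5.0), _sample(12.0)])
        assert scheme.stats.loc["low", "n"] == 2
        assert scheme.stats.loc["medium", "n"] == 1
        assert "high" not in scheme.stats.index
        assert scheme.mean_c_pct("low") == pytest.approx(4.0)

    def test_single_sample_se_missing(self):
        scheme = fit_bin_stats([_sample(12.0)])
        assert np.isnan(scheme.stats.loc["medium", "c_pct_se"])


class TestStockFormula:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((0.0, 1.0, 20.0, 1.0), 0.0),
            ((3.64, 1.0, 20.0, 1.0), 72.8),   # low-bin means over 1 ha
            ((30.43, 0.27, 20.0, 1.0), 164.322),  # high-bin means
        ],
    )
    def test_dimensional_identity(self, args, expected):
        assert stock_formula(*args) == pytest.approx(expected)

    @given(
        c=st.floats(0.1, 40), bd=st.floats(0.1, 2), d=st.floats(1, 50),
        a=st.floats(0.01, 100), k=st.floats(0.5, 4),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linear_in_each_argument(self, c, bd, d, a, k):
        base = stock_formula(c, bd, d, a)
        assert stock_formula(c * k, bd, d, a) == pytest.approx(k * base, rel=1e-9)
        assert stock_formula(c, bd, d, a * k) == pytest.approx(k * base, rel=1e-9)

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            stock_formula(-1, 1, 20, 1)


def _classified_samples(n_per=6, seed=0):
    """Bin is a pure function of community: separable training data."""
    rng = np.random.default_rng(seed)
    samples = []
    for comm, sp, mean in [
        ("C. nucifera", "Cocos nucifera", 3.0),
        ("P. grandis", "Pisonia grandis", 14.0),
        ("P. grandis/H. foertherianum", "Pisonia grandis", 30.0),
    ]:
        for _ in range(n_per):
            samples.append(_sample(mean + rng.uniform(-1, 1), community=comm, species=sp))
    return samples


class TestBinClassifier:
    def test_separable_data_high_oob_accuracy(self):
        clf = fit_bin_classifier(_classified_samples(n_per=12), seed=0)
        assert clf.oob_accuracy >= 0.95

    def test_permuted_labels_near_majority_rate(self):
        rng = np.random.default_rng(1)
        samples = _classified_samples(n_per=12, seed=1)
        values = [s.organic_c_pct for s in samples]
        rng.shuffle(values)
        for s, v in zip(samples, values):
            s.organic_c_pct = v
        clf = fit_bin_classifier(samples, seed=0)
        # no signal left: accuracy should be near the 1/3 majority-class rate
        assert clf.oob_accuracy < 0.6

    def test_fixed_seed_deterministic(self):
        samples = _classified_samples()
        labels = [("C. nucifera", "Cocos nucifera"), ("P. grandis", "Pisonia grandis")]
        p1 = fit_bin_classifier(samples, seed=5).predict(labels)
        p2 = fit_bin_classifier(samples, seed=5).predict(labels)
        assert p1 == p2

    def test_single_class_constant_with_warning(self):
        with pytest.warns(UserWarning):
            clf = fit_bin_classifier([_sample(3.0), _sample(4.0)])
        assert clf.predict([("x", "y")]) == ["low"]


def _uniform_rasters(label_comm, label_sp, n=10):
    g = GridSpec(origin=(0.0, n), cell_size=1.0, width=n, height=n)
    legend_c = {0: "", 1: "water", 2: "unknown", 3: "runway", 4: "bare_ground",
                5: "grassland", 10: label_comm}
    legend_s = {0: "", 1: "water", 2: "unknown", 3: "runway", 4: "bare_ground",
                5: "grassland", 10: label_sp}
    codes = np.full((n, n), 10)
    return (
        CategoricalRaster(grid=g, codes=codes, legend=legend_c),
        CategoricalRaster(grid=g, codes=codes.copy(), legend=legend_s),
    )


class TestPredictSoilMap:
    def test_uniform_low_raster_matches_stock_formula(self):
        samples = [_sample(3.64, bd=1.0), _sample(3.64, bd=1.0)]
        with pytest.warns(UserWarning):  # single-class training set
            clf = fit_bin_classifier(samples)
        bins = fit_bin_stats(samples)
        comm, sp = _uniform_rasters("C. nucifera", "Cocos nucifera", n=100)
        density, total = predict_soil_map(clf, comm, sp, bins)
        assert density[0, 0] == pytest.approx(72.8)
        assert total == pytest.approx(72.8 * 1.0)  # 10^4 cells of 1 m^2 = 1 ha

    def test_all_water_raster_zero_total(self):
        samples = [_sample(3.64), _sample(3.64)]
        with pytest.warns(UserWarning):
            clf = fit_bin_classifier(samples)
        bins = fit_bin_stats(samples)
        comm, sp = _uniform_rasters("C. nucifera", "Cocos nucifera")
        comm.codes[:] = WATER
        sp.codes[:] = WATER
        _, total = predict_soil_map(clf, comm, sp, bins)
        assert total == 0.0

    def test_total_conserved_under_partition(self):
        samples = _classified_samples(n_per=12)
        clf = fit_bin_classifier(samples, seed=0)
        bins = fit_bin_stats(samples)
        comm, sp = _uniform_rasters("C. nucifera", "Cocos nucifera", n=40)
        density, total = predict_soil_map(clf, comm, sp, bins)
        cell_ha = comm.grid.cell_area_ha
        halves = density[:, :20].sum() + density[:, 20:].sum()
        assert halves * cell_ha == pytest.approx(total)


class TestAveragesMethod:
    def _samples(self):
        return (
            [_sample(4.0, community="A", species="x", bd=1.0) for _ in range(3)]
            + [_sample(8.0, community="A", species="y", bd=1.0)]  # combo n=1
            + [_sample(20.0, community="B", species="y", bd=0.5) for _ in range(2)]
        )

    def test_combination_mean_used_when_n_at_least_2(self):
        polys = [AttributedPolygon(box(0, 0, 100, 100), community="A", species="x")]
        df, total = averages_method(polys, self._samples())
        assert df.iloc[0]["c_pct"] == pytest.approx(4.0)
        assert total == pytest.approx(stock_formula(4.0, 1.0, 20.0, 1.0))

    def test_combo_n1_falls_back_to_community_mean(self):
        polys = [AttributedPolygon(box(0, 0, 1, 1), community="A", species="y")]
        df, _ = averages_method(polys, self._samples())
        # community A mean over its 4 samples: (4*3 + 8)/4 = 5.0
        assert df.iloc[0]["c_pct"] == pytest.approx(5.0)

    def test_unsampled_community_falls_back_to_species_mean(self):
        polys = [AttributedPolygon(box(0, 0, 1, 1), community="C", species="y")]
        df, _ = averages_method(polys, self._samples())
        # species y pooled over communities: (8 + 20 + 20)/3 = 16
        assert df.iloc[0]["c_pct"] == pytest.approx(16.0)

    def test_blank_species_polygon_contributes_zero(self):
        polys = [AttributedPolygon(box(0, 0, 1, 1), community="A", species="")]
        df, total = averages_method(polys, self._samples())
        assert total == 0.0

    def test_no_samples_errors(self):
        polys = [AttributedPolygon(box(0, 0, 1, 1), community="A", species="x")]
        with pytest.raises(ValueError):
            averages_method(polys, [])


class TestCompareMethods:
    def test_identical_totals(self):
        r = compare_methods(100.0, 100.0)
        assert r["abs_difference_mg_c"] == 0.0

    def test_future_averages_exceeding_rf_reported_not_error(self):
        r = compare_methods(13590.8, 15378.2)
        assert r["more_conservative"] == "random_forest"
        assert r["rel_difference"] > 0.1
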