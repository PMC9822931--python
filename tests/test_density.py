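"""Equal-count density binning, bootstrap uncertainty, and the threshold."""

import numpy as np
import pytest

import windcape as wc
from windcape import density
from windcape.density import _bin_index


def toy_model(edges, counts, areas):
    counts = np.asarray(counts, dtype=int)
    areas = np.asarray(areas, dtype=float)
    return wc.DensityModel(np.asarray(edges, dtype=float), counts, areas,
                           counts / areas * 1.0e4)


class TestSampleCapeAtPoints:
    def test_event_at_cell_center_gets_cell_value(self, small_field):
        ev = wc.EventSet([small_field.lons[3]], [small_field.lats[5]])
        assert wc.sample_cape_at_points(small_field, ev)[0] == small_field.values[5, 3]

    def test_constant_field_gives_constant(self, uniform_field):
        f = uniform_field(321.0)
        ev = wc.EventSet(np.linspace(-69.9, -64.1, 20), np.linspace(-5.9, -0.1, 20))
        assert (wc.sample_cape_at_points(f, ev) == 321.0).all()

    def test_matches_brute_force_containment(self, small_field):
        rng = np.random.default_rng(2)
        lons = rng.uniform(-70.0, -64.0, 50)
        lats = rng.uniform(-6.0, 0.0, 50)
        got = wc.sample_cape_at_points(small_field, wc.EventSet(lons, lats))
        for k in range(50):
            iy = int(np.argmin(np.abs(small_field.lats - lats[k])))
            ix = int(np.argmin(np.abs(small_field.lons - lons[k])))
            assert got[k] == small_field.values[iy, ix]

    def test_outside_extent_lists_indices(self, small_field):
        ev = wc.EventSet([-67.0, 10.0], [-3.0, -3.0])
        with pytest.raises(density.OutOfRegionError) as err:
            wc.sample_cape_at_points(small_field, ev)
        assert err.value.indices == [1]


class TestFitDensityModel:
    def test_1012_events_split_into_168_or_169(self, small_field):
        """The six equal-count groups of 1012 distinct values hold 168 or
        169 events each and conserve the total."""
        rng = np.random.default_rng(0)
        capes = rng.uniform(42.0, 1549.0, 1012)
        model = wc.fit_density_model(capes, small_field, n_bins=6)
        assert set(model.bin_counts) <= {168, 169}
        assert model.bin_counts.sum() == 1012
        assert model.bin_edges[0] == 0.0 and np.isinf(model.bin_edges[-1])

    def test_exact_division_twelve_events(self, small_field):
        capes = np.linspace(100.0, 1200.0, 12)
        model = wc.fit_density_model(capes, small_field, n_bins=6)
        assert (model.bin_counts == 2).all()

    def test_bin_areas_partition_region(self, small_field):
        rng = np.random.default_rng(1)
        capes = rng.uniform(42.0, 1549.0, 100)
        model = wc.fit_density_model(capes, small_field)
        assert model.bin_areas.sum() == pytest.approx(small_field.region_area, rel=1e-12)

    def test_density_definition(self, small_field):
        rng = np.random.default_rng(4)
        model = wc.fit_density_model(rng.uniform(42.0, 1549.0, 60), small_field)
        assert np.allclose(model.bin_density, model.bin_counts / model.bin_areas * 1.0e4)

    def test_membership_reproduces_counts(self, small_field):
        rng = np.random.default_rng(5)
        capes = rng.uniform(42.0, 1549.0, 500)
        model = wc.fit_density_model(capes, small_field)
        recount = np.bincount(_bin_index(model.bin_edges, capes), minlength=6)
        assert (recount == model.bin_counts).all()

    def test_fewer_events_than_bins_raises(self, small_field):
        with pytest.raises(density.UnderdeterminedModelError):
            wc.fit_density_model(np.arange(5.0) + 10.0, small_field, n_bins=6)

    def test_ties_reported(self, small_field):
        capes = np.array([100.0, 200.0, 300.0, 300.0, 300.0, 500.0,
                          600.0, 700.0, 800.0, 900.0, 950.0, 990.0])
        with pytest.warns(density.TieWarning):
            model = wc.fit_density_model(capes, small_field, n_bins=6)
        assert model.bin_counts.sum() == 12  # conservation survives the ties

    def test_recovers_known_step_intensity(self, small_field):
        """Densities fitted to events from a known step intensity agree
        with the true intensity within 3 binomial SEs in every bin."""
        fn = wc.step_intensity([400.0, 1000.0], [1.0, 3.0, 9.0])
        events = wc.simulate_windthrows(small_field, fn, seed=42)
        capes = wc.sample_cape_at_points(small_field, events)
        model = wc.fit_density_model(capes, small_field)
        valid = small_field.valid
        cell_idx = _bin_index(model.bin_edges, small_field.values[valid])
        w = small_field.cell_areas[valid]
        for b in range(model.n_bins):
            sel = cell_idx == b
            true_density = np.average(fn(small_field.values[valid][sel]), weights=w[sel])
            se = np.sqrt(model.bin_counts[b]) / model.bin_areas[b] * 1.0e4
            assert abs(model.bin_density[b] - true_density) <= 3.0 * se


class TestPredictDensity:
    @pytest.fixture
    def model(self):
        return toy_model([0.0, 200.0, 500.0, np.inf], [10, 20, 30], [1.0e4] * 3)

    def test_lower_and_upper_extensions(self, model):
        assert wc.predict_density(model, 0.0) == model.bin_density[0]
        assert wc.predict_density(model, 1.0e6) == model.bin_density[-1]

    def test_interior_edge_goes_to_upper_bin(self, model):
        assert wc.predict_density(model, 200.0) == model.bin_density[1]

    def test_negative_cape_rejected(self, model):
        with pytest.raises(ValueError):
            wc.predict_density(model, -1.0)

    def test_piecewise_constant_and_bounded(self, model):
        x = np.linspace(0.0, 2000.0, 999)
        y = wc.predict_density(model, x)
        assert set(np.unique(y)) <= set(model.bin_density)
        assert y.min() >= model.bin_density.min()
        assert y.max() <= model.bin_density.max()


class TestBootstrap:
    def test_single_bin_sd_is_zero(self, uniform_field):
        model = toy_model([0.0, np.inf], [50], [2.0e4])
        sd = wc.bootstrap_density_sd(np.full(50, 100.0), model, n_boot=200, seed=0)
        assert sd[0] == 0.0

    def test_matches_binomial_closed_form(self, small_field):
        """With fixed edges the replicate counts are multinomial, so the
        SD of a bin holding 169 of 1012 events is √(n·p(1−p)) within 5%
        at n_boot = 10000."""
        rng = np.random.default_rng(3)
        capes = rng.uniform(42.0, 1549.0, 1012)
        model = wc.fit_density_model(capes, small_field)
        sd = wc.bootstrap_density_sd(capes, model, n_boot=10_000, seed=9)
        n = 1012
        for b in range(model.n_bins):
            p = model.bin_counts[b] / n
            expected = np.sqrt(n * p * (1.0 - p)) / model.bin_areas[b] * 1.0e4
            assert sd[b] == pytest.approx(expected, rel=0.05)

    def test_seed_determinism(self, small_field):
        rng = np.random.default_rng(8)
        capes = rng.uniform(42.0, 1549.0, 300)
        model = wc.fit_density_model(capes, small_field)
        sd1 = wc.bootstrap_density_sd(capes, model, n_boot=500, seed=77)
        sd2 = wc.bootstrap_density_sd(capes, model, n_boot=500, seed=77)
        assert (sd1 == sd2).all()

    def test_too_few_replicates(self, small_field):
        model = toy_model([0.0, np.inf], [10], [1.0e4])
        with pytest.raises(ValueError):
            wc.bootstrap_density_sd(np.arange(10.0), model, n_boot=1, seed=0)


class TestFavorableThreshold:
    def test_two_bin_model_returns_single_edge(self):
        model = toy_model([0.0, 750.0, np.inf], [10, 80], [1.0e5, 1.0e5])
        assert wc.favorable_threshold(model) == 750.0

    def test_maximal_contrast_edge(self):
        model = toy_model(
            [0.0, 100.0, 200.0, 300.0, 400.0, 500.0, np.inf],
            [10, 10, 10, 80, 80, 80],
            [1.0e5] * 6,
        )
        assert wc.favorable_threshold(model) == 300.0

    def test_flat_density_warns_and_returns_lowest_edge(self):
        model = toy_model([0.0, 100.0, 200.0, np.inf], [10, 10, 10], [1.0e5] * 3)
        with pytest.warns(density.NoThresholdWarning):
            assert wc.favorable_threshold(model) == 100.0

    def test_recovers_planted_change_point(self, small_field):
        """A step intensity jumping at c* = 900 is recovered within one
        bin width."""
        fn = wc.step_intensity([900.0], [0.8, 8.0])
        events = wc.simulate_windthrows(small_field, fn, seed=5)
        capes = wc.sample_cape_at_points(small_field, events)
        model = wc.fit_density_model(capes, small_field)
        thr = wc.favorable_threshold(model)
        j = int(np.searchsorted(model.bin_edges, 900.0)) - 1
        width = np.diff(model.bin_edges)[max(1, min(j, model.n_bins - 2))]
        assert abs(thr - 900.0) <= width


class TestDensityRatio:
    def test_homogeneous_is_one(self):
        model = toy_model([0.0, 300.0, 600.0, np.inf], [20, 20, 20], [2.0e5] * 3)
        assert wc.density_ratio(model, 300.0) == pytest.approx(1.0)

    def test_two_class_fourfold(self):
        model = toy_model([0.0, 500.0, np.inf], [10, 40], [1.0e5, 1.0e5])
        assert wc.density_ratio(model, 500.0) == pytest.approx(4.0)

    def test_printed_quantities_reconstruct_eightfold(self):
        """1012 events, lowest equal-count bin on 62% of the region, the
        other five sixths on 38%: the fold ratio rounds to 8."""
        total_area = 6.0e6  # km², order of the Amazon
        counts = [169, 169, 169, 169, 168, 168]
        areas = [0.62 * total_area] + [0.38 * total_area / 5.0] * 5
        model = toy_model([0.0, 1023.0, 1100.0, 1200.0, 1300.0, 1400.0, np.inf],
                          counts, areas)
        ratio = wc.density_ratio(model, 1023.0)
        assert round(ratio) == 8

    def test_zero_events_below_raises(self):
        model = toy_model([0.0, 500.0, np.inf], [0, 40], [1.0e5, 1.0e5])
        with pytest.raises(density.UndefinedRatioError):
            wc.density_ratio(model, 500.0)

    def test_threshold_inside_finite_bin_splits_proportionally(self):
        model = toy_model([0.0, 400.0, np.inf], [40, 40], [1.0e5, 1.0e5])
        # at 200, half of bin 1's area and count move above: ratio stays
        # computable and bounded by the bin densities' ratio
        r = wc.density_ratio(model, 200.0)
        assert 1.0 <= r <= 2.0
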