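"""Contracts of the synthetic-landscape and series generators."""

import numpy as np
import pandas as pd
import pytest

from lucsim import demand, synthetic
from lucsim.synthetic import SyntheticScenarioSpec


def spec_with(**kw):
    base = dict(grid_shape=(60, 60), seed=3, autocorrelation_scale=3.0)
    base.update(kw)
    return SyntheticScenarioSpec(**base)


class TestGenerateLandscape:
    def test_degenerate_fractions_give_single_class(self):
        spec = spec_with(class_fractions=(1.0,) + (0.0,) * 7)
        land = synthetic.generate_landscape(spec)
        assert (land.grid == 1).all()

    def test_deterministic_for_fixed_seed(self):
        a = synthetic.generate_landscape(spec_with(seed=7))
        b = synthetic.generate_landscape(spec_with(seed=7))
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_seed_changes_output(self):
        a = synthetic.generate_landscape(spec_with(seed=7))
        b = synthetic.generate_landscape(spec_with(seed=8))
        assert (a.grid != b.grid).any()

    def test_equal_fractions_calibrated_within_band(self):
        spec = spec_with(grid_shape=(200, 200), class_fractions=(0.125,) * 8,
                         autocorrelation_scale=6.0)
        land = synthetic.generate_landscape(spec)
        shares = np.bincount(land.grid.ravel(), minlength=9)[1:] / land.grid.size
        assert shares.min() >= 0.105 and shares.max() <= 0.145

    def test_default_fractions_within_two_points(self, toy_landscape, toy_spec):
        shares = np.bincount(toy_landscape.grid.ravel(), minlength=9)[1:] / toy_landscape.grid.size
        assert np.all(np.abs(shares - np.array(toy_spec.class_fractions)) <= 0.02)

    def test_spatial_autocorrelation_exceeds_random_expectation(self, toy_landscape):
        """Same-class join fraction beats the random-labeling expectation sum p_k^2."""
        g = toy_landscape.grid
        joins = np.concatenate([(g[:, 1:] == g[:, :-1]).ravel(),
                                (g[1:, :] == g[:-1, :]).ravel()])
        shares = np.bincount(g.ravel(), minlength=9)[1:] / g.size
        assert joins.mean() > (shares ** 2).sum() + 0.1

    def test_grid_too_small_names_class(self):
        with pytest.raises(ValueError, match="too small to realize class"):
            synthetic.generate_landscape(spec_with(
                grid_shape=(3, 3),
                class_fractions=(0.3, 0.2, 0.2, 0.1, 0.1, 0.05, 0.03, 0.02)))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            spec_with(class_fractions=(0.5,) * 8)


class TestEvolveLandscape:
    def test_zero_changes_identity(self, toy_landscape, rules):
        out = synthetic.evolve_landscape(toy_landscape, rules, 0, seed=1)
        np.testing.assert_array_equal(out.grid, toy_landscape.grid)

    def test_exact_hamming_distance(self, toy_landscape, rules):
        out = synthetic.evolve_landscape(toy_landscape, rules, 100, seed=1)
        assert int((out.grid != toy_landscape.grid).sum()) == 100

    def test_every_change_is_permitted(self, toy_landscape, rules):
        out = synthetic.evolve_landscape(toy_landscape, rules, 200, seed=2)
        changed = out.grid != toy_landscape.grid
        for i, j in zip(toy_landscape.grid[changed], out.grid[changed]):
            assert rules.allows(int(i), int(j))

    def test_restricted_cells_untouched(self, toy_landscape, rules):
        mask = toy_landscape.grid == 1
        out = synthetic.evolve_landscape(toy_landscape, rules, 150, seed=3,
                                         restricted_mask=mask)
        np.testing.assert_array_equal(out.grid[mask], toy_landscape.grid[mask])

    def test_identity_rules_permit_no_change(self, toy_landscape):
        import pandas as pd
        from lucsim.ca import TransitionRules
        with pytest.warns(UserWarning, match="no change"):
            ident = TransitionRules(pd.DataFrame(np.eye(7, dtype=int)))
        out = synthetic.evolve_landscape(toy_landscape, ident, 0, seed=1)
        np.testing.assert_array_equal(out.grid, toy_landscape.grid)
        with pytest.raises(ValueError, match="changeable"):
            synthetic.evolve_landscape(toy_landscape, ident, 5, seed=1)

    def test_too_many_changes_rejected(self, toy_landscape, rules):
        with pytest.raises(ValueError, match="exceeds"):
            synthetic.evolve_landscape(toy_landscape, rules,
                                       toy_landscape.grid.size + 1, seed=1)


class TestAreaSeries:
    def test_constant_rate_zero_noise(self):
        spec = spec_with(class_fractions=(0.5, 0.5) + (0.0,) * 6,
                         trend_rates=(1.0,) * 8,
                         years=(2000, 2001, 2002, 2003, 2004))
        df = synthetic.generate_area_series(spec, noise_sd=0.0)
        for cls, grp in df.groupby("class"):
            assert np.ptp(grp["area"].to_numpy()) < 1e-9

    def test_geometric_closed_form(self):
        rates = (1.02, 1.0 / 1.02) + (1.0,) * 6
        spec = spec_with(class_fractions=(0.4, 0.4, 0.05, 0.05, 0.04, 0.03, 0.02, 0.01),
                         trend_rates=rates, years=tuple(range(2000, 2006)))
        df = synthetic.generate_area_series(spec, noise_sd=0.0)
        a = df[df["class"] == "paddy_field"].sort_values("year")["area"].to_numpy()
        b = df[df["class"] == "unirrigated_field"].sort_values("year")["area"].to_numpy()
        # renormalization rescales both classes by the same yearly factor,
        # so the ratio keeps the exact geometric trend
        np.testing.assert_allclose((a / b)[-1] / (a / b)[0], (1.02 * 1.02) ** 5, rtol=1e-9)

    def test_yearly_totals_conserved(self, toy_spec):
        df = synthetic.generate_area_series(toy_spec, noise_sd=0.01)
        totals = df.groupby("year")["area"].sum()
        np.testing.assert_allclose(totals, totals.iloc[0], rtol=1e-6)

    def test_too_few_years_names_gm_requirement(self):
        with pytest.raises(ValueError, match="GM"):
            synthetic.generate_area_series(spec_with(years=(2000, 2005, 2010)))

    def test_noise_free_series_reaches_best_grey_accuracy_grade(self, toy_spec):
        """Exactly exponential class trajectories must grade level 1."""
        df = synthetic.generate_area_series(toy_spec, noise_sd=0.0)
        for cls, grp in df.groupby("class"):
            fit = demand.fit_gm11(grp.sort_values("year")["area"].to_numpy())
            assert demand.posterior_difference_test(fit).level == 1


class TestSocioEconomicSeries:
    def test_identical_streams_propagate_unit_factors(self):
        from lucsim import esv
        df = synthetic.generate_socioeconomic_series([2000, 2005], seed=1, identical=True)
        reg = df[(df.region == "regional") & (df.year == 2000)].iloc[0].to_dict()
        nat = df[(df.region == "national") & (df.year == 2000)].iloc[0].to_dict()
        f = esv.correction_factors(reg, nat)
        assert f.Q == f.Pw == f.Pv == f.S == 1.0

    def test_value_domains(self):
        df = synthetic.generate_socioeconomic_series(range(1995, 2019), seed=4)
        assert df["engel_coefficient"].between(0, 1, inclusive="neither").all()
        assert (df["population_density"] > 1).all()
        wide = df.pivot_table(index="year", columns="region")
        for col in ["engel_coefficient", "per_capita_gdp", "urbanization_rate",
                    "population_density", "grain_yield", "grain_price"]:
            ratio = wide[(col, "regional")] / wide[(col, "national")]
            assert ratio.between(0.2, 5).all()

    def test_deterministic(self):
        a = synthetic.generate_socioeconomic_series([2000, 2010], seed=9)
        b = synthetic.generate_socioeconomic_series([2000, 2010], seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_years_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_socioeconomic_series([], seed=0)


class TestDrivingFactors:
    def test_default_stack_has_16_layers(self, toy_landscape):
        stack = synthetic.generate_driving_factors(toy_landscape, seed=3)
        assert stack.n_layers == 16
        assert stack.shape == toy_landscape.shape

    def test_distance_layer_zero_at_feature(self, toy_landscape):
        stack = synthetic.generate_driving_factors(toy_landscape, n_continuous=0,
                                                   n_distance=1, n_multiclass=0, seed=1)
        from scipy.ndimage import distance_transform_edt
        layer = stack.layers[0]
        assert (layer == 0).any()
        np.testing.assert_allclose(layer, distance_transform_edt(layer != 0), atol=1e-9)
        # strictly Euclidean: distance to the nearest zero cell, brute force
        zr, zc = np.nonzero(layer == 0)
        rr, cc = np.indices(layer.shape)
        brute = np.min(np.hypot(rr[..., None] - zr, cc[..., None] - zc), axis=-1)
        np.testing.assert_allclose(layer, brute, atol=1e-9)

    def test_deterministic(self, toy_landscape):
        a = synthetic.generate_driving_factors(toy_landscape, seed=3)
        b = synthetic.generate_driving_factors(toy_landscape, seed=3)
        np.testing.assert_array_equal(a.layers, b.layers)

    def test_multiclass_layers_small_integer_codes(self, toy_landscape):
        stack = synthetic.generate_driving_factors(toy_landscape, n_continuous=0,
                                                   n_distance=0, n_multiclass=2, seed=2)
        for layer in stack.layers:
            assert set(np.unique(layer)) <= {1.0, 2.0, 3.0, 4.0, 5.0}
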