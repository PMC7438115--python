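"""Analytic coalescence-rate curves and their Monte-Carlo counterpart."""

import math

import numpy as np
import pytest

import demesim as d
from demesim.demography import DemographicModel, PopulationDef
from demesim.rates import empirical_rate_from_tmrcas, hazard_band_check
from demesim.validation import two_island_model


class TestAnalytic:
    def test_constant_population_inverse_size_is_N(self):
        grid = np.linspace(0.0, 50000.0, 21)
        curve = d.pairwise_coalescence_rate(d.generic_piecewise_constant([10000.0]), 0, 0, grid)
        np.testing.assert_allclose(curve.inverse_size, 10000.0, rtol=1e-9)

    def test_clean_split_rate_zero_before_divergence(self):
        m = d.generic_im(7300.0, 1e4, 1e4, 4000.0, 0.0, 0.0)
        curve = d.pairwise_coalescence_rate(m, 0, 1, np.array([0.0, 2000.0, 3999.0, 4000.0, 8000.0]))
        assert np.all(curve.rate[:3] == 0.0)
        assert np.all(np.isinf(curve.inverse_size[:3]))
        assert curve.rate[3] == pytest.approx(1.0 / (2 * 7300.0), rel=1e-9)

    def test_mass_conservation_on_structured_model(self):
        m = d.generic_im(7300.0, 1e4, 5e3, 4000.0, 1e-4, 5e-5)
        grid = np.linspace(0.0, 60000.0, 31)
        curve = d.pairwise_coalescence_rate(m, 0, 1, grid)
        # survival is the unabsorbed mass; with the absorbed complement it must
        # stay a probability: monotone from 1, never outside [0, 1]
        assert curve.survival[0] == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(curve.survival) <= 1e-10)
        assert np.all((curve.survival >= -1e-8) & (curve.survival <= 1 + 1e-8))

    def test_single_population_growth_identity(self):
        alpha = 1e-3
        m = DemographicModel(
            id="Growth",
            populations=[PopulationDef("a")],
            initial_sizes=[10000.0],
            initial_growth_rates=[alpha],
            migration_matrix=[[0.0]],
        )
        grid = np.linspace(0.0, 3000.0, 13)
        curve = d.pairwise_coalescence_rate(m, 0, 0, grid)
        truth = d.true_size_curve(m, grid)[:, 0]
        np.testing.assert_allclose(curve.inverse_size, truth, rtol=1e-7)

    def test_panmixia_limit_of_symmetric_island_model(self):
        # as m -> infinity the two-island model coalesces like one deme of 2N
        curve = d.pairwise_coalescence_rate(
            two_island_model(5000.0, 0.5), 0, 0, np.array([0.0, 5000.0, 20000.0, 40000.0])
        )
        np.testing.assert_allclose(curve.inverse_size[1:], 10000.0, rtol=2e-3)

    def test_grid_before_sampling_time_rejected(self, constant_model):
        with pytest.raises(ValueError):
            d.pairwise_coalescence_rate(constant_model, 0, 0, np.array([-10.0, 0.0]))


class TestEmpirical:
    def test_exponential_draws_recover_flat_inverse_size(self):
        N = 2000.0
        rng = np.random.default_rng(1)
        tm = rng.exponential(2 * N, size=200_000)
        # bins narrow relative to the hazard (lambda*width ~ 0.06) so the
        # within-bin discretization bias of the binned estimator stays small
        curve = empirical_rate_from_tmrcas(tm, np.linspace(0.0, 4000.0, 17))
        np.testing.assert_allclose(curve.inverse_size, N, rtol=0.06)

    def test_all_equal_tmrcas_make_single_bin_spike(self):
        tm = np.full(500, 1234.0)
        curve = empirical_rate_from_tmrcas(tm, np.array([0.0, 1000.0, 2000.0, 3000.0]))
        assert curve.rate[0] == 0.0
        assert curve.rate[1] > 0
        assert np.isnan(curve.rate[2])  # nobody left at risk

    def test_two_epoch_step_appears_at_boundary(self, two_epoch_model):
        tm = d.pairwise_tmrca_replicates(two_epoch_model, 0, 0, 50_000, seed=3)
        grid = np.array([0.0, 250.0, 500.0, 750.0, 1000.0, 1100.0, 1200.0])
        emp = empirical_rate_from_tmrcas(tm, grid)
        ana = d.pairwise_coalescence_rate(two_epoch_model, 0, 0, grid[:-1])
        # step visible at the bottleneck; post-step bin close to analytic
        assert emp.inverse_size[0] > 5 * emp.inverse_size[4]
        np.testing.assert_allclose(
            emp.inverse_size[4], ana.inverse_size[4], rtol=0.1
        )

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            empirical_rate_from_tmrcas(np.ones(50), np.array([0.0, 1.0]))


class TestTrueSizeCurve:
    def test_constant_model_flat_line(self, constant_model):
        out = d.true_size_curve(constant_model, np.linspace(0, 1e4, 5))
        np.testing.assert_allclose(out[:, 0], 1000.0)

    def test_disagrees_with_inverse_rate_before_split_under_migration(self):
        m = d.generic_im(7300.0, 1e4, 1e4, 4000.0, 1e-4, 1e-4)
        grid = np.array([0.0, 1000.0, 2000.0])
        census = d.true_size_curve(m, grid)[:, 0]
        curve = d.pairwise_coalescence_rate(m, 0, 1, grid)
        # census sizes are finite; cross-population inverse rate is much larger
        assert np.all(curve.inverse_size > 2 * census)


class TestCrossValidation:
    def test_island_hazard_matches_analytic_band(self):
        m = two_island_model(5000.0, 5e-5)
        tm = d.pairwise_tmrca_replicates(m, 0, 0, 100_000, seed=7)
        res = hazard_band_check(tm, m, 0, 0, np.linspace(0.0, 80000.0, 11))
        assert res["checked"] >= 8
        assert res["failures"] == 0

    def test_analytic_curve_matches_msprime_debugger(self):
        """Independent oracle: msprime's coalescence-rate trajectory for a
        bottleneck + island model must agree with our master-equation curve."""
        msprime = pytest.importorskip("msprime")
        N1, N2, m_rate, T = 8000.0, 3000.0, 8e-5, 2500.0
        model = DemographicModel(
            id="X",
            populations=[PopulationDef("a"), PopulationDef("b")],
            initial_sizes=[N1, N2],
            initial_growth_rates=[0.0, 0.0],
            migration_matrix=[[0.0, m_rate], [m_rate, 0.0]],
            events=[d.SizeGrowthChange(time=T, population=0, new_size=1000.0)],
        )
        dem = msprime.Demography()
        dem.add_population(name="a", initial_size=N1)
        dem.add_population(name="b", initial_size=N2)
        dem.set_migration_rate("a", "b", m_rate)
        dem.set_migration_rate("b", "a", m_rate)
        dem.add_population_parameters_change(time=T, population="a", initial_size=1000.0)
        steps = np.linspace(0.0, 20000.0, 41)
        rates_ms, _ = dem.debug().coalescence_rate_trajectory(
            steps, {"a": 1, "b": 1}, double_step_validation=False
        )
        ours = d.pairwise_coalescence_rate(model, 0, 1, steps)
        np.testing.assert_allclose(ours.rate, rates_ms, rtol=1e-4, atol=1e-12)
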