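import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maxentflux.fixtures import synthetic_strain, synthetic_thermo
from maxentflux.maxent import (
    AtUniformLimit,
    InfeasibleTarget,
    R,
    StrainObservation,
    boltzmann_probabilities,
    compare_variants,
    fit_b,
    fit_b_least_squares,
    fit_strain,
    predict_max_rates,
)
from maxentflux.thermo import ModeThermo

from ._oracles import boltzmann_highprec


def _obs(mu=0.89, qs=12.0, y=0.42):
    return StrainObservation(name="t", mu=mu, qs=qs, yield_bg=y)


class TestBoltzmannProbabilities:
    def test_zero_uptake_gives_uniform(self):
        x = np.array([100.0, 900.0, 400.0])
        p, Z, c = boltzmann_probabilities(x, 0.0, 0.5)
        assert np.allclose(p, 1 / 3)
        assert Z == pytest.approx(3.0)
        assert c == pytest.approx(-math.log(3.0))

    def test_equal_values_split_evenly(self):
        p, _, _ = boltzmann_probabilities([700.0, 700.0], 0.01, 0.4)
        assert np.allclose(p, 0.5)

    def test_three_mode_high_precision_oracle(self):
        x = [231.7, 845.2, 1402.9]
        xi, b = 0.0123, 0.37
        p, Z, c = boltzmann_probabilities(x, xi, b)
        p_ref, _ = boltzmann_highprec(x, xi / b, 1.0)
        assert np.allclose(p, p_ref, rtol=1e-12)
        assert c == pytest.approx(-math.log(Z), rel=1e-12)

    @pytest.mark.parametrize("scale", [1e-3, 1e-1, 1e1, 1e3])
    def test_normalization_across_decades(self, scale):
        rng = np.random.default_rng(0)
        x = rng.uniform(200, 1500, 100)
        p, _, _ = boltzmann_probabilities(x, 0.012 * scale, 0.4)
        assert abs(p.sum() - 1.0) < 1e-10
        assert (p >= 0).all() and p.max() > 0

    def test_monotone_decreasing_in_x(self):
        x = np.array([200.0, 600.0, 1000.0, 1400.0])
        p, _, _ = boltzmann_probabilities(x, 0.01, 0.4)
        assert (np.diff(p) < 0).all()

    def test_larger_b_flattens_toward_uniform(self):
        x = np.array([200.0, 600.0, 1400.0])
        p_lo, _, _ = boltzmann_probabilities(x, 0.01, 0.2)
        p_hi, _, _ = boltzmann_probabilities(x, 0.01, 50.0)
        assert p_hi.max() - p_hi.min() < p_lo.max() - p_lo.min()
        assert np.allclose(p_hi, 1 / 3, atol=0.05)

    def test_unit_scale_consistency(self):
        # expressing the mode values in kJ while scaling the uptake keeps p
        x = np.array([250.0, 800.0, 1300.0])
        p1, _, _ = boltzmann_probabilities(x, 0.012, 0.4)
        p2, _, _ = boltzmann_probabilities(x / 1000.0, 0.012 * 1000.0, 0.4)
        assert np.allclose(p1, p2, rtol=1e-12)

    def test_log_probability_slope_is_gas_constant(self):
        # ln p_j against xi*ds_j/b has slope -1/R for every strain at once
        rng = np.random.default_rng(4)
        x = rng.uniform(200, 1500, 60)
        for xi, b in [(0.00846, 0.30410), (0.01197, 0.41514)]:
            p, _, _ = boltzmann_probabilities(x, xi, b)
            slope = np.polyfit(xi * x / b, np.log(p), 1)[0]
            assert slope == pytest.approx(-1.0 / R, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        xs=st.lists(
            st.floats(min_value=1.0, max_value=5000.0), min_size=2, max_size=30
        ),
        xi=st.floats(min_value=0.0, max_value=1.0),
        b=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_property_normalized_and_ordered(self, xs, xi, b):
        """Probabilities always normalize and never increase with the
        mode's reaction entropy."""
        p, _, c = boltzmann_probabilities(xs, xi, b)
        assert abs(p.sum() - 1.0) < 1e-9
        order = np.argsort(xs)
        assert (np.diff(p[order]) <= 1e-15).all()
        assert math.isfinite(c)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            boltzmann_probabilities([1.0], 0.01, 0.0)
        with pytest.raises(ValueError):
            boltzmann_probabilities([], 0.01, 0.5)


class TestFitB:
    def test_recovers_known_b_exactly(self):
        thermos = synthetic_thermo(50, seed=1)
        strain = synthetic_strain(thermos, 0.40, seed=1)
        ds = [mt.ds for mt in thermos]
        fit = fit_b(ds, strain.xi_hat, strain.ds_observed)
        assert fit.b == pytest.approx(0.40, rel=1e-6)
        assert abs(fit.p.sum() - 1.0) < 1e-10

    def test_grid_search_oracle_agreement(self):
        thermos = synthetic_thermo(50, seed=2)
        strain = synthetic_strain(thermos, 0.55, seed=2)
        ds = np.array([mt.ds for mt in thermos])
        fit = fit_b(ds, strain.xi_hat, strain.ds_observed)
        grid = np.linspace(0.4, 0.7, 20001)
        errs = [
            abs(boltzmann_probabilities(ds, strain.xi_hat, b)[0] @ ds - strain.ds_observed)
            for b in grid
        ]
        assert fit.b == pytest.approx(grid[int(np.argmin(errs))], abs=2e-5)

    def test_scalar_and_least_squares_formulations_agree(self):
        thermos = synthetic_thermo(25, seed=3)
        strain = synthetic_strain(thermos, 0.33, seed=3)
        ds = [mt.ds for mt in thermos]
        fit = fit_b(ds, strain.xi_hat, strain.ds_observed)
        b_lm, p_lm = fit_b_least_squares(ds, strain.xi_hat, strain.ds_observed)
        assert b_lm == pytest.approx(fit.b, rel=1e-6)
        assert np.allclose(p_lm, fit.p, rtol=1e-6)

    def test_uniform_mean_target_reports_limit(self):
        ds = np.array([300.0, 700.0, 1100.0])
        with pytest.raises((InfeasibleTarget, AtUniformLimit)):
            fit_b(ds, 0.012, float(ds.mean()))

    def test_target_bounds_named_in_errors(self):
        ds = np.array([300.0, 700.0, 1100.0])
        with pytest.raises(InfeasibleTarget, match="minimum"):
            fit_b(ds, 0.012, 250.0)
        with pytest.raises(InfeasibleTarget, match="uniform"):
            fit_b(ds, 0.012, 900.0)


class TestPredictMaxRates:
    def test_b_of_one_changes_nothing(self):
        obs = _obs(mu=0.9)
        rates = predict_max_rates(obs, 1.0)
        assert rates["mu_max_per_h"] == pytest.approx(0.9)

    def test_published_strain_ratios(self):
        # evolved strain ALE-1: mu=0.886, b=0.42324 -> mu_max ~ 2.09
        obs = StrainObservation(name="ALE-1", mu=0.886, qs=11.57, yield_bg=0.425)
        rates = predict_max_rates(obs, 0.42324)
        assert rates["mu_max_per_h"] == pytest.approx(2.09, abs=0.005)
        assert rates["qs_max_signed"] == pytest.approx(-27.34, abs=0.05)

    def test_doubling_time_unit(self):
        obs = _obs(mu=math.log(2.0) * 60)  # mu_max of ln2 per minute
        rates = predict_max_rates(obs, 1.0)
        assert rates["tau_min_minutes"] == pytest.approx(1.0)


class TestVariants:
    def test_zero_enthalpy_variants_coincide(self):
        thermos = synthetic_thermo(40, dh_model="zero", seed=6)
        strain = synthetic_strain(thermos, 0.45, seed=6)
        observed = ModeThermo(
            ds=strain.ds_observed, dh=0.0, dg=-310.15 * strain.ds_observed
        )
        report = compare_variants(thermos, strain.observation, observed)
        assert report["entropy"]["b"] == pytest.approx(
            report["affinity"]["b"], rel=1e-9
        )

    def test_correlated_enthalpy_separates_variants(self):
        thermos = synthetic_thermo(40, dh_model="correlated", seed=7)
        strain = synthetic_strain(thermos, 0.45, seed=7)
        ds_obs = strain.ds_observed
        # per-variant observed overall reaction: same p*, own property
        p = strain.p_true
        dg_obs = float(p @ np.array([mt.dg for mt in thermos]))
        dh_obs = dg_obs + 310.15 * ds_obs
        observed = ModeThermo(ds=ds_obs, dh=dh_obs, dg=dg_obs)
        report = compare_variants(thermos, strain.observation, observed)
        assert report["entropy"]["b"] != pytest.approx(report["affinity"]["b"], rel=1e-3)
        # the entropy variant reproduces its own generating b
        assert report["entropy"]["b"] == pytest.approx(0.45, rel=1e-6)

    def test_each_variant_recovers_its_own_generator(self):
        thermos = synthetic_thermo(40, dh_model="correlated", seed=8)
        # generate from the affinity variant
        T = 310.15
        a_over_t = np.array([mt.affinity / T for mt in thermos])
        xi = 0.012
        p_star, _, _ = boltzmann_probabilities(a_over_t, xi, 0.38)
        dg_obs = float(p_star @ np.array([mt.dg for mt in thermos]))
        ds_obs = float(p_star @ np.array([mt.ds for mt in thermos]))
        observed = ModeThermo(ds=ds_obs, dh=dg_obs + T * ds_obs, dg=dg_obs)
        obs = _obs(qs=xi * 1000)
        fit = fit_strain(thermos, obs, observed, variant="affinity")
        assert fit.b == pytest.approx(0.38, rel=1e-6)
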