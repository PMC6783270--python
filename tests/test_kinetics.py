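"""Fibril-elongation models: integration, observables, global fitting."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import spearmanr

from oligopath.equilibrium import population_fractions, solve_equilibrium
from oligopath.kinetics import (DEFAULT_FREE, FibrilDistribution, KineticModel,
                                ThTCurve, average_replicates, fibril_yield,
                                global_fit_tht, initial_rate, integrate_model,
                                tht_signal)
from oligopath.synthetic import (GENERATING_RATE_CONSTANTS, SyntheticSpec,
                                 make_tht_dataset)

HEX = GENERATING_RATE_CONSTANTS["hexamer_addition"]


def hex_model(**overrides):
    return KineticModel("hexamer_addition", {**HEX, **overrides})


class TestIntegrateModel:
    def test_decoupled_limit_relaxes_to_equilibrium(self):
        """With ke = 0 the ladder is frozen and the soluble pool relaxes to
        the equilibrium implied by the rate-constant ratios."""
        model = hex_model(ke=0.0, ke_rev=0.0)
        fib = FibrilDistribution.from_seeds(20.0, 200, 20)
        times = np.linspace(0.0, 5.0, 20)
        traj = integrate_model(model, 300.0, fib, times)
        assert np.allclose(traj.fibrils, traj.fibrils[0], atol=1e-12)
        state = solve_equilibrium(300.0, model.equilibrium_params())
        assert traj.species["X1"][-1] == pytest.approx(state.conc_X1, rel=1e-6)
        assert traj.species["X2"][-1] == pytest.approx(state.conc_X2, rel=1e-6)
        assert traj.species["X6"][-1] == pytest.approx(state.conc_X6, rel=1e-6)

    def test_ladder_matches_matrix_exponential(self):
        """With the soluble pool clamped the ladder is a linear birth-death
        chain whose populations follow the matrix exponential exactly."""
        n = 5
        ke, ke_rev, x = 0.3, 0.05, 40.0
        model = KineticModel("monomer_addition", {"ke": ke, "ke_rev": ke_rev})
        fib = FibrilDistribution.from_seeds(20.0, 200, n)
        times = np.linspace(0.0, 4.0, 9)
        traj = integrate_model(model, x, fib, times,
                               clamp_elongation_unit=True,
                               rtol=1e-10, atol=1e-14)
        a, b = ke * x, ke_rev
        q = np.zeros((n + 1, n + 1))
        for i in range(n):
            q[i, i] -= a          # outflow i -> i+1
            q[i + 1, i] += a
            q[i, i + 1] += b      # inflow from reverse i+1 -> i
            q[i + 1, i + 1] -= b
        for j, t in enumerate(times):
            expected = expm(q * t) @ fib.f
            assert np.allclose(traj.fibrils[j], expected, rtol=1e-6,
                               atol=1e-12)

    @pytest.mark.parametrize("variant", sorted(GENERATING_RATE_CONSTANTS))
    def test_mass_and_fibril_number_conserved(self, variant):
        model = KineticModel(variant, GENERATING_RATE_CONSTANTS[variant])
        fib = FibrilDistribution.from_seeds(20.0, 200, 40)
        times = np.linspace(0.0, 30.0, 31)
        traj = integrate_model(model, 300.0, fib, times)
        mass = traj.monomer_mass()
        assert np.all(np.abs(mass - mass[0]) / mass[0] < 1e-6)
        number = traj.fibril_number()
        assert np.all(np.abs(number - number[0]) / number[0] < 1e-6)
        for arr in traj.species.values():
            assert np.all(arr > -1e-9)
        assert np.all(traj.fibrils > -1e-12)

    def test_concentration_threshold_behavior(self, quiet_integrations):
        """Hexamer addition: negligible elongation at 50 uM, fast at 500 uM."""
        model = hex_model()
        times = np.linspace(0.0, 10.0, 21)  # before the ladder caps at 500 uM
        grown = {}
        for total in (50.0, 500.0):
            fib = FibrilDistribution.from_seeds(20.0, 200, 200)
            traj = integrate_model(model, total, fib, times)
            grown[total] = traj.elongated_monomer_mass()[-1]
        assert grown[50.0] / 50.0 < 0.05
        assert grown[500.0] / 500.0 > 0.1
        assert grown[500.0] / grown[50.0] > 20.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            KineticModel("hexamer_addition", {"ke": 1.0})  # incomplete
        with pytest.raises(ValueError):
            KineticModel("monomer_addition", {"ke": -1.0, "ke_rev": 0.0})
        with pytest.raises(ValueError):
            KineticModel("unknown", {})
        model = hex_model()
        fib = FibrilDistribution.from_seeds(20.0, 200, 10)
        with pytest.raises(ValueError):
            integrate_model(model, -5.0, fib, np.linspace(0, 1, 5))

    def test_short_ladder_warns(self):
        model = hex_model()
        fib = FibrilDistribution.from_seeds(20.0, 200, 5)
        with pytest.warns(UserWarning, match="ladder"):
            integrate_model(model, 500.0, fib, np.linspace(0.0, 50.0, 21))


class TestThTSignal:
    def make_traj(self):
        model = hex_model()
        fib = FibrilDistribution.from_seeds(20.0, 200, 30)
        return integrate_model(model, 300.0, fib, np.linspace(0.0, 20.0, 21))

    def test_no_elongation_gives_baseline(self):
        model = hex_model(ke=0.0, ke_rev=0.0)
        fib = FibrilDistribution.from_seeds(20.0, 200, 10)
        traj = integrate_model(model, 100.0, fib, np.linspace(0.0, 5.0, 6))
        curve = tht_signal(traj, k_tht=3.0, baseline=1.5)
        assert np.allclose(curve.signal, 1.5, atol=1e-10)

    def test_linear_in_k_tht(self):
        traj = self.make_traj()
        a = tht_signal(traj, 1.0, baseline=2.0).signal
        b = tht_signal(traj, 2.0, baseline=2.0).signal
        assert np.allclose(b - 2.0, 2.0 * (a - 2.0), rtol=1e-12)

    def test_equals_weighted_sum(self):
        traj = self.make_traj()
        i = np.arange(traj.fibrils.shape[1])
        by_hand = 0.7 * (traj.fibrils * (i * traj.unit_size)).sum(axis=1) + 0.1
        curve = tht_signal(traj, 0.7, baseline=0.1)
        assert np.allclose(curve.signal, by_hand, rtol=1e-12)
        unit_curve = tht_signal(traj, 0.7, weighting="unit")
        assert np.allclose(unit_curve.signal,
                           0.7 * (traj.fibrils * i).sum(axis=1), rtol=1e-12)

    def test_non_decreasing_without_depolymerization(self):
        model = hex_model(ke_rev=0.0)
        fib = FibrilDistribution.from_seeds(20.0, 200, 30)
        traj = integrate_model(model, 300.0, fib, np.linspace(0.0, 20.0, 21))
        signal = tht_signal(traj, 1.0).signal
        assert np.all(np.diff(signal) >= -1e-9)


class TestInitialRate:
    def test_exact_line(self):
        t = np.linspace(0.0, 10.0, 11)
        curve = ThTCurve(times=t, signal=3.5 * t + 1.0, total_monomer=100.0)
        assert initial_rate(curve, window=10.0) == pytest.approx(3.5)

    def test_window_validation(self):
        t = np.linspace(0.0, 10.0, 11)
        curve = ThTCurve(times=t, signal=t, total_monomer=100.0)
        with pytest.raises(ValueError):
            initial_rate(curve, window=0.5)  # < 3 points

    def test_monomer_addition_rates_are_hyperbolic(self, quiet_integrations):
        """Monomer addition: rate vs concentration is linear then saturating."""
        spec = SyntheticSpec(sigma=0.0, n_replicates=1)
        curves, _ = make_tht_dataset(spec, variant="monomer_addition")
        rates = {c.total_monomer: initial_rate(c, window=10.0) for c in curves}
        concs = sorted(rates)
        per_conc = [rates[c] / c for c in concs]
        assert all(b <= a * 1.01 for a, b in zip(per_conc, per_conc[1:]))
        assert rates[concs[-1]] / rates[concs[0]] < 0.5 * (concs[-1] / concs[0])

    def test_hexamer_addition_rates_have_threshold(self, quiet_integrations):
        """Hexamer addition: upward curvature below ~200 uM, matching the
        finite-difference slopes of the simulated curves."""
        spec = SyntheticSpec(sigma=0.0, n_replicates=1)
        curves, _ = make_tht_dataset(spec, variant="hexamer_addition")
        rates = {c.total_monomer: initial_rate(c, window=10.0) for c in curves}
        assert rates[125.0] / rates[50.0] > 2.0 * (125.0 / 50.0)
        assert rates[500.0] / rates[50.0] > 3.0 * (500.0 / 50.0)
        for c in curves:
            early = c.times <= 10.0
            fd = np.gradient(c.signal[early], c.times[early]).mean()
            assert initial_rate(c, window=10.0) == pytest.approx(
                fd, rel=0.25, abs=1e-3)


class TestFibrilYield:
    def test_zero_without_elongation(self):
        model = hex_model(ke=0.0, ke_rev=0.0)
        fib = FibrilDistribution.from_seeds(20.0, 200, 10)
        traj = integrate_model(model, 100.0, fib, np.linspace(0.0, 5.0, 6))
        assert fibril_yield(traj) == 0.0

    def test_irreversible_growth_consumes_all_monomer(self):
        """ke' = 0 with excess ladder capacity converts the entire soluble
        pool: the long-time yield approaches 1."""
        model = KineticModel("monomer_addition", {"ke": 10.0, "ke_rev": 0.0})
        fib = FibrilDistribution.from_seeds(20.0, 200, 100)  # capacity 10 uM
        traj = integrate_model(model, 5.0, fib, np.linspace(0.0, 40.0, 21))
        assert fibril_yield(traj) == pytest.approx(1.0, abs=1e-3)

    def test_yield_tracks_unseeded_hexamer_population(self, quiet_integrations,
                                                      kinetic_params):
        """Predicted yield across the panel rank-correlates perfectly with the
        no-seed hexamer population (rho = 1 on the 5-point grid)."""
        model = hex_model()
        times = np.linspace(0.0, 10.0, 21)
        concs = [50.0, 125.0, 240.0, 410.0, 500.0]
        yields, p_hex = [], []
        for total in concs:
            fib = FibrilDistribution.from_seeds(20.0, 200, 200)
            yields.append(fibril_yield(integrate_model(model, total, fib, times)))
            p_hex.append(population_fractions(
                solve_equilibrium(total, kinetic_params)).p_hex)
        rho, _ = spearmanr(yields, p_hex)
        assert rho == pytest.approx(1.0)


class TestGlobalFit:
    @pytest.mark.parametrize("variant", sorted(GENERATING_RATE_CONSTANTS))
    def test_parameter_recovery(self, variant, quiet_integrations):
        """Fitting data generated by each variant (5% noise, 5 concentrations,
        5 replicates) recovers the identifiable shared constants within 25%."""
        spec = SyntheticSpec(seed=7)
        curves, _ = make_tht_dataset(spec, variant=variant, n_ladder=60)
        avg = average_replicates(curves)
        gen = dict(GENERATING_RATE_CONSTANTS[variant])
        start = dict(gen)
        for name in DEFAULT_FREE[variant]:
            start[name] = gen[name] * 3.0
        fit = global_fit_tht(avg, variant, start, n_ladder=60,
                             n_starts=1, seed=0)
        assert fit.converged
        identifiable = [n for n in DEFAULT_FREE[variant]
                        if not (variant == "monomer_addition" and n == "ke_rev")]
        for name in identifiable:
            assert fit.params[name] == pytest.approx(gen[name], rel=0.25), name
        assert fit.params["k_tht"] == pytest.approx(spec.k_tht, rel=0.25)

    def test_noise_free_recovery_is_tight(self, quiet_integrations):
        """Zero-noise hexamer data pin ke and the hexamer Kd within 10%."""
        spec = SyntheticSpec(seed=0, sigma=0.0, n_replicates=1)
        curves, _ = make_tht_dataset(spec, n_ladder=60)
        start = dict(HEX, ke=HEX["ke"] * 4.0, k2_rev=HEX["k2_rev"] / 4.0)
        fit = global_fit_tht(curves, "hexamer_addition", start, n_ladder=60,
                             n_starts=1, seed=0)
        assert fit.params["ke"] == pytest.approx(HEX["ke"], rel=0.10)
        kd_fit = fit.params["k2_rev"] / fit.params["k2"]
        kd_gen = HEX["k2_rev"] / HEX["k2"]
        assert kd_fit == pytest.approx(kd_gen, rel=0.10)

    def test_wrong_model_fits_worse(self, quiet_integrations):
        """Monomer addition cannot reproduce hexamer-generated data."""
        spec = SyntheticSpec(seed=0, sigma=0.0, n_replicates=1)
        curves, _ = make_tht_dataset(spec, n_ladder=60)
        fit_h = global_fit_tht(curves, "hexamer_addition", dict(HEX),
                               n_ladder=60, n_starts=1, seed=0)
        fit_m = global_fit_tht(curves, "monomer_addition",
                               GENERATING_RATE_CONSTANTS["monomer_addition"],
                               n_ladder=60, n_starts=2, seed=0)
        assert fit_m.rss > 2.0 * max(fit_h.rss, 1e-12)

    def test_flat_data_imply_no_elongation(self, quiet_integrations):
        """A no-growth dataset yields a fit whose predicted elongation signal
        is negligible against the baseline."""
        t = np.linspace(0.0, 20.0, 21)
        curves = [ThTCurve(times=t, signal=np.full_like(t, 2.0),
                           total_monomer=c) for c in (100.0, 400.0)]
        fit = global_fit_tht(curves, "monomer_addition",
                             {"ke": 0.1, "ke_rev": 1e-3},
                             n_ladder=30, n_starts=1, seed=0)
        model = KineticModel("monomer_addition",
                             {"ke": fit.params["ke"],
                              "ke_rev": fit.params["ke_rev"]})
        fib = FibrilDistribution.from_seeds(20.0, 200, 30)
        traj = integrate_model(model, 400.0, fib, t)
        growth = abs(fit.params["k_tht"]) * np.ptp(traj.elongated_monomer_mass())
        assert growth < 0.02 * 2.0
        assert fit.rss < 1e-3

    def test_requires_two_concentrations(self):
        t = np.linspace(0.0, 5.0, 6)
        curves = [ThTCurve(times=t, signal=t, total_monomer=100.0)]
        with pytest.raises(ValueError):
            global_fit_tht(curves, "monomer_addition",
                           {"ke": 0.1, "ke_rev": 1e-3})


def test_average_replicates_groups_and_means():
    t = np.linspace(0.0, 5.0, 6)
    curves = [ThTCurve(times=t, signal=np.full_like(t, v), total_monomer=c,
                       replicate=r)
              for c in (50.0, 100.0) for r, v in enumerate((1.0, 3.0))]
    avg = average_replicates(curves)
    assert [c.total_monomer for c in avg] == [50.0, 100.0]
    for c in avg:
        assert np.allclose(c.signal, 2.0)
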