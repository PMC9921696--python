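"""Correlation engine and transport calculators against oracles."""

import numpy as np
import pytest

from mdpost import fixtures
from mdpost.dynamic import (
    CorrelationResult,
    autocorrelation_fft,
    crosscorrelation_fft,
    distinct_diffusion,
    ensemble_correlate,
    ionic_conductivity,
    msd_slope,
    running_integral,
    self_diffusion,
    thermal_conductivity,
    viscosity,
)
from mdpost.errors import MDPostError
from mdpost.units import BOLTZMANN, ELEMENTARY_CHARGE


def acf_direct(x):
    """O(n^2) multi-origin ACF oracle, summed over components."""
    n = x.shape[0]
    out = np.empty(n)
    for k in range(n):
        out[k] = np.sum(x[: n - k] * x[k:]) / (n - k)
    return out


class TestCorrelationEngine:
    def test_fft_acf_equals_direct_quadratic_acf(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=(rng.integers(8, 128), 3))
            np.testing.assert_allclose(autocorrelation_fft(x), acf_direct(x),
                                       atol=1e-10)

    def test_cross_correlation_against_direct_loop(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 40, 3))
        direct = np.array([
            np.sum(a[k:] * b[: 40 - k]) / (40 - k) for k in range(40)
        ])
        np.testing.assert_allclose(crosscorrelation_fft(a, b), direct, atol=1e-10)

    def test_constant_series_acf_is_square_with_zero_sem(self):
        c = np.full((60, 3), 2.0)
        corr = ensemble_correlate(c, data_range=20, correlation_time=20, kind="acf")
        np.testing.assert_allclose(corr.mean_values, 12.0)  # 3 comps * 2*2
        np.testing.assert_allclose(corr.sem_values, 0.0, atol=1e-12)

    def test_single_window_flagged_and_sem_zero(self):
        rng = np.random.default_rng(2)
        corr = ensemble_correlate(rng.normal(size=(30, 3)), 30, 30, "acf")
        assert corr.single_ensemble and corr.n_ensembles == 1
        np.testing.assert_array_equal(corr.sem_values, 0.0)

    def test_short_series_errors_with_required_length(self):
        with pytest.raises(MDPostError, match="need at least 50"):
            ensemble_correlate(np.zeros((10, 3)), 50, 10, "acf")

    def test_disjoint_windows_match_manual_split_bit_exactly(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(90, 3))
        corr = ensemble_correlate(x, data_range=30, correlation_time=30, kind="msd")
        manual = np.stack([((x[s:s + 30] - x[s]) ** 2).sum(axis=1)
                           for s in (0, 30, 60)])
        np.testing.assert_array_equal(corr.mean_values, manual.mean(axis=0))
        assert corr.n_ensembles == 3


class TestRunningIntegral:
    def _corr(self, values, dt=1.0, sem=None):
        n = len(values)
        return CorrelationResult(np.arange(n) * dt, np.asarray(values, float),
                                 np.zeros(n) if sem is None else sem, 1, "acf")

    def test_unit_acf_integrates_to_elapsed_time(self):
        corr = self._corr(np.ones(101))
        _, value, _ = running_integral(corr, 101)
        assert value == pytest.approx(100.0)

    def test_integration_beyond_data_range_errors(self):
        with pytest.raises(MDPostError, match="exceeds data_range"):
            running_integral(self._corr(np.ones(10)), 11)

    def test_exponential_acf_integrates_to_tau(self):
        tau, dt = 10.0, 0.05
        t = np.arange(0, 100 * tau, dt)
        corr = self._corr(np.exp(-t / tau), dt=dt)
        _, value, _ = running_integral(corr, len(t))
        assert value == pytest.approx(tau, rel=1e-4)


class TestMSDSlope:
    def test_exact_line_recovers_slope_with_zero_error(self):
        t = np.arange(50.0)
        corr = CorrelationResult(t, 6e-9 * t + 1.0, np.zeros(50), 1, "msd")
        slope, err = msd_slope(corr, (5, 45))
        assert slope == pytest.approx(6e-9)
        assert err <= 1e-9 * slope  # zero up to float cancellation

    def test_constant_offset_does_not_change_slope(self):
        t = np.arange(50.0)
        base = CorrelationResult(t, 2.0 * t, np.zeros(50), 1, "msd")
        shifted = CorrelationResult(t, 2.0 * t + 7.0, np.zeros(50), 1, "msd")
        assert msd_slope(base, (5, 45))[0] == pytest.approx(
            msd_slope(shifted, (5, 45))[0])

    def test_window_outside_lags_errors(self):
        corr = CorrelationResult(np.arange(10.0), np.arange(10.0),
                                 np.zeros(10), 1, "msd")
        with pytest.raises(MDPostError, match="outside"):
            msd_slope(corr, (5, 20))


class TestSelfDiffusion:
    def test_stationary_atoms_have_zero_diffusion_both_methods(self):
        store = fixtures.random_walk(n_particles=5, n_frames=100, D=0.0, seed=0)
        for method in ("einstein_helfand", "green_kubo"):
            res = self_diffusion(store, "X", method)
            assert res.value == pytest.approx(0.0, abs=1e-30)

    def test_einstein_recovers_random_walk_constant(self):
        store = fixtures.random_walk(n_particles=60, n_frames=3000, D=1e-9, seed=10)
        res = self_diffusion(store, "X", "einstein_helfand",
                             data_range=300, correlation_time=100)
        assert res.value == pytest.approx(1e-9, rel=0.05)

    def test_green_kubo_recovers_ou_closed_form_and_agrees_with_einstein(self):
        sigma_v2, tau = 5e4, 2e-14  # D = sigma_v2 * tau = 1e-9
        store = fixtures.ou_velocity(n_particles=60, n_frames=3000,
                                     sigma_v2=sigma_v2, tau=tau, dt=5e-15, seed=11)
        gk = self_diffusion(store, "X", "green_kubo", data_range=300,
                            correlation_time=300, integration_range=40)
        eh = self_diffusion(store, "X", "einstein_helfand", data_range=300,
                            correlation_time=300)
        assert gk.value == pytest.approx(sigma_v2 * tau, rel=0.05)
        combined = np.hypot(gk.uncertainty, eh.uncertainty)
        assert abs(gk.value - eh.value) <= 3.0 * combined

    def test_reported_one_sigma_interval_covers_truth_at_plausible_rate(self):
        """Over 50 seeds the +/-1 SE interval should cover the true D in
        55-85% of runs (a loose bracket: members share windows)."""
        cover = 0
        for seed in range(50):
            store = fixtures.random_walk(n_particles=30, n_frames=1200, D=1e-9,
                                         seed=seed)
            res = self_diffusion(store, "X", "einstein_helfand",
                                 data_range=300, correlation_time=300)
            cover += abs(res.value - 1e-9) <= res.uncertainty
        assert 0.55 <= cover / 50 <= 0.85


class TestDistinctDiffusion:
    def test_pair_sum_identity_matches_brute_force_double_loop(self):
        store = fixtures.random_walk(n_particles=10, n_frames=200, D=1e-9, seed=5)
        dr = 100
        res = distinct_diffusion(store, ("X", "X"), "green_kubo", data_range=dr,
                                 correlation_time=dr, integration_range=dr)
        v = store.load_property("X", "velocities")
        windows = [0, 100]
        acc = np.zeros(dr)
        for s in windows:
            for i in range(10):
                for j in range(10):
                    if i == j:
                        continue
                    acc += np.array([
                        np.sum(v[i, s + k:s + dr] * v[j, s:s + dr - k]) / (dr - k)
                        for k in range(dr)
                    ])
        acc /= len(windows)
        lags = np.arange(dr) * store.box.timestep
        expected = np.trapezoid(acc, lags) / (3 * 10 * 10)
        assert res.value == pytest.approx(expected, rel=1e-10)

    def test_independent_walkers_have_zero_cross_diffusion(self):
        store = fixtures.charged_walkers(n_frames=3000, seed=6)
        res = distinct_diffusion(store, ("P", "M"), "green_kubo", data_range=300,
                                 correlation_time=300, integration_range=100)
        assert abs(res.value) <= 3.0 * res.uncertainty

    def test_identical_motion_makes_cross_equal_self_terms(self):
        """Two atoms moving identically: the distinct sum (2 ordered pairs)
        equals twice each atom's self correlation."""
        store = fixtures.random_walk(n_particles=1, n_frames=400, D=1e-9, seed=7)
        v = store.load_property("X", "velocities")
        v2 = np.concatenate([v, v], axis=0)
        from mdpost.store import BoxMetadata, ConfigurationBatch, SpeciesRecord, TrajectoryStore

        box = store.box
        st2 = TrajectoryStore.create(None, box, [SpeciesRecord("X", (0, 1))])
        st2.ingest([ConfigurationBatch({"X": {"velocities": v2}})])
        res = distinct_diffusion(st2, ("X", "X"), "green_kubo", data_range=200,
                                 correlation_time=200, integration_range=200)
        self_res = self_diffusion(store, "X", "green_kubo", data_range=200,
                                  correlation_time=200, integration_range=200)
        # distinct: (1/(3*2*2)) * 2 * integral_self_sum = self integral / 2
        assert res.value == pytest.approx(self_res.value / 2.0, rel=1e-9)


class TestConductivity:
    def test_neutral_system_has_zero_conductivity_all_methods(self):
        store = fixtures.charged_walkers(
            species_specs=(("N", 10, 1e-9, 0),), n_frames=300, seed=8)
        for method in ("green_kubo", "einstein_helfand", "nernst_einstein",
                       "corrected_nernst_einstein"):
            res = ionic_conductivity(store, method, data_range=100,
                                     correlation_time=100)
            assert res.value == pytest.approx(0.0, abs=1e-25)

    def test_nernst_einstein_closed_form_single_species(self):
        store = fixtures.charged_walkers(
            species_specs=(("P", 20, 1e-9, 1),), n_frames=500, seed=9)
        d = self_diffusion(store, "P", "einstein_helfand", data_range=100,
                           correlation_time=100)
        res = ionic_conductivity(store, "nernst_einstein", data_range=100,
                                 correlation_time=100,
                                 diffusion_results={"P": d})
        beta = 1.0 / (BOLTZMANN * 300.0)
        expected = ELEMENTARY_CHARGE**2 * beta / store.box.volume * 20 * d.value
        assert res.value == pytest.approx(expected, rel=1e-12)

    def test_printed_mass_fraction_convention_available(self):
        store = fixtures.charged_walkers(
            species_specs=(("P", 20, 1e-9, 1),), n_frames=500, seed=9)
        d = self_diffusion(store, "P", "einstein_helfand", data_range=100,
                           correlation_time=100)
        res = ionic_conductivity(store, "nernst_einstein", data_range=100,
                                 correlation_time=100, convention="printed",
                                 diffusion_results={"P": d})
        beta = 1.0 / (BOLTZMANN * 300.0)
        expected = ELEMENTARY_CHARGE**2 * beta / (3 * store.box.volume) * 1.0 * d.value
        assert res.value == pytest.approx(expected, rel=1e-12)

    def test_green_kubo_matches_nernst_einstein_for_independent_ions(self):
        store = fixtures.charged_walkers(n_frames=4000, seed=12)
        gk = ionic_conductivity(store, "green_kubo", data_range=400,
                                correlation_time=400, integration_range=100)
        ne = ionic_conductivity(store, "nernst_einstein", data_range=400,
                                correlation_time=400)
        assert abs(gk.value - ne.value) <= 3 * np.hypot(gk.uncertainty,
                                                        ne.uncertainty)


class TestViscosityAndThermal:
    def test_zero_series_give_zero_coefficients(self):
        store = fixtures.random_walk(n_particles=2, n_frames=50, seed=0)
        store.write_observable("stress_offdiag", np.zeros((50, 3)))
        store.write_observable("thermal_flux", np.zeros((50, 3)))
        assert viscosity(store, "green_kubo", data_range=20,
                         correlation_time=20).value == 0.0
        assert thermal_conductivity(store, "green_kubo", data_range=20,
                                    correlation_time=20).value == 0.0

    def test_green_kubo_viscosity_matches_ou_closed_form(self):
        dt, tau, sig2 = 1e-12, 2e-11, 1e12
        store = fixtures.random_walk(n_particles=2, n_frames=10, box_length=2e-9,
                                     dt=dt, seed=0)
        store.write_observable("stress_offdiag",
                               fixtures.ou_flux(sig2, tau, 200000, dt, seed=21))
        res = viscosity(store, "green_kubo", data_range=1000,
                        correlation_time=1000, integration_range=200)
        V, T = store.box.volume, 300.0
        expected = V * sig2 * tau / (BOLTZMANN * T)
        assert res.value == pytest.approx(expected, rel=0.10)

    def test_doubling_stress_variance_doubles_viscosity(self):
        dt, tau = 1e-12, 2e-11
        store = fixtures.random_walk(n_particles=2, n_frames=10, box_length=2e-9,
                                     dt=dt, seed=0)
        P = fixtures.ou_flux(1e12, tau, 20000, dt, seed=22)
        store.write_observable("stress_offdiag", P)
        v1 = viscosity(store, "green_kubo", data_range=500, correlation_time=500,
                       integration_range=200).value
        store.write_observable("stress_offdiag", np.sqrt(2.0) * P)
        v2 = viscosity(store, "green_kubo", data_range=500, correlation_time=500,
                       integration_range=200).value
        assert v2 == pytest.approx(2.0 * v1, rel=1e-12)

    def test_thermal_conductivity_gk_and_eh_agree_on_tied_fixture(self):
        """When the integrated current is the exact cumulative integral of
        the flux, both estimators measure the same transport coefficient."""
        dt, tau, sig2 = 1e-12, 2e-11, 1e20
        store = fixtures.random_walk(n_particles=2, n_frames=10, box_length=2e-9,
                                     dt=dt, seed=0)
        V = store.box.volume
        J = fixtures.ou_flux(sig2, tau, 60000, dt, seed=23) * V
        store.write_observable("thermal_flux", J)
        store.write_observable("integrated_heat_current",
                               np.cumsum(J, axis=0) * dt)
        gk = thermal_conductivity(store, "green_kubo", data_range=1000,
                                  correlation_time=500, integration_range=200)
        eh = thermal_conductivity(store, "einstein_helfand", data_range=1000,
                                  correlation_time=500)
        T = 300.0
        expected = V * sig2 * tau / (BOLTZMANN * T**2)
        assert gk.value == pytest.approx(expected, rel=0.10)
        assert abs(gk.value - eh.value) <= 3 * np.hypot(gk.uncertainty,
                                                        eh.uncertainty)
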