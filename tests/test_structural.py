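"""Structural calculators against brute-force and closed-form oracles."""

import numpy as np
import pytest

from mdpost import fixtures
from mdpost.errors import MDPostError
from mdpost.store import BoxMetadata, ConfigurationBatch, SpeciesRecord, TrajectoryStore
from mdpost.structural import (
    ADFParams,
    RDFResult,
    compute_adf,
    compute_rdf,
    coordination_number,
    find_rdf_minima,
    golden_section_minimize,
    kirkwood_buff,
    kirkwood_buff_uncertainty,
    potential_of_mean_force,
)
from mdpost.units import BOLTZMANN


def brute_force_rdf_counts(store, pair, n_bins, cutoff):
    """Independent O(N^2) per-atom pair counter with its own minimum image."""
    alpha, beta = pair
    pos_a = store.load_property(alpha, "positions")
    pos_b = pos_a if alpha == beta else store.load_property(beta, "positions")
    L = np.asarray(store.box.edge_lengths)
    edges = np.linspace(0.0, cutoff, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    for f in range(pos_a.shape[1]):
        for i in range(pos_a.shape[0]):
            d = pos_b[:, f, :] - pos_a[i, f, :]
            d -= L * np.rint(d / L)
            r = np.sqrt((d**2).sum(axis=1))
            if alpha == beta:
                r = np.delete(r, i)
            counts += np.histogram(r, bins=edges)[0]
    return counts


def uniform_rdf(g_values, r_max=5.0, counts=None):
    n = len(g_values)
    dr = r_max / n
    centres = (np.arange(n) + 0.5) * dr
    if counts is None:
        counts = np.full(n, 1000)
    return RDFResult(("X", "X"), centres, np.asarray(g_values, float), counts,
                     1, 0.5, 100, dr)


class TestRDF:
    def test_matches_brute_force_pair_counter_exactly(self):
        store = fixtures.ideal_gas(n_particles=60, n_frames=3, box_length=10.0,
                                   seed=9)
        rdf = compute_rdf(store, ("X", "X"), n_bins=50, cutoff=5.0)
        oracle = brute_force_rdf_counts(store, ("X", "X"), 50, 5.0)
        np.testing.assert_array_equal(rdf.counts, oracle)

    def test_two_atoms_at_unit_distance_fill_a_single_bin(self):
        box = BoxMetadata((100.0,) * 3, timestep=1.0, temperature=300.0)
        sp = [SpeciesRecord("A", (0,)), SpeciesRecord("B", (1,))]
        store = TrajectoryStore.create(None, box, sp)
        store.ingest([ConfigurationBatch({
            "A": {"positions": np.array([[[1.0, 1.0, 1.0]]])},
            "B": {"positions": np.array([[[2.0, 1.0, 1.0]]])},
        })])
        rdf = compute_rdf(store, ("A", "B"), n_bins=100, cutoff=10.0)
        nz = np.nonzero(rdf.counts)[0]
        assert len(nz) == 1
        assert abs(rdf.bin_centres[nz[0]] - 1.0) <= rdf.bin_width

    def test_ideal_gas_normalises_to_one(self):
        store = fixtures.ideal_gas(n_particles=200, n_frames=10, box_length=10.0,
                                   seed=2)
        rdf = compute_rdf(store, ("X", "X"), n_bins=100, cutoff=5.0)
        mask = rdf.bin_centres > 1.0
        assert np.mean(np.abs(rdf.g_values[mask] - 1.0)) < 0.05

    def test_lattice_first_peak_bin_contains_the_spacing(self):
        store = fixtures.lattice(n_side=4, a=1.0)
        rdf = compute_rdf(store, ("X", "X"), n_bins=100, cutoff=2.0)
        first = np.nonzero(rdf.counts)[0][0]
        lo = rdf.bin_centres[first] - rdf.bin_width / 2
        hi = rdf.bin_centres[first] + rdf.bin_width / 2
        assert lo <= 1.0 <= hi

    def test_cutoff_beyond_half_box_rejected(self):
        store = fixtures.ideal_gas(n_particles=10, n_frames=1, box_length=10.0)
        with pytest.raises(MDPostError, match="half the shortest box edge"):
            compute_rdf(store, ("X", "X"), cutoff=6.0)


class TestADF:
    def _triple_store(self, centre, p1, p2):
        box = BoxMetadata((100.0,) * 3, timestep=1.0, temperature=300.0)
        sp = [SpeciesRecord("C", (0,)), SpeciesRecord("A", (1,)),
              SpeciesRecord("B", (2,))]
        store = TrajectoryStore.create(None, box, sp)
        store.ingest([ConfigurationBatch({
            "C": {"positions": np.array([[centre]], float)},
            "A": {"positions": np.array([[p1]], float)},
            "B": {"positions": np.array([[p2]], float)},
        })])
        return store

    def test_right_angle_lands_in_90_degree_bin(self):
        store = self._triple_store([5, 5, 5], [6, 5, 5], [5, 6, 5])
        adf = compute_adf(store, ADFParams(("C", "A", "B"), cutoff=2.0, n_bins=18))
        assert np.argmax(adf.raw_weights) == 9  # [90, 100) of 18 bins

    def test_collinear_triple_lands_in_last_bin(self):
        store = self._triple_store([5, 5, 5], [6, 5, 5], [4, 5, 5])
        adf = compute_adf(store, ADFParams(("C", "A", "B"), cutoff=2.0, n_bins=18))
        assert np.argmax(adf.raw_weights) == 17

    @pytest.mark.parametrize("zeta", [0.0, 1.0, 3.0])
    def test_equilateral_triangle_peaks_at_60_regardless_of_zeta(self, zeta):
        box = BoxMetadata((100.0,) * 3, timestep=1.0, temperature=300.0)
        sp = [SpeciesRecord("X", (0, 1, 2))]
        store = TrajectoryStore.create(None, box, sp)
        pts = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]]) + 5.0
        store.ingest([ConfigurationBatch({"X": {"positions": pts[:, None, :]}})])
        adf = compute_adf(store, ADFParams(("X", "X", "X"), 2.0, 18, zeta))
        assert np.argmax(adf.raw_weights) == 6  # [60, 70)

    def test_zeta_zero_matches_brute_force_triple_loop(self):
        store = fixtures.ideal_gas(n_particles=12, n_frames=2, box_length=10.0,
                                   seed=4)
        cutoff, n_bins = 4.0, 36
        adf = compute_adf(store, ADFParams(("X", "X", "X"), cutoff, n_bins, 0.0))
        pos = store.load_property("X", "positions")
        L = np.asarray(store.box.edge_lengths)
        hist = np.zeros(n_bins)
        for f in range(pos.shape[1]):
            for i in range(12):
                for j in range(12):
                    for k in range(j + 1, 12):
                        if i in (j, k):
                            continue
                        dij = pos[j, f] - pos[i, f]
                        dij -= L * np.rint(dij / L)
                        dik = pos[k, f] - pos[i, f]
                        dik -= L * np.rint(dik / L)
                        rij, rik = np.linalg.norm(dij), np.linalg.norm(dik)
                        if rij > cutoff or rik > cutoff:
                            continue
                        c = np.clip(dij @ dik / (rij * rik), -1, 1)
                        theta = np.degrees(np.arccos(c))
                        hist[min(int(theta / 180 * n_bins), n_bins - 1)] += 1
        np.testing.assert_allclose(adf.raw_weights, hist)

    def test_distribution_integrates_to_unit_area(self):
        store = fixtures.ideal_gas(n_particles=15, n_frames=2, seed=6)
        adf = compute_adf(store, ADFParams(("X", "X", "X"), 4.0, 30, 1.0))
        width = 180.0 / 30
        assert adf.density.sum() * width == pytest.approx(1.0)


class TestMinima:
    def test_double_gaussian_minimum_matches_dense_grid_argmin(self):
        r = np.linspace(0.25, 3.0, 551)
        g = 1 + np.exp(-((r - 1) ** 2) / 0.01) + np.exp(-((r - 2) ** 2) / 0.01)
        rdf = RDFResult(("X", "X"), r, g, np.full(len(r), 10**6), 1, 0.5, 100,
                        r[1] - r[0])
        shells = find_rdf_minima(rdf, savgol_window=9, savgol_order=3,
                                 golden_tol=1e-4)
        dense = np.linspace(1.05, 1.95, 200001)
        argmin = dense[np.argmin(1 + np.exp(-((dense - 1) ** 2) / 0.01)
                                 + np.exp(-((dense - 2) ** 2) / 0.01))]
        assert min(abs(m - argmin) for m in shells.minima_radii) < 5e-3

    def test_monotone_curve_has_no_minima_and_errors(self):
        rdf = uniform_rdf(np.linspace(0.1, 2.0, 200))
        with pytest.raises(MDPostError, match="larger cutoff"):
            find_rdf_minima(rdf)

    def test_smoothing_an_already_smooth_curve_barely_moves_the_minimum(self):
        r = np.linspace(0.25, 3.0, 551)
        g = 1 + np.exp(-((r - 1) ** 2) / 0.05) + np.exp(-((r - 2) ** 2) / 0.05)
        rdf = RDFResult(("X", "X"), r, g, np.full(len(r), 10**6), 1, 0.5, 100,
                        r[1] - r[0])
        tol = 1e-4
        narrow = find_rdf_minima(rdf, savgol_window=5, savgol_order=3,
                                 golden_tol=tol)
        wide = find_rdf_minima(rdf, savgol_window=11, savgol_order=3,
                               golden_tol=tol)
        assert abs(narrow.minima_radii[0] - wide.minima_radii[0]) < 10 * tol

    def test_golden_section_refines_to_tolerance(self):
        f = lambda x: (x - 1.2345) ** 2
        assert abs(golden_section_minimize(f, 0.0, 3.0, 1e-8) - 1.2345) < 1e-8


class TestCoordinationNumber:
    def test_uniform_g_gives_ideal_gas_shell_population(self):
        rdf = uniform_rdf(np.ones(500))
        rho = rdf.number_density_beta
        from mdpost.structural import ShellBoundaries

        shells = ShellBoundaries([2.0], 9, 3, 1e-4)
        n, _ = coordination_number(rdf, shells, 1)
        assert n == pytest.approx(4.0 / 3.0 * np.pi * rho * 2.0**3, rel=1e-3)

    def test_simple_cubic_first_shell_is_six_neighbours(self):
        store = fixtures.lattice(n_side=6, a=1.0)
        rdf = compute_rdf(store, ("X", "X"), n_bins=250, cutoff=2.5)
        shells = find_rdf_minima(rdf)
        n, unc = coordination_number(rdf, shells, 1)
        # direct neighbour-count oracle at the first minimum radius
        pos = store.load_property("X", "positions")[:, 0, :]
        L = np.asarray(store.box.edge_lengths)
        d = pos[None] - pos[:, None]
        d -= L * np.rint(d / L)
        r = np.linalg.norm(d, axis=-1)
        direct = (r[0] <= shells.minima_radii[0]).sum() - 1
        assert direct == 6
        assert n == pytest.approx(6.0, abs=0.1)

    def test_zero_density_gives_zero(self):
        rdf = uniform_rdf(np.ones(100))
        rdf.number_density_beta = 0.0
        from mdpost.structural import ShellBoundaries

        n, unc = coordination_number(rdf, ShellBoundaries([1.0], 9, 3, 1e-4), 1)
        assert n == 0.0 and unc == 0.0


class TestPMF:
    def test_uniform_g_gives_zero_free_energy(self):
        pmf = potential_of_mean_force(uniform_rdf(np.ones(100)), 300.0)
        assert np.nanmax(np.abs(pmf.w_values)) == 0.0

    def test_definition_at_g_equal_inverse_e(self):
        g = np.ones(100)
        g[40] = np.exp(-1.0)
        pmf = potential_of_mean_force(uniform_rdf(g), 300.0)
        assert pmf.w_values[40] == pytest.approx(BOLTZMANN * 300.0)

    def test_zero_g_bins_are_masked(self):
        g = np.ones(100)
        g[:10] = 0.0
        pmf = potential_of_mean_force(uniform_rdf(g), 300.0)
        assert np.all(np.isnan(pmf.w_values[:10]))
        assert np.all(np.isfinite(pmf.w_values[10:]))

    def test_deeper_rdf_peak_gives_lower_pmf_minimum(self):
        heights = [1.5, 2.5, 4.0]
        minima = []
        for h in heights:
            r = np.linspace(0.005, 4.995, 500)
            g = 1 + (h - 1) * np.exp(-((r - 2) ** 2) / 0.05)
            pmf = potential_of_mean_force(uniform_rdf(g), 300.0)
            minima.append(pmf.w_min)
        assert minima[0] > minima[1] > minima[2]


class TestKirkwoodBuff:
    def test_uniform_g_gives_identically_zero_integral(self):
        r, G = kirkwood_buff(uniform_rdf(np.ones(200)))
        np.testing.assert_array_equal(G, np.zeros_like(G))

    def test_step_rdf_reproduces_closed_form(self):
        # g = 1 + A on [0, R], 1 beyond: G(inf) = (4/3) pi A R^3
        A, R = 0.5, 2.0
        n = 1000
        r = np.linspace(0.0025, 4.9975, n)
        g = np.where(r <= R, 1 + A, 1.0)
        rdf = uniform_rdf(g, r_max=5.0)
        rdf.bin_centres = r
        _, G = kirkwood_buff(rdf)
        expected = 4.0 / 3.0 * np.pi * A * R**3
        assert G[-1] == pytest.approx(expected, rel=5e-3)

    def test_ideal_gas_integral_within_propagated_sampling_error(self):
        store = fixtures.ideal_gas(n_particles=300, n_frames=10, box_length=10.0,
                                   seed=8)
        rdf = compute_rdf(store, ("X", "X"), n_bins=100, cutoff=5.0)
        _, G = kirkwood_buff(rdf)
        sigma = kirkwood_buff_uncertainty(rdf)
        assert abs(G[-1]) < 3.0 * sigma

    def test_post_processing_is_pure_function_of_the_rdf(self):
        """CN/PMF/KB recomputation from a stored RDF never re-reads the store."""
        store = fixtures.ideal_gas(n_particles=50, n_frames=2, seed=1)
        rdf = compute_rdf(store, ("X", "X"), n_bins=100, cutoff=4.0)
        store.close()  # no trajectory access possible beyond this point
        kirkwood_buff(rdf)
        potential_of_mean_force(rdf, 300.0)
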