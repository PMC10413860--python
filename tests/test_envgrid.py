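"""Environment grids, Coulomb potentials, and LDA nonadditive terms."""

import numpy as np
import pytest

from basinavg.constants import BOHR_ANGSTROM
from basinavg.envgrid import (
    GridSpec,
    PotentialField,
    accumulate_density,
    assemble_embedding_potential,
    dirac_exchange_potential,
    effective_electrons,
    electrostatic_potential,
    nonadditive_lda_potential,
    thomas_fermi_potential,
    vwn5_correlation_potential,
    _C_TF,
)
from basinavg.trajio import ChargeTyping


def _typing(q=1.0, Z=1):
    return ChargeTyping(q={"X": q}, Z={"X": Z})


class TestEffectiveElectrons:
    @pytest.mark.parametrize("Z, q, n", [(8, -0.834, 8.834), (6, 0.0, 6.0), (1, 0.417, 0.583)])
    def test_examples(self, Z, q, n):
        assert effective_electrons(Z, q) == pytest.approx(n, abs=1e-12)

    def test_nonpositive_Z_raises(self):
        with pytest.raises(ValueError):
            effective_electrons(0, 0.1)


class TestAccumulate:
    def test_static_atom_single_voxel(self):
        grid = GridSpec(np.zeros(3), 0.5, (4, 4, 4))
        frames = np.tile(np.array([[[0.5, 1.0, 1.5]]]), (10, 1, 1))
        g = accumulate_density(frames, ["X"], _typing(), grid)
        dens = g.densities["X"]
        assert np.count_nonzero(dens) == 1
        assert dens[1, 2, 3] * grid.voxel_volume == pytest.approx(1.0, abs=1e-12)

    def test_alternating_atom_half_occupancy(self):
        grid = GridSpec(np.zeros(3), 1.0, (3, 3, 3))
        pos = np.array([[[0.0, 0.0, 0.0]], [[2.0, 0.0, 0.0]]])
        frames = np.tile(pos, (50, 1, 1)).reshape(100, 1, 3)
        g = accumulate_density(frames, ["X"], _typing(), grid)
        dens = g.densities["X"]
        assert dens[0, 0, 0] * grid.voxel_volume == pytest.approx(0.5, abs=1e-12)
        assert dens[2, 0, 0] * grid.voxel_volume == pytest.approx(0.5, abs=1e-12)

    def test_types_accumulate_independently(self, rng):
        grid = GridSpec(np.zeros(3), 0.5, (8, 8, 8))
        typing = ChargeTyping(q={"O": -0.8, "H": 0.4}, Z={"O": 8, "H": 1})
        frames = rng.uniform(0.5, 3.0, (20, 4, 3))
        labels = ["O", "H", "O", "H"]
        g = accumulate_density(frames, labels, typing, grid)
        assert g.mean_in_grid_count("O") == pytest.approx(2.0, abs=1e-10)
        assert g.mean_in_grid_count("H") == pytest.approx(2.0, abs=1e-10)

    def test_density_normalization_identity(self, rng):
        """sum_alpha g_t nu_alpha equals the mean in-grid count, exactly."""
        grid = GridSpec(np.zeros(3), 0.7, (6, 6, 6))
        frames = rng.uniform(-1.0, 5.0, (30, 8, 3))  # some atoms fall outside
        g = accumulate_density(frames, ["X"] * 8, _typing(), grid)
        total_in = 0
        for f in range(30):
            idx = np.rint((frames[f] - grid.origin) / grid.spacing).astype(int)
            total_in += np.sum(np.all((idx >= 0) & (idx < 6), axis=1))
        assert g.mean_in_grid_count("X") == pytest.approx(total_in / 30, abs=1e-10)
        assert g.out_of_grid["X"] == 30 * 8 - total_in

    def test_charge_conservation(self, rng):
        grid = GridSpec(np.zeros(3), 0.5, (10, 10, 10))
        typing = ChargeTyping(q={"O": -0.834, "H": 0.417}, Z={"O": 8, "H": 1})
        frames = rng.uniform(0.5, 4.0, (25, 6, 3))
        labels = ["O", "O", "H", "H", "H", "H"]
        g = accumulate_density(frames, labels, typing, grid)
        expected = -0.834 * g.mean_in_grid_count("O") + 0.417 * g.mean_in_grid_count("H")
        assert g.total_charge() == pytest.approx(expected, abs=1e-10)


class TestElectrostatic:
    def test_point_charge_analytic(self):
        grid = GridSpec(np.zeros(3), 0.5, (3, 3, 3))
        frames = np.array([[[0.5, 0.5, 0.5]]])
        g = accumulate_density(frames, ["X"], _typing(q=1.0), grid)
        query = np.array([[0.5, 0.5, 0.5 + 10.0 * BOHR_ANGSTROM]])
        v = electrostatic_potential(g, query)
        assert v.values[0] == pytest.approx(0.1, abs=1e-6)

    def test_empty_grid_zero(self):
        grid = GridSpec(np.zeros(3), 0.5, (3, 3, 3))
        g = accumulate_density(np.array([[[99.0, 99.0, 99.0]]]), ["X"], _typing(), grid)
        v = electrostatic_potential(g, np.array([[1.0, 1.0, 1.0]]))
        assert v.values[0] == 0.0

    def test_dipole_far_field_converges(self):
        """Far-field error vs the analytic dipole shrinks with grid refinement."""
        d = 1.0  # Angstrom separation
        pos = np.array([[[0.0, 0.0, 0.5 * d], [0.0, 0.0, -0.5 * d]]])
        labels = ["P", "M"]
        typing = ChargeTyping(q={"P": 1.0, "M": -1.0}, Z={"P": 1, "M": 1})
        query = np.array([[0.3, 0.2, 12.0]])
        r_b = np.linalg.norm(query[0]) / BOHR_ANGSTROM
        # exact two-charge potential
        vp = 1.0 / (np.linalg.norm(query[0] - pos[0, 0]) / BOHR_ANGSTROM)
        vm = -1.0 / (np.linalg.norm(query[0] - pos[0, 1]) / BOHR_ANGSTROM)
        exact = vp + vm
        errors = []
        for spacing in (0.8, 0.4, 0.2):
            grid = GridSpec(np.full(3, -2.0) + 0.013, spacing, tuple(np.full(3, int(4.0 / spacing) + 1)))
            g = accumulate_density(pos, labels, typing, grid)
            v = electrostatic_potential(g, query)
            errors.append(abs(v.values[0] - exact))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 0.05 * abs(exact) + 1e-8

    def test_singularity_regularized(self):
        grid = GridSpec(np.zeros(3), 0.5, (3, 3, 3))
        g = accumulate_density(np.array([[[0.5, 0.5, 0.5]]]), ["X"], _typing(), grid)
        v = electrostatic_potential(g, np.array([[0.5, 0.5, 0.5]]))  # on the charge
        assert np.isfinite(v.values[0])
        r_min_b = 0.25 / BOHR_ANGSTROM
        assert v.values[0] == pytest.approx(1.0 / r_min_b, abs=1e-10)


class TestNonadditive:
    def test_zero_environment_density(self, rng):
        rho_a = rng.uniform(0.0, 0.1, (4, 4, 4))
        v = nonadditive_lda_potential(rho_a, np.zeros_like(rho_a))
        np.testing.assert_allclose(v.values, 0.0, atol=1e-14)

    def test_uniform_density_tf_closed_form(self):
        rho0 = 0.02
        rho = np.full((3, 3, 3), rho0)
        v = nonadditive_lda_potential(rho, rho, functionals=("TF",))
        expected = (5.0 / 3.0) * _C_TF * ((2 * rho0) ** (2 / 3) - rho0 ** (2 / 3))
        np.testing.assert_allclose(v.values, expected, atol=1e-10)

    def test_zero_reference_gives_plain_functional(self, rng):
        rho_b = rng.uniform(0.0, 0.05, (3, 3, 3))
        v = nonadditive_lda_potential(np.zeros_like(rho_b), rho_b)
        direct = (thomas_fermi_potential(rho_b) + dirac_exchange_potential(rho_b)
                  + vwn5_correlation_potential(rho_b))
        np.testing.assert_allclose(v.values, direct, atol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            nonadditive_lda_potential(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))

    def test_negative_density_raises(self):
        rho = np.zeros((2, 2, 2))
        bad = rho.copy()
        bad[0, 0, 0] = -1e-3
        with pytest.raises(ValueError):
            nonadditive_lda_potential(rho, bad)

    def test_vwn_matches_numerical_derivative(self):
        """v_c must equal d(rho * eps_c)/drho; checked by central differences."""
        from basinavg.envgrid import _vwn_eps_and_deriv

        for rho in (1e-4, 1e-3, 1e-2, 1e-1, 1.0):
            h = rho * 1e-6

            def e_density(r):
                rs = (3.0 / (4.0 * np.pi * r)) ** (1.0 / 3.0)
                eps, _ = _vwn_eps_and_deriv(np.sqrt(np.atleast_1d(rs)))
                return r * eps[0]

            numeric = (e_density(rho + h) - e_density(rho - h)) / (2 * h)
            analytic = vwn5_correlation_potential(np.array([rho]))[0]
            assert analytic == pytest.approx(numeric, rel=1e-5)
            assert analytic < 0.0  # correlation potential is attractive

    def test_assemble_is_pointwise_sum(self, rng):
        es = PotentialField(rng.normal(size=(4, 4, 4)), "electrostatic")
        nad = PotentialField(rng.normal(size=(4, 4, 4)), "nonadditive")
        total = assemble_embedding_potential(es, nad)
        np.testing.assert_allclose(total.values, es.values + nad.values, atol=1e-15)
        only = assemble_embedding_potential(es, None)
        np.testing.assert_allclose(only.values, es.values, atol=1e-15)

    def test_assemble_mismatch_raises(self):
        with pytest.raises(ValueError):
            assemble_embedding_potential(PotentialField(np.zeros(3), "electrostatic"),
                                         PotentialField(np.zeros(4), "nonadditive"))


class TestBasinCoupling:
    def test_per_basin_centroids_track_environment(self, two_basin_run):
        """Basin-restricted grids put the charge centroid at the conformer's environment."""
        from basinavg import synthgen as sg
        from basinavg.geometry import align_trajectory, apply_alignment

        sol = two_basin_run["solute"]
        env = two_basin_run["env"]
        truth = two_basin_run["truth"]
        part = two_basin_run["partition"]
        core = [0, 1, 2, 3, 8]  # atoms rigid across the conformers
        _, rot, cm = align_trajectory(sol.coords, 0, subset=core)
        env_al = apply_alignment(env.coords, rot, cm)
        typing = sg.default_charge_typing()
        grid = GridSpec.from_bounding_box(sol.coords[0], margin=6.0, spacing=0.5)
        for b in part.basins:
            labs, counts = np.unique(truth.labels[b], return_counts=True)
            lab = labs[np.argmax(counts)]
            g = accumulate_density(env_al[b], env.elements, typing, grid)
            dens = sum(g.densities.values())
            centroid = (dens[..., None] * grid.centers()).sum(axis=(0, 1, 2)) / dens.sum()
            assert np.all(np.abs(centroid - truth.env_centroids[lab]) < grid.spacing)
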