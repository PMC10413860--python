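"""Structure averaging, rotor placement, and theta diagnostics."""

import numpy as np
import pytest

import basinavg as ba
from basinavg import synthgen as sg
from basinavg.avgstruct import (
    RotorGroup,
    average_internal,
    basin_average_structure,
    direct_average_structure,
    is_bimodal,
    place_free_rotors,
)
from basinavg.geometry import kabsch_rmsd_batch, wrap_to_pm180
from basinavg.zmatrix import ZMatrixSeries, chain_connectivity


def _series(dihedral_rows, bonds=1.5, angles=110.0):
    """Tiny 4-atom ZMatrixSeries with a single controllable dihedral."""
    rows = np.asarray(dihedral_rows, dtype=float)
    n = rows.size
    b = np.full((n, 4), np.nan)
    b[:, 1:] = bonds
    a = np.full((n, 4), np.nan)
    a[:, 2:] = angles
    d = np.full((n, 4), np.nan)
    d[:, 3] = rows
    return ZMatrixSeries(chain_connectivity(4), ["C"] * 4, b, a, d)


class TestAverageInternal:
    def test_wraparound_dihedral(self):
        z = average_internal(_series([179.0, -179.0]))
        assert z.dihedrals[3] == pytest.approx(180.0, abs=1e-10)

    def test_symmetric_bond_noise(self, rng):
        noise = rng.normal(0.0, 0.05, 100)
        zs = _series(np.zeros(100))
        zs.bonds[:, 2] = 1.50 + noise
        z = average_internal(zs)
        assert z.bonds[2] == pytest.approx(1.50 + noise.mean(), abs=1e-12)

    def test_known_means_recovered(self, rng):
        """Closed-form check: plain means of every coordinate, exactly."""
        vals = rng.uniform(-170.0, 170.0, 50)
        zs = _series(vals)
        zs.bonds[:, 1] = rng.uniform(1.3, 1.6, 50)
        zs.angles[:, 2] = rng.uniform(100.0, 130.0, 50)
        z = average_internal(zs)
        assert z.bonds[1] == pytest.approx(sum(zs.bonds[:, 1]) / 50, abs=1e-12)
        assert z.angles[2] == pytest.approx(sum(zs.angles[:, 2]) / 50, abs=1e-12)

    def test_frame_order_invariance(self, rng):
        vals = rng.uniform(-179.0, 179.0, 40)
        zs = _series(vals)
        perm = rng.permutation(40)
        z1 = average_internal(zs)
        z2 = average_internal(_series(vals[perm]))
        assert z1.dihedrals[3] == pytest.approx(z2.dihedrals[3], abs=1e-10)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            average_internal(_series([10.0]), frames=[])


class TestRotorPlacement:
    def _rotor_series(self, pivot_values, offsets=(120.0, -120.0)):
        n = len(pivot_values)
        b = np.full((n, 6), np.nan)
        b[:, 1:] = 1.2
        a = np.full((n, 6), np.nan)
        a[:, 2:] = 109.5
        d = np.full((n, 6), np.nan)
        d[:, 3] = pivot_values
        d[:, 4] = wrap_to_pm180(np.asarray(pivot_values) + offsets[0])
        d[:, 5] = wrap_to_pm180(np.asarray(pivot_values) + offsets[1])
        conn = chain_connectivity(6)
        return ZMatrixSeries(conn, ["C"] * 6, b, a, d)

    def test_major_cluster_and_offsets(self, rng):
        pivots = np.concatenate([
            60.0 + rng.normal(0.0, 3.0, 55),
            180.0 + rng.normal(0.0, 3.0, 45),
        ])
        zs = self._rotor_series(wrap_to_pm180(pivots))
        out = place_free_rotors(zs, [RotorGroup(3, (4, 5))], seed=0)
        assert out[3] == pytest.approx(60.0, abs=2.0)
        assert wrap_to_pm180(out[4] - out[3]) == pytest.approx(120.0, abs=1e-6)
        assert wrap_to_pm180(out[5] - out[3]) == pytest.approx(-120.0, abs=1e-6)

    def test_single_cluster_center(self, rng):
        pivots = 45.0 + rng.normal(0.0, 4.0, 80)
        zs = self._rotor_series(pivots)
        out = place_free_rotors(zs, [RotorGroup(3, ())], seed=0)
        assert out[3] == pytest.approx(pivots.mean(), abs=1e-6)

    def test_observed_offsets_not_idealized(self, rng):
        """Dependents sit at the trajectory's own mean offset, e.g. 119.5."""
        pivots = 60.0 + rng.normal(0.0, 2.0, 60)
        zs = self._rotor_series(pivots, offsets=(119.5, -119.5))
        out = place_free_rotors(zs, [RotorGroup(3, (4, 5))], seed=0)
        assert wrap_to_pm180(out[4] - out[3]) == pytest.approx(119.5, abs=1e-6)
        assert wrap_to_pm180(out[5] - out[3]) == pytest.approx(-119.5, abs=1e-6)

    def test_empty_basin_raises(self):
        zs = self._rotor_series([60.0, 61.0])
        with pytest.raises(ValueError):
            place_free_rotors(zs, [RotorGroup(3, ())], frames=np.array([], dtype=int))


class TestBasinAverage:
    def test_rigid_trajectory_reproduces_frame(self, rng):
        from scipy.spatial.transform import Rotation

        cfg = sg.default_config(n_frames=1, schedule=((0, "A"),), seed=4, rigid_motion=False)
        sol, _, truth = sg.make_trajectory(cfg)
        base = sol.coords[0]
        frames = np.empty((20, base.shape[0], 3))
        for f in range(20):
            R = Rotation.random(random_state=rng).as_matrix()
            frames[f] = base @ R.T + rng.uniform(-5, 5, 3)
        traj = ba.Trajectory(sol.elements, frames)
        avg = basin_average_structure(traj, np.arange(20), truth.connectivity)
        assert kabsch_rmsd_batch(avg.geometry.coords[None], base)[0] < 1e-8

    def test_recovers_generator_references(self, two_basin_run):
        """Per-basin averaged internals sit within sampling error of the truth."""
        part = two_basin_run["partition"]
        truth = two_basin_run["truth"]
        sol = two_basin_run["solute"]
        cfg = two_basin_run["cfg"]
        for b in part.basins:
            labs, counts = np.unique(truth.labels[b], return_counts=True)
            lab = labs[np.argmax(counts)]
            avg = basin_average_structure(sol, b, truth.connectivity,
                                          rotors=two_basin_run["rotors"])
            ref = truth.conformers[lab]
            nk = b.size
            for atom in (4, 5, 6, 7):  # backbone dihedrals incl. the switchers
                err = abs(wrap_to_pm180(avg.zmatrix.dihedrals[atom] - ref["dihedrals"][atom]))
                assert err < 5 * cfg.sigma_dihedral / np.sqrt(nk) + 0.5

    def test_direct_average_lands_between_conformers(self):
        cfg = sg.default_config(n_frames=400, schedule=((0, "A"), (200, "B")), seed=6)
        sol, _, truth = sg.make_trajectory(cfg)
        direct = direct_average_structure(sol, truth.connectivity,
                                          rotors=[RotorGroup(9, (10, 11))])
        d4 = direct.zmatrix.dihedrals[4]
        # 50/50 mixture of +60/-60: the mean is near 0, matching neither well
        assert abs(d4) < 20.0
        assert abs(abs(d4) - 60.0) > 30.0

    def test_single_basin_equals_direct(self):
        cfg = sg.default_config(n_frames=150, schedule=((0, "A"),), seed=8)
        sol, _, truth = sg.make_trajectory(cfg)
        rotors = [RotorGroup(9, (10, 11))]
        a = basin_average_structure(sol, np.arange(150), truth.connectivity, rotors=rotors)
        d = direct_average_structure(sol, truth.connectivity, rotors=rotors)
        np.testing.assert_allclose(a.geometry.coords, d.geometry.coords, atol=1e-12)

    def test_unknown_frames_raise(self, two_basin_run):
        with pytest.raises(ValueError):
            basin_average_structure(two_basin_run["solute"], np.array([10_000]),
                                    two_basin_run["truth"].connectivity)

    def test_reconstruction_roundtrips_own_zmatrix(self, two_basin_run):
        part = two_basin_run["partition"]
        avg = basin_average_structure(two_basin_run["solute"], part.basins[0],
                                      two_basin_run["truth"].connectivity)
        from basinavg.zmatrix import to_internal

        z2 = to_internal(avg.geometry.coords, avg.zmatrix.connectivity)
        np.testing.assert_allclose(z2.bonds[1:], avg.zmatrix.bonds[1:], atol=1e-8)
        assert np.all(avg.zmatrix.dihedrals[3:] > -180.0)
        assert np.all(avg.zmatrix.dihedrals[3:] <= 180.0)


class TestThetaDiagnostics:
    def test_direct_bimodal_basin_unimodal(self, two_basin_run):
        part = two_basin_run["partition"]
        aligned = two_basin_run["aligned"]
        sol = two_basin_run["solute"]
        conn = two_basin_run["truth"].connectivity
        rotors = two_basin_run["rotors"]
        moiety = list(sg.MOIETY_ATOMS)
        direct = direct_average_structure(sol, conn, rotors=rotors)
        th_direct = ba.theta_set(direct.geometry, aligned, subset=moiety)
        assert is_bimodal(th_direct)
        for b in part.basins:
            avg = basin_average_structure(sol, b, conn, rotors=rotors)
            th = ba.theta_set(avg.geometry, aligned[b], subset=moiety)
            assert not is_bimodal(th)

    def test_average_beats_random_frames(self, two_basin_run, rng):
        part = two_basin_run["partition"]
        aligned = two_basin_run["aligned"]
        subset = list(sg.NON_ROTOR_ATOMS)
        b = part.basins[0]
        avg = basin_average_structure(two_basin_run["solute"], b,
                                      two_basin_run["truth"].connectivity,
                                      rotors=two_basin_run["rotors"])
        mean_avg = ba.theta_set(avg.geometry, aligned[b], subset=subset).mean()
        picks = rng.choice(b, size=25, replace=False)
        for p in picks:
            assert mean_avg < ba.theta_set(aligned[p], aligned[b], subset=subset).mean()
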