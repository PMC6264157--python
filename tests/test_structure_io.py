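"""Container, PDB I/O, superposition, RMSD and RMSF behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from hampkin.structure_io import (
    PDBFormatError,
    Selection,
    Structure,
    Trajectory,
    geometric_center,
    read_pdb,
    read_trajectory,
    rmsd,
    rmsd_series,
    rmsf,
    superpose,
    write_pdb,
    write_trajectory,
)

from conftest import kabsch_oracle


def _toy_structure(n=10, seed=0):
    rng = np.random.default_rng(seed)
    return Structure(
        chain=np.full(n, "A"),
        resid=np.arange(1, n + 1),
        resname=np.full(n, "GLY"),
        atom_name=np.full(n, "CA"),
        element=np.full(n, "C"),
        coord=rng.normal(scale=5.0, size=(n, 3)),
    )


class TestPDBIO:
    def test_write_read_round_trip(self, tmp_path, dimer_model):
        path = tmp_path / "model.pdb"
        write_pdb(dimer_model, path)
        back = read_pdb(path)
        assert back.n_atoms == dimer_model.n_atoms
        assert list(back.chain) == list(dimer_model.chain)
        assert list(back.resid) == list(dimer_model.resid)
        assert list(back.atom_name) == list(dimer_model.atom_name)
        # PDB stores three decimals
        assert np.abs(back.coord - dimer_model.coord).max() < 1e-3

    def test_multi_model_trajectory(self, tmp_path):
        top = _toy_structure()
        coords = np.stack([top.coord + i for i in range(3)])
        traj = Trajectory(topology=top, coords=coords)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path, topology=top)
        assert back.n_frames == 3
        assert np.abs(back.coords - coords).max() < 1e-3
        # default frame spacing is 10 ps
        assert back.times_ps[1] - back.times_ps[0] == pytest.approx(10.0)

    def test_insertion_code_rejected(self, tmp_path):
        lines = [
            "ATOM      1  CA  GLY A  10      1.000   2.000   3.000  1.00  0.00           C",
            "ATOM      2  CA  GLY A  10A     2.000   2.000   3.000  1.00  0.00           C",
            "END",
        ]
        path = tmp_path / "ins.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(PDBFormatError, match="insertion code"):
            read_pdb(path)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        lines = [
            "ATOM      1  CA AGLY A  10      1.000   0.000   0.000  0.40  0.00           C",
            "ATOM      2  CA BGLY A  10      9.000   0.000   0.000  0.60  0.00           C",
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        s = read_pdb(path)
        assert s.n_atoms == 1
        assert s.coord[0, 0] == pytest.approx(9.0, abs=1e-3)


class TestGeometricCenter:
    def test_two_and_four_point_means(self):
        s = _toy_structure(4)
        s.coord[:] = [[0, 0, 0], [2, 0, 0], [0, 0, 0], [2, 0, 0]]
        assert np.allclose(geometric_center(s, np.array([0, 1])), [1, 0, 0])
        s.coord[:] = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        assert np.allclose(geometric_center(s), [0.5, 0.5, 0])

    def test_single_atom_identity(self):
        s = _toy_structure(3)
        assert np.allclose(geometric_center(s, np.array([2])), s.coord[2])

    def test_empty_selection_errors(self):
        s = _toy_structure()
        with pytest.raises(ValueError, match="empty selection"):
            geometric_center(s, Selection(chains=("Z",)))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    def test_center_commutes_with_translation(self, shift):
        s = _toy_structure(8, seed=3)
        t = np.array(shift)
        c0 = geometric_center(s)
        c1 = geometric_center(s.with_coord(s.coord + t))
        assert np.allclose(c1, c0 + t, atol=1e-9)


class TestSuperpose:
    def test_identical_structures(self):
        s = _toy_structure()
        rot, t, fitted = superpose(s, s)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert rmsd(fitted.coord, s.coord) < 1e-9

    def test_recovers_arbitrary_rigid_transform(self):
        s = _toy_structure(12, seed=1)
        rot = Rotation.from_rotvec([0.4, -1.1, 0.7]).as_matrix()
        moved = s.with_coord(s.coord @ rot.T + np.array([3.0, -5.0, 8.0]))
        _, _, fitted = superpose(moved, s)
        assert rmsd(fitted.coord, s.coord) < 1e-6

    def test_no_reflection(self):
        s = _toy_structure(10, seed=2)
        mirrored = s.with_coord(s.coord * np.array([-1.0, 1.0, 1.0]))
        rot, _, _ = superpose(mirrored, s)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_displaced_atom_matches_brute_force_oracle(self):
        s = _toy_structure(10, seed=4)
        mobile = s.copy()
        mobile.coord[9] += np.array([2.0, -1.0, 0.5])
        nine = Selection(resid_ranges=((1, 9),))
        _, _, fitted = superpose(mobile, s, nine)
        got = rmsd(fitted.coord, s.coord)
        rot_o, t_o = kabsch_oracle(mobile.coord[:9], s.coord[:9])
        expect = rmsd(mobile.coord @ rot_o.T + t_o, s.coord)
        assert got == pytest.approx(expect, abs=1e-9)

    def test_too_few_atoms_errors(self):
        s = _toy_structure(2)
        with pytest.raises(ValueError, match=">= 3 atoms"):
            superpose(s, s)

    def test_mismatched_atom_maps_error_lists_atoms(self):
        a = _toy_structure(10)
        b = _toy_structure(10)
        b.resid = b.resid + 100
        with pytest.raises(ValueError, match="unmatched"):
            superpose(a, b)

    def test_optimality_against_random_perturbations(self):
        s = _toy_structure(15, seed=5)
        rng = np.random.default_rng(0)
        mobile = s.with_coord(s.coord + rng.normal(scale=0.4, size=(15, 3)))
        rot, t, fitted = superpose(mobile, s)
        best = rmsd(fitted.coord, s.coord)
        for _ in range(100):
            d_rot = Rotation.from_rotvec(rng.normal(scale=0.02, size=3)).as_matrix()
            d_t = rng.normal(scale=0.02, size=3)
            perturbed = fitted.coord @ d_rot.T + d_t
            assert rmsd(perturbed, s.coord) >= best - 1e-12


class TestRMSD:
    def _traj(self, top, frames):
        return Trajectory(topology=top, coords=np.stack(frames))

    def test_copies_of_reference_are_zero(self):
        s = _toy_structure()
        traj = self._traj(s, [s.coord.copy() for _ in range(4)])
        series = rmsd_series(traj, s, Selection())
        assert np.abs(series.values).max() < 1e-9

    def test_translation_removed_by_fitting(self):
        s = _toy_structure()
        traj = self._traj(s, [s.coord + np.array([5.0, 0, 0])])
        series = rmsd_series(traj, s, Selection())
        assert series.values[0] < 1e-9

    def test_known_displacements_match_direct_formula(self):
        s = _toy_structure(6, seed=6)
        disp = np.zeros((6, 3))
        disp[0] = [0.3, 0, 0]
        disp[3] = [0, -0.4, 0]
        moved = s.coord + disp
        rot_o, t_o = kabsch_oracle(moved, s.coord)
        expect = rmsd(moved @ rot_o.T + t_o, s.coord)
        traj = self._traj(s, [moved])
        series = rmsd_series(traj, s, Selection())
        assert series.values[0] == pytest.approx(expect, abs=1e-9)

    def test_invariant_under_whole_frame_rigid_transform(self):
        s = _toy_structure(12, seed=7)
        rng = np.random.default_rng(1)
        frames = [s.coord + rng.normal(scale=0.5, size=(12, 3)) for _ in range(3)]
        traj = self._traj(s, frames)
        base = rmsd_series(traj, s, Selection()).values
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        traj2 = self._traj(s, [f @ rot.T + np.array([1.0, 2.0, 3.0]) for f in frames])
        moved = rmsd_series(traj2, s, Selection()).values
        assert np.allclose(base, moved, atol=1e-6)


class TestRMSF:
    def test_static_trajectory_is_zero(self):
        s = _toy_structure()
        traj = Trajectory(topology=s, coords=np.stack([s.coord] * 5))
        _, values = rmsf(traj, s, Selection())
        assert np.abs(values).max() < 1e-9

    def test_single_frame_errors(self):
        s = _toy_structure()
        traj = Trajectory(topology=s, coords=s.coord[None])
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(traj, s, Selection())

    @pytest.mark.parametrize("sigma", [0.25, 0.5])
    def test_isotropic_jitter_gives_sigma_sqrt3(self, sigma):
        s = _toy_structure(30, seed=8)
        rng = np.random.default_rng(2)
        coords = s.coord + rng.normal(scale=sigma, size=(500, 30, 3))
        traj = Trajectory(topology=s, coords=coords)
        _, values = rmsf(traj, s, Selection())
        assert values.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.10)

    def test_doubling_sigma_doubles_rmsf(self):
        s = _toy_structure(30, seed=8)
        rng = np.random.default_rng(3)
        noise = rng.normal(size=(400, 30, 3))
        v1 = rmsf(Trajectory(topology=s, coords=s.coord + 0.2 * noise), s, Selection())[1]
        v2 = rmsf(Trajectory(topology=s, coords=s.coord + 0.4 * noise), s, Selection())[1]
        assert v2.mean() / v1.mean() == pytest.approx(2.0, rel=0.05)

    def test_group_by_residue_labels(self, dimer_model):
        rng = np.random.default_rng(4)
        coords = dimer_model.coord + rng.normal(scale=0.1, size=(3, dimer_model.n_atoms, 3))
        traj = Trajectory(topology=dimer_model, coords=coords)
        labels, values = rmsf(traj, dimer_model,
                              Selection.ca(("A",), ((189, 195),)),
                              group_by_residue=True)
        assert labels == [("A", r) for r in range(189, 196)]
        assert len(values) == 7
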