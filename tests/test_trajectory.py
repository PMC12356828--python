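import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cnstriage.simulate import TrajectorySimSpec, generate_trajectory
from cnstriage.trajectory import (
    AtomRecord,
    HBondCriterion,
    SASAParams,
    Trajectory,
    detect_hbonds,
    fibonacci_sphere,
    hbond_count_series,
    kabsch_superpose,
    read_trajectory_pdb,
    rmsd,
    rmsd_series,
    shrake_rupley_sasa,
    summarize_stability,
    write_trajectory_pdb,
    write_trajectory_xyz,
)

SPHERE_AREA = lambda r: 4.0 * math.pi * r * r  # noqa: E731


def carbon_atoms(n):
    return [AtomRecord(i + 1, "C", 1.7) for i in range(n)]


# ---------------------------------------------------------------------------
class TestKabsch:
    def test_identity(self, rng):
        coords = rng.normal(0, 3, (10, 3))
        moved, fitted = kabsch_superpose(coords, coords)
        assert fitted == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(moved, coords)

    def test_translation_removed(self, rng):
        coords = rng.normal(0, 3, (10, 3))
        moved, fitted = kabsch_superpose(coords, coords + np.array([5.0, 0, 0]))
        assert fitted == pytest.approx(0.0, abs=1e-10)

    def test_rotation_removed(self, rng):
        coords = rng.normal(0, 3, (10, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = coords @ rot.T
        assert rmsd(coords, mobile) > 0.1  # unfitted is nonzero
        _, fitted = kabsch_superpose(coords, mobile)
        assert fitted == pytest.approx(0.0, abs=1e-10)

    def test_matches_scipy_alignment_oracle(self, rng):
        ref = rng.normal(0, 2, (15, 3))
        mobile = ref @ Rotation.random(random_state=1).as_matrix().T + 2.5
        mobile += rng.normal(0, 0.1, mobile.shape)  # noisy correspondence
        _, fitted = kabsch_superpose(ref, mobile)
        rot_est, rssd = Rotation.align_vectors(
            ref - ref.mean(0), mobile - mobile.mean(0)
        )
        oracle = rssd / math.sqrt(len(ref))
        assert fitted == pytest.approx(oracle, rel=1e-6)

    def test_proper_rotation_no_reflection(self, rng):
        coords = rng.normal(0, 3, (10, 3))
        mirrored = coords * np.array([-1.0, 1.0, 1.0])
        _, fitted = kabsch_superpose(coords, mirrored)
        assert fitted > 0.1  # reflection must not be used to cheat the fit

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line + 1.0)

    def test_empty_selection_rejected(self, rng):
        coords = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(coords, coords, fit_selection=[])


class TestRMSDSeries:
    def _traj(self, frames):
        return Trajectory(np.asarray(frames), carbon_atoms(np.asarray(frames).shape[1]))

    def test_static_zeros(self, rng):
        frame = rng.normal(0, 3, (8, 3))
        traj = self._traj([frame] * 4)
        assert np.allclose(rmsd_series(traj, np.arange(8)), 0.0)

    def test_fitting_removes_rigid_motion(self, rng):
        frame = rng.normal(0, 3, (8, 3))
        frames = [frame]
        for k in range(1, 5):
            rot = Rotation.from_euler("xyz", [10 * k, 5 * k, 0], degrees=True).as_matrix()
            frames.append(frame @ rot.T + k * np.array([1.0, 0.5, 0]))
        traj = self._traj(frames)
        sel = np.arange(8)
        assert np.allclose(rmsd_series(traj, sel, sel), 0.0, atol=1e-9)
        assert (rmsd_series(traj, sel)[1:] > 0.1).all()

    def test_fitted_never_exceeds_unfitted(self, rng):
        spec = TrajectorySimSpec(
            n_frames=10, n_protein_atoms=12, n_ligand_atoms=8,
            fluctuation_sd=0.5, drift_per_frame=0.3, seed=5,
        )
        traj = generate_trajectory(spec)
        sel = traj.indices()
        fitted = rmsd_series(traj, sel, sel)
        unfitted = rmsd_series(traj, sel)
        assert (fitted <= unfitted + 1e-9).all()

    def test_empty_selection_rejected(self, rng):
        traj = self._traj([rng.normal(size=(5, 3))] * 2)
        with pytest.raises(ValueError):
            rmsd_series(traj, [])


# ---------------------------------------------------------------------------
class TestSASA:
    def test_single_atom_closed_form(self):
        areas, total = shrake_rupley_sasa(
            np.zeros((1, 3)), [AtomRecord(1, "X", 1.5)], SASAParams()
        )
        assert total == pytest.approx(SPHERE_AREA(2.9), rel=1e-12)
        assert areas[0] == total

    def test_two_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        atoms = [AtomRecord(1, "X", 1.5), AtomRecord(2, "X", 1.5)]
        _, total = shrake_rupley_sasa(coords, atoms)
        assert total == pytest.approx(2 * SPHERE_AREA(2.9), rel=1e-12)

    def test_two_overlapping_spheres_converge_to_closed_form(self):
        # equal radii R at distance d: exposed area per sphere is
        # 4*pi*R^2 - 2*pi*R*h with cap height h = R - d/2
        r, d = 1.7 + 1.4, 2.0
        exact = 2 * (SPHERE_AREA(r) - 2 * math.pi * r * (r - d / 2))
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        atoms = [AtomRecord(1, "C", 1.7), AtomRecord(2, "C", 1.7)]
        errors = []
        for n in (240, 960, 3840):
            _, total = shrake_rupley_sasa(coords, atoms, SASAParams(n_sphere_points=n))
            errors.append(abs(total - exact) / exact)
        assert errors[-1] < 0.005
        assert errors[-1] < errors[0]  # error shrinks with the lattice density

    def test_matches_dense_brute_force_oracle(self, rng):
        coords = rng.normal(0, 2.5, (10, 3))
        atoms = carbon_atoms(10)
        _, ours = shrake_rupley_sasa(coords, atoms, SASAParams(n_sphere_points=960))
        oracle = brute_force_sasa(coords, [1.7] * 10, 1.4, 10_000, rng)
        assert ours == pytest.approx(oracle, rel=0.02)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(0, 2.5, (10, 3))
        atoms = carbon_atoms(10)
        _, base = shrake_rupley_sasa(coords, atoms)
        rot = Rotation.random(random_state=7).as_matrix()
        _, moved = shrake_rupley_sasa(coords @ rot.T + np.array([3.0, -1, 2]), atoms)
        assert moved == pytest.approx(base, rel=1e-9)

    def test_buried_atom_near_zero(self):
        # central atom fully enclosed by a tight shell of large atoms
        shell = fibonacci_sphere(40) * 2.0
        coords = np.vstack([[0.0, 0, 0], shell])
        atoms = [AtomRecord(1, "H", 1.2)] + [
            AtomRecord(i + 2, "S", 1.8) for i in range(40)
        ]
        areas, _ = shrake_rupley_sasa(coords, atoms, group=[0])
        assert areas[0] < 1.0

    def test_per_atom_bounded_by_isolated_sphere(self, rng):
        coords = rng.normal(0, 2.0, (8, 3))
        atoms = carbon_atoms(8)
        areas, _ = shrake_rupley_sasa(coords, atoms)
        assert (areas >= 0).all()
        assert (areas <= SPHERE_AREA(1.7 + 1.4) + 1e-9).all()

    def test_param_validation(self):
        with pytest.raises(ValueError):
            SASAParams(probe_radius=-1.0)
        with pytest.raises(ValueError):
            SASAParams(n_sphere_points=4)


def brute_force_sasa(coords, radii, probe, n_points, rng):
    """Independent dense-oracle: random (not lattice) points, explicit loops."""
    total = 0.0
    for i in range(len(coords)):
        ri = radii[i] + probe
        dirs = rng.normal(size=(n_points, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = coords[i] + ri * dirs
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            rj = radii[j] + probe
            accessible &= np.linalg.norm(pts - coords[j], axis=1) > rj
        total += 4.0 * math.pi * ri * ri * accessible.mean()
    return total


# ---------------------------------------------------------------------------
def hbond_system(acceptor_pos):
    """Donor at origin, hydrogen at (1,0,0), acceptor wherever requested."""
    atoms = [
        AtomRecord(1, "N", 1.55, role="ligand", hbond_class="donor-heavy"),
        AtomRecord(2, "H", 1.20, role="ligand", hbond_class="hydrogen", bonded_heavy=1),
        AtomRecord(3, "O", 1.52, role="protein", hbond_class="acceptor"),
    ]
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], list(acceptor_pos)])
    return coords, atoms


class TestHBonds:
    def test_collinear_bond_detected(self):
        coords, atoms = hbond_system((3.0, 0, 0))
        bonds = detect_hbonds(coords, atoms)
        assert bonds == [(0, 1, 2)]

    def test_distance_cutoff(self):
        coords, atoms = hbond_system((4.0, 0, 0))
        assert detect_hbonds(coords, atoms) == []

    def test_angle_cutoff(self):
        # acceptor at H + 2 along y: D-H...A angle is exactly 90 degrees,
        # D-A distance sqrt(1+4) = 2.24 <= 3.5 -> distance passes, angle fails
        coords, atoms = hbond_system((1.0, 2.0, 0))
        assert np.linalg.norm(coords[0] - coords[2]) < 3.5
        assert detect_hbonds(coords, atoms) == []

    def test_angle_just_above_cutoff_passes(self):
        # acceptor 2 A from H with a D-H...A angle of 121 degrees
        theta = math.radians(121)
        acceptor = (1.0 - 2 * math.cos(theta), 2 * math.sin(theta), 0.0)
        coords, atoms = hbond_system(acceptor)
        v1 = coords[0] - coords[1]
        v2 = coords[2] - coords[1]
        ang = math.degrees(
            math.acos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        )
        assert ang == pytest.approx(121.0, abs=1e-9)
        assert len(detect_hbonds(coords, atoms)) == 1

    def test_groups_must_be_disjoint(self):
        coords, atoms = hbond_system((3.0, 0, 0))
        with pytest.raises(ValueError):
            detect_hbonds(coords, atoms, between=([0, 1], [1, 2]))

    def test_missing_bonded_heavy_rejected(self):
        with pytest.raises(ValueError):
            AtomRecord(2, "H", 1.2, hbond_class="hydrogen")

    def test_dangling_bonded_heavy_rejected(self):
        atoms = [
            AtomRecord(1, "N", 1.55, role="ligand", hbond_class="donor-heavy"),
            AtomRecord(2, "H", 1.2, role="ligand", hbond_class="hydrogen", bonded_heavy=99),
            AtomRecord(3, "O", 1.52, role="protein", hbond_class="acceptor"),
        ]
        with pytest.raises(ValueError, match="99"):
            detect_hbonds(np.zeros((3, 3)), atoms)

    def test_monotone_in_criterion(self, rng):
        spec = TrajectorySimSpec(
            n_frames=5, n_protein_atoms=12, n_ligand_atoms=10,
            fluctuation_sd=0.8, n_contacts=3, seed=13,
        )
        traj = generate_trajectory(spec)
        loose = hbond_count_series(traj, HBondCriterion(3.5, 120.0))
        tighter_d = hbond_count_series(traj, HBondCriterion(3.0, 120.0))
        tighter_a = hbond_count_series(traj, HBondCriterion(3.5, 150.0))
        assert (tighter_d <= loose).all()
        assert (tighter_a <= loose).all()

    def test_rigid_motion_invariance(self):
        spec = TrajectorySimSpec(
            n_frames=4, n_protein_atoms=10, n_ligand_atoms=8,
            fluctuation_sd=0.3, n_contacts=2, seed=3,
        )
        traj = generate_trajectory(spec)
        base = hbond_count_series(traj)
        rot = Rotation.random(random_state=2).as_matrix()
        moved = Trajectory(traj.coords @ rot.T + 7.5, traj.atoms)
        assert (hbond_count_series(moved) == base).all()

    def test_empty_ligand_group_zero(self):
        coords, atoms = hbond_system((3.0, 0, 0))
        traj = Trajectory(coords[None, :, :], atoms)
        counts = hbond_count_series(traj, between=([2], []))
        assert (counts == 0).all()

    def test_matches_brute_force_enumeration(self, rng):
        spec = TrajectorySimSpec(
            n_frames=10, n_protein_atoms=15, n_ligand_atoms=10,
            fluctuation_sd=1.2, n_contacts=3, seed=17,
        )
        traj = generate_trajectory(spec)
        criterion = HBondCriterion(3.5, 120.0)
        for k in range(traj.n_frames):
            ours = set(detect_hbonds(traj.coords[k], traj.atoms, criterion))
            oracle = brute_force_hbonds(traj.coords[k], traj.atoms, 3.5, 120.0)
            assert ours == oracle

    def test_coupled_mode_tighter_than_fixed(self, rng):
        spec = TrajectorySimSpec(
            n_frames=5, n_protein_atoms=12, n_ligand_atoms=10,
            fluctuation_sd=1.0, n_contacts=3, seed=19,
        )
        traj = generate_trajectory(spec)
        fixed = hbond_count_series(traj, HBondCriterion(3.5, 120.0, mode="fixed"))
        coupled = hbond_count_series(traj, HBondCriterion(3.5, 120.0, mode="coupled"))
        assert (coupled <= fixed).all()

    def test_nm_constructor(self):
        crit = HBondCriterion.from_nm(0.35)
        assert crit.max_da_distance == pytest.approx(3.5)


def brute_force_hbonds(coords, atoms, max_dist, min_angle):
    """Exhaustive oracle: all (donor, hydrogen, acceptor) triples, explicit math."""
    by_serial = {a.serial: i for i, a in enumerate(atoms)}
    found = set()
    for hi, h in enumerate(atoms):
        if h.hbond_class != "hydrogen":
            continue
        di = by_serial[h.bonded_heavy]
        if atoms[di].hbond_class != "donor-heavy":
            continue
        for ai, acc in enumerate(atoms):
            if acc.hbond_class != "acceptor":
                continue
            if atoms[di].role == acc.role:
                continue  # within-group contacts are not counted
            d = math.dist(coords[di], coords[ai])
            v1 = coords[di] - coords[hi]
            v2 = coords[ai] - coords[hi]
            cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if d <= max_dist and ang >= min_angle:
                found.add((di, hi, ai))
    return found


# ---------------------------------------------------------------------------
class TestSummaries:
    def test_constant_series(self):
        c = np.full(10, 3.5)
        s = summarize_stability("x", c, c, c, c, c)
        assert s.protein_rmsd_mean == 3.5
        assert s.protein_rmsd_sd == 0.0

    def test_population_sd(self):
        series = np.array([1.0, 2.0, 3.0])
        s = summarize_stability("x", series, series, series, series, series)
        assert s.protein_rmsd_mean == pytest.approx(2.0)
        assert s.protein_rmsd_sd == pytest.approx(0.8165, abs=1e-4)

    def test_frame_slicing(self):
        two_regime = np.concatenate([np.full(50, 10.0), np.full(50, 2.0)])
        s = summarize_stability(
            "x", two_regime, two_regime, two_regime, two_regime, two_regime,
            frame_slice=slice(50, None),
        )
        assert s.protein_rmsd_mean == pytest.approx(2.0)
        assert s.protein_rmsd_sd == 0.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            summarize_stability("x", np.array([]), np.array([1.0]), np.array([1.0]),
                                np.array([1.0]), np.array([1.0]))


class TestSerialization:
    def test_pdb_round_trip(self, tmp_path):
        spec = TrajectorySimSpec(n_frames=3, n_protein_atoms=8, n_ligand_atoms=6, seed=1)
        traj = generate_trajectory(spec)
        write_trajectory_pdb(traj, tmp_path / "t.pdb", tmp_path / "t_meta.tsv")
        back = read_trajectory_pdb(tmp_path / "t.pdb", tmp_path / "t_meta.tsv")
        assert back.n_frames == traj.n_frames
        assert np.allclose(back.coords, traj.coords, atol=1e-3)  # PDB stores 3 dp
        assert [a.serial for a in back.atoms] == [a.serial for a in traj.atoms]
        assert [a.hbond_class for a in back.atoms] == [a.hbond_class for a in traj.atoms]

    def test_pdb_has_model_records(self, tmp_path):
        spec = TrajectorySimSpec(n_frames=3, n_protein_atoms=8, n_ligand_atoms=6, seed=1)
        traj = generate_trajectory(spec)
        write_trajectory_pdb(traj, tmp_path / "t.pdb", tmp_path / "t_meta.tsv")
        text = (tmp_path / "t.pdb").read_text()
        assert text.count("MODEL") == 3
        assert text.count("ENDMDL") == 3

    def test_xyz_output(self, tmp_path):
        spec = TrajectorySimSpec(n_frames=2, n_protein_atoms=8, n_ligand_atoms=6, seed=1)
        traj = generate_trajectory(spec)
        write_trajectory_xyz(traj, tmp_path / "t.xyz", tmp_path / "t_meta.tsv")
        lines = (tmp_path / "t.xyz").read_text().splitlines()
        assert lines[0] == str(traj.n_atoms)
        assert len(lines) == 2 * (traj.n_atoms + 2)


def test_trajectory_validation(rng):
    with pytest.raises(ValueError):
        Trajectory(rng.normal(size=(3, 5, 2)), carbon_atoms(5))
    with pytest.raises(ValueError):
        Trajectory(rng.normal(size=(3, 5, 3)), carbon_atoms(4))
    coords = rng.normal(size=(2, 3, 3))
    coords[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        Trajectory(coords, carbon_atoms(3))
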