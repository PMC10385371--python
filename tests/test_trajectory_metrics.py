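import numpy as np
import pytest

from reactscreen import synthetic_data as sd
from reactscreen import trajectory_metrics as tm
from reactscreen.io_formats import AtomRecord, MolecularGeometry, Trajectory


def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent oracle: minimal RMSD via Horn's quaternion
    eigenvalue method (no SVD, no shared code with the Kabsch path)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k).max()
    n = len(a)
    val = (a ** 2).sum() + (b ** 2).sum() - 2.0 * lam
    return float(np.sqrt(max(val, 0.0) / n))


def _random_rigid(rng, coords):
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=rng).as_matrix()
    return coords @ rot.T + rng.normal(scale=5.0, size=3)


class TestKabsch:
    def test_identity_on_identical_structures(self):
        coords = np.random.default_rng(0).normal(size=(10, 3))
        fit = tm.kabsch_superpose(coords, coords)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-10)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(20, 3))
        moved = _random_rigid(rng, coords)
        fit = tm.kabsch_superpose(moved, coords)
        assert fit.rmsd < 1e-8
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(fit.rotation @ fit.rotation.T, np.eye(3),
                                   atol=1e-8)

    def test_matches_quaternion_oracle_on_100_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a = rng.normal(size=(5, 3)) * 3
            b = rng.normal(size=(5, 3)) * 3
            assert tm.kabsch_superpose(a, b).rmsd == pytest.approx(
                quaternion_rmsd(a, b), abs=1e-8
            )

    def test_reflection_corrected_to_proper_rotation(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(8, 3))
        mirrored = coords * np.array([-1.0, 1.0, 1.0])
        fit = tm.kabsch_superpose(mirrored, coords)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_selection_translation_only(self):
        a = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        b = a + np.array([2.0, 0, 0])
        with pytest.warns(UserWarning, match="translation-only"):
            fit = tm.kabsch_superpose(a, b)
        np.testing.assert_allclose(fit.rotation, np.eye(3))
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_count_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            tm.kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))


class TestRmsdSeries:
    def test_static_trajectory_all_zero_stable(self):
        base = sd.gen_geometry(1, n_atoms=10)
        traj = Trajectory(base, [base.coords] * 5)
        s = tm.rmsd_series(traj)
        np.testing.assert_allclose(s.values, 0.0, atol=1e-12)
        assert s.verdict == "stable"

    def test_rigid_tumbling_zero_after_alignment(self):
        base = sd.gen_geometry(2, n_atoms=15)
        traj, _ = sd.gen_trajectory(2, base, n_frames=10, sigma=0.0)
        s = tm.rmsd_series(traj)
        np.testing.assert_allclose(s.values, 0.0, atol=1e-8)

    def test_gaussian_noise_matches_monte_carlo_expectation(self):
        """sigma = 0.5 Å i.i.d. noise on 200 atoms x 200 frames: mean
        RMSD within 5% of a direct numpy simulation of the same-size
        displacement statistic."""
        n_atoms, n_frames, sigma = 200, 200, 0.5
        base = sd.gen_geometry(3, n_atoms=n_atoms)
        traj, _ = sd.gen_trajectory(3, base, n_frames=n_frames, sigma=sigma)
        s = tm.rmsd_series(traj)
        rng = np.random.default_rng(12345)
        mc = []
        for _ in range(300):
            ref = rng.normal(scale=sigma, size=(n_atoms, 3))
            frame = rng.normal(scale=sigma, size=(n_atoms, 3))
            mc.append(np.sqrt(((frame - ref) ** 2).sum(axis=1).mean()))
        expected = float(np.mean(mc))
        # frame 0 is the reference itself; exclude it from the mean
        measured = s.values[1:].mean()
        assert measured == pytest.approx(expected, rel=0.05)

    def test_measure_without_refit_ligand_drift(self):
        base = sd.gen_geometry(4, n_atoms=30)
        lig = np.arange(25, 30)
        traj, _ = sd.gen_trajectory(
            4, base, n_frames=10, sigma=0.0,
            drift=np.array([5.0, 0.0, 0.0]), drift_selection=lig,
        )
        protein = np.arange(0, 25)
        s_lig = tm.rmsd_series(traj, align_selection=protein,
                               measure_selection=lig)
        # ligand drifts monotonically away while the protein stays put
        assert np.all(np.diff(s_lig.values) > -1e-9)
        assert s_lig.values[-1] == pytest.approx(5.0, rel=1e-6)
        s_prot = tm.rmsd_series(traj, align_selection=protein,
                                measure_selection=protein)
        np.testing.assert_allclose(s_prot.values, 0.0, atol=1e-8)

    def test_empty_selection_rejected(self):
        base = sd.gen_geometry(5, n_atoms=5)
        traj = Trajectory(base, [base.coords])
        with pytest.raises(ValueError, match="empty"):
            tm.rmsd_series(traj, align_selection=[])

    def test_series_statistics_consistent(self):
        base = sd.gen_geometry(6, n_atoms=20)
        traj, _ = sd.gen_trajectory(6, base, n_frames=20, sigma=0.3)
        s = tm.rmsd_series(traj)
        assert s.mean == pytest.approx(s.values.mean(), abs=1e-10)
        assert s.std == pytest.approx(s.values.std(ddof=1), abs=1e-10)


class TestRmsf:
    def test_static_zero(self):
        base = sd.gen_geometry(7, n_atoms=8)
        traj = Trajectory(base, [base.coords] * 4)
        prof = tm.rmsf(traj)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_two_point_alternation(self):
        base = sd.gen_geometry(8, n_atoms=3)
        a = 0.7
        up = base.coords.copy()
        up[0, 0] += a
        down = base.coords.copy()
        down[0, 0] -= a
        traj = Trajectory(base, [up, down, up, down])
        prof = tm.rmsf(traj)
        assert prof.rmsf[0] == pytest.approx(a, abs=1e-12)
        np.testing.assert_allclose(prof.rmsf[1:], 0.0, atol=1e-12)

    def test_gaussian_noise_approaches_sigma_sqrt3(self):
        sigma = 0.4
        base = sd.gen_geometry(9, n_atoms=100)
        traj, _ = sd.gen_trajectory(9, base, n_frames=500, sigma=sigma,
                                    rigid_motion=False)
        prof = tm.rmsf(traj)
        assert prof.rmsf.mean() == pytest.approx(sigma * np.sqrt(3),
                                                 rel=0.05)

    def test_single_frame_rejected(self):
        base = sd.gen_geometry(10, n_atoms=5)
        with pytest.raises(ValueError, match="two frames"):
            tm.rmsf(Trajectory(base, [base.coords]))

    def test_residue_grouping_averages_members(self):
        atoms = [
            AtomRecord(1, "C", np.zeros(3), residue_id=1),
            AtomRecord(2, "C", np.array([1.0, 0, 0]), residue_id=1),
            AtomRecord(3, "C", np.array([2.0, 0, 0]), residue_id=2),
        ]
        base = MolecularGeometry("m", atoms)
        up = base.coords.copy()
        up[0, 1] += 1.0
        traj = Trajectory(base, [base.coords, up])
        atom_prof = tm.rmsf(traj)
        res_prof = tm.rmsf(traj, group_by_residue=True)
        assert res_prof.labels == [1, 2]
        assert res_prof.rmsf[0] == pytest.approx(atom_prof.rmsf[:2].mean())


class TestRadiusOfGyration:
    def test_two_equal_masses(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert tm.radius_of_gyration(coords, np.ones(2)) == pytest.approx(1.0)

    def test_coincident_atoms_zero(self):
        coords = np.zeros((5, 3))
        assert tm.radius_of_gyration(coords, np.ones(5)) == 0.0

    def test_unit_cube_closed_form(self):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
            dtype=float,
        )
        assert tm.radius_of_gyration(corners, np.ones(8)) == pytest.approx(
            np.sqrt(3) / 2
        )

    def test_mass_weighting_matters(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        rg = tm.radius_of_gyration(coords, np.array([3.0, 1.0]))
        # com at 0.5; rg = sqrt((3*0.25 + 1*2.25)/4) = sqrt(0.75)
        assert rg == pytest.approx(np.sqrt(0.75))


class TestSasa:
    def test_lone_sphere_closed_form(self):
        areas, total = tm.sasa_shrake_rupley(np.zeros((1, 3)), ["C"])
        assert total == pytest.approx(4 * np.pi * 3.1 ** 2, rel=0.01)

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        _, total = tm.sasa_shrake_rupley(coords, ["C", "O"])
        lone_c = tm.sasa_shrake_rupley(np.zeros((1, 3)), ["C"])[1]
        lone_o = tm.sasa_shrake_rupley(np.zeros((1, 3)), ["O"])[1]
        assert total == pytest.approx(lone_c + lone_o, rel=1e-6)

    @pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
    def test_two_spheres_match_cap_area_oracle(self, d):
        """Overlapping equal spheres against the analytic spherical-cap
        buried-area formula."""
        r = 1.7 + 1.4
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        _, total = tm.sasa_shrake_rupley(coords, ["C", "C"])
        x = d / 2.0  # intersection plane, equal radii
        cap = 2 * np.pi * r * (r - x)
        expected = 2 * (4 * np.pi * r ** 2 - cap)
        assert total == pytest.approx(expected, rel=0.02)

    def test_point_density_stability(self):
        _, a = tm.sasa_shrake_rupley(np.zeros((1, 3)), ["C"], n_points=480)
        _, b = tm.sasa_shrake_rupley(np.zeros((1, 3)), ["C"], n_points=1920)
        assert a == pytest.approx(b, rel=0.01)

    def test_per_atom_bounded_by_isolated_sphere(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 6, size=(10, 3))
        areas, _ = tm.sasa_shrake_rupley(coords, ["C"] * 10)
        bound = 4 * np.pi * 3.1 ** 2
        assert np.all(areas >= 0)
        assert np.all(areas <= bound + 1e-9)


class TestHbonds:
    def _traj(self, d, theta):
        geom = sd.gen_hbond_scene(d, theta)
        return Trajectory(geom, [geom.coords])

    def test_linear_close_counts_one(self):
        s = tm.hbond_series(self._traj(2.8, 0.0))
        assert s.values[0] == 1

    def test_angle_gate(self):
        s = tm.hbond_series(self._traj(2.8, 15.0))
        assert s.values[0] == 0

    def test_distance_gate(self):
        s = tm.hbond_series(self._traj(3.2, 0.0))
        assert s.values[0] == 0

    def test_grid_matches_definitional_predicate(self):
        """Over the full (distance, deviation) grid the pipeline count
        equals the definitional predicate d <= rcut and theta <=
        angle_cut."""
        for d in (2.6, 2.8, 3.0, 3.2, 3.4):
            for theta in (0.0, 5.0, 9.0, 10.0, 11.0, 15.0, 20.0):
                s = tm.hbond_series(self._traj(d, theta))
                expected = 1 if (d <= 3.0 and theta <= 10.0) else 0
                assert s.values[0] == expected, (d, theta)

    def test_loosening_cutoffs_never_decreases_counts(self):
        for d in (2.8, 3.2):
            for theta in (5.0, 15.0):
                traj = self._traj(d, theta)
                tight = tm.hbond_series(traj, rcut=3.0, angle_cut=10.0)
                loose_r = tm.hbond_series(traj, rcut=3.5, angle_cut=10.0)
                loose_a = tm.hbond_series(traj, rcut=3.0, angle_cut=20.0)
                assert loose_r.values[0] >= tight.values[0]
                assert loose_a.values[0] >= tight.values[0]

    def test_donor_without_hydrogen_excluded_with_warning(self):
        atoms = [
            AtomRecord(1, "N", np.zeros(3)),
            AtomRecord(2, "O", np.array([2.8, 0.0, 0.0])),
        ]
        geom = MolecularGeometry("nh-less", atoms)
        traj = Trajectory(geom, [geom.coords])
        with pytest.warns(UserWarning, match="without bonded hydrogens"):
            s = tm.hbond_series(traj, donors=[0])
        assert s.values[0] == 0


class TestContacts:
    def _system(self, residue_offsets):
        """Ligand atom at origin; one single-atom residue per offset."""
        atoms = [AtomRecord(1, "C", np.zeros(3), residue_id=None)]
        for i, off in enumerate(residue_offsets, start=2):
            atoms.append(
                AtomRecord(i, "C", np.array([off, 0.0, 0.0]),
                           residue_id=i - 1, residue_name="RES")
            )
        return MolecularGeometry("sys", atoms)

    def test_always_within_cutoff(self):
        geom = self._system([3.0])
        traj = Trajectory(geom, [geom.coords] * 4)
        table = tm.contact_frequency(traj, ligand_selection=[0])
        assert table.frequencies[1] == 1.0

    def test_never_within_cutoff(self):
        geom = self._system([10.0])
        traj = Trajectory(geom, [geom.coords] * 4)
        table = tm.contact_frequency(traj, ligand_selection=[0])
        assert table.frequencies[1] == 0.0

    def test_half_the_frames(self):
        geom = self._system([3.0])
        near = geom.coords
        far = near.copy()
        far[1, 0] = 20.0
        traj = Trajectory(geom, [near, far, near, far])
        table = tm.contact_frequency(traj, ligand_selection=[0])
        assert table.frequencies[1] == 0.5
        assert table.counts[1] == 2

    def test_subsampling_preserves_deterministic_frequency(self):
        geom = self._system([3.0])
        near = geom.coords
        far = near.copy()
        far[1, 0] = 20.0
        frames = [near, far] * 10
        full = tm.contact_frequency(Trajectory(geom, frames), [0])
        half = tm.contact_frequency(Trajectory(geom, frames[::2]), [0])
        assert full.frequencies[1] == 0.5
        assert half.frequencies[1] == 1.0  # kept the in-contact frames
        quarter = tm.contact_frequency(Trajectory(geom, frames[:4]), [0])
        assert quarter.frequencies[1] == 0.5

    def test_unknown_residue_rejected(self):
        geom = self._system([3.0])
        traj = Trajectory(geom, [geom.coords])
        with pytest.raises(KeyError, match="99"):
            tm.contact_frequency(traj, [0], residues=[99])

    def test_hydrogens_ignored(self):
        atoms = [
            AtomRecord(1, "C", np.zeros(3)),
            AtomRecord(2, "H", np.array([3.0, 0.0, 0.0]), residue_id=1),
            AtomRecord(3, "C", np.array([9.0, 0.0, 0.0]), residue_id=1),
        ]
        geom = MolecularGeometry("hsys", atoms)
        traj = Trajectory(geom, [geom.coords])
        table = tm.contact_frequency(traj, ligand_selection=[0])
        assert table.frequencies[1] == 0.0  # only the H was close


class TestRigidMotionInvariance:
    def test_metrics_invariant_under_global_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        base = sd.gen_geometry(20, n_atoms=25)
        traj, _ = sd.gen_trajectory(20, base, n_frames=8, sigma=0.2,
                                    rigid_motion=False)
        rot = Rotation.random(random_state=5).as_matrix()
        shift = np.array([3.0, -2.0, 7.0])
        moved = Trajectory(base, [f @ rot.T + shift for f in traj.frames])

        s1 = tm.rmsd_series(traj)
        s2 = tm.rmsd_series(moved)
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-6)

        p1 = tm.rmsf(tm.align_trajectory(traj))
        p2 = tm.rmsf(tm.align_trajectory(moved))
        np.testing.assert_allclose(p1.rmsf, p2.rmsf, atol=1e-6)

        r1 = tm.rg_series(traj)
        r2 = tm.rg_series(moved)
        np.testing.assert_allclose(r1.values, r2.values, atol=1e-6)

        # SASA is a finite point-sample estimate: rotating the molecule
        # relative to the fixed test-point lattice moves the value by the
        # sampling resolution, not machine precision
        elements = base.elements
        a1 = tm.sasa_shrake_rupley(traj.frames[0], elements)[1]
        a2 = tm.sasa_shrake_rupley(moved.frames[0], elements)[1]
        assert a1 == pytest.approx(a2, rel=5e-3)
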