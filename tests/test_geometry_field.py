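import numpy as np
import pytest

from reactscreen import geometry_field as gf
from reactscreen.io_formats import AtomRecord, MolecularGeometry


def _geom(elements, coords, charges=None):
    atoms = [
        AtomRecord(i + 1, e, np.asarray(c, dtype=float),
                   partial_charge=None if charges is None else charges[i])
        for i, (e, c) in enumerate(zip(elements, coords))
    ]
    return MolecularGeometry("test", atoms)


class TestInternalCoords:
    def test_two_bonded_atoms(self):
        g = _geom(["C", "C"], [[0, 0, 0], [1.0, 0, 0]])
        ic = gf.perceive_internal_coords(g)
        assert ic.bonds == {(1, 2): pytest.approx(1.0)}
        assert ic.angles == {} and ic.dihedrals == {}

    def test_right_angle(self):
        g = _geom(["C", "C", "C"], [[1, 0, 0], [0, 0, 0], [0, 1, 0]])
        ic = gf.perceive_internal_coords(g)
        key = (1, 2, 3)
        assert ic.angles[key] == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("torsion", [60.0, -60.0, 175.0, -90.0, 180.0])
    def test_dihedral_recovered_from_constructed_torsion(self, torsion):
        """Build a 4-atom chain with a chosen torsion by explicit
        rotation and recover it, sign included (IUPAC convention)."""
        t = np.radians(torsion)
        b = 1.5  # long bonds keep 1-3 diagonals out of bonding range
        coords = [
            [b, b, 0.0],
            [b, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            # minus sine: the IUPAC-positive sense is clockwise viewed
            # down the 2->3 bond
            (b / np.sqrt(2)) * np.array([-1.0, np.cos(t), -np.sin(t)]),
        ]
        g = _geom(["C"] * 4, coords)
        ic = gf.perceive_internal_coords(g)
        (key, value), = ic.dihedrals.items()
        expected = 180.0 if torsion == -180.0 else torsion
        assert value == pytest.approx(expected, abs=1e-9)

    def test_isolated_atoms_yield_empty_sets(self):
        g = _geom(["C", "C"], [[0, 0, 0], [50.0, 0, 0]])
        ic = gf.perceive_internal_coords(g)
        assert not ic.bonds


class TestGeometryMae:
    def test_identical_sets_zero(self):
        g = _geom(["C", "C", "C"], [[1, 0, 0], [0, 0, 0], [0, 1, 0]])
        ic = gf.perceive_internal_coords(g)
        mae = gf.geometry_mae(ic, ic)
        assert mae["bonds"]["mae"] == 0.0
        assert mae["angles"]["mae"] == 0.0

    def test_single_bond_difference(self):
        a = gf.InternalCoordinateSet({(1, 2): 1.50}, {}, {})
        b = gf.InternalCoordinateSet({(2, 1): 1.54}, {}, {})
        mae = gf.geometry_mae(a, b)
        assert mae["bonds"]["mae"] == pytest.approx(0.04)

    def test_dihedral_wraparound(self):
        a = gf.InternalCoordinateSet({}, {}, {(1, 2, 3, 4): 179.0})
        b = gf.InternalCoordinateSet({}, {}, {(1, 2, 3, 4): -179.0})
        mae = gf.geometry_mae(a, b)
        assert mae["dihedrals"]["mae"] == pytest.approx(2.0)

    def test_symmetric_and_counts_unmatched(self):
        a = gf.InternalCoordinateSet({(1, 2): 1.5, (2, 3): 1.4}, {}, {})
        b = gf.InternalCoordinateSet({(1, 2): 1.6}, {}, {})
        m1 = gf.geometry_mae(a, b)
        m2 = gf.geometry_mae(b, a)
        assert m1["bonds"]["mae"] == m2["bonds"]["mae"]
        assert m1["bonds"]["n_unmatched_ref"] == 1
        assert m2["bonds"]["n_unmatched_test"] == 1

    def test_empty_intersection_is_error(self):
        a = gf.InternalCoordinateSet({(1, 2): 1.5}, {}, {})
        b = gf.InternalCoordinateSet({(3, 4): 1.5}, {}, {})
        with pytest.raises(ValueError, match="bonds"):
            gf.geometry_mae(a, b)


class TestDipole:
    def test_closed_form_two_charges(self):
        g = _geom(["H", "H"], [[0.5, 0, 0], [-0.5, 0, 0]],
                  charges=[0.5, -0.5])
        vec, norm = gf.point_charge_dipole(g)
        assert norm == pytest.approx(0.5 * gf.EA_TO_DEBYE)
        assert vec[0] > 0 and abs(vec[1]) < 1e-12

    def test_translation_invariance_for_neutral_system(self):
        coords = np.array([[0.5, 0, 0], [-0.5, 0, 0], [0, 1.0, 0]])
        charges = [0.5, -0.3, -0.2]
        g1 = _geom(["H"] * 3, coords, charges)
        g2 = _geom(["H"] * 3, coords + np.array([3.0, -7.0, 11.0]), charges)
        v1, _ = gf.point_charge_dipole(g1)
        v2, _ = gf.point_charge_dipole(g2)
        np.testing.assert_allclose(v1, v2, atol=1e-9)

    def test_rotation_rotates_vector_preserving_norm(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(5, 3))
        charges = rng.normal(size=5)
        charges -= charges.mean()  # neutral
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(random_state=1).as_matrix()
        g1 = _geom(["C"] * 5, coords, list(charges))
        g2 = _geom(["C"] * 5, coords @ rot.T, list(charges))
        v1, n1 = gf.point_charge_dipole(g1)
        v2, n2 = gf.point_charge_dipole(g2)
        np.testing.assert_allclose(rot @ v1, v2, atol=1e-9)
        assert n1 == pytest.approx(n2, abs=1e-9)

    def test_symmetric_distribution_zero(self):
        g = _geom(["H", "H"], [[1, 0, 0], [-1, 0, 0]], charges=[0.3, 0.3])
        vec, norm = gf.point_charge_dipole(g)
        assert norm == pytest.approx(0.0, abs=1e-12)

    def test_missing_charge_is_error(self):
        g = _geom(["H", "H"], [[1, 0, 0], [-1, 0, 0]])
        with pytest.raises(ValueError, match="without partial charges"):
            gf.point_charge_dipole(g)


class TestDotSurface:
    def test_single_atom_radius_and_count(self):
        g = _geom(["C"], [[0, 0, 0]])  # Bondi r = 1.7
        pts, owners = gf.vdw_dot_surface(g, scale=1.2, density=5.0)
        r = np.linalg.norm(pts, axis=1)
        np.testing.assert_allclose(r, 2.04, atol=1e-9)
        expected = round(4 * np.pi * 2.04 ** 2 * 5.0)
        assert len(pts) == expected
        assert set(owners) == {1}

    def test_density_scales_point_count(self):
        g = _geom(["C"], [[0, 0, 0]])
        n1 = len(gf.vdw_dot_surface(g, density=5.0)[0])
        n2 = len(gf.vdw_dot_surface(g, density=10.0)[0])
        assert n2 == pytest.approx(2 * n1, rel=0.01)

    def test_no_point_inside_scaled_union(self):
        g = _geom(["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
        pts, owners = gf.vdw_dot_surface(g)
        radii = 1.2 * 1.7
        for center in g.coords:
            d = np.linalg.norm(pts - center, axis=1)
            assert np.all(d >= radii * (1 - 1e-9))


class TestEsp:
    def test_coulomb_closed_form(self):
        g = _geom(["H"], [[0, 0, 0]], charges=[1.0])
        surf = gf.esp_at_points(g, np.array([[2.0, 0, 0]]))
        assert surf.values[0] == pytest.approx(166.032, abs=5e-4)

    def test_superposition(self):
        coords = [[0, 0, 0], [1.0, 0.5, -0.3]]
        p = np.array([[2.5, 1.0, 0.7]])
        both = gf.esp_at_points(_geom(["H", "H"], coords, [0.4, -0.7]), p)
        one = gf.esp_at_points(_geom(["H"], [coords[0]], [0.4]), p)
        two = gf.esp_at_points(_geom(["H"], [coords[1]], [-0.7]), p)
        assert both.values[0] == pytest.approx(one.values[0] + two.values[0],
                                               abs=1e-9)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(4, 3))
        q = rng.normal(size=4)
        pts = rng.normal(size=(10, 3)) * 5 + 10
        a = gf.esp_at_points(_geom(["C"] * 4, coords, list(q)), pts)
        b = gf.esp_at_points(_geom(["C"] * 4, coords, list(-q)), pts)
        np.testing.assert_allclose(a.values, -b.values, atol=1e-9)

    def test_unit_conversion_consistent(self):
        g = _geom(["H"], [[0, 0, 0]], charges=[1.0])
        p = np.array([[2.0, 0, 0]])
        kcal = gf.esp_at_points(g, p, unit="kcal/mol").values[0]
        au = gf.esp_at_points(g, p, unit="a.u.").values[0]
        assert kcal / au == pytest.approx(gf.COULOMB_KCAL / gf.BOHR_A,
                                          rel=1e-6)

    def test_singular_point_rejected(self):
        g = _geom(["H"], [[0, 0, 0]], charges=[1.0])
        with pytest.raises(ValueError, match="nucleus"):
            gf.esp_at_points(g, np.array([[0.0, 0, 0]]))


class TestExtrema:
    def test_single_positive_charge(self):
        g = _geom(["H"], [[0, 0, 0]], charges=[1.0])
        pts, owners = gf.vdw_dot_surface(g)
        surf = gf.esp_at_points(g, pts, owner_atom=owners)
        ext = gf.surface_extrema(surf)
        assert ext.v_min <= ext.v_max
        assert ext.v_min > 0

    def test_dipole_min_owner_near_negative_charge(self):
        g = _geom(["O", "H"], [[0, 0, 0], [4.0, 0, 0]], charges=[-0.5, 0.5])
        pts, owners = gf.vdw_dot_surface(g)
        surf = gf.esp_at_points(g, pts, owner_atom=owners)
        ext = gf.surface_extrema(surf)
        assert ext.min_owner == 1
        assert ext.max_owner == 2

    def test_extrema_equal_exhaustive_scan(self):
        """On an asymmetric 4-charge fixture the reported extrema equal a
        brute-force scan over every surface point."""
        rng = np.random.default_rng(7)
        coords = rng.uniform(-2, 2, size=(4, 3))
        q = np.array([0.7, -0.4, 0.1, -0.4])
        g = _geom(["C", "N", "O", "H"], coords, list(q))
        pts, owners = gf.vdw_dot_surface(g)
        surf = gf.esp_at_points(g, pts, owner_atom=owners)
        ext = gf.surface_extrema(surf)
        assert ext.v_min == surf.values.min()
        assert ext.v_max == surf.values.max()
        assert ext.min_owner == owners[np.argmin(surf.values)]
        minima = gf.per_atom_minima(surf)
        for owner, vmin in minima.items():
            assert vmin == surf.values[owners == owner].min()

    def test_empty_surface_rejected(self):
        surf = gf.EspSurface(np.zeros((0, 3)), np.zeros(0), "kcal/mol",
                             np.zeros(0, dtype=int))
        with pytest.raises(ValueError):
            gf.surface_extrema(surf)
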