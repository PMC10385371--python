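"""Geometry comparison, point-charge dipoles and electrostatic
potential surfaces.

Internal coordinates (bonds, angles, proper dihedrals) are perceived
from Cartesian geometry with a covalent-radius bond criterion and
compared between two structures as per-class mean absolute errors.
The electrostatic potential is evaluated in the atomic-monopole
approximation V(r) = sum_A q_A / |R_A - r| on a deterministic
Fibonacci-lattice dot surface at a scaled van der Waals envelope; the
surface extrema are attributed to their owning atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .elements import atomic_number, covalent_radius, vdw_radius
from .io_formats import MolecularGeometry

#: Coulomb constant, kcal mol^-1 Å e^-2
COULOMB_KCAL = 332.0637
#: Bohr radius, Å
BOHR_A = 0.529177
#: e·Å in Debye
EA_TO_DEBYE = 4.80320
#: slack added to the covalent-radius sum in the bond criterion, Å
BOND_TOLERANCE = 0.4


@dataclass
class InternalCoordinateSet:
    """Bond lengths (Å), bond angles and signed proper dihedrals (deg),
    keyed by direction-normalized 1-based atom tuples."""

    bonds: dict[tuple[int, int], float]
    angles: dict[tuple[int, int, int], float]
    dihedrals: dict[tuple[int, int, int, int], float]


@dataclass
class EspSurface:
    points: np.ndarray          # (n, 3), Å
    values: np.ndarray          # (n,), unit below
    unit: str                   # "kcal/mol" or "a.u."
    owner_atom: np.ndarray      # (n,), 1-based generating atom


@dataclass
class SurfaceExtrema:
    v_min: float
    v_max: float
    min_position: np.ndarray
    max_position: np.ndarray
    min_owner: int
    max_owner: int


# ---------------------------------------------------------------------------
# internal coordinates


def _bond_pairs(geom: MolecularGeometry) -> list[tuple[int, int]]:
    coords = geom.coords
    rcov = np.array([covalent_radius(e) for e in geom.elements])
    d = cdist(coords, coords)
    cut = rcov[:, None] + rcov[None, :] + BOND_TOLERANCE
    pairs = []
    n = len(geom)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= cut[i, j]:
                pairs.append((i + 1, j + 1))
    return pairs


def _angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    v1 = p0 - p1
    v2 = p2 - p1
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed proper dihedral, IUPAC sign convention (clockwise positive
    looking down the 2->3 bond), degrees in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    # projections of the outer bonds onto the plane normal to b1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def perceive_internal_coords(geom: MolecularGeometry) -> InternalCoordinateSet:
    """Perceive bonds (covalent-radius criterion), angles over bonded
    triples and proper dihedrals over bonded quadruples; deterministic
    ordering by atom indices."""
    if len(geom) < 2:
        return InternalCoordinateSet({}, {}, {})
    coords = geom.coords
    pairs = _bond_pairs(geom)
    bonds = {
        (i, j): float(np.linalg.norm(coords[i - 1] - coords[j - 1]))
        for i, j in pairs
    }
    neighbors: dict[int, list[int]] = {k: [] for k in range(1, len(geom) + 1)}
    for i, j in pairs:
        neighbors[i].append(j)
        neighbors[j].append(i)
    for k in neighbors:
        neighbors[k].sort()

    angles = {}
    for j in range(1, len(geom) + 1):
        nb = neighbors[j]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                angles[(i, j, k)] = _angle(
                    coords[i - 1], coords[j - 1], coords[k - 1]
                )

    dihedrals = {}
    for j, k in pairs:
        for i in neighbors[j]:
            if i == k:
                continue
            for l in neighbors[k]:
                if l == j or l == i:
                    continue
                key = _normalize_dihedral_key((i, j, k, l))
                if key not in dihedrals:
                    a, b, c, d = key
                    dihedrals[key] = dihedral_angle(
                        coords[a - 1], coords[b - 1],
                        coords[c - 1], coords[d - 1],
                    )
    return InternalCoordinateSet(bonds, angles, dihedrals)


def _normalize_bond_key(key):
    i, j = key
    return (i, j) if i < j else (j, i)


def _normalize_angle_key(key):
    i, j, k = key
    return (i, j, k) if i < k else (k, j, i)


def _normalize_dihedral_key(key):
    i, j, k, l = key
    return (i, j, k, l) if j < k or (j == k and i < l) else (l, k, j, i)


def wrap_angle_difference(a: float, b: float) -> float:
    """Minimal angular distance between two dihedrals, degrees."""
    d = (a - b + 180.0) % 360.0 - 180.0
    return abs(d)


def geometry_mae(
    ref: InternalCoordinateSet, test: InternalCoordinateSet
) -> dict[str, dict[str, float]]:
    """Per-class mean absolute error over the intersection of internal
    coordinates.  Dihedral differences use the minimal angular distance.
    Unmatched keys are counted, never silently dropped."""
    out: dict[str, dict[str, float]] = {}
    specs = [
        ("bonds", ref.bonds, test.bonds, _normalize_bond_key, False),
        ("angles", ref.angles, test.angles, _normalize_angle_key, False),
        ("dihedrals", ref.dihedrals, test.dihedrals, _normalize_dihedral_key, True),
    ]
    for name, rd, td, norm, wrap in specs:
        rn = {norm(k): v for k, v in rd.items()}
        tn = {norm(k): v for k, v in td.items()}
        common = sorted(set(rn) & set(tn))
        entry: dict[str, float] = {
            "n_matched": len(common),
            "n_unmatched_ref": len(rn) - len(common),
            "n_unmatched_test": len(tn) - len(common),
        }
        if common:
            if wrap:
                diffs = [wrap_angle_difference(rn[k], tn[k]) for k in common]
            else:
                diffs = [abs(rn[k] - tn[k]) for k in common]
            entry["mae"] = float(np.mean(diffs))
        elif rn or tn:
            raise ValueError(f"no matched {name} between the two structures")
        out[name] = entry
    return out


# ---------------------------------------------------------------------------
# dipole and ESP


def point_charge_dipole(geom: MolecularGeometry) -> tuple[np.ndarray, float]:
    """Dipole of the partial-charge distribution about the center of
    nuclear charge.  Returns (vector, norm) in Debye."""
    q = geom.charges
    coords = geom.coords
    z = np.array([atomic_number(e) for e in geom.elements], dtype=float)
    origin = (z[:, None] * coords).sum(axis=0) / z.sum()
    mu = (q[:, None] * (coords - origin)).sum(axis=0) * EA_TO_DEBYE
    return mu, float(np.linalg.norm(mu))


def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, nearly uniform unit vectors (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def vdw_dot_surface(
    geom: MolecularGeometry,
    scale: float = 1.2,
    density: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Dot surface on the union of spheres of radius ``scale * r_vdw``.

    Per-atom Fibonacci lattices sized to ``density`` points/Å²; points
    strictly inside any other atom's scaled sphere are removed.
    Returns (points, owner_atom) with 1-based owners.
    """
    coords = geom.coords
    radii = scale * np.array([vdw_radius(e) for e in geom.elements])
    points = []
    owners = []
    for a, (center, r) in enumerate(zip(coords, radii), start=1):
        n = max(1, int(round(4.0 * np.pi * r * r * density)))
        pts = center + r * fibonacci_sphere(n)
        keep = np.ones(len(pts), dtype=bool)
        for b, (oc, orad) in enumerate(zip(coords, radii), start=1):
            if b == a:
                continue
            keep &= np.linalg.norm(pts - oc, axis=1) >= orad * (1 - 1e-9)
        points.append(pts[keep])
        owners.append(np.full(keep.sum(), a))
    return np.vstack(points), np.concatenate(owners)


def esp_at_points(
    geom: MolecularGeometry,
    points: np.ndarray,
    unit: str = "kcal/mol",
    owner_atom: np.ndarray | None = None,
) -> EspSurface:
    """Electrostatic potential of the atomic monopoles at the given
    points.  ``kcal/mol`` is the energy of a unit positive test charge;
    ``a.u.`` uses Bohr-scaled distances."""
    q = geom.charges
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = cdist(points, geom.coords)
    if np.any(d < 1e-6):
        raise ValueError("evaluation point coincides with a nucleus")
    inv = 1.0 / d
    if unit == "kcal/mol":
        values = COULOMB_KCAL * inv @ q
    elif unit == "a.u.":
        values = (inv * BOHR_A) @ q
    else:
        raise ValueError(f"unknown ESP unit {unit!r}")
    if owner_atom is None:
        owner_atom = np.argmin(d, axis=1) + 1
    return EspSurface(points, values, unit, np.asarray(owner_atom))


def surface_extrema(surface: EspSurface) -> SurfaceExtrema:
    """Global minimum and maximum of the surface potential with their
    positions and owning atoms."""
    if len(surface.values) == 0:
        raise ValueError("empty surface")
    imin = int(np.argmin(surface.values))
    imax = int(np.argmax(surface.values))
    return SurfaceExtrema(
        v_min=float(surface.values[imin]),
        v_max=float(surface.values[imax]),
        min_position=surface.points[imin],
        max_position=surface.points[imax],
        min_owner=int(surface.owner_atom[imin]),
        max_owner=int(surface.owner_atom[imax]),
    )


def per_atom_minima(surface: EspSurface) -> dict[int, float]:
    """Most negative potential attributed to each owning atom."""
    out: dict[int, float] = {}
    for owner in np.unique(surface.owner_atom):
        mask = surface.owner_atom == owner
        out[int(owner)] = float(surface.values[mask].min())
    return out
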