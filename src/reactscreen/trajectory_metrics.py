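"""Trajectory stability metrics.

Implements the standard MD post-processing battery: Kabsch optimal
superposition and RMSD series against a reference frame, per-atom RMSF,
mass-weighted radius of gyration, Shrake–Rupley solvent-accessible
surface area, geometric hydrogen-bond counting and ligand–residue
contact frequencies.

The RMSD series carries a stability verdict against the conventional
3.0 Å acceptability threshold.  Hydrogen bonds use donor–acceptor
heavy-atom distance <= rcut together with a D–H···A deviation from
linearity <= angle_cut (the angle-cut semantics of common trajectory
viewers: 10° means the D–H···A angle must be at least 170°).  RMSD and
RMSF are unweighted; Rg is mass-weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .elements import vdw_radius
from .geometry_field import fibonacci_sphere, perceive_internal_coords
from .io_formats import MolecularGeometry, Trajectory

#: conventional RMSD acceptability threshold, Å
RMSD_ACCEPTABLE = 3.0


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # (3, 3) proper orthogonal
    translation: np.ndarray   # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class MetricSeries:
    """A named per-frame series with sample statistics (ddof=1 std)."""

    name: str
    values: np.ndarray
    frames: np.ndarray
    verdict: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frames = np.asarray(self.frames)
        if self.values.shape != self.frames.shape:
            raise ValueError("values/frames length mismatch")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def std(self) -> float:
        if len(self.values) < 2:
            return 0.0
        return float(self.values.std(ddof=1))


@dataclass
class PerAtomProfile:
    labels: list          # atom indices or residue ids
    rmsf: np.ndarray      # Å, >= 0


@dataclass
class ContactTable:
    total_frames: int
    counts: dict = field(default_factory=dict)     # residue id -> frames in contact

    @property
    def frequencies(self) -> dict:
        return {r: c / self.total_frames for r, c in self.counts.items()}


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(
    mobile: np.ndarray,
    ref: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Weighted least-squares optimal proper rotation + translation
    mapping ``mobile`` onto ``ref`` (Kabsch, via SVD of the covariance;
    reflections corrected by flipping the smallest singular direction).

    Degenerate selections (< 3 atoms or collinear) fall back to a
    translation-only fit with a warning.
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape:
        raise ValueError(
            f"atom count mismatch: {mobile.shape[0]} vs {ref.shape[0]}"
        )
    n = mobile.shape[0]
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights length mismatch")
        w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * ref).sum(axis=0)
    a = mobile - mc
    b = ref - rc

    degenerate = n < 3 or np.linalg.matrix_rank(a * np.sqrt(w)[:, None],
                                               tol=1e-10) < 2
    if degenerate:
        warnings.warn("degenerate selection: translation-only superposition")
        rot = np.eye(3)
    else:
        h = (w[:, None] * a).T @ b
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        corr = np.diag([1.0, 1.0, d])
        rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    diff = a @ rot.T - b
    rmsd = float(np.sqrt((w * (diff * diff).sum(axis=1)).sum()))
    return SuperpositionResult(rot, trans, rmsd)


def rmsd(mobile: np.ndarray, ref: np.ndarray,
         weights: np.ndarray | None = None) -> float:
    return kabsch_superpose(mobile, ref, weights).rmsd


# ---------------------------------------------------------------------------
# series metrics


def _resolve_selection(sel, n: int) -> np.ndarray:
    if sel is None:
        return np.arange(n)
    idx = np.asarray(sel, dtype=int)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError("selection index out of range")
    return idx


def rmsd_series(
    traj: Trajectory,
    ref_frame: int = 0,
    align_selection=None,
    measure_selection=None,
    name: str = "rmsd",
) -> MetricSeries:
    """Per-frame RMSD to a reference frame.

    Each frame is superposed onto the reference using
    ``align_selection``; the RMSD is then evaluated over
    ``measure_selection`` without refitting, so e.g. ligand RMSD after
    protein-backbone alignment is expressible.  The verdict is
    ``"stable"`` when the mean RMSD is at or below 3.0 Å.
    """
    n = len(traj.topology)
    align = _resolve_selection(align_selection, n)
    measure = _resolve_selection(measure_selection, n)
    ref = traj.frames[ref_frame]
    values = []
    for frame in traj.frames:
        fit = kabsch_superpose(frame[align], ref[align])
        moved = fit.apply(frame[measure])
        diff = moved - ref[measure]
        values.append(float(np.sqrt((diff * diff).sum(axis=1).mean())))
    series = MetricSeries(name, np.array(values), np.arange(traj.n_frames))
    series.verdict = "stable" if series.mean <= RMSD_ACCEPTABLE else "unstable"
    return series


def align_trajectory(
    traj: Trajectory, ref_frame: int = 0, align_selection=None
) -> Trajectory:
    """New trajectory with every frame superposed onto the reference."""
    n = len(traj.topology)
    align = _resolve_selection(align_selection, n)
    ref = traj.frames[ref_frame]
    frames = []
    for frame in traj.frames:
        fit = kabsch_superpose(frame[align], ref[align])
        frames.append(fit.apply(frame))
    return Trajectory(traj.topology, frames, traj.frame_times)


def rmsf(
    traj: Trajectory,
    selection=None,
    group_by_residue: bool = False,
) -> PerAtomProfile:
    """Root-mean-square fluctuation about the per-atom trajectory mean.
    Expects an aligned trajectory (see :func:`align_trajectory`)."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    sel = _resolve_selection(selection, len(traj.topology))
    coords = traj.coords[:, sel, :]
    mean = coords.mean(axis=0)
    fluct = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    if not group_by_residue:
        labels = [traj.topology.atoms[i].index for i in sel]
        return PerAtomProfile(labels, fluct)
    groups: dict = {}
    for pos, i in enumerate(sel):
        rid = traj.topology.atoms[i].residue_id
        groups.setdefault(rid, []).append(pos)
    labels = sorted(groups, key=lambda r: (r is None, r))
    values = np.array([fluct[groups[r]].mean() for r in labels])
    return PerAtomProfile(labels, values)


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration, Å."""
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * coords).sum(axis=0) / total
    d2 = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((masses * d2).sum() / total))


def rg_series(traj: Trajectory, selection=None) -> MetricSeries:
    sel = _resolve_selection(selection, len(traj.topology))
    masses = traj.topology.masses[sel]
    values = [radius_of_gyration(f[sel], masses) for f in traj.frames]
    return MetricSeries("rg", np.array(values), np.arange(traj.n_frames))


# ---------------------------------------------------------------------------
# SASA


def sasa_shrake_rupley(
    coords: np.ndarray,
    elements: list[str],
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict | None = None,
) -> tuple[np.ndarray, float]:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's probe-inflated sphere carries ``n_points`` golden-spiral
    test points; a point is accessible if no neighbor's inflated sphere
    contains it.  Returns (per-atom Å², total Å²).
    """
    coords = np.asarray(coords, dtype=float)
    r = np.array(
        [radii[e] if radii and e in radii else vdw_radius(e) for e in elements]
    ) + probe
    n = len(coords)
    unit = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = r.max()
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + r[i] * unit
        neighbors = [
            j for j in tree.query_ball_point(coords[i], r[i] + max_r)
            if j != i
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= r[j]
        areas[i] = 4.0 * np.pi * r[i] ** 2 * accessible.mean()
    return areas, float(areas.sum())


def sasa_series(traj: Trajectory, selection=None, probe: float = 1.4,
                n_points: int = 960) -> MetricSeries:
    sel = _resolve_selection(selection, len(traj.topology))
    elements = [traj.topology.atoms[i].element for i in sel]
    values = [
        sasa_shrake_rupley(f[sel], elements, probe, n_points)[1]
        for f in traj.frames
    ]
    return MetricSeries("sasa", np.array(values), np.arange(traj.n_frames))


# ---------------------------------------------------------------------------
# hydrogen bonds


def find_polar_hydrogens(
    geom: MolecularGeometry, donor_elements=("N", "O")
) -> dict[int, list[int]]:
    """Map 0-based donor heavy-atom index -> list of 0-based bonded
    hydrogen indices, from covalent-radius bond perception."""
    ic = perceive_internal_coords(geom)
    elements = geom.elements
    donors: dict[int, list[int]] = {}
    for (i, j) in ic.bonds:
        a, b = i - 1, j - 1
        for heavy, hyd in ((a, b), (b, a)):
            if elements[heavy] in donor_elements and elements[hyd] == "H":
                donors.setdefault(heavy, []).append(hyd)
    return donors


def hbond_present(
    coords: np.ndarray,
    donor: int,
    hydrogens: list[int],
    acceptor: int,
    rcut: float = 3.0,
    angle_cut: float = 10.0,
) -> bool:
    """Definitional predicate: heavy-atom D···A distance <= rcut and,
    for some donor hydrogen, the D–H···A angle within ``angle_cut``
    degrees of linearity."""
    # boundary-inclusive within floating-point slack so that a geometry
    # constructed exactly at a cutoff classifies as inside it
    eps = 1e-9
    if np.linalg.norm(coords[donor] - coords[acceptor]) > rcut + eps:
        return False
    for h in hydrogens:
        v1 = coords[donor] - coords[h]
        v2 = coords[acceptor] - coords[h]
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        dha = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
        if 180.0 - dha <= angle_cut + eps:
            return True
    return False


def hbond_series(
    traj: Trajectory,
    donors=None,
    acceptors=None,
    rcut: float = 3.0,
    angle_cut: float = 10.0,
    donor_elements=("N", "O"),
    acceptor_elements=("N", "O"),
) -> MetricSeries:
    """Per-frame hydrogen-bond counts over donor/acceptor candidates.

    Donors default to N/O atoms with at least one perceived bonded
    hydrogen (donors without hydrogens are excluded with a warning);
    acceptors default to all N/O atoms.  Counts distinct (donor,
    acceptor) pairs per frame.
    """
    geom = traj.topology
    elements = geom.elements
    donor_h = find_polar_hydrogens(geom, donor_elements)
    if donors is not None:
        donors = [int(d) for d in donors]
        no_h = [d for d in donors if d not in donor_h]
        if no_h:
            warnings.warn(f"donors without bonded hydrogens excluded: {no_h}")
        donor_h = {d: donor_h[d] for d in donors if d in donor_h}
    if acceptors is None:
        acceptors = [
            i for i, e in enumerate(elements) if e in acceptor_elements
        ]
    counts = []
    for frame in traj.frames:
        c = 0
        for d, hyds in donor_h.items():
            for a in acceptors:
                if a == d:
                    continue
                if hbond_present(frame, d, hyds, a, rcut, angle_cut):
                    c += 1
        counts.append(c)
    return MetricSeries("hbonds", np.array(counts, dtype=float),
                        np.arange(traj.n_frames))


# ---------------------------------------------------------------------------
# contacts


def contact_frequency(
    traj: Trajectory,
    ligand_selection,
    residues=None,
    cutoff: float = 4.0,
) -> ContactTable:
    """Fraction of frames in which any residue heavy atom lies within
    ``cutoff`` of any ligand heavy atom."""
    topo = traj.topology
    lig = _resolve_selection(ligand_selection, len(topo))
    lig = np.array([i for i in lig if topo.atoms[i].element != "H"])
    if lig.size == 0:
        raise ValueError("ligand selection has no heavy atoms")
    res_atoms: dict = {}
    lig_set = set(lig.tolist())
    for i, atom in enumerate(topo.atoms):
        if i in lig_set or atom.element == "H" or atom.residue_id is None:
            continue
        res_atoms.setdefault(atom.residue_id, []).append(i)
    if residues is not None:
        unknown = [r for r in residues if r not in res_atoms]
        if unknown:
            raise KeyError(f"unknown residue ids: {unknown}")
        res_atoms = {r: res_atoms[r] for r in residues}
    table = ContactTable(total_frames=traj.n_frames,
                         counts={r: 0 for r in res_atoms})
    for frame in traj.frames:
        tree = cKDTree(frame[lig])
        for r, atoms in res_atoms.items():
            d, _ = tree.query(frame[atoms], k=1)
            if np.any(d <= cutoff):
                table.counts[r] += 1
    return table
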