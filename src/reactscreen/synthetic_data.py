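"""Seeded generators emulating every upstream engine.

The pipeline's real inputs come from quantum-chemistry, docking and MD
programs whose raw outputs are not redistributable here; these
generators produce statistically structured stand-ins with *planted
ground truth*, so every downstream stage can be tested end-to-end:

* ``gen_species_triplet`` — N/N-1/N+1 atomic populations constructed
  from planted Fukui vectors and frontier energies from planted (I, A);
* ``gen_geometry`` / ``gen_trajectory`` — point geometries and rigid
  rotation+translation frames with i.i.d. Gaussian coordinate noise and
  an optional linear ligand drift;
* ``gen_hbond_scene`` — a donor–hydrogen–acceptor triple at an exact
  heavy-atom distance and deviation from linearity;
* ``gen_energy_table`` — complex/receptor/ligand component energies
  whose per-frame binding delta is N(mean, sigma^2), split across
  components in planted proportions;
* ``gen_assay`` — 4PL dose–response points with multiplicative
  Gaussian noise and independent replicates.

Every generator is a pure function of its arguments: one integer seed
plus a per-generator stream tag feeds ``numpy.random.default_rng``, so
draws for one field never perturb another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    AssayTable,
    AtomRecord,
    EnergyComponentTable,
    MolecularGeometry,
    SpeciesTriplet,
    Trajectory,
)

# stable stream tags: adding a generator never shifts another's draws
_STREAMS = {
    "species": 11,
    "geometry": 23,
    "trajectory": 37,
    "energy": 53,
    "assay": 71,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# electronic structure


def gen_species_triplet(
    seed: int,
    f_minus: np.ndarray,
    f_plus: np.ndarray,
    i_pot: float = 8.29,
    e_aff: float = 0.37,
    compound_id: str = "synthetic",
    elements: list[str] | None = None,
) -> SpeciesTriplet:
    """Species triplet with planted condensed Fukui vectors.

    ``pop_cation = pop_neutral - f_minus`` and ``pop_anion =
    pop_neutral + f_plus``, so the condensed Fukui functions of the
    result are exactly the planted vectors.  Both vectors must sum to
    one (within 1e-10).  Frontier energies are -I and -A.
    """
    f_minus = np.asarray(f_minus, dtype=float)
    f_plus = np.asarray(f_plus, dtype=float)
    if f_minus.shape != f_plus.shape:
        raise ValueError("planted Fukui vectors must share length")
    for name, v in (("f_minus", f_minus), ("f_plus", f_plus)):
        if abs(v.sum() - 1.0) > 1e-10:
            raise ValueError(f"planted {name} must sum to 1 (got {v.sum()!r})")
    rng = _rng(seed, "species")
    n = f_minus.shape[0]
    # base populations comfortably above the planted removals
    base = rng.uniform(2.0, 8.0, size=n) + np.maximum(f_minus, 0.0)
    return SpeciesTriplet(
        compound_id=compound_id,
        e_homo=-i_pot,
        e_lumo=-e_aff,
        pop_neutral=base,
        pop_cation=base - f_minus,
        pop_anion=base + f_plus,
        elements=elements,
    )


def random_fukui_vector(seed: int, n_atoms: int) -> np.ndarray:
    """A random non-negative vector summing to one (Dirichlet-flat)."""
    rng = _rng(seed, "species")
    v = rng.dirichlet(np.ones(n_atoms))
    return v / v.sum()


# ---------------------------------------------------------------------------
# geometries and trajectories


def gen_geometry(
    seed: int,
    n_atoms: int = 20,
    box: float = 10.0,
    elements: list[str] | None = None,
    charges: np.ndarray | None = None,
    compound_id: str = "synthetic",
) -> MolecularGeometry:
    """Random point geometry in a cubic box (no bonding structure
    implied); optional per-atom charges."""
    rng = _rng(seed, "geometry")
    coords = rng.uniform(-box / 2.0, box / 2.0, size=(n_atoms, 3))
    if elements is None:
        elements = list(rng.choice(["C", "N", "O", "H"], size=n_atoms))
    atoms = [
        AtomRecord(
            i + 1, elements[i], coords[i],
            partial_charge=None if charges is None else float(charges[i]),
        )
        for i in range(n_atoms)
    ]
    return MolecularGeometry(compound_id, atoms)


@dataclass
class TrajectoryTruth:
    sigma: float
    drift: np.ndarray | None
    drift_selection: np.ndarray | None


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def gen_trajectory(
    seed: int,
    base: MolecularGeometry,
    n_frames: int = 100,
    sigma: float = 0.5,
    rigid_motion: bool = True,
    translation_scale: float = 5.0,
    drift: np.ndarray | None = None,
    drift_selection=None,
) -> tuple[Trajectory, TrajectoryTruth]:
    """Rigid-motion + Gaussian-noise trajectory over a base geometry.

    Each frame is a uniform random rotation and translation of the base
    coordinates plus i.i.d. N(0, sigma^2) noise per coordinate.  In
    drift mode the selected atoms are additionally displaced by
    ``drift * t/(n_frames-1)`` in the body frame before the rigid
    motion, so the drift survives alignment.  Frame 0 is the unmoved
    base (plus noise), making it a natural reference.
    """
    rng = _rng(seed, "trajectory")
    coords0 = base.coords
    frames = []
    for t in range(n_frames):
        c = coords0.copy()
        if drift is not None and n_frames > 1:
            sel = (
                np.arange(len(base)) if drift_selection is None
                else np.asarray(drift_selection, dtype=int)
            )
            c[sel] += np.asarray(drift, dtype=float) * (t / (n_frames - 1))
        if rigid_motion and t > 0:
            rot = _random_rotation(rng)
            trans = rng.normal(scale=translation_scale, size=3)
            c = c @ rot.T + trans
        if sigma > 0:
            c = c + rng.normal(scale=sigma, size=c.shape)
        frames.append(c)
    truth = TrajectoryTruth(
        sigma=sigma,
        drift=None if drift is None else np.asarray(drift, dtype=float),
        drift_selection=(
            None if drift_selection is None
            else np.asarray(drift_selection, dtype=int)
        ),
    )
    return Trajectory(base, frames), truth


def gen_hbond_scene(
    distance: float, angle_deviation: float, oh_bond: float = 0.96
) -> MolecularGeometry:
    """A donor O–H and acceptor O at an exact heavy-atom distance and
    D–H···A deviation from linearity (degrees).

    The donor sits at the origin, the acceptor on +x; the hydrogen is
    rotated off the D–A axis until the angle at H between D and A
    deviates from 180° by exactly the requested amount (root-found, then
    asserted geometrically to 1e-6 deg).
    """
    if not 0.0 <= angle_deviation < 90.0:
        raise ValueError("angle deviation must be in [0, 90) degrees")
    if distance <= oh_bond:
        raise ValueError("D-A distance must exceed the O-H bond length")
    d_pos = np.zeros(3)
    a_pos = np.array([distance, 0.0, 0.0])

    def deviation(phi: float) -> float:
        h = oh_bond * np.array([np.cos(phi), np.sin(phi), 0.0])
        v1 = d_pos - h
        v2 = a_pos - h
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return 180.0 - np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))

    if angle_deviation == 0.0:
        phi = 0.0
    else:
        phi = brentq(
            lambda p: deviation(p) - angle_deviation, 1e-12, np.pi * 0.75,
            xtol=1e-14,
        )
    h_pos = oh_bond * np.array([np.cos(phi), np.sin(phi), 0.0])
    achieved = deviation(phi)
    assert abs(achieved - angle_deviation) < 1e-6, achieved
    atoms = [
        AtomRecord(1, "O", d_pos, residue_id=1, residue_name="DON"),
        AtomRecord(2, "H", h_pos, residue_id=1, residue_name="DON"),
        AtomRecord(3, "O", a_pos, residue_id=2, residue_name="ACC"),
    ]
    return MolecularGeometry(f"hbond_d{distance}_t{angle_deviation}", atoms)


# ---------------------------------------------------------------------------
# energies


@dataclass
class EnergyTruth:
    dg_mean: float
    dg_sigma: float
    proportions: dict[str, float]
    per_frame_dg: np.ndarray = field(repr=False, default=None)


def gen_energy_table(
    seed: int,
    n_frames: int = 100,
    dg_mean: float = -36.042,
    dg_sigma: float = 2.0,
    proportions: dict[str, float] | None = None,
    entity_scale: float = 50.0,
) -> tuple[EnergyComponentTable, EnergyTruth]:
    """Complex/receptor/ligand component table with a planted per-frame
    binding energy ~ N(dg_mean, dg_sigma^2).

    The per-frame delta is split across the four components in fixed
    ``proportions`` (default: attraction dominated by vdW and
    electrostatics, opposed by GB desolvation — the usual MM/GBSA
    signature); receptor and ligand rows get independent fluctuating
    baselines, and the complex row is baseline sum plus the delta, so
    assembly recovers the truth exactly per frame.
    """
    if proportions is None:
        proportions = {"e_vdw": 1.35, "e_ele": 0.30, "g_gb": -0.75,
                       "g_sa": 0.10}
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("component proportions must sum to 1")
    rng = _rng(seed, "energy")
    comps = list(proportions)
    dg = rng.normal(dg_mean, dg_sigma, size=n_frames)
    rows = []
    for f in range(n_frames):
        base_r = rng.normal(-10.0 * entity_scale, entity_scale, size=len(comps))
        base_l = rng.normal(-1.0 * entity_scale, entity_scale / 5.0,
                            size=len(comps))
        for k, c in enumerate(comps):
            delta_c = dg[f] * proportions[c]
            rows.append({"frame": f, "entity": "receptor", "component": c,
                         "value": base_r[k]})
            rows.append({"frame": f, "entity": "ligand", "component": c,
                         "value": base_l[k]})
            rows.append({"frame": f, "entity": "complex", "component": c,
                         "value": base_r[k] + base_l[k] + delta_c})
    long = pd.DataFrame(rows)
    wide = long.pivot_table(index=["frame", "entity"], columns="component",
                            values="value").reset_index()
    wide.columns.name = None
    table = EnergyComponentTable(wide[["frame", "entity"] + comps])
    return table, EnergyTruth(dg_mean, dg_sigma, dict(proportions), dg)


# ---------------------------------------------------------------------------
# assays


@dataclass
class AssayTruth:
    ic50: float
    hill: float
    top: float
    bottom: float
    noise: float
    unit: str


def gen_assay(
    seed: int,
    ic50: float = 0.2,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    noise: float = 0.02,
    n_concentrations: int = 8,
    replicates: int = 3,
    decades: float = 2.0,
    unit: str = "µM",
    compound_id: str = "synthetic",
) -> tuple[AssayTable, AssayTruth]:
    """4PL dose–response points with multiplicative Gaussian noise.

    Concentrations are log-spaced over ``±decades`` around the planted
    IC50; each replicate draws independent noise
    ``response = y_true * (1 + N(0, noise^2))``.
    """
    if n_concentrations < 4:
        raise ValueError("need at least 4 distinct concentrations")
    rng = _rng(seed, "assay")
    conc = np.logspace(
        np.log10(ic50) - decades, np.log10(ic50) + decades, n_concentrations
    )
    from .potency_sar import four_pl  # local import avoids a cycle

    y_true = four_pl(conc, bottom, top, hill, np.log10(ic50))
    rows = []
    for rep in range(1, replicates + 1):
        eps = rng.normal(0.0, noise, size=n_concentrations)
        for c, y, e in zip(conc, y_true, eps):
            rows.append({
                "compound_id": compound_id,
                "concentration": c,
                "unit": unit,
                "response": y * (1.0 + e),
                "response_kind": "percent_inhibition",
                "replicate": rep,
            })
    table = AssayTable(pd.DataFrame(rows))
    return table, AssayTruth(ic50, hill, top, bottom, noise, unit)
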