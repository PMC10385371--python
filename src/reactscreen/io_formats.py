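"""Canonical in-memory records and text-format readers/writers.

The pipeline exchanges five kinds of external data: Cartesian geometries
(XYZ), trajectories (multi-frame XYZ or multi-model PDB), per-compound
electronic-structure records (species-triplet CSV), per-frame energy
component tables, and assay / physicochemical tables.  All coordinates
are Å; electronic-structure energies are eV and binding-stage energies
kcal/mol — the unit system is part of each type and never converted
implicitly.

Atom indices are 1-based (chemistry convention); trajectory frames are
0-based in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .elements import atomic_mass, normalize_symbol

ENERGY_ENTITIES = ("complex", "receptor", "ligand")
ENERGY_COMPONENTS = ("e_vdw", "e_ele", "g_gb", "g_sa")
ASSAY_UNITS = ("µM", "µg/mL")
_UNIT_ALIASES = {
    "um": "µM", "µm": "µM", "μm": "µM",
    "ug/ml": "µg/mL", "µg/ml": "µg/mL", "μg/ml": "µg/mL",
}


class FormatError(ValueError):
    """Malformed external file or table."""


# ---------------------------------------------------------------------------
# structures


@dataclass
class AtomRecord:
    """One atom: 1-based index, element symbol, position (Å), optional
    partial charge (e), mass (amu, from the element unless overridden)
    and residue labels."""

    index: int
    element: str
    position: np.ndarray
    partial_charge: float | None = None
    mass: float | None = None
    residue_id: int | None = None
    residue_name: str | None = None

    def __post_init__(self) -> None:
        self.element = normalize_symbol(self.element)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.index}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.index}: non-finite position")
        if self.mass is None:
            self.mass = atomic_mass(self.element, "average")


@dataclass
class MolecularGeometry:
    """An ordered set of atoms with an optional total charge."""

    compound_id: str
    atoms: list[AtomRecord]
    total_charge: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("geometry needs at least one atom")
        indices = [a.index for a in self.atoms]
        if indices != list(range(1, len(self.atoms) + 1)):
            raise ValueError("atom indices must be contiguous from 1")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        q = [a.partial_charge for a in self.atoms]
        if any(c is None for c in q):
            missing = [a.index for a in self.atoms if a.partial_charge is None]
            raise ValueError(f"atoms without partial charges: {missing}")
        return np.array(q, dtype=float)

    def with_charges(self, charges: Sequence[float]) -> "MolecularGeometry":
        if len(charges) != len(self.atoms):
            raise ValueError("charge vector length mismatch")
        atoms = [
            AtomRecord(a.index, a.element, a.position.copy(), float(q),
                       a.mass, a.residue_id, a.residue_name)
            for a, q in zip(self.atoms, charges)
        ]
        return MolecularGeometry(self.compound_id, atoms, self.total_charge)


@dataclass
class Trajectory:
    """Frames over a fixed topology; every frame carries the topology's
    atom count in the topology's atom order."""

    topology: MolecularGeometry
    frames: list[np.ndarray]
    frame_times: list[float] | None = None

    def __post_init__(self) -> None:
        n = len(self.topology)
        clean = []
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise FormatError(
                    f"frame {i}: expected {n} atoms, got {f.shape[0]}"
                )
            clean.append(f)
        self.frames = clean
        if self.frame_times is not None and len(self.frame_times) != len(clean):
            raise ValueError("frame_times length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) array."""
        return np.stack(self.frames)


@dataclass
class SpeciesTriplet:
    """Frontier-orbital energies (eV) plus atom-aligned electron
    populations q_k for the N, N-1 and N+1 electron states of one
    compound.  Population sums must differ by exactly one electron
    between adjacent states (within ``tol``)."""

    compound_id: str
    e_homo: float
    e_lumo: float
    pop_neutral: np.ndarray
    pop_cation: np.ndarray
    pop_anion: np.ndarray
    natural_charge: np.ndarray | None = None
    elements: list[str] | None = None
    tol: float = 1e-3

    def __post_init__(self) -> None:
        self.pop_neutral = np.asarray(self.pop_neutral, dtype=float)
        self.pop_cation = np.asarray(self.pop_cation, dtype=float)
        self.pop_anion = np.asarray(self.pop_anion, dtype=float)
        n = self.pop_neutral.shape[0]
        if self.pop_cation.shape[0] != n or self.pop_anion.shape[0] != n:
            raise ValueError("population vectors must share length")
        if self.e_lumo <= self.e_homo:
            raise ValueError(
                f"e_lumo ({self.e_lumo}) must exceed e_homo ({self.e_homo})"
            )
        dev_cat = abs(self.pop_neutral.sum() - self.pop_cation.sum() - 1.0)
        if dev_cat > self.tol:
            raise ValueError(
                "cation population sum must be one electron below neutral; "
                f"deviation {dev_cat:.6g} e exceeds tol {self.tol:g}"
            )
        dev_an = abs(self.pop_anion.sum() - self.pop_neutral.sum() - 1.0)
        if dev_an > self.tol:
            raise ValueError(
                "anion population sum must be one electron above neutral; "
                f"deviation {dev_an:.6g} e exceeds tol {self.tol:g}"
            )

    @property
    def n_atoms(self) -> int:
        return self.pop_neutral.shape[0]


@dataclass
class EnergyComponentTable:
    """Per-frame MM/GBSA component energies (kcal/mol) for the complex,
    receptor and ligand.  If no ``total`` column is supplied the total is
    the sum of the components."""

    data: pd.DataFrame
    components: tuple[str, ...] = ENERGY_COMPONENTS

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"frame", "entity", *self.components}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"energy table missing columns: {sorted(missing)}")
        bad = set(df["entity"]) - set(ENERGY_ENTITIES)
        if bad:
            raise FormatError(f"unknown entities: {sorted(bad)}")
        counts = df.groupby("frame")["entity"].apply(set)
        for frame, ents in counts.items():
            if ents != set(ENERGY_ENTITIES):
                raise FormatError(
                    f"frame {frame} incomplete: has {sorted(ents)}, "
                    f"needs {list(ENERGY_ENTITIES)}"
                )
        if "total" not in df.columns:
            df["total"] = df[list(self.components)].sum(axis=1)
        self.data = df.sort_values(["frame", "entity"]).reset_index(drop=True)

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.data["frame"].unique())


@dataclass
class AssayTable:
    """Concentration/response records, one row per replicate point."""

    data: pd.DataFrame
    mw: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"compound_id", "concentration", "unit", "response",
                    "response_kind", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"assay table missing columns: {sorted(missing)}")
        df = self.data.copy()
        df["unit"] = [normalize_unit(u) for u in df["unit"]]
        if (df["concentration"] <= 0).any():
            raise FormatError("assay concentrations must be positive")
        self.data = df

    def for_compound(self, compound_id: str) -> pd.DataFrame:
        sub = self.data[self.data["compound_id"] == compound_id]
        if sub.empty:
            raise KeyError(f"no assay rows for {compound_id!r}")
        return sub.reset_index(drop=True)

    @property
    def compound_ids(self) -> list[str]:
        return sorted(self.data["compound_id"].unique())


def normalize_unit(unit: str) -> str:
    u = str(unit).strip()
    if u in ASSAY_UNITS:
        return u
    key = u.lower().replace("μ", "µ")
    if key in _UNIT_ALIASES:
        return _UNIT_ALIASES[key]
    raise FormatError(
        f"unsupported concentration unit {unit!r}; accepted: {list(ASSAY_UNITS)}"
    )


# ---------------------------------------------------------------------------
# XYZ


def read_xyz(path: str | Path) -> MolecularGeometry:
    """Read a single-frame XYZ file (count line, comment, element x y z)."""
    geoms = read_multi_xyz(path)
    if len(geoms) != 1:
        raise FormatError(f"{path}: expected a single XYZ frame, got {len(geoms)}")
    return geoms[0]


def read_multi_xyz(path: str | Path) -> list[MolecularGeometry]:
    path = Path(path)
    lines = path.read_text().splitlines()
    geoms: list[MolecularGeometry] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise FormatError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        comment = lines[i + 1].strip() if i + 1 < len(lines) else ""
        atoms = []
        for k in range(count):
            lineno = i + 2 + k
            if lineno >= len(lines) or not lines[lineno].strip():
                raise FormatError(
                    f"{path}: header at line {i + 1} declares {count} atoms "
                    f"but only {k} records follow"
                )
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{lineno + 1}: expected 'element x y z', "
                    f"got {lines[lineno]!r}"
                )
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno + 1}: unparseable coordinate in "
                    f"{lines[lineno]!r}"
                ) from None
            charge = float(parts[4]) if len(parts) > 4 else None
            atoms.append(AtomRecord(k + 1, parts[0], np.array(xyz),
                                    partial_charge=charge))
        cid = comment if comment else f"frame{len(geoms)}"
        geoms.append(MolecularGeometry(cid, atoms))
        i += 2 + count
    if not geoms:
        raise FormatError(f"{path}: empty XYZ file")
    return geoms


def write_xyz(geom: MolecularGeometry, path: str | Path,
              comment: str | None = None) -> None:
    path = Path(path)
    out = [str(len(geom)), comment if comment is not None else geom.compound_id]
    with_charges = all(a.partial_charge is not None for a in geom.atoms)
    for a in geom.atoms:
        x, y, z = a.position
        line = f"{a.element:<3s} {x:14.6f} {y:14.6f} {z:14.6f}"
        if with_charges:
            line += f" {a.partial_charge:12.6f}"
        out.append(line)
    path.write_text("\n".join(out) + "\n", encoding="utf-8", newline="\n")


def write_multi_xyz(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    out = []
    for i, frame in enumerate(traj.frames):
        out.append(str(len(traj.topology)))
        out.append(f"{traj.topology.compound_id} frame {i}")
        for a, pos in zip(traj.topology.atoms, frame):
            out.append(
                f"{a.element:<3s} {pos[0]:14.6f} {pos[1]:14.6f} {pos[2]:14.6f}"
            )
    path.write_text("\n".join(out) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# PDB (fixed-column, PDB 3.3)


def _parse_pdb_atom(line: str, lineno: int, index: int) -> AtomRecord:
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip() or None
        resseq = line[22:26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError):
        raise FormatError(f"line {lineno}: malformed ATOM/HETATM record") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the atom-name convention: first alphabetic character
        element = next((c for c in name if c.isalpha()), "")
    return AtomRecord(
        index=index,
        element=element,
        position=np.array([x, y, z]),
        residue_id=int(resseq) if resseq else None,
        residue_name=resname,
    )


def read_pdb(path: str | Path) -> MolecularGeometry:
    traj = read_trajectory(path, format="pdb")
    geom = traj.topology
    return MolecularGeometry(geom.compound_id, geom.atoms, geom.total_charge)


def read_trajectory(path: str | Path, format: str | None = None) -> Trajectory:
    """Read a multi-frame XYZ or multi-model PDB trajectory.

    ``format`` is ``"xyz"`` or ``"pdb"``; inferred from the suffix when
    omitted.  All frames must carry the same atoms in the same order.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "xyz":
        geoms = read_multi_xyz(path)
        topo = geoms[0]
        frames = []
        for i, g in enumerate(geoms):
            if len(g) != len(topo):
                raise FormatError(
                    f"frame {i}: atom count {len(g)} != {len(topo)} in frame 0"
                )
            frames.append(g.coords)
        return Trajectory(topo, frames)
    if format == "pdb":
        return _read_pdb_trajectory(path)
    raise FormatError(f"unsupported trajectory format: {format!r}")


def _read_pdb_trajectory(path: Path) -> Trajectory:
    frames_atoms: list[list[AtomRecord]] = []
    current: list[AtomRecord] | None = None
    saw_model = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            current = []
        elif rec == "ENDMDL":
            if current is not None:
                frames_atoms.append(current)
            current = None
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                if saw_model:
                    raise FormatError(
                        f"line {lineno}: atom record outside MODEL/ENDMDL"
                    )
                current = []
                frames_atoms.append(current)
            current.append(_parse_pdb_atom(line, lineno, len(current) + 1))
    if not frames_atoms or not frames_atoms[0]:
        raise FormatError(f"{path}: no atoms found")
    topo = MolecularGeometry(path.stem, frames_atoms[0])
    n = len(topo)
    frames = []
    for i, atoms in enumerate(frames_atoms):
        if len(atoms) != n:
            raise FormatError(
                f"frame {i}: atom count {len(atoms)} != {n} in frame 0"
            )
        frames.append(np.array([a.position for a in atoms]))
    return Trajectory(topo, frames)


def write_pdb(traj: Trajectory | MolecularGeometry, path: str | Path) -> None:
    """Write a (multi-model) PDB file, 3-decimal coordinates."""
    if isinstance(traj, MolecularGeometry):
        traj = Trajectory(traj, [traj.coords])
    path = Path(path)
    out = []
    multi = traj.n_frames > 1
    for m, frame in enumerate(traj.frames, start=1):
        if multi:
            out.append(f"MODEL     {m:4d}")
        for a, pos in zip(traj.topology.atoms, frame):
            resname = (a.residue_name or "LIG")[:3]
            resseq = a.residue_id if a.residue_id is not None else 1
            name = a.element[:2].upper() + str(a.index % 100)
            out.append(
                f"HETATM{a.index:5d} {name:<4s} {resname:<3s} A{resseq:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element.upper():>2s}"
            )
        if multi:
            out.append("ENDMDL")
    out.append("END")
    path.write_text("\n".join(out) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# species triplet CSV


def read_species_triplet(path: str | Path, tol: float = 1e-3) -> SpeciesTriplet:
    """Read the species-triplet CSV.

    Populations are canonical.  A charge-encoded file (columns
    ``charge_neutral, charge_cation, charge_anion``) is accepted only
    with an explicit per-atom ``ref_electrons`` column; populations are
    then ``ref_electrons - charge``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        elif line.strip():
            break
    for key in ("compound_id", "e_homo_ev", "e_lumo_ev"):
        if key not in meta:
            raise FormatError(f"{path}: missing '# {key}=...' header")
    df = pd.read_csv(path, comment="#")
    pop_cols = {"pop_neutral", "pop_cation", "pop_anion"}
    charge_cols = {"charge_neutral", "charge_cation", "charge_anion"}
    if pop_cols <= set(df.columns):
        pops = {c: df[c].to_numpy(float) for c in pop_cols}
    elif charge_cols <= set(df.columns):
        if "ref_electrons" not in df.columns:
            raise FormatError(
                f"{path}: charge-encoded file requires a 'ref_electrons' column"
            )
        ref = df["ref_electrons"].to_numpy(float)
        pops = {
            "pop_" + c.split("_")[1]: ref - df[c].to_numpy(float)
            for c in charge_cols
        }
    else:
        raise FormatError(
            f"{path}: need either population columns {sorted(pop_cols)} or "
            f"charge columns {sorted(charge_cols)} + ref_electrons"
        )
    order = np.argsort(df["atom_index"].to_numpy())
    elements = (
        [str(e) for e in df["element"].to_numpy()[order]]
        if "element" in df.columns else None
    )
    nat = (
        df["natural_charge"].to_numpy(float)[order]
        if "natural_charge" in df.columns else None
    )
    return SpeciesTriplet(
        compound_id=meta["compound_id"],
        e_homo=float(meta["e_homo_ev"]),
        e_lumo=float(meta["e_lumo_ev"]),
        pop_neutral=pops["pop_neutral"][order],
        pop_cation=pops["pop_cation"][order],
        pop_anion=pops["pop_anion"][order],
        natural_charge=nat,
        elements=elements,
        tol=tol,
    )


def write_species_triplet(triplet: SpeciesTriplet, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# compound_id={triplet.compound_id}",
        f"# e_homo_ev={float(triplet.e_homo)!r}",
        f"# e_lumo_ev={float(triplet.e_lumo)!r}",
        "atom_index,element,pop_neutral,pop_cation,pop_anion",
    ]
    elements = triplet.elements or ["X"] * triplet.n_atoms
    for k in range(triplet.n_atoms):
        lines.append(
            f"{k + 1},{elements[k]},{float(triplet.pop_neutral[k])!r},"
            f"{float(triplet.pop_cation[k])!r},{float(triplet.pop_anion[k])!r}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# generic tables


_PHYSCHEM_REQUIRED = (
    "compound_id", "mw", "volume_A3", "hydration_kcal", "logp",
    "refractivity_A3", "sag_A2", "polarizability_A3",
)


def read_table(path: str | Path, schema: str):
    """Read a delimited table with one of the known schemas:
    ``energy`` -> EnergyComponentTable, ``assay`` -> AssayTable,
    ``physchem`` -> validated DataFrame."""
    path = Path(path)
    df = pd.read_csv(path)
    if schema == "energy":
        for col in ("e_vdw", "e_ele", "g_gb", "g_sa"):
            if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
                raise FormatError(f"{path}: non-numeric values in {col!r}")
        return EnergyComponentTable(df)
    if schema == "assay":
        for col in ("concentration", "response"):
            if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
                raise FormatError(f"{path}: non-numeric values in {col!r}")
        return AssayTable(df)
    if schema == "physchem":
        missing = set(_PHYSCHEM_REQUIRED) - set(df.columns)
        if missing:
            raise FormatError(
                f"{path}: physchem table missing columns {sorted(missing)}"
            )
        for col in _PHYSCHEM_REQUIRED[1:]:
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise FormatError(f"{path}: non-numeric values in {col!r}")
        return df
    raise ValueError(f"unknown schema {schema!r}")
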