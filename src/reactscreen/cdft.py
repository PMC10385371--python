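"""Conceptual-DFT reactivity descriptors.

Global descriptors follow the Koopmans-style finite-difference
convention: I = -E_HOMO, A = -E_LUMO, and

    gap = I - A          (= E_LUMO - E_HOMO)
    mu  = -(I + A) / 2   chemical potential
    chi = -mu            electronegativity (Mulliken)
    eta = (I - A) / 2    chemical hardness
    S   = 1 / (2 eta)    global softness
    omega = mu^2 / (2 eta)  electrophilicity index (Parr)

Local reactivity comes from the condensed Fukui functions over
atom-aligned electron populations of the N, N-1 and N+1 electron
states,

    f-(k) = q_k(N)   - q_k(N-1)    electrophilic attack
    f+(k) = q_k(N+1) - q_k(N)      nucleophilic attack
    f0(k) = [q_k(N+1) - q_k(N-1)] / 2   radical attack
    df(k) = f+(k) - f-(k)          dual descriptor

together with the Fukui-weighted partitions omega_k = omega * f_k
(local philicity), s_k = S * f_k (local softness) and the relative
electrophilicity f+/f- and nucleophilicity f-/f+ site indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SpeciesTriplet

#: denominator threshold below which relative indices are flagged undefined
REL_INDEX_EPS = 1e-8


@dataclass(frozen=True)
class GlobalDescriptors:
    """Global reactivity descriptors, all in eV except ``soft`` (eV^-1)."""

    i_pot: float
    e_aff: float
    gap: float
    mu: float
    chi: float
    eta: float
    soft: float
    omega: float
    e_homo: float
    e_lumo: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Report view: descriptors rounded for presentation."""
        return {
            "I": round(self.i_pot, ndigits),
            "A": round(self.e_aff, ndigits),
            "gap": round(self.gap, ndigits),
            "mu": round(self.mu, ndigits),
            "chi": round(self.chi, ndigits),
            "eta": round(self.eta, ndigits),
            "S": round(self.soft, ndigits),
            "omega": round(self.omega, ndigits),
        }


def global_from_frontier(e_homo: float, e_lumo: float) -> GlobalDescriptors:
    """Global descriptors from frontier-orbital energies (eV)."""
    if e_lumo <= e_homo:
        raise ValueError(
            f"e_lumo ({e_lumo}) must be above e_homo ({e_homo})"
        )
    return global_from_ia(-e_homo, -e_lumo)


def global_from_ia(i_pot: float, e_aff: float) -> GlobalDescriptors:
    """Global descriptors from ionization potential and electron
    affinity (eV)."""
    if i_pot <= e_aff:
        raise ValueError(f"I ({i_pot}) must exceed A ({e_aff})")
    eta = (i_pot - e_aff) / 2.0
    if eta == 0.0:  # unreachable given the check above; kept for clarity
        raise ValueError("degenerate hardness: S and omega undefined")
    mu = -(i_pot + e_aff) / 2.0
    return GlobalDescriptors(
        i_pot=i_pot,
        e_aff=e_aff,
        gap=i_pot - e_aff,
        mu=mu,
        chi=-mu,
        eta=eta,
        soft=softness_from_hardness(eta),
        omega=electrophilicity(mu, eta),
        e_homo=-i_pot,
        e_lumo=-e_aff,
    )


def softness_from_hardness(eta: float) -> float:
    """Global softness S = 1/(2 eta), eV^-1."""
    if eta <= 0:
        raise ValueError("hardness must be positive")
    return 1.0 / (2.0 * eta)


def electrophilicity(mu: float, eta: float) -> float:
    """Electrophilicity index omega = mu^2/(2 eta), eV."""
    if eta <= 0:
        raise ValueError("hardness must be positive")
    return mu * mu / (2.0 * eta)


def condensed_fukui(triplet: SpeciesTriplet, tol: float = 1e-6) -> pd.DataFrame:
    """Condensed Fukui functions per atom.

    Returns a table indexed by 1-based atom with columns ``element``
    (when known), ``f_minus``, ``f_plus``, ``f_zero`` and ``dual``.
    The three Fukui columns each sum to one and the dual descriptor to
    zero (asserted to ``tol`` against the triplet's own sums).
    """
    f_minus = triplet.pop_neutral - triplet.pop_cation
    f_plus = triplet.pop_anion - triplet.pop_neutral
    f_zero = (triplet.pop_anion - triplet.pop_cation) / 2.0
    dual = f_plus - f_minus

    expect_minus = triplet.pop_neutral.sum() - triplet.pop_cation.sum()
    expect_plus = triplet.pop_anion.sum() - triplet.pop_neutral.sum()
    if abs(f_minus.sum() - expect_minus) > tol or abs(f_minus.sum() - 1) > max(
        tol, triplet.tol
    ):
        raise ValueError(f"f- normalization violated: sum {f_minus.sum():.8f}")
    if abs(f_plus.sum() - expect_plus) > tol or abs(f_plus.sum() - 1) > max(
        tol, triplet.tol
    ):
        raise ValueError(f"f+ normalization violated: sum {f_plus.sum():.8f}")

    table = pd.DataFrame(
        {
            "f_minus": f_minus,
            "f_plus": f_plus,
            "f_zero": f_zero,
            "dual": dual,
        },
        index=pd.RangeIndex(1, triplet.n_atoms + 1, name="atom_index"),
    )
    if triplet.elements is not None:
        table.insert(0, "element", triplet.elements)
    return table


def local_indices(
    local: pd.DataFrame, global_desc: GlobalDescriptors
) -> pd.DataFrame:
    """Fukui-weighted local indices: philicity, local softness and the
    relative electrophilicity/nucleophilicity ratios.

    Sites whose denominator magnitude is below ``REL_INDEX_EPS`` get a
    NaN ratio and are flagged in ``rel_electro_undefined`` /
    ``rel_nucleo_undefined`` rather than dividing.
    """
    for col in ("f_minus", "f_plus"):
        if col not in local.columns:
            raise ValueError(f"local table lacks Fukui column {col!r}")
    out = local.copy()
    out["omega_minus"] = global_desc.omega * out["f_minus"]
    out["omega_plus"] = global_desc.omega * out["f_plus"]
    out["s_minus"] = global_desc.soft * out["f_minus"]
    out["s_plus"] = global_desc.soft * out["f_plus"]

    fm = out["f_minus"].to_numpy()
    fp = out["f_plus"].to_numpy()
    rel_e = np.full(len(out), np.nan)
    rel_n = np.full(len(out), np.nan)
    ok_e = np.abs(fm) >= REL_INDEX_EPS
    ok_n = np.abs(fp) >= REL_INDEX_EPS
    rel_e[ok_e] = fp[ok_e] / fm[ok_e]
    rel_n[ok_n] = fm[ok_n] / fp[ok_n]
    out["rel_electro"] = rel_e
    out["rel_nucleo"] = rel_n
    out["rel_electro_undefined"] = ~ok_e
    out["rel_nucleo_undefined"] = ~ok_n
    return out


def rank_descriptor(
    values: dict[str, float],
    direction: str = "descending",
    tol: float = 0.005,
) -> str:
    """Render an ordering string like ``"13j > 13b = 13c"``.

    Values within ``tol`` of the running group are rendered equal; ties
    are broken lexicographically by compound id so the output is
    deterministic.
    """
    if not values:
        raise ValueError("no values to rank")
    if direction not in ("ascending", "descending"):
        raise ValueError(f"unknown direction {direction!r}")
    for k, v in values.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite value for {k!r}")
    reverse = direction == "descending"
    items = sorted(values.items(), key=lambda kv: (-kv[1] if reverse else kv[1], kv[0]))
    groups: list[list[str]] = []
    group_value = None
    for cid, v in items:
        if group_value is not None and abs(v - group_value) <= tol:
            groups[-1].append(cid)
        else:
            groups.append([cid])
            group_value = v
    return " > ".join(" = ".join(sorted(g)) for g in groups)
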