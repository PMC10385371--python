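"""MM/GBSA-style binding free-energy assembly.

Given per-frame component energies (kcal/mol) for the complex, the
receptor and the ligand, the binding energy of each snapshot is the
defining difference

    dG_bind(f) = G_complex(f) - G_receptor(f) - G_ligand(f)

applied per component (van der Waals, electrostatic, GB polar
solvation, nonpolar surface term) and to the totals, followed by
snapshot statistics (mean, sample std, standard error).  The optional
nonpolar term can be rebuilt from a SASA via the conventional linear
model g_sa = gamma * SASA + beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import EnergyComponentTable

#: conventional GBSA surface-tension coefficient, kcal mol^-1 Å^-2
GAMMA_DEFAULT = 0.00542
#: conventional GBSA nonpolar offset, kcal mol^-1
BETA_DEFAULT = 0.92


@dataclass
class BindingEnergyRecord:
    """Per-frame binding-energy deltas plus snapshot statistics."""

    label: str
    per_frame: pd.DataFrame   # frame + d_<component> + dg_bind
    summary: pd.DataFrame     # term | mean | std | sem

    @property
    def mean_dg(self) -> float:
        row = self.summary.loc[self.summary["term"] == "dg_bind", "mean"]
        return float(row.iloc[0])


def mmgbsa_assemble(
    table: EnergyComponentTable, label: str = ""
) -> BindingEnergyRecord:
    """Assemble per-frame binding-energy deltas from a complete
    complex/receptor/ligand component table."""
    df = table.data
    comps = list(table.components)
    wide = df.pivot(index="frame", columns="entity",
                    values=comps + ["total"])
    frames = wide.index.to_numpy()
    per = pd.DataFrame({"frame": frames})
    for c in comps:
        per["d_" + c] = (
            wide[(c, "complex")] - wide[(c, "receptor")] - wide[(c, "ligand")]
        ).to_numpy()
    per["dg_bind"] = (
        wide[("total", "complex")]
        - wide[("total", "receptor")]
        - wide[("total", "ligand")]
    ).to_numpy()

    comp_sum = per[["d_" + c for c in comps]].sum(axis=1).to_numpy()
    if not np.allclose(comp_sum, per["dg_bind"].to_numpy(), atol=1e-6):
        # totals were supplied independently of the components
        warnings.warn(
            "per-frame dG differs from the component sum; totals kept as given"
        )

    rows = []
    n = len(per)
    for term in ["d_" + c for c in comps] + ["dg_bind"]:
        v = per[term].to_numpy()
        std = float(v.std(ddof=1)) if n > 1 else 0.0
        rows.append({
            "term": term,
            "mean": float(v.mean()),
            "std": std,
            "sem": std / np.sqrt(n) if n > 1 else 0.0,
        })
    return BindingEnergyRecord(label, per, pd.DataFrame(rows))


def nonpolar_from_sasa(
    sasa: float, gamma: float = GAMMA_DEFAULT, beta: float = BETA_DEFAULT
) -> float:
    """Nonpolar solvation term g_sa = gamma * SASA + beta, kcal/mol."""
    if sasa < 0:
        raise ValueError("SASA must be non-negative")
    return gamma * sasa + beta


def compare_complexes(
    records: dict[str, BindingEnergyRecord], tol: float = 1e-9
) -> dict:
    """Rank complexes by mean binding energy, most negative (strongest)
    first, with a per-component contribution table."""
    if len(records) < 2:
        labels = list(records)
        return {
            "ranking": labels,
            "ordering": labels[0] if labels else "",
            "ties": [],
            "components": _component_table(records),
        }
    items = sorted(records.items(), key=lambda kv: (kv[1].mean_dg, kv[0]))
    labels = [k for k, _ in items]
    ties = [
        (items[i][0], items[i + 1][0])
        for i in range(len(items) - 1)
        if abs(items[i][1].mean_dg - items[i + 1][1].mean_dg) <= tol
    ]
    parts = []
    for i, lab in enumerate(labels):
        if i and (labels[i - 1], lab) in ties:
            parts.append(f"= {lab}")
        else:
            parts.append(f"> {lab}" if i else lab)
    return {
        "ranking": labels,
        "ordering": " ".join(parts),
        "ties": ties,
        "components": _component_table(records),
    }


def _component_table(records: dict[str, BindingEnergyRecord]) -> pd.DataFrame:
    frames = []
    for label, rec in sorted(records.items()):
        t = rec.summary.copy()
        t.insert(0, "complex", label)
        frames.append(t)
    if not frames:
        return pd.DataFrame(columns=["complex", "term", "mean", "std", "sem"])
    return pd.concat(frames, ignore_index=True)
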