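#!/usr/bin/env python
"""IC50 fitting, fold potency, SAR ordering and descriptor flags.

Fits the 4PL dose-response curves from the assay plate of 01, compares
every compound with the reference inhibitor, ranks substituent classes
by geometric-mean IC50, and reports the HRMS-style monoisotopic masses
and Log P window verdicts for the mock series."""

import json
from pathlib import Path

import pandas as pd

from reactscreen import io_formats as iof
from reactscreen import potency_sar as ps

ROOT = Path(__file__).resolve().parents[1] / "results"

# mock series bookkeeping: substituent class, formula, Log P
SERIES = {
    "cmp_a": {"class": "Cl", "formula": "C24H18ClNO4", "logp": 4.1},
    "cmp_b": {"class": "Cl", "formula": "C25H20ClNO5", "logp": 4.0},
    "cmp_c": {"class": "H", "formula": "C24H19NO4", "logp": 3.6},
    "reference": {"class": None, "formula": None, "logp": None},
}


def main() -> None:
    truth = json.loads((ROOT / "inputs" / "truth.json").read_text())
    assay = iof.read_table(ROOT / "inputs" / "assay.csv", "assay")

    fits = {cid: ps.fit_ic50(assay, cid) for cid in assay.compound_ids}
    rows = []
    for cid, fit in sorted(fits.items()):
        row = {
            "compound_id": cid,
            "ic50_uM": fit.ic50,
            "se_ic50_uM": fit.se_ic50,
            "hill": fit.hill,
            "planted_uM": truth["assay"][cid],
        }
        if cid != "reference":
            ratio, nearest = ps.fold_potency(fits["reference"].ic50, fit.ic50)
            row["fold_vs_reference"] = ratio
            row["fold_nearest_int"] = nearest
            meta = SERIES[cid]
            row["substituent_class"] = meta["class"]
            row["monoisotopic_mass"] = round(
                ps.formula_mass(meta["formula"]), 4
            )
            row["logp_verdict"] = ps.logp_window(meta["logp"])["verdict"]
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "potency_summary.csv", index=False)

    sar_rows = table.dropna(subset=["substituent_class"])[
        ["substituent_class", "ic50_uM"]
    ].rename(columns={"ic50_uM": "ic50"})
    ordering = ps.sar_rank_classes(sar_rows)
    (ROOT / "sar_ordering.json").write_text(
        json.dumps({"class_ordering": ordering}, indent=2) + "\n",
        encoding="utf-8",
    )

    cols = ["compound_id", "ic50_uM", "planted_uM", "fold_vs_reference"]
    print(table[cols].to_string(index=False))
    print(f"substituent-class ordering (most potent first): {ordering}")
    best = table[table["compound_id"] != "reference"].nsmallest(1, "ic50_uM")
    print(
        f"most potent: {best['compound_id'].iloc[0]} at "
        f"{best['ic50_uM'].iloc[0]:.3f} uM, "
        f"{best['fold_nearest_int'].iloc[0]:.0f}-fold over the reference"
    )


if __name__ == "__main__":
    main()
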