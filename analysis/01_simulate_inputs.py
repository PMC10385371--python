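#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emulates the five upstream engines (electronic structure, geometry +
charges, MD, MM/GBSA components, assay plate) with seeded generators and
planted ground truth, writing plain-text inputs under
results/inputs/ and the truth records alongside as JSON."""

import json
from pathlib import Path

import numpy as np

from reactscreen import io_formats as iof
from reactscreen import synthetic_data as sd

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth: dict = {"seed": SEED}

    # electronic-structure records for three mock hybrids; the anchor
    # compound carries the study's printed frontier values I/A = 8.29/0.37 eV
    frontier = {"cmp_a": (8.29, 0.37), "cmp_b": (7.75, 0.37), "cmp_c": (8.10, 0.52)}
    truth["species"] = {}
    for k, (cid, (i_pot, e_aff)) in enumerate(frontier.items()):
        fm = sd.random_fukui_vector(SEED + k, 10)
        fp = sd.random_fukui_vector(SEED + 50 + k, 10)
        trip = sd.gen_species_triplet(SEED + 100 + k, fm, fp, i_pot=i_pot,
                                      e_aff=e_aff, compound_id=cid)
        iof.write_species_triplet(trip, OUT / f"species_{cid}.csv")
        truth["species"][cid] = {"i_pot": i_pot, "e_aff": e_aff,
                                 "f_minus": fm.tolist(), "f_plus": fp.tolist()}

    # charged point geometry for the ESP stage
    rng = np.random.default_rng(SEED)
    charges = rng.normal(0.0, 0.3, size=12)
    charges -= charges.mean()  # neutral molecule
    geom = sd.gen_geometry(SEED, n_atoms=12, charges=charges,
                           compound_id="cmp_a")
    iof.write_xyz(geom, OUT / "geom_cmp_a.xyz")
    truth["geometry"] = {"n_atoms": 12, "net_charge": 0.0}

    # rigid + noise trajectory (sigma = 0.5 A, the validation condition)
    base = sd.gen_geometry(SEED + 1, n_atoms=200)
    traj, ttruth = sd.gen_trajectory(SEED + 1, base, n_frames=200, sigma=0.5)
    iof.write_multi_xyz(traj, OUT / "traj_complex.xyz")
    truth["trajectory"] = {"sigma": ttruth.sigma, "n_frames": 200,
                           "n_atoms": 200}

    # MM/GBSA component tables planted at the study's two complex means
    truth["energies"] = {}
    for cid, mean in (("cmp_a", -36.042), ("cmp_b", -23.645)):
        table, et = sd.gen_energy_table(SEED + hash(cid) % 97, n_frames=100,
                                        dg_mean=mean, dg_sigma=2.0)
        table.data.to_csv(OUT / f"energies_{cid}.csv", index=False)
        truth["energies"][cid] = {"dg_mean": et.dg_mean,
                                  "dg_sigma": et.dg_sigma}

    # assay plates: reference drug at 1.142 uM, test compounds at the
    # study's potency scale
    import pandas as pd

    plates = []
    ic50s = {"reference": 1.142, "cmp_a": 0.232, "cmp_b": 0.190,
             "cmp_c": 0.513}
    for k, (cid, ic50) in enumerate(ic50s.items()):
        t, at = sd.gen_assay(SEED + 200 + k, ic50=ic50, noise=0.02,
                             compound_id=cid)
        plates.append(t.data)
    pd.concat(plates).to_csv(OUT / "assay.csv", index=False)
    truth["assay"] = ic50s

    (OUT / "truth.json").write_text(json.dumps(truth, indent=2) + "\n",
                                    encoding="utf-8")
    print(f"wrote synthetic inputs + truth records to {OUT}")


if __name__ == "__main__":
    main()
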