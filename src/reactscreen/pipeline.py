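"""Configuration-driven orchestration.

A :class:`PipelineConfig` (strict schema: unknown keys rejected) names
the input files and per-stage parameter overrides; :func:`run_pipeline`
runs the enabled stages in dependency order and returns one
:class:`CompoundReport` per compound plus study-level trajectory and
binding blocks.  A failure in one compound is recorded in that
compound's report and does not abort the others.  Every parameter
actually used is echoed into the provenance block so any reported
number can be reconstructed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from . import binding_energy, cdft, geometry_field, io_formats, potency_sar
from . import trajectory_metrics as tm


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cdft: bool = False
    esp: bool = False
    traj: bool = False
    mmgbsa: bool = False
    potency: bool = False


class PipelineInputs(BaseModel):
    model_config = ConfigDict(extra="forbid")
    species: dict[str, str] = {}        # compound id -> triplet CSV
    geometries: dict[str, str] = {}     # compound id -> XYZ (with charges)
    trajectories: dict[str, str] = {}   # label -> trajectory file
    energies: dict[str, str] = {}       # label -> energy CSV
    assay: str | None = None
    physchem: str | None = None
    reference_compound: str | None = None


class PipelineParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    round_ev: int = 2
    esp_scale: float = 1.2
    esp_density: float = 5.0
    esp_unit: str = "kcal/mol"
    rmsd_ref_frame: int = 0
    hbond_rcut: float = 3.0
    hbond_angle_cut: float = 10.0
    contact_cutoff: float = 4.0
    sasa_probe: float = 1.4
    sasa_points: int = 960


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stages: StageToggles = StageToggles()
    inputs: PipelineInputs = PipelineInputs()
    params: PipelineParams = PipelineParams()
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "info"

    @field_validator("inputs")
    @classmethod
    def _paths_exist(cls, v: PipelineInputs) -> PipelineInputs:
        paths = (
            list(v.species.values()) + list(v.geometries.values())
            + list(v.trajectories.values()) + list(v.energies.values())
        )
        if v.assay:
            paths.append(v.assay)
        if v.physchem:
            paths.append(v.physchem)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ValueError(f"input paths do not exist: {missing}")
        return v


@dataclass
class CompoundReport:
    compound_id: str
    blocks: dict[str, Any] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def block(self, name: str) -> Any:
        return self.blocks.get(name, "not run")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the enabled stages; returns ``{"compounds": {...},
    "study": {...}, "provenance": {...}}``."""
    reports: dict[str, CompoundReport] = {}
    study: dict[str, Any] = {}
    prov: dict[str, Any] = {"seed": config.seed,
                            "params": config.params.model_dump()}

    def rep(cid: str) -> CompoundReport:
        return reports.setdefault(cid, CompoundReport(cid))

    if config.stages.cdft:
        eta_by_compound: dict[str, float] = {}
        for cid, path in sorted(config.inputs.species.items()):
            try:
                triplet = io_formats.read_species_triplet(path)
                g = cdft.global_from_frontier(triplet.e_homo, triplet.e_lumo)
                local = cdft.local_indices(cdft.condensed_fukui(triplet), g)
                rep(cid).blocks["cdft"] = {
                    "global": g.rounded(config.params.round_ev),
                    "per_atom": local.round(3).to_dict(orient="index"),
                }
                eta_by_compound[cid] = g.eta
            except Exception as exc:  # per-compound isolation
                rep(cid).errors["cdft"] = str(exc)
        if len(eta_by_compound) >= 2:
            study["hardness_ordering"] = cdft.rank_descriptor(
                eta_by_compound, direction="descending"
            )

    if config.stages.esp:
        for cid, path in sorted(config.inputs.geometries.items()):
            try:
                geom = io_formats.read_xyz(path)
                points, owners = geometry_field.vdw_dot_surface(
                    geom, config.params.esp_scale, config.params.esp_density
                )
                surf = geometry_field.esp_at_points(
                    geom, points, config.params.esp_unit, owners
                )
                ext = geometry_field.surface_extrema(surf)
                vec, norm = geometry_field.point_charge_dipole(geom)
                rep(cid).blocks["esp"] = {
                    "v_min": ext.v_min, "v_max": ext.v_max,
                    "min_owner": ext.min_owner, "max_owner": ext.max_owner,
                    "unit": surf.unit,
                    "dipole_debye": norm,
                    "n_surface_points": int(len(surf.values)),
                }
            except Exception as exc:
                rep(cid).errors["esp"] = str(exc)

    if config.stages.traj:
        blocks = {}
        for label, path in sorted(config.inputs.trajectories.items()):
            try:
                traj = io_formats.read_trajectory(path)
                series = tm.rmsd_series(traj, config.params.rmsd_ref_frame)
                aligned = tm.align_trajectory(traj,
                                              config.params.rmsd_ref_frame)
                prof = tm.rmsf(aligned)
                rg = tm.rg_series(traj)
                blocks[label] = {
                    "rmsd_mean": series.mean, "rmsd_std": series.std,
                    "rmsd_verdict": series.verdict,
                    "rmsf_mean": float(prof.rmsf.mean()),
                    "rg_mean": rg.mean,
                }
            except Exception as exc:
                blocks[label] = {"error": str(exc)}
        study["trajectories"] = blocks

    if config.stages.mmgbsa:
        records = {}
        errors = {}
        for label, path in sorted(config.inputs.energies.items()):
            try:
                table = io_formats.read_table(path, "energy")
                records[label] = binding_energy.mmgbsa_assemble(table, label)
            except Exception as exc:
                errors[label] = str(exc)
        block: dict[str, Any] = {
            label: {
                "dg_mean": r.mean_dg,
                "summary": r.summary.to_dict(orient="records"),
            }
            for label, r in records.items()
        }
        if len(records) >= 2:
            block["comparison"] = binding_energy.compare_complexes(records)[
                "ordering"
            ]
        if errors:
            block["errors"] = errors
        study["binding"] = block

    if config.stages.potency:
        assay = (
            io_formats.read_table(config.inputs.assay, "assay")
            if config.inputs.assay else None
        )
        physchem = (
            io_formats.read_table(config.inputs.physchem, "physchem")
            if config.inputs.physchem else None
        )
        fits: dict[str, potency_sar.DoseResponseFit] = {}
        if assay is not None:
            for cid in assay.compound_ids:
                try:
                    fits[cid] = potency_sar.fit_ic50(assay, cid)
                except Exception as exc:
                    rep(cid).errors["potency"] = str(exc)
            ref = config.inputs.reference_compound
            for cid, fit in fits.items():
                block = {
                    "ic50": fit.ic50, "se_ic50": fit.se_ic50,
                    "unit": fit.unit, "hill": fit.hill,
                    "converged": fit.converged,
                }
                if ref and ref in fits and cid != ref:
                    ratio, nearest = potency_sar.fold_potency(
                        fits[ref].ic50, fit.ic50
                    )
                    block["fold_vs_reference"] = ratio
                    block["fold_nearest_int"] = nearest
                rep(cid).blocks["potency"] = block
        if physchem is not None:
            for _, row in physchem.iterrows():
                rep(str(row["compound_id"])).blocks["physchem"] = {
                    **{k: row[k] for k in physchem.columns if k != "compound_id"},
                    "logp_verdict": potency_sar.logp_window(row["logp"]),
                }

    return {
        "compounds": {
            cid: {"blocks": r.blocks, "errors": r.errors}
            for cid, r in sorted(reports.items())
        },
        "study": study,
        "provenance": prov,
    }


def render_report(result: dict[str, Any], out_dir: str | Path,
                  formats: tuple[str, ...] = ("json",)) -> list[Path]:
    """Write the pipeline result deterministically (sorted keys, fixed
    column order) as json / markdown / csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        if fmt == "json":
            p = out_dir / "report.json"
            p.write_text(
                json.dumps(result, indent=2, sort_keys=True, default=_coerce)
                + "\n",
                encoding="utf-8",
            )
        elif fmt == "markdown":
            p = out_dir / "report.md"
            p.write_text(_to_markdown(result), encoding="utf-8")
        elif fmt == "csv":
            p = out_dir / "report.csv"
            rows = []
            for cid, rec in sorted(result["compounds"].items()):
                for block, payload in sorted(rec["blocks"].items()):
                    rows.append({"compound_id": cid, "block": block,
                                 "payload": json.dumps(payload, sort_keys=True,
                                                       default=_coerce)})
            pd.DataFrame(rows, columns=["compound_id", "block", "payload"]
                         ).to_csv(p, index=False)
        else:
            raise ValueError(f"unsupported report format {fmt!r}")
        written.append(p)
    return written


def _coerce(obj):
    try:
        import numpy as np
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except Exception:
        pass
    return str(obj)


def _to_markdown(result: dict[str, Any]) -> str:
    lines = ["# Compound report", ""]
    for cid, rec in sorted(result["compounds"].items()):
        lines.append(f"## {cid}")
        for block in ("cdft", "esp", "physchem", "potency"):
            payload = rec["blocks"].get(block, "not run")
            lines.append(f"- **{block}**: "
                         + json.dumps(payload, sort_keys=True, default=_coerce))
        for stage, err in sorted(rec["errors"].items()):
            lines.append(f"- **{stage} error**: {err}")
        lines.append("")
    if result.get("study"):
        lines.append("## Study-level")
        lines.append(json.dumps(result["study"], indent=2, sort_keys=True,
                                default=_coerce))
        lines.append("")
    return "\n".join(lines)
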