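"""End-to-end orchestration: descriptors -> profile -> Ki/rank -> correlate
-> trajectory stats, driven by a JSON config, with a machine-readable run
manifest.

Stages run in dependency order; a stage whose input is absent is skipped, a
stage that errors is recorded in the manifest and its dependents are skipped.
Analytic outputs are deterministic for identical inputs; only the manifest
timestamp varies between reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .descriptors import descriptor_table, read_orbitals_tsv, write_descriptor_tsv
from .docking_metrics import (
    format_ki,
    halogen_trend,
    ki_from_binding_energy,
    rank_ligands,
    read_docking_tsv,
)
from .interaction_profiler import ProfilerConfig, profile_complex
from .structure_io import read_complex
from .structure_property import correlation_matrix
from .trajectory_metrics import read_trajectory, stability_summary, trajectory_rmsf, trajectory_rmsd

log = logging.getLogger("halodock")

STAGES = ("descriptors", "docking", "profile", "correlate", "trajectory")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages and write reports plus a manifest.

    ``config`` keys (all optional, at least one stage required):
      orbitals_tsv, docking_tsv, complex_pdb + ligand_resname,
      trajectory_pdb, profiler (criteria dict), temperature_k.

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    Raises ``FileNotFoundError`` for a named input that does not exist and
    ``ValueError`` when no stage is configured.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        k: Path(config[k])
        for k in ("orbitals_tsv", "docking_tsv", "complex_pdb", "trajectory_pdb")
        if config.get(k)
    }
    if not inputs:
        raise ValueError("config names no inputs; nothing to run")
    for k, p in inputs.items():
        if not p.exists():
            raise FileNotFoundError(f"{k}: {p}")

    manifest: dict = {
        "tool": "halodock",
        "version": __version__,
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": {k: {"path": str(p), "sha256_16": _digest(p)} for k, p in inputs.items()},
        "config": {k: v for k, v in config.items() if k not in inputs},
        "stages": {},
    }

    desc_df = None
    dock_records = None

    def record(stage: str, status: str, detail: str = "") -> None:
        manifest["stages"][stage] = {"status": status, "detail": detail}
        log.info("stage %s: %s %s", stage, status, detail)

    # descriptors
    if "orbitals_tsv" in inputs:
        try:
            orbitals = read_orbitals_tsv(inputs["orbitals_tsv"])
            desc_df = descriptor_table(orbitals)
            write_descriptor_tsv(desc_df, out / "descriptors.tsv")
            record("descriptors", "ok", f"{len(desc_df)} compounds")
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed
            record("descriptors", "error", str(exc))
    else:
        record("descriptors", "skipped", "no orbitals_tsv")

    # docking: Ki + ranking + halogen trend
    if "docking_tsv" in inputs:
        try:
            dock_records = read_docking_tsv(inputs["docking_tsv"])
            temp = float(config.get("temperature_k", 298.15))
            ranked = rank_ligands(dock_records)
            rows = [
                {
                    "compound_id": r.compound_id,
                    "binding_energy": r.binding_energy,
                    "ki_molar": ki_from_binding_energy(r.binding_energy, temp),
                    "ki_display": format_ki(ki_from_binding_energy(r.binding_energy, temp)),
                    "halogen": r.halogen,
                }
                for r in ranked
            ]
            pd.DataFrame(rows).to_csv(out / "ranked.tsv", sep="\t", index=False)
            trend = halogen_trend(dock_records)
            (out / "halogen_trend.json").write_text(
                json.dumps(
                    {
                        "means_kcal_mol": trend.means,
                        "ordered_F_Cl_Br_I": trend.ordered,
                        "missing_classes": list(trend.missing),
                        "temperature_k": temp,
                    },
                    indent=2,
                )
                + "\n"
            )
            record("docking", "ok", f"{len(rows)} ligands ranked")
        except Exception as exc:
            record("docking", "error", str(exc))
    else:
        record("docking", "skipped", "no docking_tsv")

    # interaction profile
    if "complex_pdb" in inputs:
        try:
            resname = config.get("ligand_resname", "LIG")
            cplx = read_complex(inputs["complex_pdb"].read_text(), resname)
            cfg = ProfilerConfig(**config.get("profiler", {}))
            report = profile_complex(cplx, cfg)
            (out / "interactions.json").write_text(report.to_json() + "\n")
            (out / "interactions.tsv").write_text(report.to_tsv())
            record("profile", "ok", f"{report.total_contacts} contacts")
        except Exception as exc:
            record("profile", "error", str(exc))
    else:
        record("profile", "skipped", "no complex_pdb")

    # descriptor-activity correlation (needs both upstream tables)
    up_ok = desc_df is not None and dock_records is not None
    if up_ok:
        try:
            dock_df = pd.DataFrame(
                {
                    "compound_id": [r.compound_id for r in dock_records],
                    "binding_energy": [r.binding_energy for r in dock_records],
                }
            )
            joined = desc_df.merge(dock_df, on="compound_id", how="inner")
            corr = correlation_matrix(joined)
            corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
            record("correlate", "ok", f"n={int(corr['n'].iloc[0])}")
        except Exception as exc:
            record("correlate", "error", str(exc))
    else:
        record("correlate", "skipped", "needs descriptors and docking stages")

    # trajectory stability
    if "trajectory_pdb" in inputs:
        try:
            traj = read_trajectory(inputs["trajectory_pdb"].read_text())
            selection = config.get("selection", "ca")
            skip = int(config.get("equilibration_skip", 0))
            series = trajectory_rmsd(traj, selection=selection)
            rmsf = trajectory_rmsf(traj, selection=selection)
            stats = {
                "rmsd_series": [round(float(v), 4) for v in series],
                "rmsd_range": [
                    round(float(series[skip:].min()), 4),
                    round(float(series[skip:].max()), 4),
                ],
                "rmsf": {k: round(v, 4) for k, v in rmsf.items()},
                "settings": {"selection": selection, "skip": skip, "reference_frame": 0},
            }
            (out / "trajectory_stats.json").write_text(json.dumps(stats, indent=2) + "\n")
            record("trajectory", "ok", f"{traj.n_frames} frames")
        except Exception as exc:
            record("trajectory", "error", str(exc))
    else:
        record("trajectory", "skipped", "no trajectory_pdb")

    manifest["ok"] = all(
        s["status"] in ("ok", "skipped") for s in manifest["stages"].values()
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
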