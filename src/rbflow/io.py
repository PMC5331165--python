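"""Plain-text interchange: TAC CSVs, study manifests, and report tables.

A study directory holds one TAC CSV per sampled region per scan, a sector
CSV per scan (the polar map), and a ``manifest.json`` linking files to
their roles, conditions, repeats and hemodynamics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import Scan, Study, StudyFlows
from .model import TAC, PolarMap, TimeGrid, TERRITORIES

__all__ = [
    "read_tac_csv",
    "write_tac_csv",
    "write_study",
    "read_study",
    "write_flows_csv",
]

_TAC_COLUMNS = ["frame_start_s", "frame_duration_s", "value_kBq_per_mL"]


def write_tac_csv(tac: TAC, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "frame_start_s": tac.grid.frame_start,
            "frame_duration_s": tac.grid.frame_duration,
            "value_kBq_per_mL": tac.values,
        }
    )
    df.to_csv(path, index=False)


def read_tac_csv(path: str | Path) -> TAC:
    df = pd.read_csv(path)
    missing = [c for c in _TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing TAC columns {missing}")
    grid = TimeGrid(df.frame_start_s.to_numpy(), df.frame_duration_s.to_numpy())
    return TAC(grid, df.value_kBq_per_mL.to_numpy())


def _write_sectors_csv(polar: PolarMap, path: Path) -> None:
    cols = {
        "sector_id": np.arange(polar.n_sectors),
        "territory": polar.territory,
        "septal": polar.septal.astype(int),
    }
    for j in range(polar.grid.n_frames):
        cols[f"f{j}"] = polar.values[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def _read_sectors_csv(path: Path, grid: TimeGrid) -> PolarMap:
    df = pd.read_csv(path)
    fcols = [f"f{j}" for j in range(grid.n_frames)]
    return PolarMap(
        grid,
        df[fcols].to_numpy(),
        df.territory.to_numpy(),
        df.septal.to_numpy(dtype=bool),
    )


def write_study(study: Study, directory: str | Path) -> Path:
    """Write a study as TAC CSVs + sector CSVs + manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subject_id": study.subject_id, "scans": []}
    for scan in study.scans:
        tag = f"{scan.condition}_{scan.repeat}"
        entry = {"condition": scan.condition, "repeat": scan.repeat, "rpp": scan.rpp}
        for role in ("blood_roi", "uptake_roi", "whole_lv", "rv"):
            fname = f"{tag}_{role}.csv"
            write_tac_csv(getattr(scan, role), directory / fname)
            entry[role] = fname
        sect = f"{tag}_sectors.csv"
        _write_sectors_csv(scan.polar, directory / sect)
        entry["sectors"] = sect
        manifest["scans"].append(entry)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def read_study(directory: str | Path) -> Study:
    """Load a study directory written by :func:`write_study`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    scans = []
    for entry in manifest["scans"]:
        tacs = {role: read_tac_csv(directory / entry[role]) for role in ("blood_roi", "uptake_roi", "whole_lv", "rv")}
        grid = tacs["blood_roi"].grid
        polar = _read_sectors_csv(directory / entry["sectors"], grid)
        scans.append(
            Scan(
                condition=entry["condition"],
                repeat=entry["repeat"],
                polar=polar,
                rpp=float(entry.get("rpp", float("nan"))),
                **tacs,
            )
        )
    return Study(manifest["subject_id"], scans)


def write_flows_csv(flows: StudyFlows, path: str | Path) -> None:
    """Tidy per-territory flow results for one study/variant."""
    rows = []
    for (condition, repeat), res in flows.results.items():
        for terr in TERRITORIES:
            rows.append(
                dict(
                    subject=flows.subject_id,
                    variant=flows.variant.key,
                    condition=condition,
                    repeat=repeat,
                    territory=terr,
                    mbf=res.territory_mbf[terr],
                )
            )
    mfr_t, mfr_r = flows.mfr("test"), flows.mfr("retest")
    d_t, d_r = flows.delta_mbf("test"), flows.delta_mbf("retest")
    for repeat, mfr, d in (("test", mfr_t, d_t), ("retest", mfr_r, d_r)):
        for terr in TERRITORIES:
            rows.append(
                dict(
                    subject=flows.subject_id,
                    variant=flows.variant.key,
                    condition="both",
                    repeat=repeat,
                    territory=terr,
                    mfr=mfr.get(terr, float("nan")),
                    dmbf=d[terr],
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)
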