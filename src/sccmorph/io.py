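"""File formats: cohort CSV, meshes (PLY/STL), landmarks, phantom truth."""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .parameters import PARAMETERS
from .preprocess import LandmarkPair

log = logging.getLogger(__name__)

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_curves_csv",
    "write_mesh",
    "read_mesh",
    "read_landmarks",
    "write_truth",
]

_COHORT_COLUMNS = ["subject_id", "group", "side", "parameter", "value"]


def read_cohort_csv(path: str | Path, require_group: bool = True) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV.

    Columns: subject_id, group, side, parameter, value. Empty value cells
    become missing values (never zeros). Errors name the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "side": str, "parameter": str})
    cols = _COHORT_COLUMNS if require_group else [c for c in _COHORT_COLUMNS if c != "group"]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = vals.isna() & df["value"].notna() & (df["value"].astype(str).str.strip() != "")
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header + 1-based
        raise ValueError(f"{path}:{line}: non-numeric value {df.loc[bad, 'value'].iloc[0]!r}")
    df["value"] = vals

    unknown = set(df["parameter"].unique()) - set(PARAMETERS)
    if unknown:
        line = int(df.index[df["parameter"].isin(unknown)][0]) + 2
        raise ValueError(f"{path}:{line}: unknown parameter name {sorted(unknown)[0]!r}")
    bad_side = ~df["side"].isin(["R", "L"])
    if bad_side.any():
        line = int(df.index[bad_side][0]) + 2
        raise ValueError(f"{path}:{line}: side must be 'R' or 'L'")
    dup = df.duplicated(subset=["subject_id", "side", "parameter"])
    if dup.any():
        row = df[dup].iloc[0]
        line = int(df.index[dup][0]) + 2
        raise ValueError(
            f"{path}:{line}: duplicate measurement for subject "
            f"{row['subject_id']!r}, parameter {row['parameter']!r}, side {row['side']!r}"
        )
    return df


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _COHORT_COLUMNS if c in table.columns]
    table.to_csv(path, index=False, columns=cols)


def read_curves_csv(path: str | Path) -> pd.DataFrame:
    """Curve-type records: patient_id, curve_type, cobb1[, cobb2]."""
    df = pd.read_csv(path, dtype={"patient_id": str, "curve_type": str})
    missing = {"patient_id", "curve_type", "cobb1"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "cobb2" not in df.columns:
        df["cobb2"] = np.nan
    return df


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write a surface mesh as binary PLY or STL (by extension)."""
    path = Path(path)
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    ext = path.suffix.lower()
    if ext not in (".ply", ".stl"):
        raise ValueError(f"unsupported mesh format {ext!r} (use .ply or .stl)")
    if not mesh.is_watertight:
        warnings.warn(f"{path.name}: mesh is not watertight; writing anyway",
                      RuntimeWarning, stacklevel=2)
    mesh.export(str(path))


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    m = trimesh.load(str(path), force="mesh", process=False)
    return m


def read_landmarks(path: str | Path) -> LandmarkPair:
    """Landmarks as JSON ``{"ac": [x, y, z], "pc": [x, y, z]}`` in world mm."""
    with open(path) as fh:
        d = json.load(fh)
    return LandmarkPair(np.asarray(d["ac"], float), np.asarray(d["pc"], float))


def write_truth(truth, path_yaml: str | Path, path_csv: str | Path | None = None,
                subject_id: str = "phantom") -> None:
    """Phantom ground truth as YAML (geometry) plus optional CSV (the nine
    parameters via :func:`sccmorph.phantom.truth_report`)."""
    from .phantom import truth_report

    doc = {}
    for (side, canal), ct in truth.canals.items():
        doc.setdefault(side, {})[canal] = {
            "plane_normal": [float(x) for x in ct.normal],
            "min_csa_mm2": float(ct.min_csa_mm2),
            "max_abs_x_mm": float(ct.max_abs_x_mm),
            "junction_points": np.asarray(ct.junction_points).tolist(),
        }
    for side, j in truth.junctions.items():
        doc.setdefault(side, {})["junctions"] = {
            k: [float(x) for x in v] for k, v in j.items()
        }
    with open(path_yaml, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    if path_csv is not None:
        truth_report(truth, subject_id).to_csv(path_csv, index=False)
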