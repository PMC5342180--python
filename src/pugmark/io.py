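"""Readers and writers for footprint tables, landmark files and configs.

Measurement tables are CSV with metadata columns
(footprint_id, trail_id, animal_id, sex, age_years, site, side) followed by
V1..V128; an XLSX dialect with a user-editable column-name mapping covers
externally deposited spreadsheets.  Landmarks are read from TPS (the
standard geometric-morphometrics format) or a JSON schema with named points.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .morphometry import N_LANDMARKS, LandmarkSet
from .pairwise import AlgorithmConfig, variable_columns

__all__ = [
    "META_COLUMNS",
    "read_table",
    "write_table",
    "ingest_report",
    "read_landmarks",
    "write_landmarks_json",
    "load_config",
    "config_hash",
]

META_COLUMNS = ["footprint_id", "trail_id", "animal_id", "sex", "age_years", "site", "side"]
_META_DEFAULTS = {"animal_id": None, "sex": "unknown", "age_years": np.nan,
                  "site": "", "side": "LH"}


def _validate_table(df: pd.DataFrame, source: str) -> pd.DataFrame:
    for col, default in _META_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    missing = [c for c in ("footprint_id", "trail_id") if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: unmappable columns: missing {missing}")
    vcols = variable_columns(df)
    if not vcols:
        raise ValueError(f"{source}: no measurement columns (V1..V128) found")
    df[vcols] = df[vcols].apply(pd.to_numeric, errors="coerce")
    bad = df[vcols].isna().any(axis=1)
    n_rejected = int(bad.sum())
    if n_rejected:
        ids = df.loc[bad, "footprint_id"].astype(str).tolist()
        warnings.warn(
            f"{source}: rejected {n_rejected} footprint(s) with missing "
            "measurements: " + ", ".join(ids[:10]) + ("..." if len(ids) > 10 else ""),
            stacklevel=3,
        )
        df = df[~bad].copy()
    if df["trail_id"].isna().any() or (df["trail_id"].astype(str) == "").any():
        raise ValueError(f"{source}: empty trail_id values")
    df = df[META_COLUMNS + vcols].reset_index(drop=True)
    df.attrs["n_rejected"] = n_rejected
    return df


def read_table(
    path: str | Path,
    dialect: str = "csv",
    column_mapping: str | Path | dict | None = None,
) -> pd.DataFrame:
    """Read and validate a footprint measurement table.

    ``dialect`` is ``csv`` or ``s1-xlsx`` (a deposited spreadsheet whose
    headers are renamed via ``column_mapping``, a JSON file or dict of
    source-name -> canonical-name).  Footprints with missing measurement
    values are dropped with a warning and counted in ``.attrs['n_rejected']``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        df = pd.read_csv(path, comment="#")
    elif dialect == "s1-xlsx":
        df = pd.read_excel(path, engine="openpyxl")
        mapping: dict[str, str] = {}
        if isinstance(column_mapping, (str, Path)):
            mapping = json.loads(Path(column_mapping).read_text())
        elif isinstance(column_mapping, dict):
            mapping = dict(column_mapping)
        if mapping:
            unknown = [k for k in mapping if k not in df.columns]
            if unknown:
                raise ValueError(f"{path}: mapping references absent columns: {unknown}")
            df = df.rename(columns=mapping)
        # normalize headers like "v1"/"V 1" to "V1"
        df = df.rename(
            columns={
                c: "V" + c.upper().replace("V", "").strip()
                for c in df.columns
                if c.upper().replace("V", "").strip().isdigit()
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _validate_table(df, str(path))


def write_table(
    table: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a measurement table as CSV with 6-significant-digit floats.

    ``provenance`` (e.g. the generating seed) is recorded as a leading
    ``#`` comment line, which :func:`read_table` skips.
    """
    path = Path(path)
    header = ""
    if provenance:
        header = "# " + " ".join(f"{k}={v}" for k, v in provenance.items()) + "\n"
    body = table.to_csv(index=False, float_format="%.6g")
    path.write_text(header + body)


def ingest_report(table: pd.DataFrame) -> dict:
    """Summary statistics of an ingested table (counts and per-animal means)."""
    n_prints = len(table)
    trails = table["trail_id"].nunique()
    animals = table["animal_id"].dropna().nunique()
    report: dict[str, object] = {
        "n_footprints": int(n_prints),
        "n_trails": int(trails),
        "n_individuals": int(animals),
        "n_rejected": int(table.attrs.get("n_rejected", 0)),
    }
    if animals:
        report["mean_footprints_per_individual"] = round(n_prints / animals, 2)
        report["mean_trails_per_individual"] = round(trails / animals, 2)
        per_animal = table.groupby("animal_id").agg(
            prints=("footprint_id", "size"), trails=("trail_id", "nunique")
        )
        report["footprints_per_individual_range"] = [
            int(per_animal["prints"].min()), int(per_animal["prints"].max())
        ]
        report["trails_per_individual_range"] = [
            int(per_animal["trails"].min()), int(per_animal["trails"].max())
        ]
        by_sex = {}
        firsts = table.drop_duplicates("animal_id")
        for sex, sub in table.groupby(firsts.set_index("animal_id")["sex"]
                                      .reindex(table["animal_id"]).to_numpy()):
            a = sub["animal_id"].nunique()
            by_sex[str(sex)] = {
                "n_individuals": int(a),
                "n_footprints": int(len(sub)),
                "n_trails": int(sub["trail_id"].nunique()),
                "mean_footprints_per_individual": round(len(sub) / a, 2) if a else None,
                "mean_trails_per_individual": round(sub["trail_id"].nunique() / a, 2) if a else None,
            }
        report["by_sex"] = by_sex
    return report


# --- landmark files --------------------------------------------------------

def _tps_records(text: str) -> list[dict]:
    records: list[dict] = []
    current: dict | None = None
    coords_left = 0
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            current = {"points": [], "meta": {}}
            records.append(current)
            current["lm"] = int(line.split("=", 1)[1])
            coords_left = current["lm"]
        elif current is not None and coords_left > 0:
            x, y = line.split()
            current["points"].append((float(x), float(y)))
            coords_left -= 1
        elif current is not None and "=" in line:
            key, val = line.split("=", 1)
            current["meta"][key.upper()] = val.strip()
    return records


def read_landmarks(
    path: str | Path,
    fmt: str = "json",
    scale_separation_mm: float | None = None,
) -> list[LandmarkSet]:
    """Read landmark sets from a TPS or JSON file.

    TPS records need ``LM=25``; the ``SCALE=`` factor (mm per px) is encoded
    as a synthetic pair of scale points one pixel apart, so downstream
    calibration reproduces it.  Missing scale information is an error unless
    ``scale_separation_mm`` supplies it.
    """
    path = Path(path)
    text = path.read_text()
    out: list[LandmarkSet] = []
    if fmt == "tps":
        for i, rec in enumerate(_tps_records(text)):
            if rec["lm"] != N_LANDMARKS:
                raise ValueError(
                    f"{path}: record {i}: LM={rec['lm']}, expected {N_LANDMARKS}"
                )
            meta = rec["meta"]
            scale = meta.get("SCALE")
            if scale is not None:
                sep_mm = float(scale)  # mm per px, points 1 px apart
            elif scale_separation_mm is not None:
                sep_mm = float(scale_separation_mm)
            else:
                raise ValueError(f"{path}: record {i}: no SCALE= and no scale flag")
            fid = meta.get("ID", f"{path.stem}-{i}")
            out.append(
                LandmarkSet(
                    footprint_id=str(fid),
                    trail_id=str(meta.get("TRAIL", meta.get("IMAGE", fid))),
                    landmarks=np.array(rec["points"]),
                    scale_points=np.array([(0.0, 0.0), (1.0, 0.0)]),
                    scale_separation_mm=sep_mm,
                )
            )
        return out

    if fmt == "json":
        payload = json.loads(text)
        if isinstance(payload, dict):
            payload = payload.get("landmarks", [payload])
        for i, rec in enumerate(payload):
            pts = rec["points"]
            names = [f"{k:02d}" for k in range(1, N_LANDMARKS + 1)]
            missing = [nm for nm in names if nm not in pts]
            if missing:
                raise ValueError(f"{path}: record {i}: missing points {missing}")
            sep_mm = rec.get("scale_separation_mm", scale_separation_mm)
            if sep_mm is None:
                raise ValueError(f"{path}: record {i}: no scale separation given")
            out.append(
                LandmarkSet(
                    footprint_id=str(rec.get("footprint_id", f"{path.stem}-{i}")),
                    trail_id=str(rec.get("trail_id", path.stem)),
                    landmarks=np.array([pts[nm] for nm in names], dtype=float),
                    scale_points=np.array(rec["scale_points"], dtype=float),
                    scale_separation_mm=float(sep_mm),
                    calibrated=bool(rec.get("calibrated", False)),
                    animal_id=rec.get("animal_id"),
                    sex=rec.get("sex", "unknown"),
                    age_years=rec.get("age_years"),
                    side=rec.get("side", "LH"),
                )
            )
        return out
    raise ValueError(f"unknown landmark format {fmt!r}")


def write_landmarks_json(sets: list[LandmarkSet], path: str | Path,
                         provenance: dict | None = None) -> None:
    """Write landmark sets to the JSON landmark schema."""
    payload = []
    for ls in sets:
        payload.append(
            {
                "footprint_id": ls.footprint_id,
                "trail_id": ls.trail_id,
                "animal_id": ls.animal_id,
                "sex": ls.sex,
                "age_years": ls.age_years,
                "side": ls.side,
                "calibrated": ls.calibrated,
                "scale_separation_mm": ls.scale_separation_mm,
                "scale_points": ls.scale_points.tolist(),
                "points": {
                    f"{i + 1:02d}": [float(x) for x in ls.landmarks[i]]
                    for i in range(N_LANDMARKS)
                },
            }
        )
    doc: dict[str, object] = {"records": len(payload)}
    if provenance:
        doc.update(provenance)
    Path(path).write_text(json.dumps({"provenance": doc, "landmarks": payload}, indent=1))


# --- configuration ---------------------------------------------------------

_CONFIG_KEYS = {"n_variables", "contour_probability", "ward_threshold", "rcv_mode", "seed"}


def load_config(path: str | Path | None) -> AlgorithmConfig:
    """Load an AlgorithmConfig from YAML or JSON; unknown keys are rejected."""
    if path is None:
        return AlgorithmConfig()
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = sorted(set(data) - _CONFIG_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {', '.join(unknown)}")
    return AlgorithmConfig(**data)


def config_hash(config: AlgorithmConfig) -> str:
    blob = json.dumps(
        {
            "n_variables": config.n_variables,
            "contour_probability": config.contour_probability,
            "ward_threshold": config.ward_threshold,
            "rcv_mode": config.rcv_mode,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
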