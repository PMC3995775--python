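"""File formats: landmark files (JSON / long CSV), results, ratings, truth.

The landmark file is the tool's data contract: named 3D anatomical points in
world millimetres, one record per shoulder — no images, no DICOM.  The
primary format is JSON::

    {
      "schema_version": 1,
      "shoulders": [
        {
          "shoulder_id": "S0001",
          "side": "right",
          "dominance": "unknown",
          "landmarks": {"glenoid_center": [x, y, z], ...}
        }
      ]
    }

A flat long CSV alternative carries one landmark per row with columns
``shoulder_id, side, dominance, landmark, x_mm, y_mm, z_mm``.  Validation
failures name the offending record and landmark.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GlenvaultError, InputError
from .geometry import LandmarkSet
from .reliability import RatingMatrix

__all__ = [
    "SCHEMA_VERSION",
    "read_landmarks",
    "write_landmarks",
    "read_results",
    "write_results",
    "read_ratings",
    "write_ratings",
]

SCHEMA_VERSION = 1


def _record_to_landmarkset(rec: dict, where: str) -> LandmarkSet:
    for key in ("shoulder_id", "side", "landmarks"):
        if key not in rec:
            raise InputError(f"{where}: missing field {key!r}")
    if not isinstance(rec["landmarks"], dict) or not rec["landmarks"]:
        raise InputError(f"{where}: 'landmarks' must be a non-empty mapping")
    try:
        return LandmarkSet(
            shoulder_id=str(rec["shoulder_id"]),
            side=rec["side"],
            dominance=rec.get("dominance", "unknown"),
            points={str(k): np.asarray(v, dtype=float) for k, v in rec["landmarks"].items()},
        )
    except (GlenvaultError, ValueError, TypeError) as exc:
        raise InputError(f"{where}: {exc}") from exc


def read_landmarks(path) -> list[LandmarkSet]:
    """Read and fully validate a landmark file (.json or .csv), preserving
    record order."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"landmark file not found: {path}")
    if path.suffix.lower() == ".csv":
        return _read_landmarks_csv(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "shoulders" not in doc:
        raise InputError(f"{path}: expected an object with a 'shoulders' list")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise InputError(
            f"{path}: unsupported schema_version {version!r} (expected {SCHEMA_VERSION})"
        )
    out, seen = [], set()
    for i, rec in enumerate(doc["shoulders"]):
        lm = _record_to_landmarkset(rec, f"{path}: shoulders[{i}]")
        if lm.shoulder_id in seen:
            raise InputError(f"{path}: duplicate shoulder_id {lm.shoulder_id!r}")
        seen.add(lm.shoulder_id)
        out.append(lm)
    return out


def _read_landmarks_csv(path: Path) -> list[LandmarkSet]:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["shoulder_id", "side", "dominance", "landmark", "x_mm", "y_mm", "z_mm"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    out, seen = [], set()
    # preserve first-appearance order of shoulders
    for sid in dict.fromkeys(df["shoulder_id"]):
        sub = df[df["shoulder_id"] == sid]
        if sub["landmark"].duplicated().any():
            dup = sorted(sub["landmark"][sub["landmark"].duplicated()])
            raise InputError(f"{path}: shoulder {sid!r} repeats landmark(s) {dup}")
        rec = {
            "shoulder_id": sid,
            "side": sub["side"].iloc[0],
            "dominance": sub["dominance"].iloc[0],
            "landmarks": {
                r.landmark: [r.x_mm, r.y_mm, r.z_mm] for r in sub.itertuples()
            },
        }
        lm = _record_to_landmarkset(rec, f"{path}: shoulder {sid!r}")
        if lm.shoulder_id in seen:
            raise InputError(f"{path}: duplicate shoulder_id {lm.shoulder_id!r}")
        seen.add(lm.shoulder_id)
        out.append(lm)
    return out


def write_landmarks(landmark_sets: Iterable[LandmarkSet], path) -> None:
    """Write landmark records to .json (default) or long .csv; full double
    precision, round-trips exactly through :func:`read_landmarks`."""
    path = Path(path)
    sets = list(landmark_sets)
    if path.suffix.lower() == ".csv":
        rows = [
            {
                "shoulder_id": lm.shoulder_id,
                "side": lm.side,
                "dominance": lm.dominance,
                "landmark": name,
                "x_mm": p[0],
                "y_mm": p[1],
                "z_mm": p[2],
            }
            for lm in sets
            for name, p in lm.points.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
        return
    doc = {
        "schema_version": SCHEMA_VERSION,
        "shoulders": [
            {
                "shoulder_id": lm.shoulder_id,
                "side": lm.side,
                "dominance": lm.dominance,
                "landmarks": {n: [float(x) for x in p] for n, p in lm.points.items()},
            }
            for lm in sets
        ],
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")


def write_results(results: pd.DataFrame, path, round_deg: float | None = None) -> None:
    """Write a version-results table; optionally round angles to a reporting
    resolution (e.g. 0.1°)."""
    df = results.copy()
    if round_deg:
        df["version_deg"] = (df["version_deg"] / round_deg).round() * round_deg
    df.to_csv(path, index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"results file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("shoulder_id", "method", "version_deg") if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    if not np.all(np.isfinite(df["version_deg"].to_numpy(dtype=float))):
        raise InputError(f"{path}: non-finite version_deg values")
    return df


def write_ratings(matrices: dict[str, RatingMatrix], path) -> None:
    """Write rating matrices as long CSV:
    shoulder_id, rater, session, method, version_deg."""
    rows = []
    for method, m in matrices.items():
        for i, sid in enumerate(m.subject_ids):
            for j, rid in enumerate(m.rater_ids):
                for s in range(m.n_sessions):
                    rows.append(
                        {
                            "shoulder_id": sid,
                            "rater": rid,
                            "session": s + 1,
                            "method": method,
                            "version_deg": m.values[i, j, s],
                        }
                    )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_ratings(path) -> dict[str, RatingMatrix]:
    """Read a long ratings CSV into one complete RatingMatrix per method."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"ratings file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["shoulder_id", "rater", "session", "method", "version_deg"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    out: dict[str, RatingMatrix] = {}
    for method, sub in df.groupby("method", sort=True):
        subjects = list(dict.fromkeys(sub["shoulder_id"]))
        raters = sorted(set(sub["rater"]))
        sessions = sorted(set(sub["session"]))
        values = np.full((len(subjects), len(raters), len(sessions)), np.nan)
        sidx = {s: i for i, s in enumerate(subjects)}
        ridx = {r: j for j, r in enumerate(raters)}
        eidx = {e: s for s, e in enumerate(sessions)}
        for row in sub.itertuples():
            values[sidx[row.shoulder_id], ridx[row.rater], eidx[row.session]] = row.version_deg
        if np.isnan(values).any():
            n_missing = int(np.isnan(values).sum())
            raise InputError(
                f"{path}: method {method!r} has an incomplete design "
                f"({n_missing} missing subject × rater × session cells)"
            )
        out[str(method)] = RatingMatrix(
            values=values, subject_ids=[str(s) for s in subjects],
            rater_ids=[str(r) for r in raters],
        )
    if not out:
        raise InputError(f"{path}: no rating rows")
    return out
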