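"""Landmark file I/O.

Format: a CSV with header ``label,cx,cy,cz,ax,ay,az,lx,ly,lz,ux,uy,uz``
(centroid, anterior axis, left axis, up axis; mm, global frame), one row per
vertebra S1..T1, plus a JSON sidecar carrying ``patient_id``, ``posture`` and
optionally ``body_mass``.  The same content can live in a single JSON document
with a ``vertebrae`` list of records using the same field names.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import pandas as pd

from .geometry import SpineShape, VertebraPose

LANDMARK_COLUMNS = [
    "label",
    "cx", "cy", "cz",
    "ax", "ay", "az",
    "lx", "ly", "lz",
    "ux", "uy", "uz",
]


def spine_to_frame(spine: SpineShape) -> pd.DataFrame:
    rows = []
    for v in spine.vertebrae:
        rows.append([v.label, *v.centroid, *v.anterior, *v.left, *v.up])
    return pd.DataFrame(rows, columns=LANDMARK_COLUMNS)


def write_landmarks(spine: SpineShape, csv_path, sidecar_path=None) -> None:
    csv_path = Path(csv_path)
    spine_to_frame(spine).to_csv(csv_path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = {"patient_id": spine.patient_id, "posture": spine.posture}
    if spine.body_mass is not None:
        meta["body_mass"] = spine.body_mass
    sidecar.write_text(json.dumps(meta, indent=2))


def _frame_to_spine(df: pd.DataFrame, meta: dict) -> SpineShape:
    vertebrae = []
    for _, r in df.iterrows():
        vertebrae.append(
            VertebraPose(
                label=str(r["label"]),
                centroid=np.array([r["cx"], r["cy"], r["cz"]], dtype=float),
                anterior=np.array([r["ax"], r["ay"], r["az"]], dtype=float),
                left=np.array([r["lx"], r["ly"], r["lz"]], dtype=float),
                up=np.array([r["ux"], r["uy"], r["uz"]], dtype=float),
            )
        )
    return SpineShape(
        patient_id=str(meta.get("patient_id", "unknown")),
        posture=str(meta.get("posture", "reference")),
        vertebrae=tuple(vertebrae),
        body_mass=meta.get("body_mass"),
    )


def read_landmarks(path, sidecar_path=None) -> SpineShape:
    """Read a spine from a landmark CSV (+ JSON sidecar) or a JSON document."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        df = pd.DataFrame(doc["vertebrae"])[LANDMARK_COLUMNS]
        return _frame_to_spine(df, doc)
    df = pd.read_csv(path)
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
    meta: dict = {}
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return _frame_to_spine(df, meta)


def write_spine_json(spine: SpineShape, path) -> None:
    doc = {
        "patient_id": spine.patient_id,
        "posture": spine.posture,
        "body_mass": spine.body_mass,
        "vertebrae": spine_to_frame(spine).to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(doc, indent=2))
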