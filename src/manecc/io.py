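"""Text-format I/O for connectomes, parcel metadata, cohort and result tables.

All formats are plain delimited text (TSV by default, comma auto-detected).
Connectome files are dense numeric matrices with no header; parcel order is
owned by the ParcelTable, never by the matrix file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .datatypes import Connectome, VisitRecord
from .parcellation import ParcelTable

PathLike = Union[str, Path]

REQUIRED_VISIT_COLUMNS = ("subject_id", "visit", "age", "sex", "site", "motion")


def _detect_delimiter(path: PathLike) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") else "\t"


def read_connectome(path: PathLike, parcels: ParcelTable,
                    asym_tol: float = 1e-6) -> Connectome:
    """Read and validate a dense connectome matrix.

    The file must hold one row per parcel of the accompanying ParcelTable.
    Small asymmetries (<= asym_tol, relative to the largest weight) are
    repaired by averaging; anything larger is treated as corruption.
    """
    w = np.loadtxt(path, delimiter=_detect_delimiter(path), ndmin=2)
    n = parcels.n_parcels
    if w.shape != (n, n):
        raise ValueError(
            f"{path}: expected a {n}x{n} matrix, got {w.shape[0]}x{w.shape[1]}")
    if np.isnan(w).any():
        i, j = np.argwhere(np.isnan(w))[0]
        raise ValueError(f"{path}: NaN entry at ({i},{j})")
    if (w < 0).any():
        i, j = np.argwhere(w < 0)[0]
        raise ValueError(f"{path}: negative weight at ({i},{j})")
    scale = max(w.max(), 1.0)
    asym = np.abs(w - w.T).max()
    if asym > asym_tol * scale:
        i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
        raise ValueError(f"{path}: gross asymmetry at ({i},{j})")
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    conn = Connectome(weights=w, parcel_ids=parcels.table.parcel_id.to_numpy())
    conn.validate(atol=1e-8 * scale)
    return conn


def write_connectome(conn: Connectome, path: PathLike) -> None:
    np.savetxt(path, conn.weights, delimiter="\t", fmt="%.12g")


def read_visit_table(path: PathLike) -> list[VisitRecord]:
    """Parse a cohort visit table (TSV/CSV)."""
    df = pd.read_csv(path, sep=_detect_delimiter(path))
    missing = [c for c in REQUIRED_VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for _, row in df.iterrows():
        iq = row.get("iq")
        tanner = row.get("tanner")
        records.append(VisitRecord(
            subject_id=str(row.subject_id), visit=str(row.visit),
            age=float(row.age), sex=str(row.sex), site=str(row.site),
            motion=float(row.motion),
            iq=None if pd.isna(iq) else float(iq),
            tanner=None if pd.isna(tanner) else int(tanner)))
    counts = df.groupby("subject_id").size()
    odd = counts[counts != 2]
    if len(odd):
        import warnings
        warnings.warn(f"subjects without exactly 2 visits: {list(odd.index)}")
    return records


def write_visit_table(visits: list[VisitRecord], path: PathLike) -> None:
    from .datatypes import visits_to_frame
    visits_to_frame(visits).to_csv(path, sep="\t", index=False)


def write_parcel_table(parcels: ParcelTable, path: PathLike) -> None:
    t = parcels.table.copy()
    t["neighbors"] = [
        ",".join(map(str, parcels.neighbors.get(pid, [])))
        for pid in t.parcel_id
    ]
    t.to_csv(path, sep="\t", index=False)


def read_parcel_table(path: PathLike) -> ParcelTable:
    t = pd.read_csv(path, sep=_detect_delimiter(path))
    neighbors = {}
    if "neighbors" in t.columns:
        for pid, cell in zip(t.parcel_id, t.neighbors):
            if isinstance(cell, str) and cell:
                neighbors[int(pid)] = [int(x) for x in cell.split(",")]
            elif not pd.isna(cell) and cell != "":
                neighbors[int(pid)] = [int(cell)]
        t = t.drop(columns=["neighbors"])
    pt = ParcelTable(table=t, neighbors=neighbors)
    pt.validate()
    return pt


RESULT_COLUMNS = ("feature_id", "beta_age", "t", "p", "q", "significant")


def write_result_table(results: pd.DataFrame, path: PathLike) -> None:
    """Write a per-feature statistics table (LME, graph, or prediction rows)."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.15g")


def read_result_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep=_detect_delimiter(path))


def load_config(path: PathLike) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_config(config: dict, path: PathLike) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(config, indent=2, default=str))
    else:
        p.write_text(yaml.safe_dump(config, sort_keys=False))
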