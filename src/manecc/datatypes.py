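"""Core data containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class Connectome:
    """Symmetric nonnegative parcel x parcel weight matrix.

    ``weights[i, j]`` is the streamline cross-section strength between parcels
    ``parcel_ids[i]`` and ``parcel_ids[j]`` (or its log(1+w) transform when
    ``log_transformed`` is set).
    """

    weights: np.ndarray
    parcel_ids: np.ndarray
    log_transformed: bool = False

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectome must be square, got shape {w.shape}")
        if len(self.parcel_ids) != w.shape[0]:
            raise ValueError("parcel_ids length does not match matrix size")
        if np.isnan(w).any():
            i, j = np.argwhere(np.isnan(w))[0]
            raise ValueError(f"NaN weight at ({i},{j})")
        if (w < 0).any():
            i, j = np.argwhere(w < 0)[0]
            raise ValueError(f"negative weight at ({i},{j})")
        if np.abs(w - w.T).max() > atol:
            i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
            raise ValueError(f"asymmetric weights at ({i},{j})")
        if np.abs(np.diag(w)).max() > atol:
            raise ValueError("diagonal must be zero")


@dataclass
class VisitRecord:
    """One longitudinal phenotype row (one scan of one subject)."""

    subject_id: str
    visit: str  # "baseline" | "followup"
    age: float  # years
    sex: str  # "M" | "F"
    site: str
    motion: float  # framewise-displacement-like nuisance, mm
    iq: Optional[float] = None
    tanner: Optional[int] = None  # pubertal stage 1-5, baseline only


def visits_to_frame(visits: list[VisitRecord]) -> pd.DataFrame:
    """Tabulate visit records (one row per record, stable column order)."""
    return pd.DataFrame(
        [
            dict(subject_id=v.subject_id, visit=v.visit, age=v.age, sex=v.sex,
                 site=v.site, motion=v.motion, iq=v.iq, tanner=v.tanner)
            for v in visits
        ]
    )
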