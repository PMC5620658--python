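"""Labeled dataset container and its CSV dialect.

Feature CSV: header ``f1..fd,label``, one vector per row, comma-separated,
'.' decimal; the label column holds 1 (patient) or 0 (health) and may be
absent for unlabeled query sets.  Generator provenance travels in a JSON
sidecar (``<name>.meta.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["LabeledDataset"]

PATIENT, HEALTH = 1, 0


@dataclass
class LabeledDataset:
    """Feature vectors with binary labels (1 = patient, 0 = health)."""

    X: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise InputError(f"|X|={self.X.shape[0]} != |y|={self.y.shape[0]}")
        if self.y.size and not np.isin(self.y, (0, 1)).all():
            raise InputError("labels must be binary {0, 1}")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def patient_X(self) -> np.ndarray:
        return self.X[self.y == PATIENT]

    @property
    def health_X(self) -> np.ndarray:
        return self.X[self.y == HEALTH]

    @property
    def n_patient(self) -> int:
        return int((self.y == PATIENT).sum())

    @property
    def n_health(self) -> int:
        return int((self.y == HEALTH).sum())

    def to_frame(self) -> pd.DataFrame:
        d = self.X.shape[1]
        df = pd.DataFrame(self.X, columns=[f"f{i + 1}" for i in range(d)])
        df["label"] = self.y
        return df

    def to_csv(self, path, write_meta: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if write_meta and self.meta:
            meta_path = path.with_suffix(".meta.json")
            meta_path.write_text(json.dumps(_jsonable(self.meta), indent=2))

    @classmethod
    def from_csv(cls, path) -> "LabeledDataset":
        path = Path(path)
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise InputError(f"{path}: no 'label' column; use pandas directly for query sets")
        y = df.pop("label").to_numpy()
        meta_path = path.with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(X=df.to_numpy(dtype=float), y=y, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
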