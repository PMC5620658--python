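"""Beat-curve featurization: resample to 50 voltages, rescale to [0, 1].

Each instance contributes a fixed number of heartbeats (default five); each
beat becomes a 50-dimensional vector of voltages linearly resampled along
the curve and min-max rescaled per beat.  Classification downstream is per
beat vector.  Beat detection / segmentation from continuous recordings is
out of scope — inputs are already-cut beat curves, one per row.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["resample_beat", "rescale_beat", "beats_to_instances", "BEAT_DIM"]

BEAT_DIM = 50


def resample_beat(curve, n_out: int = BEAT_DIM) -> np.ndarray:
    """Linear interpolation of a beat curve onto n_out equally spaced points
    spanning the full curve (endpoints preserved)."""
    curve = np.asarray(curve, dtype=float).ravel()
    if curve.shape[0] < 2:
        raise InputError(f"beat curve needs >= 2 samples, got {curve.shape[0]}")
    pos = np.linspace(0.0, curve.shape[0] - 1.0, n_out)
    return np.interp(pos, np.arange(curve.shape[0]), curve)


def rescale_beat(v) -> np.ndarray:
    """Per-beat min-max rescale to [0, 1]; a constant beat maps to zeros."""
    v = np.asarray(v, dtype=float).ravel()
    if v.shape[0] < 1:
        raise InputError("empty beat")
    lo, hi = v.min(), v.max()
    if hi - lo <= 0:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def beats_to_instances(beat_table: pd.DataFrame, beats_per_instance: int = 5,
                       n_points: int = BEAT_DIM, selection: str = "first",
                       seed: int | None = None) -> pd.DataFrame:
    """Group raw beats by instance and emit 50-dim feature vectors.

    ``beat_table`` columns: ``instance_id``, optional ``label``, then the raw
    voltage samples ``v1..vM``.  Per instance, ``beats_per_instance`` beats
    are kept (``selection="first"`` by default, ``"random"`` with a seed),
    each resampled to ``n_points`` and min-max rescaled.  Instances with too
    few beats are skipped with a warning.

    Returns a DataFrame with columns ``instance_id``, ``label`` (if present)
    and ``f1..f{n_points}``, one row per beat vector.
    """
    if "instance_id" not in beat_table.columns:
        raise InputError("beat table must have an 'instance_id' column")
    if selection not in ("first", "random"):
        raise InputError(f"unknown selection rule {selection!r}")
    rng = np.random.default_rng(seed)
    has_label = "label" in beat_table.columns
    vcols = [c for c in beat_table.columns if c not in ("instance_id", "label")]
    rows = []
    for iid, grp in beat_table.groupby("instance_id", sort=True):
        if len(grp) < beats_per_instance:
            warnings.warn(
                f"instance {iid!r}: {len(grp)} beats < {beats_per_instance}; skipped",
                stacklevel=2,
            )
            continue
        if selection == "first":
            sel = grp.iloc[:beats_per_instance]
        else:
            sel = grp.iloc[rng.choice(len(grp), beats_per_instance, replace=False)]
        for _, row in sel.iterrows():
            vec = rescale_beat(resample_beat(row[vcols].to_numpy(dtype=float), n_points))
            rec = {"instance_id": iid}
            if has_label:
                rec["label"] = int(row["label"])
            rec.update({f"f{i + 1}": vec[i] for i in range(n_points)})
            rows.append(rec)
    return pd.DataFrame(rows)
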