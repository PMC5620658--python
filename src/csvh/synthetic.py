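"""Seeded generators for the statistical structures the classifier targets.

All generators are pure functions of their parameters and seed.  They
emulate, in order: the two planar benchmark layouts (exclusive-OR quadrant
clusters and two crossing lines), a two-blob scene with a diverse patient
class containing planted far outliers and class-overlap points next to a
compact health class, and multi-beat ECG-like instances whose patient class
differs in P-wave morphology (the electrocardiographic signature of atrial
hypertrophy).

Quantitative defaults (cluster positions, spreads, effect sizes) are this
package's own choices, recorded in each dataset's ``meta``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .errors import InputError

__all__ = [
    "make_xor",
    "make_crossing_lines",
    "make_blobs_with_outliers",
    "make_synthetic_beats",
]


def make_xor(n_per_quadrant: int = 25, spread: float = 0.3, seed: int = 0) -> LabeledDataset:
    """Four isotropic Gaussian clusters at (+-1, +-1), XOR-labeled.

    The patient class (label 1) occupies the (+,+) and (-,-) quadrants, so
    neither class is linearly separable nor unimodal.
    """
    if n_per_quadrant < 1:
        raise InputError("n_per_quadrant must be >= 1")
    if spread < 0:
        raise InputError("spread must be >= 0")
    rng = np.random.default_rng(seed)
    centers = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
    labels = np.array([1, 1, 0, 0])
    X = np.vstack([c + spread * rng.standard_normal((n_per_quadrant, 2)) for c in centers])
    y = np.repeat(labels, n_per_quadrant)
    meta = {"generator": "xor", "seed": seed, "n_per_quadrant": n_per_quadrant,
            "spread": spread, "patient_quadrants": "(+,+) and (-,-)"}
    return LabeledDataset(X=X, y=y, meta=meta)


def make_crossing_lines(n_per_line: int = 150, noise: float = 0.03,
                        angle: float = np.pi / 2, seed: int = 0) -> LabeledDataset:
    """Two line segments crossing at the origin, one class per line.

    Lines run through the origin at +-angle/2 around the x-axis, positions
    uniform along [-1, 1], with Gaussian perpendicular noise.  The patient
    class (label 1) is the +angle/2 line.
    """
    if n_per_line < 1:
        raise InputError("n_per_line must be >= 1")
    rng = np.random.default_rng(seed)
    rows, ys = [], []
    for lab, a in ((1, angle / 2.0), (0, -angle / 2.0)):
        t = rng.uniform(-1.0, 1.0, size=n_per_line)
        u = np.array([np.cos(a), np.sin(a)])         # along-line direction
        v = np.array([-np.sin(a), np.cos(a)])        # perpendicular
        pts = t[:, None] * u + (noise * rng.standard_normal(n_per_line))[:, None] * v
        rows.append(pts)
        ys.append(np.full(n_per_line, lab))
    meta = {"generator": "crossing_lines", "seed": seed, "n_per_line": n_per_line,
            "noise": noise, "angle": angle, "patient_line": "+angle/2"}
    return LabeledDataset(X=np.vstack(rows), y=np.concatenate(ys), meta=meta)


def make_blobs_with_outliers(n_p: int = 80, n_h: int = 80, separation: float = 6.0,
                             outlier_frac: float = 0.025, overlap_frac: float = 0.025,
                             patient_lobes: int = 1, seed: int = 0) -> LabeledDataset:
    """Diverse patient blob vs. compact health blob, with planted anomalies.

    Patient: unit-sd Gaussian at the origin, of which ``outlier_frac`` are
    replaced by far outliers and ``overlap_frac`` by draws from the health
    blob region (class-overlap points).  Health: sd-0.5 Gaussian at
    (separation, 0).

    The far outliers emulate non-classical patient records, which in this
    problem resemble healthy subjects rather than drifting into empty
    feature space: they are placed dispersed around the health cloud
    (stratified angles over the arc facing away from the patient blob,
    radius 6-8 health sd from the health center) and are pushed radially,
    if needed, to at least 5 patient sd from the patient-blob center.
    Being individually atypical, they are mutually distant by construction.
    Planted indices are recorded in ``meta``.

    ``patient_lobes > 1`` draws the patient core from a mixture of unit-sd
    lobes at radius 2.5 around the origin (angles on the arc facing away
    from the health class), emulating a genuinely diverse, multi-modal
    patient population that small training samples cannot cover.
    """
    if not (0 <= outlier_frac < 1 and 0 <= overlap_frac < 1):
        raise InputError("fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sd_p, sd_h = 1.0, 0.5
    center_h = np.array([separation, 0.0])
    n_out = int(round(outlier_frac * n_p))
    n_ov = int(round(overlap_frac * n_p))
    n_core = n_p - n_out - n_ov
    if n_core < 0:
        raise InputError("outlier_frac + overlap_frac leave no core patient points")
    if patient_lobes < 1:
        raise InputError("patient_lobes must be >= 1")
    if patient_lobes == 1:
        lobe_centers = np.zeros((1, 2))
    else:
        lobe_ang = np.pi / 2.0 + np.pi * np.arange(patient_lobes) / (patient_lobes - 1)
        lobe_centers = 2.5 * np.column_stack([np.cos(lobe_ang), np.sin(lobe_ang)])
    assign = rng.integers(0, patient_lobes, size=n_core)
    core = lobe_centers[assign] + sd_p * rng.standard_normal((n_core, 2))
    # dispersed ring around the health cloud, off the patient-facing arc
    excl = np.pi / 2.0
    frac = (np.arange(n_out) + rng.uniform(0.1, 0.9, size=n_out)) / max(n_out, 1)
    theta = np.pi + excl + (2.0 * np.pi - 2.0 * excl) * frac  # relative to patient direction
    radius = rng.uniform(6.0, 8.0, size=n_out) * sd_h
    outliers = center_h + radius[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
    norms = np.linalg.norm(outliers, axis=1)
    push = np.maximum(1.0, 5.0 * sd_p / np.maximum(norms, 1e-12))
    outliers *= push[:, None]
    overlap = center_h + sd_h * rng.standard_normal((n_ov, 2))
    Xp = np.vstack([core, outliers, overlap])
    Xh = center_h + sd_h * rng.standard_normal((n_h, 2))
    X = np.vstack([Xp, Xh])
    y = np.concatenate([np.ones(n_p, int), np.zeros(n_h, int)])
    meta = {
        "generator": "blobs_with_outliers", "seed": seed,
        "n_p": n_p, "n_h": n_h, "separation": separation,
        "sd_patient": sd_p, "sd_health": sd_h,
        "outlier_frac": outlier_frac, "overlap_frac": overlap_frac,
        "patient_lobes": patient_lobes,
        "outlier_indices": list(range(n_core, n_core + n_out)),
        "overlap_indices": list(range(n_core + n_out, n_p)),
    }
    return LabeledDataset(X=X, y=y, meta=meta)


# -- ECG-like beats ---------------------------------------------------------

def _bump(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def _beat_curve(t: np.ndarray, rng: np.random.Generator, p_amp: float,
                p_width: float, noise: float) -> np.ndarray:
    """One synthetic beat: P / QRS / T as Gaussian bumps with per-beat jitter.

    Atrial hypertrophy manifests as increased P-wave amplitude and duration,
    so those two parameters carry the class difference.
    """
    jit = lambda v, s: v * (1.0 + s * rng.standard_normal())
    curve = (
        _bump(t, jit(0.15, 0.03), jit(p_width, 0.08), jit(p_amp, 0.10))   # P
        + _bump(t, 0.37, 0.012, jit(-0.12, 0.10))                          # Q
        + _bump(t, jit(0.40, 0.01), jit(0.015, 0.08), jit(1.00, 0.05))     # R
        + _bump(t, 0.43, 0.012, jit(-0.18, 0.10))                          # S
        + _bump(t, jit(0.65, 0.02), jit(0.05, 0.08), jit(0.30, 0.10))      # T
    )
    return curve + noise * rng.standard_normal(t.shape[0])


def make_synthetic_beats(n_patient_instances: int = 20, n_health_instances: int = 20,
                         beats_per_instance: int = 5, samples_per_beat: int = 100,
                         atypical_frac: float = 0.1, noise: float = 0.01,
                         seed: int = 0) -> pd.DataFrame:
    """Raw multi-beat ECG-like instances as a long-format table.

    Returns a DataFrame with columns ``instance_id, label, v1..vM`` holding
    ``beats_per_instance`` raw beat curves per instance.  Patient beats have
    a taller, broader P bump (amp 0.30, width 0.05 vs. 0.15 / 0.03); an
    ``atypical_frac`` of beats swap class morphology, emulating records
    without classical symptoms.
    """
    if min(n_patient_instances, n_health_instances, beats_per_instance) < 1:
        raise InputError("instance and beat counts must be >= 1")
    if samples_per_beat < 50:
        raise InputError("samples_per_beat must be >= 50")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, samples_per_beat, endpoint=False)
    params = {1: (0.30, 0.05), 0: (0.15, 0.03)}  # (P amplitude, P width)
    rows = []
    iid = 0
    for label, n_inst in ((1, n_patient_instances), (0, n_health_instances)):
        for _ in range(n_inst):
            for _b in range(beats_per_instance):
                p_amp, p_width = params[label]
                if rng.random() < atypical_frac:
                    p_amp, p_width = params[1 - label]  # non-classical beat
                curve = _beat_curve(t, rng, p_amp, p_width, noise)
                rows.append([iid, label, *curve])
            iid += 1
    cols = ["instance_id", "label"] + [f"v{i + 1}" for i in range(samples_per_beat)]
    df = pd.DataFrame(rows, columns=cols)
    df["instance_id"] = df["instance_id"].astype(int)
    df["label"] = df["label"].astype(int)
    return df
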