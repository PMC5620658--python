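"""Two-phase characterized-hypersphere classifier.

Training fits a weighted enclosing hypersphere to the patient class (per-
sample penalties down-weight suspected outliers / overlap points, which end
up in the outlier set OsetP) and a maximally separated hypersphere to the
health class in coordinates shifted so the patient center is the origin
(its bounded points form OsetH).

Labeling computes bounded memberships

    G_p(Q) = exp(-||phi(Q) - a||^2 / (R^2 + P^2))
    G_h(Q) = exp(-||phi(Q) - b||^2 / (Z^2 + H^2))

where P^2 / H^2 are the mean squared distances of the respective outlier
sets to their centers (0 when the set is empty).  A query whose memberships
differ by more than eps_Q = epsilon_fraction * max(G_p, G_h) is labeled by
the larger membership; otherwise it is handed to the tie-break, which
assigns the class of the most analogous outlier-set member (largest
feature-space cosine with the query).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from .errors import ConfigError, DegenerateModelError, InputError, ModelIOError
from .hypersphere import (
    HealthHypersphere,
    PatientHypersphere,
    PenaltyWeights,
    fit_health_hypersphere,
    fit_patient_hypersphere,
)
from .kernels import KernelSpec, ShiftedKernelRef, gram_matrix, shifted_gram, shifted_diag

__all__ = ["CSVHConfig", "CSVHModel", "Prediction", "fit",
           "save_model", "load_model", "median_width"]

_SCHEMA_VERSION = 1

PATIENT, HEALTH = 1, 0


def median_width(X) -> float:
    """Median pairwise Euclidean distance — default Gaussian width heuristic."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(X)))
    return med if med > 0 else 1.0


@dataclass(frozen=True)
class CSVHConfig:
    """Hyperparameters of the classifier.

    width: Gaussian kernel scale; None selects the median pairwise-distance
        heuristic on the pooled training data.  In the reference protocol it
        is tuned by 10-fold cross-validation (see evaluation.grid_search_cv).
    health_c: uniform slack penalty of the health-class dual; None (default)
        applies the size-adaptive rule C = 1/(0.3 N_h), bounding roughly 30%
        of the health class as support so the geometry does not degenerate
        with class size.
    k_nn: neighborhood size of the overlap penalty C2.
    epsilon_fraction: the rejection band, eps_Q = fraction * max(G_p, G_h).
    tiebreak_mode: "cosine_normalized" (default) normalizes shifted-kernel
        similarities to true cosines; "raw" ranks raw k / k'.
    eta_mode: "literal" or "pairwise" computation of the balance coefficient.
    """

    width: float | None = None
    health_c: float | None = None
    k_nn: int = 5
    epsilon_fraction: float = 0.10
    tiebreak_mode: str = "cosine_normalized"
    eta_mode: str = "pairwise"

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon_fraction < 1.0):
            raise ConfigError(f"epsilon_fraction must be in (0,1), got {self.epsilon_fraction}")
        if self.tiebreak_mode not in ("cosine_normalized", "raw"):
            raise ConfigError(f"unknown tiebreak_mode {self.tiebreak_mode!r}")
        if self.eta_mode not in ("literal", "pairwise"):
            raise ConfigError(f"unknown eta_mode {self.eta_mode!r}")


@dataclass
class Prediction:
    """Outcome for one query: label (1=patient, 0=health), the two
    memberships, the rejection threshold, which decision path fired, and —
    on the tie-break path — the identity of the most analogous point."""

    label: int
    g_p: float
    g_h: float
    epsilon_q: float
    path: str  # "confident" | "tiebreak"
    qa_index: tuple[str, int] | None = None


@dataclass
class CSVHModel:
    """Both fitted hyperspheres plus decision configuration."""

    patient: PatientHypersphere
    health: HealthHypersphere
    kernel: KernelSpec
    config: CSVHConfig

    # -- memberships -------------------------------------------------------
    def membership_patient(self, Q) -> np.ndarray:
        denom = self.patient.r_squared + self.patient.p_squared
        if denom <= 0:
            raise DegenerateModelError("patient sphere has zero radius and empty outlier set")
        return np.exp(-self.patient.distance_sq(Q) / denom)

    def membership_health(self, Q) -> np.ndarray:
        denom = self.health.z_squared + self.health.h_squared
        if denom <= 0:
            raise DegenerateModelError("health sphere has zero radius and empty outlier set")
        return np.exp(-self.health.distance_sq(Q) / denom)

    # -- tie-break ---------------------------------------------------------
    def most_analogous(self, q) -> tuple[tuple[str, int], float]:
        """Most analogous outlier-set member of a single query.

        Similarity is the feature-space cosine of the angle to the query:
        for OsetP members the plain kernel k(Q, x) (unit diagonals make it a
        cosine already); for OsetH members the shifted kernel, normalized by
        sqrt(k'(Q,Q) k'(x,x)) in cosine mode or taken raw in literal mode.
        Ties prefer the patient class, then the lowest training index.
        """
        q = np.atleast_2d(np.asarray(q, dtype=float))
        cands: list[tuple[float, int, str, int]] = []  # (sim, class_rank, class, index)
        oset_p, oset_h = self.patient.oset_p, self.health.oset_h
        if oset_p.size:
            sims = gram_matrix(q, self.patient.X[oset_p], self.kernel)[0]
            for s, idx in zip(sims, oset_p):
                cands.append((float(s), 0, "patient", int(idx)))
        if oset_h.size:
            ref = self.health.shifted_ref
            sims = shifted_gram(q, self.health.X[oset_h], ref)[0]
            if self.config.tiebreak_mode == "cosine_normalized":
                qq = float(shifted_diag(q, ref)[0])
                xx = shifted_diag(self.health.X[oset_h], ref)
                for s, idx, x2 in zip(sims, oset_h, xx):
                    if qq <= 1e-12 or x2 <= 1e-12:
                        continue  # coincident with the patient center: no angle
                    cands.append((float(s) / float(np.sqrt(qq * x2)), 1, "health", int(idx)))
            else:
                for s, idx in zip(sims, oset_h):
                    cands.append((float(s), 1, "health", int(idx)))
        if not cands:
            raise DegenerateModelError("both outlier sets are empty")
        best = min(cands, key=lambda t: (-t[0], t[1], t[3]))
        return (best[2], best[3]), best[0]

    # -- decision ----------------------------------------------------------
    def decide(self, q) -> Prediction:
        g_p = float(self.membership_patient(q)[0])
        g_h = float(self.membership_health(q)[0])
        eps = self.config.epsilon_fraction * max(g_p, g_h)
        if abs(g_h - g_p) > eps:
            label = PATIENT if g_p > g_h else HEALTH
            return Prediction(label, g_p, g_h, eps, "confident")
        try:
            (cls, idx), _sim = self.most_analogous(q)
        except DegenerateModelError:
            label = PATIENT if g_p >= g_h else HEALTH
            return Prediction(label, g_p, g_h, eps, "tiebreak", None)
        label = PATIENT if cls == "patient" else HEALTH
        return Prediction(label, g_p, g_h, eps, "tiebreak", (cls, idx))

    def predict(self, X) -> np.ndarray:
        """Labels for each row of X (1 = patient, 0 = health)."""
        return np.array([p.label for p in self.predict_detail(X)], dtype=int)

    def predict_detail(self, X) -> list[Prediction]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        gp = self.membership_patient(X)
        gh = self.membership_health(X)
        eps = self.config.epsilon_fraction * np.maximum(gp, gh)
        out: list[Prediction] = []
        for i in range(X.shape[0]):
            if abs(gh[i] - gp[i]) > eps[i]:
                label = PATIENT if gp[i] > gh[i] else HEALTH
                out.append(Prediction(label, float(gp[i]), float(gh[i]),
                                      float(eps[i]), "confident"))
            else:
                out.append(self.decide(X[i]))
        return out


def fit(patient_X, health_X, config: CSVHConfig | None = None) -> CSVHModel:
    """Fit both hyperspheres.

    Steps: per-sample penalties -> weighted patient dual -> shift the kernel
    to the patient center -> balance coefficient eta -> furthest health dual
    -> radii and outlier sets.
    """
    config = config or CSVHConfig()
    Xp = np.atleast_2d(np.asarray(patient_X, dtype=float))
    Xh = np.atleast_2d(np.asarray(health_X, dtype=float))
    if Xp.shape[0] < 2:
        raise InputError(f"need at least 2 patient vectors, got {Xp.shape[0]}")
    if Xh.shape[0] < 1:
        raise InputError("need at least 1 health vector")
    if Xp.shape[1] != Xh.shape[1]:
        raise InputError(f"dimension mismatch: patient {Xp.shape[1]} vs health {Xh.shape[1]}")
    width = config.width if config.width is not None else median_width(np.vstack([Xp, Xh]))
    spec = KernelSpec(width=width)
    patient = fit_patient_hypersphere(Xp, Xh, spec, k_nn=config.k_nn)
    ref = ShiftedKernelRef(kernel=spec, anchor_points=Xp, anchor_weights=patient.beta)
    health_c = config.health_c if config.health_c is not None else 1.0 / (0.3 * Xh.shape[0])
    health = fit_health_hypersphere(Xh, ref, penalty_c=health_c,
                                    eta_mode=config.eta_mode)
    return CSVHModel(patient=patient, health=health, kernel=spec, config=config)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: CSVHModel, path) -> None:
    """Write a fitted model to versioned JSON (training vectors included —
    kernel models need them at prediction time)."""
    p = model.patient
    h = model.health
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "kernel_width": model.kernel.width,
        "config": asdict(model.config),
        "patient": {
            "X": p.X.tolist(),
            "beta": p.beta.tolist(),
            "c1": p.penalties.c1.tolist(),
            "c2": p.penalties.c2.tolist(),
            "c": p.penalties.c.tolist(),
            "k_nn": p.penalties.neighborhood_size,
            "center_norm_sq": p.center_norm_sq,
            "r_squared": p.r_squared,
            "oset_p": p.oset_p.tolist(),
            "p_squared": p.p_squared,
            "train_dist_sq": p.train_dist_sq.tolist(),
        },
        "health": {
            "X": h.X.tolist(),
            "gamma": h.gamma.tolist(),
            "eta": h.eta,
            "penalty_c": h.penalty_c,
            "z_squared": h.z_squared,
            "b_norm_squared": h.b_norm_squared,
            "oset_h": h.oset_h.tolist(),
            "h_squared": h.h_squared,
            "train_dist_sq": h.train_dist_sq.tolist(),
        },
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> CSVHModel:
    """Load a model saved by :func:`save_model`."""
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise ModelIOError(f"cannot parse model file {path}: {e}") from e
    if not isinstance(doc, dict) or doc.get("schema_version") != _SCHEMA_VERSION:
        raise ModelIOError(
            f"unsupported model schema {doc.get('schema_version')!r} in {path}"
        )
    try:
        spec = KernelSpec(width=float(doc["kernel_width"]))
        cfg_raw = dict(doc["config"])
        config = CSVHConfig(**cfg_raw)
        pd_ = doc["patient"]
        pw = PenaltyWeights(c1=np.array(pd_["c1"]), c2=np.array(pd_["c2"]),
                            c=np.array(pd_["c"]), neighborhood_size=int(pd_["k_nn"]))
        patient = PatientHypersphere(
            X=np.array(pd_["X"], dtype=float), kernel=spec,
            beta=np.array(pd_["beta"], dtype=float), penalties=pw,
            center_norm_sq=float(pd_["center_norm_sq"]),
            r_squared=float(pd_["r_squared"]),
            oset_p=np.array(pd_["oset_p"], dtype=int),
            p_squared=float(pd_["p_squared"]),
            train_dist_sq=np.array(pd_["train_dist_sq"], dtype=float),
        )
        hd = doc["health"]
        ref = ShiftedKernelRef(kernel=spec, anchor_points=patient.X,
                               anchor_weights=patient.beta)
        health = HealthHypersphere(
            X=np.array(hd["X"], dtype=float), shifted_ref=ref,
            gamma=np.array(hd["gamma"], dtype=float), eta=float(hd["eta"]),
            penalty_c=float(hd["penalty_c"]), z_squared=float(hd["z_squared"]),
            b_norm_squared=float(hd["b_norm_squared"]),
            oset_h=np.array(hd["oset_h"], dtype=int),
            h_squared=float(hd["h_squared"]),
            train_dist_sq=np.array(hd["train_dist_sq"], dtype=float),
        )
    except (KeyError, TypeError, ValueError) as e:
        raise ModelIOError(f"corrupt model file {path}: {e}") from e
    return CSVHModel(patient=patient, health=health, kernel=spec, config=config)
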