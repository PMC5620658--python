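"""Hypersphere duals: penalty weighting, QP solvers, radii and outlier sets.

Two convex quadratic programs are solved here, both of the form

    min  x' Q x - d' x   s.t.  0 <= x_i <= C_i,  sum_i x_i = 1.

*Patient (weighted) hypersphere*: Q is the Gaussian Gram matrix of the
patient class, d its diagonal, and the box bounds C_i are per-sample penalty
weights that let suspected outliers / overlap points fall outside cheaply.

*Health (furthest) hypersphere*: Q is the shifted-kernel Gram matrix divided
by (1 - eta), d its diagonal, and C is uniform.  The balance coefficient
eta trades sphere volume against distance of the center from the (mapped)
patient center, and is set adaptively from the mean pairwise shifted-kernel
dissimilarity.

Both are solved with a deterministic most-violating-pair SMO scheme judged
by its KKT residual (<= 1e-6 on every fitted model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, DegenerateModelError, SolverError
from .kernels import (
    KernelSpec,
    ShiftedKernelRef,
    gram_matrix,
    shifted_gram,
)

__all__ = [
    "PenaltyWeights",
    "PatientHypersphere",
    "HealthHypersphere",
    "penalty_c1",
    "penalty_c2",
    "penalty_weights",
    "solve_weighted_svdd",
    "solve_furthest_hypersphere",
    "distance_sq_to_center",
    "patient_radius",
    "extract_oset",
    "compute_eta",
    "health_geometry",
    "fit_patient_hypersphere",
    "fit_health_hypersphere",
    "kkt_report",
    "support_tau",
]

#: relative tolerance used to classify multipliers as at-bound / free.
TAU_REL = 1e-7


def support_tau(upper: np.ndarray) -> float:
    """Absolute at-bound tolerance: 1e-7 relative to the largest box bound."""
    return TAU_REL * max(1.0, float(np.max(upper)))


# ---------------------------------------------------------------------------
# penalty weighting (patient class)
# ---------------------------------------------------------------------------

@dataclass
class PenaltyWeights:
    """Per-sample slack penalties for the weighted patient hypersphere.

    c1 reflects isolation (kernel similarity to the nearest same-class
    neighbor, in (e^-2, 1]); c2 reflects class overlap (ratio of other-class
    to own-class points among the k_nn nearest neighbors, in (0, 1]); c is
    their elementwise average.
    """

    c1: np.ndarray
    c2: np.ndarray
    c: np.ndarray
    neighborhood_size: int


def penalty_c1(patient_X, spec: KernelSpec) -> np.ndarray:
    """Isolation penalty C1_i = exp(2 k(x_i, x_inear) - 2).

    x_inear is the kernel-space nearest neighbor of x_i within the patient
    class; for a Gaussian kernel this coincides with the Euclidean nearest
    neighbor.  Isolated points (k -> 0) approach the lower bound e^-2.
    """
    X = np.asarray(patient_X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ConfigError("penalty_c1 needs at least two patient points (no neighbor exists)")
    K = gram_matrix(X, X, spec)
    np.fill_diagonal(K, -np.inf)
    k_near = K.max(axis=1)
    return np.exp(2.0 * k_near - 2.0)


def penalty_c2(patient_X, health_X, k_nn: int, spec: KernelSpec) -> np.ndarray:
    """Overlap penalty C2_i = exp(-|OTHER_i| / max(|OWN_i|, 1)).

    The k_nn nearest neighbors of each patient point are taken among *all*
    other training points of both classes (kernel-space distance, i.e.
    Euclidean order for a Gaussian kernel); OWN_i counts patient-class
    neighbors, OTHER_i health-class neighbors.  The max(., 1) guard keeps the
    ratio defined when no own-class point makes the neighborhood.
    """
    Xp = np.asarray(patient_X, dtype=float)
    Xh = np.asarray(health_X, dtype=float)
    if k_nn < 1:
        raise ConfigError(f"k_nn must be >= 1, got {k_nn}")
    n_all = Xp.shape[0] + Xh.shape[0]
    if n_all <= k_nn:
        raise ConfigError(f"need more than k_nn={k_nn} training points, have {n_all}")
    allX = np.vstack([Xp, Xh]) if Xh.size else Xp
    d = cdist(Xp, allX, metric="sqeuclidean")
    rows = np.arange(Xp.shape[0])
    d[rows, rows] = np.inf  # exclude self
    nn = np.argpartition(d, k_nn - 1, axis=1)[:, :k_nn]
    own = (nn < Xp.shape[0]).sum(axis=1)
    other = k_nn - own
    return np.exp(-other / np.maximum(own, 1))


def penalty_weights(patient_X, health_X, k_nn: int, spec: KernelSpec) -> PenaltyWeights:
    """Combined penalty C_i = (C1_i + C2_i) / 2, all in (0, 1]."""
    c1 = penalty_c1(patient_X, spec)
    c2 = penalty_c2(patient_X, health_X, k_nn, spec)
    return PenaltyWeights(c1=c1, c2=c2, c=0.5 * (c1 + c2), neighborhood_size=k_nn)


# ---------------------------------------------------------------------------
# QP solver (shared by both duals)
# ---------------------------------------------------------------------------

def _solve_simplex_box_qp(Q: np.ndarray, d: np.ndarray, upper: np.ndarray,
                          tol: float = 1e-9, max_iter: int = 1_000_000) -> np.ndarray:
    """min x'Qx - d'x  s.t.  sum x = 1,  0 <= x <= upper.

    Most-violating-pair SMO: at each step mass moves between the coordinate
    with the smallest gradient that can still grow and the one with the
    largest gradient that can still shrink.  Deterministic given inputs.
    """
    Q = np.asarray(Q, dtype=float)
    d = np.asarray(d, dtype=float).ravel()
    upper = np.asarray(upper, dtype=float).ravel()
    n = d.shape[0]
    total = float(upper.sum())
    if total < 1.0:
        raise ConfigError(f"infeasible box: sum of upper bounds {total} < 1")
    x = upper / total  # feasible start: sum 1, within box
    g = 2.0 * (Q @ x) - d
    eps = 1e-12
    for it in range(max_iter):
        can_up = x < upper - eps
        can_dn = x > eps
        gi = np.where(can_up, g, np.inf)
        gj = np.where(can_dn, g, -np.inf)
        i = int(np.argmin(gi))
        j = int(np.argmax(gj))
        gap = g[j] - g[i]
        if gap <= tol:
            break
        a = Q[i, i] + Q[j, j] - 2.0 * Q[i, j]
        t_max = min(upper[i] - x[i], x[j])
        t = t_max if a <= 1e-15 else min(t_max, gap / (2.0 * a))
        if t <= 0.0:
            break
        x[i] += t
        x[j] -= t
        g += (2.0 * t) * (Q[:, i] - Q[:, j])
        if (it + 1) % 2000 == 0:  # control float drift on long runs
            np.clip(x, 0.0, upper, out=x)
            x /= x.sum()
            g = 2.0 * (Q @ x) - d
    else:
        raise SolverError(f"SMO did not converge in {max_iter} iterations (gap {gap:.3e})")
    np.clip(x, 0.0, upper, out=x)
    x /= x.sum()
    return x


def solve_weighted_svdd(K: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the weighted patient dual: min b'Kb - b'diag(K), 0<=b<=C, sum b=1.

    If the per-sample caps sum to less than 1 the simplex constraint is
    infeasible; the caps are then minimally rescaled (warned).
    Returns (beta, minimized objective).
    """
    K = np.asarray(K, dtype=float)
    c = np.asarray(c, dtype=float).ravel().copy()
    if float(c.sum()) < 1.0:
        warnings.warn(
            f"penalty caps sum to {c.sum():.6f} < 1; rescaling to restore feasibility",
            stacklevel=2,
        )
        c *= (1.0 + 1e-6) / float(c.sum())
    d = np.diag(K).copy()
    beta = _solve_simplex_box_qp(K, d, c)
    obj = float(beta @ K @ beta - d @ beta)
    return beta, obj


def solve_furthest_hypersphere(Kp: np.ndarray, C: float, eta: float) -> np.ndarray:
    """Solve the health dual: min g'Kp g/(1-eta) - g'diag(Kp), 0<=g<=C, sum g=1.

    Kp is the shifted-kernel Gram matrix of the health class.  A uniform cap
    C with N*C < 1 is rescaled to the minimal feasible value (warned).
    """
    Kp = np.asarray(Kp, dtype=float)
    n = Kp.shape[0]
    if not (0.0 < eta < 1.0):
        raise ConfigError(f"eta must lie in (0, 1), got {eta}")
    if C <= 0:
        raise ConfigError(f"health penalty C must be positive, got {C}")
    if n * C < 1.0:
        warnings.warn(
            f"health cap C={C} infeasible for N_h={n}; rescaling to {(1 + 1e-6) / n:.6g}",
            stacklevel=2,
        )
        C = (1.0 + 1e-6) / n
    upper = np.full(n, float(C))
    Q = Kp / (1.0 - eta)
    d = np.diag(Kp).copy()
    return _solve_simplex_box_qp(Q, d, upper)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def distance_sq_to_center(K_qq_diag, K_qx, beta, center_norm_sq) -> np.ndarray:
    """||phi(q) - a||^2 = k(q,q) - 2 sum_i beta_i k(q, x_i) + ||a||^2, clamped >= 0."""
    val = np.asarray(K_qq_diag, float) - 2.0 * (np.asarray(K_qx, float) @ beta) + center_norm_sq
    return np.maximum(val, 0.0)


def _radius_from_distances(mult: np.ndarray, upper: np.ndarray, dist_sq: np.ndarray) -> float:
    """Squared radius: mean over free support vectors, else max over mult > tau."""
    tau = support_tau(upper)
    free = (mult > tau) & (mult < upper - tau)
    if free.any():
        return float(dist_sq[free].mean())
    sv = mult > tau
    if sv.any():
        return float(dist_sq[sv].max())
    raise DegenerateModelError("no support vectors: all multipliers at zero")


def patient_radius(beta: np.ndarray, c: np.ndarray, dist_sq: np.ndarray) -> float:
    """R^2 from the free support vectors of the weighted patient sphere."""
    return _radius_from_distances(beta, np.asarray(c, float), dist_sq)


def extract_oset(mult: np.ndarray, upper: np.ndarray, dist_sq: np.ndarray,
                 r_squared: float) -> np.ndarray:
    """Indices at their penalty bound with positive slack: the outlier /
    overlap-region set of a fitted sphere (may be empty)."""
    upper = np.asarray(upper, dtype=float)
    tau = support_tau(upper)
    mask = (mult >= upper - tau) & (dist_sq > r_squared + tau)
    return np.flatnonzero(mask)


def compute_eta(health_X, ref: ShiftedKernelRef, mode: str = "literal") -> float:
    """Balance coefficient eta = 1 / (1 + s) in (0, 1).

    ``mode="literal"``: s = mean{2 - 2 k'(x_i, x_j)} over all ordered health
    pairs including i = j.  ``mode="pairwise"``: s is the true mean squared
    shifted-feature distance k'_ii + k'_jj - 2 k'_ij over i != j.
    A scattered health class (large s) yields a small eta (volume term
    dominates); a compact one emphasizes separation from the patient center.
    """
    X = np.asarray(health_X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    Kp = shifted_gram(X, X, ref)
    n = Kp.shape[0]
    if mode == "literal":
        s = float(np.mean(2.0 - 2.0 * Kp))
    elif mode == "pairwise":
        if n < 2:
            s = 0.0
        else:
            diag = np.diag(Kp)
            d2 = diag[:, None] + diag[None, :] - 2.0 * Kp
            s = float((d2.sum() - np.trace(d2)) / (n * (n - 1)))
    else:
        raise ConfigError(f"unknown eta mode {mode!r}")
    eta = 1.0 / (1.0 + s) if s > -1.0 else np.inf
    return float(np.clip(eta, 1e-6, 1.0 - 1e-6))


def health_geometry(gamma: np.ndarray, Kp: np.ndarray, eta: float
                    ) -> tuple[float, np.ndarray]:
    """(||b||^2, per-point squared distances) of the furthest sphere.

    From primal stationarity b = sum_i gamma_i phi'(x_i) / (1 - eta):
    ||b||^2 = g'Kp g / (1-eta)^2 and
    d^2_j = Kp_jj - 2 (Kp g)_j / (1-eta) + ||b||^2.
    Z^2 then follows as the mean distance over free support vectors
    (fallback: max over gamma > tau), exactly as for the patient radius.
    """
    gamma = np.asarray(gamma, dtype=float)
    Kp = np.asarray(Kp, dtype=float)
    Kg = Kp @ gamma
    b_norm_sq = float(gamma @ Kg) / (1.0 - eta) ** 2
    dist_sq = np.maximum(np.diag(Kp) - 2.0 * Kg / (1.0 - eta) + b_norm_sq, 0.0)
    return b_norm_sq, dist_sq


# ---------------------------------------------------------------------------
# fitted-sphere containers
# ---------------------------------------------------------------------------

@dataclass
class PatientHypersphere:
    """Weighted enclosing hypersphere of the patient class."""

    X: np.ndarray
    kernel: KernelSpec
    beta: np.ndarray
    penalties: PenaltyWeights
    center_norm_sq: float
    r_squared: float
    oset_p: np.ndarray
    p_squared: float
    train_dist_sq: np.ndarray

    def distance_sq(self, Q) -> np.ndarray:
        """Squared feature-space distance of each row of Q to the center a."""
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        Kqx = gram_matrix(Q, self.X, self.kernel)
        return distance_sq_to_center(np.ones(Q.shape[0]), Kqx, self.beta,
                                     self.center_norm_sq)


@dataclass
class HealthHypersphere:
    """Maximally separated (furthest) hypersphere of the health class."""

    X: np.ndarray
    shifted_ref: ShiftedKernelRef
    gamma: np.ndarray
    eta: float
    penalty_c: float
    z_squared: float
    b_norm_squared: float
    oset_h: np.ndarray
    h_squared: float
    train_dist_sq: np.ndarray

    def distance_sq(self, Q) -> np.ndarray:
        """Squared shifted-feature distance of each row of Q to the center b."""
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        Kq = shifted_gram(Q, self.X, self.shifted_ref)
        from .kernels import shifted_diag
        diag = shifted_diag(Q, self.shifted_ref)
        val = diag - 2.0 * (Kq @ self.gamma) / (1.0 - self.eta) + self.b_norm_squared
        return np.maximum(val, 0.0)


def fit_patient_hypersphere(patient_X, health_X, spec: KernelSpec,
                            k_nn: int = 5) -> PatientHypersphere:
    """Fit the weighted patient sphere (penalties -> dual -> radius -> OsetP)."""
    Xp = np.asarray(patient_X, dtype=float)
    pw = penalty_weights(Xp, health_X, k_nn, spec)
    K = gram_matrix(Xp, Xp, spec)
    beta, _ = solve_weighted_svdd(K, pw.c)
    center_norm_sq = float(beta @ K @ beta)
    dist_sq = distance_sq_to_center(np.diag(K), K, beta, center_norm_sq)
    r_sq = patient_radius(beta, pw.c, dist_sq)
    oset = extract_oset(beta, pw.c, dist_sq, r_sq)
    p_sq = float(dist_sq[oset].mean()) if oset.size else 0.0
    return PatientHypersphere(X=Xp, kernel=spec, beta=beta, penalties=pw,
                              center_norm_sq=center_norm_sq, r_squared=r_sq,
                              oset_p=oset, p_squared=p_sq, train_dist_sq=dist_sq)


def fit_health_hypersphere(health_X, ref: ShiftedKernelRef, penalty_c: float = 0.2,
                           eta_mode: str = "pairwise") -> HealthHypersphere:
    """Fit the furthest health sphere under the shifted kernel."""
    Xh = np.asarray(health_X, dtype=float)
    if Xh.ndim == 1:
        Xh = Xh[None, :]
    eta = compute_eta(Xh, ref, mode=eta_mode)
    Kp = shifted_gram(Xh, Xh, ref)
    # symmetrize + clamp diagonal against cancellation
    Kp = 0.5 * (Kp + Kp.T)
    np.fill_diagonal(Kp, np.maximum(np.diag(Kp), 0.0))
    gamma = solve_furthest_hypersphere(Kp, penalty_c, eta)
    b_norm_sq, dist_sq = health_geometry(gamma, Kp, eta)
    upper = np.full(gamma.shape[0], max(penalty_c, (1.0 + 1e-6) / gamma.shape[0]))
    z_sq = _radius_from_distances(gamma, upper, dist_sq)
    oset = extract_oset(gamma, upper, dist_sq, z_sq)
    h_sq = float(dist_sq[oset].mean()) if oset.size else 0.0
    return HealthHypersphere(X=Xh, shifted_ref=ref, gamma=gamma, eta=eta,
                             penalty_c=penalty_c, z_squared=z_sq,
                             b_norm_squared=b_norm_sq, oset_h=oset,
                             h_squared=h_sq, train_dist_sq=dist_sq)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _qp_terms(sphere) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(Q, d, multipliers, upper bounds) of the dual behind a fitted sphere."""
    if isinstance(sphere, PatientHypersphere):
        K = gram_matrix(sphere.X, sphere.X, sphere.kernel)
        return K, np.diag(K).copy(), sphere.beta, sphere.penalties.c
    if isinstance(sphere, HealthHypersphere):
        Kp = shifted_gram(sphere.X, sphere.X, sphere.shifted_ref)
        Kp = 0.5 * (Kp + Kp.T)
        n = Kp.shape[0]
        upper = np.full(n, max(sphere.penalty_c, (1.0 + 1e-6) / n))
        return Kp / (1.0 - sphere.eta), np.diag(Kp).copy(), sphere.gamma, upper
    raise TypeError(f"not a fitted hypersphere: {type(sphere)!r}")


def kkt_report(sphere) -> pd.DataFrame:
    """Per-point KKT diagnostics of a fitted sphere's dual.

    Columns: multiplier, upper bound, gradient, status (interior / boundary /
    outside in sphere terms), residual.  ``df.attrs['max_residual']`` carries
    the largest violation; a well-solved model stays below 1e-6.
    """
    Q, d, mult, upper = _qp_terms(sphere)
    g = 2.0 * (Q @ mult) - d
    tau = support_tau(upper)
    at_zero = mult <= tau
    at_cap = mult >= upper - tau
    free = ~(at_zero | at_cap)
    if free.any():
        lam = float(g[free].mean())
    else:
        lam = float(0.5 * (g[~at_cap].min() if (~at_cap).any() else g.min())
                    + 0.5 * (g[~at_zero].max() if (~at_zero).any() else g.max()))
    residual = np.zeros_like(g)
    residual[free] = np.abs(g[free] - lam)
    residual[at_zero] = np.maximum(0.0, lam - g[at_zero])
    residual[at_cap] = np.maximum(0.0, g[at_cap] - lam)
    status = np.where(at_zero, "interior", np.where(free, "boundary", "outside"))
    df = pd.DataFrame({
        "multiplier": mult,
        "upper": upper,
        "gradient": g,
        "status": status,
        "residual": residual,
    })
    df.attrs["max_residual"] = float(residual.max()) if len(df) else 0.0
    df.attrs["lambda"] = lam
    return df
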