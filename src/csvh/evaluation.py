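"""Evaluation protocol: holdout runs, imbalance presets, CV tuning, and the
nonparametric comparison statistics.

The reference protocol is: per dataset, 10 independent runs each training on
a stratified random 20% of the data and testing on the rest, reporting mean
and standard deviation of accuracy = (TP + TN) / (TP + TN + FP + FN).
Hyperparameters are selected by stratified 10-fold cross-validation.
Class-imbalance behavior is probed with fixed per-class training counts
(presets T1..T8).  Classifier comparison uses the Iman-Davenport form of the
Friedman rank test and the exact (enumeration) Wilcoxon signed-rank test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import classifier
from .classifier import CSVHConfig, CSVHModel
from .data import LabeledDataset
from .errors import DegenerateModelError, InputError

__all__ = [
    "RunResults",
    "FriedmanResult",
    "IMBALANCE_PRESETS",
    "accuracy",
    "repeated_holdout",
    "imbalance_protocol",
    "grid_search_cv",
    "friedman_test",
    "f_critical",
    "wilcoxon_exact",
    "membership_coordinates",
]

#: fixed per-class training counts (# patient, # health) of the imbalance
#: designs; T1-T4 starve the patient class, T5-T8 the health class.
IMBALANCE_PRESETS: dict[str, tuple[int, int]] = {
    "T1": (5, 20), "T2": (5, 25), "T3": (5, 30), "T4": (5, 35),
    "T5": (30, 5), "T6": (45, 5), "T7": (60, 5), "T8": (75, 5),
}


@dataclass
class RunResults:
    """Accuracies over repeated runs of one protocol configuration."""

    per_run_accuracy: np.ndarray
    config: dict = field(default_factory=dict)
    per_run_train_accuracy: np.ndarray | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_run_accuracy))

    @property
    def sd(self) -> float:
        a = np.asarray(self.per_run_accuracy)
        return float(np.std(a, ddof=1)) if a.size > 1 else 0.0


def accuracy(y_true, y_pred) -> float:
    """(TP + TN) / (TP + TN + FP + FN) — the fraction of correct labels."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.size == 0:
        raise InputError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise InputError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    return float(np.mean(y_true == y_pred))


def _stratified_split(y: np.ndarray, n_train: dict[int, int],
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx = []
    for label, n in n_train.items():
        idx = np.flatnonzero(y == label)
        if idx.size < n:
            raise InputError(f"class {label} has {idx.size} < {n} requested training points")
        train_idx.append(rng.choice(idx, size=n, replace=False))
    train_idx = np.concatenate(train_idx)
    mask = np.ones(y.shape[0], dtype=bool)
    mask[train_idx] = False
    return np.sort(train_idx), np.flatnonzero(mask)


def _fit_on(dataset: LabeledDataset, idx: np.ndarray,
            config: CSVHConfig | None) -> CSVHModel:
    y = dataset.y[idx]
    return classifier.fit(dataset.X[idx][y == 1], dataset.X[idx][y == 0], config)


#: default hyperparameter grid of the cross-validated protocol (a ``None``
#: health cap would mean the size-adaptive 1/(0.3 N_h) rule; the CV grid uses
#: explicit caps, suited to the small training subsets it tunes on).
DEFAULT_TUNE_GRID: dict = {"widths": (0.25, 0.5, 1.0, 2.0),
                           "health_cs": (0.1, 0.2, 0.5),
                           "k_nns": (5,)}


def repeated_holdout(dataset: LabeledDataset, config: CSVHConfig | None = None,
                     train_fraction: float = 0.2, runs: int = 10,
                     seed: int = 0, max_retries: int = 5,
                     tune: bool | dict = False) -> RunResults:
    """Repeated stratified random holdout (default 20% train, 10 runs).

    Per-class training counts are round(fraction * class size), at least 2.
    With ``tune`` truthy, each run selects hyperparameters by stratified
    10-fold cross-validation *within its training subset* over
    ``DEFAULT_TUNE_GRID`` (or the grid passed as a dict) — the reference
    protocol, in which kernel scale and penalties are CV-set.  Degenerate
    fits are retried on a fresh draw (warned, at most ``max_retries`` per
    run).  Fully seed-deterministic.
    """
    rng = np.random.default_rng(seed)
    n_train = {1: max(2, round(train_fraction * dataset.n_patient)),
               0: max(2, round(train_fraction * dataset.n_health))}
    grid = (tune if isinstance(tune, dict) else DEFAULT_TUNE_GRID) if tune else None
    test_acc, train_acc = [], []
    for _run in range(runs):
        for attempt in range(max_retries + 1):
            tr, te = _stratified_split(dataset.y, n_train, rng)
            try:
                run_config = config
                if grid is not None:
                    sub = LabeledDataset(dataset.X[tr], dataset.y[tr])
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        run_config, _ = grid_search_cv(sub, seed=seed, **grid)
                model = _fit_on(dataset, tr, run_config)
                break
            except DegenerateModelError as e:
                if attempt == max_retries:
                    raise
                warnings.warn(f"degenerate split ({e}); redrawing", stacklevel=2)
        test_acc.append(accuracy(dataset.y[te], model.predict(dataset.X[te])))
        train_acc.append(accuracy(dataset.y[tr], model.predict(dataset.X[tr])))
    return RunResults(
        per_run_accuracy=np.array(test_acc),
        per_run_train_accuracy=np.array(train_acc),
        config={"protocol": "repeated_holdout", "train_fraction": train_fraction,
                "runs": runs, "seed": seed, "tuned": bool(tune),
                "classifier": vars(config) if config else None},
    )


def imbalance_protocol(dataset: LabeledDataset, presets: dict[str, tuple[int, int]] | None = None,
                       config: CSVHConfig | None = None, runs: int = 10,
                       seed: int = 0, tune: bool | dict = False) -> dict[str, RunResults]:
    """Fixed per-class training counts; the remainder is tested.

    Presets default to T1..T8.  With ``tune`` truthy, hyperparameters are
    CV-selected within each run's training subset as in
    :func:`repeated_holdout`.  A preset the dataset cannot supply is skipped
    with a warning.
    """
    presets = presets if presets is not None else IMBALANCE_PRESETS
    grid = (tune if isinstance(tune, dict) else DEFAULT_TUNE_GRID) if tune else None
    out: dict[str, RunResults] = {}
    for pos, (name, (n_p, n_h)) in enumerate(presets.items()):
        if dataset.n_patient < n_p + 1 or dataset.n_health < n_h + 1:
            warnings.warn(f"preset {name} needs {n_p}+{n_h} training points; skipped",
                          stacklevel=2)
            continue
        rng = np.random.default_rng(np.random.SeedSequence([seed, pos]))
        accs = []
        for _ in range(runs):
            tr, te = _stratified_split(dataset.y, {1: n_p, 0: n_h}, rng)
            run_config = config
            if grid is not None:
                sub = LabeledDataset(dataset.X[tr], dataset.y[tr])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    run_config, _ = grid_search_cv(sub, seed=seed, **grid)
            model = _fit_on(dataset, tr, run_config)
            accs.append(accuracy(dataset.y[te], model.predict(dataset.X[te])))
        out[name] = RunResults(
            per_run_accuracy=np.array(accs),
            config={"protocol": "imbalance", "preset": name, "n_patient": n_p,
                    "n_health": n_h, "runs": runs, "seed": seed, "tuned": bool(tune)},
        )
    return out


def grid_search_cv(dataset: LabeledDataset, widths=(None,), health_cs=(None,),
                   k_nns=(5,), folds: int = 10, seed: int = 0
                   ) -> tuple[CSVHConfig, pd.DataFrame]:
    """Stratified k-fold CV over a hyperparameter grid.

    Returns the best config (ties: smallest width, then smallest health C,
    then smallest k_nn; a ``None`` width sorts after concrete widths) and
    the full mean-accuracy table.
    """
    n_splits = min(folds, dataset.n_patient, dataset.n_health)
    if n_splits < 2:
        raise InputError("need at least 2 folds' worth of data per class")
    if n_splits < folds:
        warnings.warn(f"reducing folds from {folds} to {n_splits} (small class)",
                      stacklevel=2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    records = []
    for width, hc, knn in itertools.product(widths, health_cs, k_nns):
        cfg = CSVHConfig(width=width, health_c=hc, k_nn=knn)
        accs, gaps = [], []
        for tr, te in skf.split(dataset.X, dataset.y):
            if min((dataset.y[tr] == 1).sum(), (dataset.y[tr] == 0).sum()) < 2:
                continue
            model = _fit_on(dataset, tr, cfg)
            accs.append(accuracy(dataset.y[te], model.predict(dataset.X[te])))
            gaps.append(float(np.mean(np.abs(
                model.membership_patient(dataset.X[te])
                - model.membership_health(dataset.X[te])))))
        records.append({"width": width, "health_c": hc, "k_nn": knn,
                        "cv_accuracy": float(np.mean(accs)) if accs else np.nan,
                        "cv_membership_gap": float(np.mean(gaps)) if gaps else np.nan})
    table = pd.DataFrame(records)

    def _num(v, none_val):
        return none_val if v is None or pd.isna(v) else float(v)

    # accuracy first; accuracy ties resolved toward the most decisive model
    # (largest mean |G_p - G_h| on held-out folds), then smallest width / cap
    key = table.apply(
        lambda r: (-r["cv_accuracy"], -r["cv_membership_gap"],
                   _num(r["width"], np.inf), _num(r["health_c"], -1.0), r["k_nn"]),
        axis=1,
    )
    best = table.loc[key.map(tuple).sort_values().index[0]]
    best_width = None if pd.isna(best["width"]) else float(best["width"])
    best_hc = None if pd.isna(best["health_c"]) else float(best["health_c"])
    best_cfg = CSVHConfig(width=best_width, health_c=best_hc, k_nn=int(best["k_nn"]))
    return best_cfg, table


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------

@dataclass
class FriedmanResult:
    """Iman-Davenport Friedman comparison of k classifiers over N blocks."""

    ff_statistic: float
    chi2_statistic: float
    df1: int
    df2: int
    critical_value: float
    reject: bool
    alpha: float
    avg_ranks: np.ndarray


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-tail critical value of the F distribution."""
    if not (0.0 < alpha < 1.0) or df1 < 1 or df2 < 1:
        raise InputError("need 0 < alpha < 1 and df >= 1")
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def friedman_test(accuracy_matrix, alpha: float = 0.05) -> FriedmanResult:
    """Friedman rank test in the Iman-Davenport F form.

    Rows are blocks (runs or datasets), columns classifiers.  Column j gets
    the mean over rows of its within-row rank (rank 1 = best accuracy, ties
    averaged); then

        chi2_F = 12 N / (k (k+1)) * [sum_j R_j^2 - k (k+1)^2 / 4]
        F_F    = (N - 1) chi2_F / (N (k - 1) - chi2_F)

    compared against F(alpha; k-1, (k-1)(N-1)).  A constant matrix gives
    F_F = 0 (no rejection); a chi2_F at its maximum N(k-1) gives F_F = inf.
    """
    M = np.asarray(accuracy_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise InputError("need an N x k matrix with N >= 2 rows and k >= 2 classifiers")
    N, k = M.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, -M)  # rank 1 = highest accuracy
    R = ranks.mean(axis=0)
    chi2 = 12.0 * N / (k * (k + 1)) * (np.sum(R**2) - k * (k + 1) ** 2 / 4.0)
    denom = N * (k - 1) - chi2
    ff = 0.0 if chi2 <= 0 else (np.inf if denom <= 0 else (N - 1) * chi2 / denom)
    df1, df2 = k - 1, (k - 1) * (N - 1)
    crit = f_critical(alpha, df1, df2)
    return FriedmanResult(ff_statistic=float(ff), chi2_statistic=float(chi2),
                          df1=df1, df2=df2, critical_value=crit,
                          reject=bool(ff > crit), alpha=alpha, avg_ranks=R)


def wilcoxon_exact(x, y) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value by full enumeration.

    Zero differences are dropped; ties in |d| get mean ranks.  The null
    distribution of the positive-rank sum is built over all 2^n sign
    assignments (via convolution over integer-doubled ranks, equivalent to
    enumeration), so p-values lie on the exact m / 2^(n-1) lattice.
    Restricted to n <= 25 after zero-dropping; all-zero differences give 1.
    """
    d = np.asarray(x, dtype=float).ravel() - np.asarray(y, dtype=float).ravel()
    d = d[d != 0.0]
    n = d.shape[0]
    if n == 0:
        return 1.0
    if n > 25:
        raise InputError(f"exact enumeration limited to n <= 25, got {n}")
    ranks = stats.rankdata(np.abs(d))
    r2 = np.rint(2.0 * ranks).astype(int)  # doubled ranks are exact integers
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= 2.0**n
    w = int(np.rint(r2[d > 0].sum()))
    p_le = counts[: w + 1].sum()
    p_ge = counts[w:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def membership_coordinates(model: CSVHModel, X) -> pd.DataFrame:
    """(G_p, G_h) membership coordinates of each query — the raw material of
    the membership scatter diagnostic.  CSV-exportable; no plotting here."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return pd.DataFrame({
        "g_p": model.membership_patient(X),
        "g_h": model.membership_health(X),
    })
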