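"""L1-penalized severity classification with leave-one-patient-out CV.

Visits are labeled low severity (CGI-S <= 4) or high severity (CGI-S > 4).
For each of the 15 non-empty combinations of the four feature families
(HRV, ACT, MSTE, MSNR) a LASSO logistic regression is evaluated by
leave-one-patient-out cross-validation: all visits of one patient are held
out per fold, features are z-scored on the training fold only, and the
penalty is tuned on a 50-point log-spaced grid spanning
[1e-4 * lambda_max, lambda_max] by an inner stratified patient-level 3-fold
CV maximizing mean inner AUC (ties to the larger, sparser lambda). The
whole experiment is repeated 5 times with different inner-split seeds; each
held-out visit's probability is the median over repetitions and the pooled
AUC is computed once over all visits. Feature popularity is the fraction of
the (reps x patients) fitted models in which a feature kept a non-zero
coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

__all__ = [
    "FAMILIES",
    "LabeledFeatureTable",
    "CVExperimentResult",
    "binarize_cgis",
    "enumerate_combinations",
    "pooled_auc",
    "loocv_experiment",
    "feature_popularity",
    "run_full_experiment",
]

FAMILIES: tuple[str, ...] = ("HRV", "ACT", "MSTE", "MSNR")

_PREFIX_TO_FAMILY = {"hrv": "HRV", "act": "ACT", "mste": "MSTE", "msnr": "MSNR"}


def binarize_cgis(score: int) -> str:
    """CGI-S <= 4 -> 'low'; CGI-S > 4 -> 'high'."""
    if score not in range(1, 8):
        raise ValueError(f"CGI-S must be an integer in 1..7, got {score!r}")
    return "low" if score <= 4 else "high"


def enumerate_combinations(
    families: tuple[str, ...] = FAMILIES,
) -> list[tuple[str, ...]]:
    """All 15 non-empty family subsets, in the canonical listed order:
    singletons, pairs, triples, then all four."""
    h, a, t, n = families
    return [
        (h,), (a,), (t,), (n,),
        (h, a), (h, t), (h, n), (a, t), (a, n), (t, n),
        (h, a, t), (h, a, n), (h, t, n), (a, t, n),
        (h, a, t, n),
    ]


@dataclass
class LabeledFeatureTable:
    """Per-visit feature matrix with patient ids and binary labels.

    Feature columns are tagged by family through their name prefix
    (``hrv_``, ``act_``, ``mste_``, ``msnr_``).
    """

    features: pd.DataFrame          # rows = visits, columns = named features
    patient_ids: np.ndarray
    labels: np.ndarray              # 'low' / 'high'

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids)
        self.labels = np.asarray(self.labels)
        if len(self.features) != len(self.patient_ids) or len(self.features) != len(self.labels):
            raise ValueError("features, patient_ids and labels must align")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        bad = set(self.labels) - {"low", "high"}
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    def family_of(self, column: str) -> str:
        prefix = column.split("_", 1)[0]
        try:
            return _PREFIX_TO_FAMILY[prefix]
        except KeyError:
            raise KeyError(f"column {column!r} has no recognised family prefix") from None

    def columns_for(self, families: tuple[str, ...]) -> list[str]:
        fams = set(families)
        return [c for c in self.features.columns if self.family_of(c) in fams]

    @property
    def y(self) -> np.ndarray:
        """Binary target: 1 = high severity."""
        return (self.labels == "high").astype(int)


@dataclass
class CVExperimentResult:
    """Outcome of one feature-combination LOOCV experiment."""

    combination: tuple[str, ...]
    columns: list[str]
    visit_index: np.ndarray                 # row index into the table
    labels: np.ndarray
    prob_per_rep: np.ndarray                # (n_reps, n_visits)
    pooled_probs: np.ndarray                # per-visit median over reps
    pooled_auc_value: float
    coefficients: list[dict] = field(default_factory=list)  # one per fitted model
    selected_lambdas: list[float] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.coefficients)


def pooled_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC over pooled held-out probabilities; ties get half credit."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "US":
        y = (y == "high").astype(int)
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("pooled AUC needs both classes present")
    ranks = rankdata(probs)  # average ranks implement half-credit ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _lambda_grid(x: np.ndarray, y: np.ndarray, n_lambda: int = 50) -> np.ndarray:
    """Log-spaced path [1e-4*lambda_max, lambda_max]; lambda_max zeroes all coefs."""
    p_bar = y.mean()
    lam_max = np.max(np.abs(x.T @ (y - p_bar))) / len(y)
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(1e-4 * lam_max, lam_max, n_lambda)


def _fit_l1(x: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    c = 1.0 / (lam * len(y))
    clf = LogisticRegression(
        l1_ratio=1.0, C=c, solver="liblinear", max_iter=2000, random_state=0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(x, y)
    return clf


def _l1_logistic_path(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, max_iter: int = 300
) -> np.ndarray:
    """Batched FISTA over the whole lambda grid (intercept unpenalized).

    Minimizes (1/n) * sum logloss + lambda * ||w||_1 for every lambda at
    once; returns an (n_lambda, p + 1) array with the intercept last. Only
    used to *rank* lambdas in the inner CV — the final per-fold model is
    refit with liblinear.
    """
    n, p = x.shape
    xt = np.column_stack([x, np.ones(n)])
    lip = np.linalg.norm(xt, 2) ** 2 / (4.0 * n)
    step = 1.0 / lip
    k = len(grid)
    w = np.zeros((k, p + 1))
    z = w.copy()
    t_k = 1.0
    thresh = step * grid[:, None]  # per-lambda soft threshold
    for _ in range(max_iter):
        logits = z @ xt.T
        prob = 1.0 / (1.0 + np.exp(-logits))
        grad = (prob - y) @ xt / n
        w_new = z - step * grad
        # soft-threshold the penalized coordinates
        w_new[:, :p] = np.sign(w_new[:, :p]) * np.maximum(np.abs(w_new[:, :p]) - thresh, 0.0)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_k**2)) / 2.0
        z = w_new + ((t_k - 1.0) / t_next) * (w_new - w)
        w, t_k = w_new, t_next
    return w


def _patient_label(y: np.ndarray, pids: np.ndarray) -> dict:
    """Majority visit label per patient (ties -> high) for stratified splits."""
    out = {}
    for pid in np.unique(pids):
        yy = y[pids == pid]
        out[pid] = 1 if yy.mean() >= 0.5 else 0
    return out

def _inner_folds(pids: np.ndarray, y: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Stratified patient-level fold assignment: list of test-patient sets."""
    plab = _patient_label(y, pids)
    folds: list[set] = [set() for _ in range(n_folds)]
    for lab in (0, 1):
        group = [p for p, l in plab.items() if l == lab]
        rng.shuffle(group)
        for i, p in enumerate(group):
            folds[i % n_folds].add(p)
    return folds


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """z-score by training statistics; returns mask of kept (non-constant) cols."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    keep = sd > 0
    return (
        (train[:, keep] - mu[keep]) / sd[keep],
        (test[:, keep] - mu[keep]) / sd[keep],
        keep,
    )


def _select_lambda(
    x: np.ndarray,
    y: np.ndarray,
    pids: np.ndarray,
    grid: np.ndarray,
    rng: np.random.Generator,
    n_folds: int = 3,
) -> float:
    folds = _inner_folds(pids, y, n_folds, rng)
    scores = np.zeros(len(grid))
    counts = np.zeros(len(grid))
    for test_patients in folds:
        te = np.isin(pids, list(test_patients))
        tr = ~te
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            continue
        xtr, xte, _ = _standardize(x[tr], x[te])
        w = _l1_logistic_path(xtr, y[tr], grid)
        logits = w[:, :-1] @ xte.T + w[:, -1:]
        probs = 1.0 / (1.0 + np.exp(-logits))  # (n_lambda, n_test)
        ranks = rankdata(probs, axis=1)
        pos = y[te] == 1
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        aucs = (ranks[:, pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        scores += aucs
        counts += 1
    if counts.max() == 0:
        return float(grid[len(grid) // 2])
    mean_auc = scores / np.maximum(counts, 1)
    best = mean_auc.max()
    # ties -> larger lambda (sparser); grid is ascending
    return float(grid[np.flatnonzero(np.isclose(mean_auc, best))[-1]])


def loocv_experiment(
    table: LabeledFeatureTable,
    columns: list[str],
    combination: tuple[str, ...] = (),
    n_reps: int = 5,
    base_seed: int = 0,
    n_lambda: int = 50,
) -> CVExperimentResult:
    """Leave-one-patient-out evaluation of one feature combination.

    Produces n_reps x n_patients fitted models; per visit the pooled
    probability is the median over repetitions, and the pooled AUC is
    computed once against the ground-truth labels.
    """
    x_all = table.features[columns].to_numpy(dtype=float)
    y_all = table.y
    pids = table.patient_ids
    patients = np.unique(pids)
    if len(np.unique(y_all)) < 2:
        raise ValueError("both classes must be present")
    n_visits = len(y_all)
    prob_per_rep = np.full((n_reps, n_visits), np.nan)
    coefficients: list[dict] = []
    selected: list[float] = []

    for rep in range(n_reps):
        rng = np.random.default_rng(base_seed + rep)
        for held_out in patients:
            te = pids == held_out
            tr = ~te
            if len(np.unique(y_all[tr])) < 2:
                warnings.warn(f"fold {held_out}: a class is absent from training; skipped")
                continue
            xtr_raw, xte_raw = x_all[tr], x_all[te]
            xtr, xte, keep = _standardize(xtr_raw, xte_raw)
            grid = _lambda_grid(xtr, y_all[tr], n_lambda)
            lam = _select_lambda(xtr, y_all[tr], pids[tr], grid, rng)
            clf = _fit_l1(xtr, y_all[tr], lam)
            prob_per_rep[rep, te] = clf.predict_proba(xte)[:, 1]
            kept_cols = [c for c, k in zip(columns, keep) if k]
            coefs = dict(zip(kept_cols, clf.coef_.ravel()))
            for c, k in zip(columns, keep):
                if not k:
                    coefs[c] = 0.0
            coefficients.append(coefs)
            selected.append(lam)

    pooled = np.nanmedian(prob_per_rep, axis=0)
    auc = pooled_auc(pooled, y_all)
    return CVExperimentResult(
        combination=combination or tuple(),
        columns=list(columns),
        visit_index=np.arange(n_visits),
        labels=table.labels.copy(),
        prob_per_rep=prob_per_rep,
        pooled_probs=pooled,
        pooled_auc_value=auc,
        coefficients=coefficients,
        selected_lambdas=selected,
    )


def feature_popularity(result: CVExperimentResult, zero_tol: float = 1e-10) -> pd.Series:
    """Fraction of fitted models in which each feature is non-zero.

    Values lie on the grid {0, 1/M, ..., 1} for M models; sorted by
    popularity descending, ties by feature name.
    """
    m = result.n_models
    counts = {c: 0 for c in result.columns}
    for coefs in result.coefficients:
        for c, w in coefs.items():
            if abs(w) > zero_tol:
                counts[c] += 1
    rho = pd.Series({c: counts[c] / m for c in result.columns}, name="popularity")
    order = sorted(rho.index, key=lambda c: (-rho[c], c))
    return rho.loc[order]


def run_full_experiment(
    table: LabeledFeatureTable,
    n_reps: int = 5,
    base_seed: int = 0,
    n_lambda: int = 50,
) -> dict[tuple[str, ...], CVExperimentResult]:
    """All 15 feature-combination experiments; failures skip that combination."""
    results: dict[tuple[str, ...], CVExperimentResult] = {}
    for combo in enumerate_combinations():
        cols = table.columns_for(combo)
        if not cols:
            warnings.warn(f"combination {combo}: no columns present; skipped")
            continue
        try:
            results[combo] = loocv_experiment(
                table, cols, combination=combo, n_reps=n_reps,
                base_seed=base_seed, n_lambda=n_lambda,
            )
        except ValueError as exc:  # propagate-per-combination contract
            warnings.warn(f"combination {combo} failed: {exc}")
    return results
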