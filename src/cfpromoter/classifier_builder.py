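"""Training stage: stepwise promoter selection, SVM/LR fitting, LOOCV, ROC.

The classifier construction mirrors the common two-model design for
promoter-coverage biomarkers: candidate promoters come from the discovery
stage, a forward stepwise search greedily grows a gene combination that
maximizes leave-one-out cross-validated AUC, and both a linear-kernel SVM
(scores = signed margin) and a logistic regression (scores = probability)
are fitted on per-gene z-scored features.  Confidence intervals and paired
model comparisons use DeLong's method for correlated ROC curves.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

from .promoter_coverage import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "PerformanceReport",
    "fit_classifier",
    "decision_scores",
    "loocv_scores",
    "roc_metrics",
    "auc_confidence_interval",
    "compare_auc_paired",
    "stepwise_select",
    "select_optimal_classifier",
]

CASE_LABEL = "macrosomia"
#: Minimum LOOCV-AUC improvement for the stepwise search to keep going.
STEPWISE_TOL = 1e-4


@dataclass
class ClassifierSpec:
    """A fitted gene-combination classifier with frozen standardization.

    ``mean_``/``scale_`` are the training per-gene moments; applying the
    classifier to new samples reuses them (no re-standardization), so the
    model is fully frozen after training.
    """

    model_type: str  # "svm" | "lr"
    genes: list[str]
    mean_: np.ndarray
    scale_: np.ndarray
    model: object = field(repr=False)
    threshold: float = 0.0

    @property
    def native_threshold(self) -> float:
        return 0.0 if self.model_type == "svm" else 0.5


@dataclass(frozen=True)
class PerformanceReport:
    auc: float
    ci_low: float
    ci_high: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    n_cases: int
    n_controls: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _binary_labels(labels: Sequence) -> np.ndarray:
    """Map labels to {1: case, 0: control}; accepts strings or 0/1."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "biu":
        return arr.astype(int)
    return (arr == CASE_LABEL).astype(int)


def _make_estimator(model_type: str, seed: int):
    if model_type == "svm":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if model_type == "lr":
        # C=inf == unpenalized maximum likelihood
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
    raise ValueError(f"unknown model_type {model_type!r}; expected 'svm' or 'lr'")


def _fit_matrix(X: np.ndarray, y: np.ndarray, model_type: str, seed: int):
    """Fit on an already standardized matrix, with a ridge fallback for LR."""
    est = _make_estimator(model_type, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
        if model_type == "lr" and np.max(est.n_iter_) >= est.max_iter:
            # complete separation: unpenalized LR diverges; refit weakly ridged
            est = LogisticRegression(C=1e3, solver="lbfgs", max_iter=500)
            est.fit(X, y)
    return est


def _scores_of(est, model_type: str, X: np.ndarray) -> np.ndarray:
    if model_type == "svm":
        return est.decision_function(X)
    return est.predict_proba(X)[:, 1]


def _feature_matrix(norm: NormalizedMatrix, genes: Sequence[str]) -> np.ndarray:
    missing = [g for g in genes if g not in norm.values.columns]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    return norm.values.loc[:, list(genes)].to_numpy(dtype=float)


def fit_classifier(
    norm: NormalizedMatrix,
    labels: Sequence,
    genes: Sequence[str],
    model_type: str,
    seed: int = 0,
) -> ClassifierSpec:
    """Fit an SVM or LR on z-scored normalized coverage of ``genes``."""
    genes = list(genes)
    if not genes:
        raise ValueError("genes must be nonempty")
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = _feature_matrix(norm, genes)
    mean, scale = X.mean(axis=0), X.std(axis=0)
    zero = [g for g, s in zip(genes, scale) if s == 0]
    if zero:
        raise ValueError(f"zero training variance for gene(s): {zero}")
    est = _fit_matrix((X - mean) / scale, y, model_type, seed)
    spec = ClassifierSpec(model_type, genes, mean, scale, est)
    spec.threshold = spec.native_threshold
    return spec


def decision_scores(spec: ClassifierSpec, norm: NormalizedMatrix) -> pd.Series:
    """Score samples with the frozen standardization and fit."""
    X = (_feature_matrix(norm, spec.genes) - spec.mean_) / spec.scale_
    return pd.Series(_scores_of(spec.model, spec.model_type, X), index=norm.samples)


def loocv_scores(
    norm: NormalizedMatrix,
    labels: Sequence,
    genes: Sequence[str],
    model_type: str,
    seed: int = 0,
) -> pd.Series:
    """Leave-one-out out-of-fold decision scores.

    Each sample is scored by a model fitted to the other n - 1 samples;
    standardization moments are re-estimated inside every fold so no
    information about the held-out sample leaks into its score.
    """
    genes = list(genes)
    y = _binary_labels(labels)
    n = len(y)
    if n < 4:
        raise ValueError("LOOCV needs n >= 4")
    X = _feature_matrix(norm, genes)
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError(f"fold leaving out sample {i} loses a class")
        mean, scale = X[mask].mean(axis=0), X[mask].std(axis=0)
        if np.any(scale == 0):
            bad = [g for g, s in zip(genes, scale) if s == 0]
            raise ValueError(f"zero training variance for gene(s): {bad}")
        est = _fit_matrix((X[mask] - mean) / scale, y[mask], model_type, seed)
        out[i] = _scores_of(est, model_type, (X[[i]] - mean) / scale)[0]
    return pd.Series(out, index=norm.samples)


def auc_mann_whitney(scores: Sequence[float], labels: Sequence) -> float:
    """AUC as the Mann-Whitney probability that a case outscores a control."""
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_metrics(
    scores: Sequence[float],
    labels: Sequence,
    threshold_rule: str = "native",
    native_threshold: float = 0.0,
    ci_method: str = "delong",
    ci_seed: int = 0,
) -> PerformanceReport:
    """ROC summary of a score vector: AUC with CI, accuracy, sens/spec.

    ``threshold_rule`` is "native" (use ``native_threshold``: 0 for an SVM
    margin, 0.5 for an LR probability) or "youden" (maximize sensitivity +
    specificity - 1 on the given scores).  A sample is called a case when its
    score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = _binary_labels(labels)
    auc = auc_mann_whitney(scores, y)
    if threshold_rule == "youden":
        fpr, tpr, thr = roc_curve(y, scores)
        threshold = float(thr[np.argmax(tpr - fpr)])
    elif threshold_rule == "native":
        threshold = float(native_threshold)
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
    pred = scores >= threshold
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    ci_low, ci_high = auc_confidence_interval(scores, y, method=ci_method, seed=ci_seed)
    return PerformanceReport(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / n_cases,
        specificity=tn / n_controls,
        threshold=threshold,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def _delong_placements(scores: np.ndarray, y: np.ndarray):
    """Per-observation placement values V10 (cases) and V01 (controls)."""
    x = scores[y == 1]
    w = scores[y == 0]
    # psi(x, w) = 1 if x > w, 0.5 if tied, 0 otherwise
    cmp = (x[:, None] > w[None, :]).astype(float) + 0.5 * (x[:, None] == w[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0), cmp.mean()


def auc_confidence_interval(
    scores: Sequence[float],
    labels: Sequence,
    level: float = 0.95,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the AUC, truncated to [0, 1].

    "delong" uses the structural-components variance with a normal interval;
    "bootstrap" stratified-resamples cases and controls (percentile
    interval).  A degenerate DeLong variance of zero falls back to the
    bootstrap, logged.
    """
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need >= 2 members of each class")
    if method == "bootstrap":
        return _bootstrap_ci(scores, y, level, n_boot, seed)
    if method != "delong":
        raise ValueError(f"unknown CI method {method!r}")
    v10, v01, auc = _delong_placements(scores, y)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    if var == 0.0:
        logger.info("DeLong variance is 0 (AUC=%.3f); falling back to bootstrap CI", auc)
        return _bootstrap_ci(scores, y, level, n_boot, seed)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def _bootstrap_ci(
    scores: np.ndarray, y: np.ndarray, level: float, n_boot: int, seed: int
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ci = rng.choice(case_idx, size=len(case_idx), replace=True)
        ni = rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True)
        idx = np.concatenate([ci, ni])
        aucs[b] = roc_auc_score(y[idx], scores[idx])
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 0.5 + level / 2])
    return float(max(0.0, lo)), float(min(1.0, hi))


def compare_auc_paired(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence
) -> float:
    """Two-sided DeLong test for two correlated ROC curves on the same samples."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must cover the same samples")
    y = _binary_labels(labels)
    v10a, v01a, auc_a = _delong_placements(a, y)
    v10b, v01b, auc_b = _delong_placements(b, y)
    var = np.var(v10a - v10b, ddof=1) / len(v10a) + np.var(v01a - v01b, ddof=1) / len(v01a)
    diff = auc_a - auc_b
    if var == 0.0:
        return 1.0 if diff == 0.0 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def stepwise_select(
    norm: NormalizedMatrix,
    labels: Sequence,
    candidate_genes: Sequence[str],
    model_type: str = "svm",
    max_genes: int = 12,
    seed: int = 0,
    tol: float = STEPWISE_TOL,
    objective: str = "loocv",
) -> tuple[list[str], pd.DataFrame]:
    """Forward stepwise search for the gene combination maximizing AUC.

    Starting from the empty set, each step adds the candidate whose addition
    gives the largest objective AUC ("loocv" scores by default;
    "resubstitution" available for comparison); the search stops when the
    best addition improves the AUC by <= ``tol`` or ``max_genes`` is reached.
    Ties break in candidate order, so passing the discovery-stage sorted
    significant set makes the search fully deterministic.  Returns the
    selected genes and a trace DataFrame (step, gene_id, auc).
    """
    candidates: list[str] = []
    for g in candidate_genes:
        if g not in candidates:
            candidates.append(g)
    if not candidates:
        raise ValueError("empty candidate set")
    if objective not in ("loocv", "resubstitution"):
        raise ValueError(f"unknown objective {objective!r}")
    y = _binary_labels(labels)

    def score_set(genes: list[str]) -> float:
        if objective == "loocv":
            s = loocv_scores(norm, y, genes, model_type, seed=seed)
        else:
            spec = fit_classifier(norm, y, genes, model_type, seed=seed)
            s = decision_scores(spec, norm)
        return auc_mann_whitney(s.to_numpy(), y)

    selected: list[str] = []
    best_auc = -np.inf
    trace_rows = []
    while len(selected) < max_genes and len(selected) < len(candidates):
        step_best_gene, step_best_auc = None, -np.inf
        for g in candidates:
            if g in selected:
                continue
            auc = score_set(selected + [g])
            if auc > step_best_auc:
                step_best_gene, step_best_auc = g, auc
        if step_best_gene is None or step_best_auc <= best_auc + tol and selected:
            break
        selected.append(step_best_gene)
        best_auc = step_best_auc
        trace_rows.append((len(selected), step_best_gene, step_best_auc))
        if best_auc >= 1.0:
            break
    trace = pd.DataFrame(trace_rows, columns=["step", "gene_id", "loocv_auc"])
    return selected, trace


def select_optimal_classifier(reports: Mapping[str, PerformanceReport]) -> str:
    """Pick the model with the larger training AUC; exact ties go to the SVM."""
    if not reports:
        raise ValueError("no reports")
    best = max(reports.values(), key=lambda r: r.auc).auc
    tied = [m for m, r in reports.items() if r.auc == best]
    if len(tied) > 1 and "svm" in tied:
        logger.info("training AUC tie between %s; selecting svm", tied)
        return "svm"
    return tied[0]
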