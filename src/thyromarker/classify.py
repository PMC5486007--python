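"""DLDA classification with doubly nested leave-one-out cross-validation.

Diagonal linear discriminant analysis models each class as a Gaussian with
class-specific per-gene means and a shared diagonal covariance (pooled
per-gene variances).  Genes enter the model through a Student t-test filter
whose significance threshold alpha is a hyperparameter.  Performance is
estimated by a doubly nested leave-one-out cross-validation: the outer loop
holds out one sample for testing; on the remaining n-1 an inner
leave-one-out loop scores every alpha on the grid — with gene selection
recomputed inside every inner training fold, so the held-out sample never
influences selection, tuning, or training — and the alpha with the best
inner accuracy (ties broken toward the smallest, most parsimonious alpha)
is used to train the model that classifies the held-out sample.

The per-sample held-out class probabilities yield the confusion matrix at
the 50% cutoff, exact (Clopper-Pearson) binomial confidence intervals for
accuracy/sensitivity/specificity, and the ROC curve with its AUC.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.stats.proportion import proportion_confint

from .datatypes import LOG2, ExpressionMatrix, SampleAnnotation, ValidationError

POSITIVE = "FTC"  # malignant class; probabilities are P(FTC | x)

#: Default grid of significance thresholds for gene selection.
DEFAULT_ALPHA_GRID = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05)

_VAR_FLOOR_REL = 1e-8


def _as_labels(labels) -> pd.Series:
    if isinstance(labels, SampleAnnotation):
        return labels.diagnosis
    return pd.Series(labels)


def _design(matrix: ExpressionMatrix, labels) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Samples-by-genes array plus boolean positive-class indicator."""
    if matrix.scale != LOG2:
        raise ValidationError("classifier expects a log2-scale matrix")
    lab = _as_labels(labels)
    missing = [s for s in matrix.samples if s not in lab.index]
    if missing:
        raise ValidationError(f"labels missing for samples: {missing[:5]}")
    lab = lab.loc[matrix.samples]
    classes = set(lab)
    if not classes <= {"FTC", "FTA"}:
        raise ValidationError(f"labels must be FTC/FTA, found {sorted(classes)}")
    if len(classes) < 2:
        raise ValidationError("both classes must be present")
    x = matrix.values.to_numpy(dtype=float).T
    if np.isnan(x).any():
        raise ValidationError("classifier input contains missing values")
    y = (lab == POSITIVE).to_numpy()
    return x, y, matrix.samples, matrix.genes


def _ttest_pvals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Equal-variance two-sample t-test p-values per column of ``x``."""
    res = stats.ttest_ind(x[y], x[~y], axis=0, equal_var=True)
    return np.asarray(res.pvalue)


class GeneSelection(NamedTuple):
    genes: list
    fallback: bool  # True when no gene met alpha and the single best was taken


def select_genes_ttest(matrix: ExpressionMatrix, labels, alpha: float) -> GeneSelection:
    """Genes with raw Student t-test p below ``alpha``.

    When no gene passes, falls back to the single smallest-p gene so the
    classifier is never left without features; the fallback is flagged.
    """
    x, y, _samples, genes = _design(matrix, labels)
    p = _ttest_pvals(x, y)
    keep = np.nonzero(p < alpha)[0]
    if keep.size == 0:
        return GeneSelection([genes[int(np.nanargmin(p))]], True)
    return GeneSelection([genes[i] for i in keep], False)


@dataclass
class DldaModel:
    """Fitted diagonal-Gaussian discriminant.

    ``mu`` holds per-class per-gene means (rows FTC/FTA), ``sigma2`` the
    pooled within-class variances (denominator n - 2, floored at 1e-8 times
    their median), ``priors`` the class priors.
    """

    genes: list
    mu: pd.DataFrame  # index: ("FTC", "FTA"), columns: genes
    sigma2: pd.Series
    priors: dict
    alpha_used: float | None = None
    selection_fallback: bool = False


def dlda_train(matrix: ExpressionMatrix, labels, priors: str = "empirical",
               alpha_used: float | None = None,
               selection_fallback: bool = False) -> DldaModel:
    """Fit DLDA: class means and pooled diagonal variances."""
    x, y, _samples, genes = _design(matrix, labels)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 < 2 or n0 < 2:
        raise ValidationError(f"need >= 2 samples per class, got FTC={n1}, FTA={n0}")
    mu1, mu0 = x[y].mean(axis=0), x[~y].mean(axis=0)
    ss = ((x[y] - mu1) ** 2).sum(axis=0) + ((x[~y] - mu0) ** 2).sum(axis=0)
    sigma2 = ss / (n1 + n0 - 2)
    sigma2 = _floor_variances(sigma2)
    if priors == "empirical":
        pi = {"FTC": n1 / (n1 + n0), "FTA": n0 / (n1 + n0)}
    elif priors == "equal":
        pi = {"FTC": 0.5, "FTA": 0.5}
    else:
        raise ValidationError(f"priors must be 'empirical' or 'equal', got {priors!r}")
    return DldaModel(genes=genes,
                     mu=pd.DataFrame([mu1, mu0], index=["FTC", "FTA"], columns=genes),
                     sigma2=pd.Series(sigma2, index=genes), priors=pi,
                     alpha_used=alpha_used, selection_fallback=selection_fallback)


def _floor_variances(sigma2: np.ndarray) -> np.ndarray:
    med = float(np.median(sigma2))
    floor = _VAR_FLOOR_REL * med if med > 0 else 1e-12
    return np.maximum(sigma2, floor)


def dlda_posterior(model: DldaModel, sample) -> float:
    """P(FTC | x) under the diagonal-Gaussian model, computed in log space."""
    if isinstance(sample, (pd.Series, dict)):
        sample = pd.Series(sample)
        missing = [g for g in model.genes if g not in sample.index]
        if missing:
            raise ValidationError(f"sample is missing values for genes: {missing[:5]}")
        x = sample.loc[model.genes].to_numpy(dtype=float)
    else:
        x = np.asarray(sample, dtype=float)
        if x.shape[-1] != len(model.genes):
            raise ValidationError(
                f"sample has {x.shape[-1]} values but model uses {len(model.genes)} genes")
    mu1 = model.mu.loc["FTC"].to_numpy()
    mu0 = model.mu.loc["FTA"].to_numpy()
    s2 = model.sigma2.to_numpy()
    log_odds = (np.log(model.priors["FTC"]) - np.log(model.priors["FTA"])
                + 0.5 * np.sum(((x - mu0) ** 2 - (x - mu1) ** 2) / s2, axis=-1))
    return float(expit(log_odds))


@dataclass
class CVResult:
    """Leave-one-out predictions and the resulting confusion counts.

    ``per_sample`` rows: true label, held-out P(FTC), predicted label at the
    50% cutoff, the alpha chosen by the inner loop, the number of genes in
    the final per-fold model, and whether selection fell back to a single
    gene.  Confusion counts treat FTC as positive.
    """

    per_sample: pd.DataFrame
    alpha_grid: tuple
    cutoff: float = 0.5

    def __post_init__(self):
        p = self.per_sample["prob_ftc"].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("probabilities must lie in [0, 1]")

    @property
    def confusion(self) -> dict:
        t = self.per_sample
        pos = t["true_label"] == POSITIVE
        pred_pos = t["predicted"] == POSITIVE
        return {"TP": int((pos & pred_pos).sum()), "FN": int((pos & ~pred_pos).sum()),
                "TN": int((~pos & ~pred_pos).sum()), "FP": int((~pos & pred_pos).sum())}


def _loo_sufficient_stats(x: np.ndarray, y: np.ndarray):
    """Leave-one-out class means and sums of squared deviations.

    For every sample i of the n x g array, returns the class-wise means and
    within-class SS computed on the other n-1 samples, vectorised over i.
    """
    yf = y[:, None].astype(float)
    s1, ss1 = (x * yf).sum(axis=0), (x ** 2 * yf).sum(axis=0)
    s0, ss0 = (x * (1 - yf)).sum(axis=0), (x ** 2 * (1 - yf)).sum(axis=0)
    n1, n0 = y.sum(), (~y).sum()
    n1_i = n1 - y.astype(int)
    n0_i = n0 - (~y).astype(int)
    s1_i = s1[None, :] - x * yf
    s0_i = s0[None, :] - x * (1 - yf)
    ss1_i = ss1[None, :] - x ** 2 * yf
    ss0_i = ss0[None, :] - x ** 2 * (1 - yf)
    mu1_i = s1_i / n1_i[:, None]
    mu0_i = s0_i / n0_i[:, None]
    a1_i = ss1_i - n1_i[:, None] * mu1_i ** 2
    a0_i = ss0_i - n0_i[:, None] * mu0_i ** 2
    return mu1_i, mu0_i, a1_i, a0_i, n1_i, n0_i


def _inner_loocv_accuracy(x: np.ndarray, y: np.ndarray, alpha: float,
                          priors: str) -> float:
    """Leave-one-out accuracy on the training block for one alpha.

    Equivalent to refitting selection + DLDA for every inner fold, via
    leave-one-out sufficient-statistic updates.
    """
    m = len(y)
    mu1, mu0, a1, a0, n1_i, n0_i = _loo_sufficient_stats(x, y)
    df = m - 1 - 2
    pooled_t = (a1 + a0) / df
    diff = mu1 - mu0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled_t * (1.0 / n1_i[:, None] + 1.0 / n0_i[:, None]))
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(t), 1.0, p)  # zero-variance, zero-difference genes

    sel = p < alpha
    none = ~sel.any(axis=1)
    if none.any():
        best = np.argmin(p[none], axis=1)
        sel[np.nonzero(none)[0], best] = True

    sigma2 = (a1 + a0) / df
    med = np.median(sigma2, axis=1)
    floor = np.where(med > 0, _VAR_FLOOR_REL * med, 1e-12)
    sigma2 = np.maximum(sigma2, floor[:, None])
    d = 0.5 * ((x - mu0) ** 2 - (x - mu1) ** 2) / sigma2
    if priors == "empirical":
        logit_prior = np.log(n1_i) - np.log(n0_i)
    else:
        logit_prior = np.zeros(m)
    score = logit_prior + (d * sel).sum(axis=1)
    pred = score > 0.0
    return float((pred == y).mean())


def nested_loocv(matrix: ExpressionMatrix, labels,
                 alpha_grid=DEFAULT_ALPHA_GRID, priors: str = "empirical") -> CVResult:
    """Doubly nested leave-one-out cross-validation of the DLDA pipeline.

    Outer loop: each sample is held out once; the inner leave-one-out loop
    on the remaining n-1 samples scores every alpha on the grid, gene
    selection recomputed inside each inner fold.  The best inner alpha
    (smallest on ties) is then used to reselect genes on all n-1 samples,
    train DLDA, and record the held-out sample's P(FTC).
    """
    alpha_grid = tuple(sorted(alpha_grid))
    if len(alpha_grid) == 0:
        raise ValidationError("alpha grid is empty")
    x, y, samples, genes = _design(matrix, labels)
    n = len(y)
    if n < 6 or y.sum() < 3 or (~y).sum() < 3:
        raise ValidationError("nested LOOCV needs n >= 6 with >= 3 samples per class")

    genes_arr = np.array(genes)
    rows = []
    for j in range(n):
        tr = np.arange(n) != j
        xtr, ytr = x[tr], y[tr]
        inner_acc = [_inner_loocv_accuracy(xtr, ytr, a, priors) for a in alpha_grid]
        best = int(np.argmax(inner_acc))  # argmax takes the first max: smallest alpha
        alpha = alpha_grid[best]

        p = _ttest_pvals(xtr, ytr)
        keep = np.nonzero(p < alpha)[0]
        fallback = keep.size == 0
        if fallback:
            keep = np.array([int(np.nanargmin(p))])

        sub = ExpressionMatrix(pd.DataFrame(xtr[:, keep].T, index=genes_arr[keep],
                                            columns=np.array(samples)[tr]), scale=LOG2)
        model = dlda_train(sub, pd.Series(np.where(ytr, "FTC", "FTA"),
                                          index=np.array(samples)[tr]),
                           priors=priors, alpha_used=alpha, selection_fallback=fallback)
        prob = dlda_posterior(model, x[j, keep])
        rows.append({"sample": samples[j],
                     "true_label": "FTC" if y[j] else "FTA",
                     "prob_ftc": prob,
                     "predicted": "FTC" if prob > 0.5 else "FTA",
                     "alpha": alpha, "n_genes": int(keep.size), "fallback": fallback})
    per_sample = pd.DataFrame(rows).set_index("sample")
    return CVResult(per_sample=per_sample, alpha_grid=alpha_grid)


def clopper_pearson(x: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles."""
    lo, hi = proportion_confint(x, n, alpha=1 - confidence, method="beta")
    return float(lo), float(hi)


def _round_percent(p: float) -> int:
    """Round a proportion to whole percent, half away from zero."""
    return int(np.floor(p * 100.0 + 0.5))


@dataclass
class MetricsReport:
    """Accuracy/sensitivity/specificity with exact 95% CIs.

    ``table`` rows hold the raw counts, the unrounded proportion and CI
    bounds, and the whole-percent values used for reporting.
    """

    table: pd.DataFrame
    confusion: dict

    def percent(self, metric: str) -> int:
        return int(self.table.loc[metric, "percent"])


def _metric_row(x: int, n: int) -> dict:
    if n == 0:
        return {"x": x, "n": n, "proportion": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "percent": np.nan, "percent_ci_low": np.nan,
                "percent_ci_high": np.nan}
    lo, hi = clopper_pearson(x, n)
    return {"x": x, "n": n, "proportion": x / n, "ci_low": lo, "ci_high": hi,
            "percent": _round_percent(x / n), "percent_ci_low": _round_percent(lo),
            "percent_ci_high": _round_percent(hi)}


def confusion_metrics(cv: CVResult | dict, stratify_by: pd.Series | None = None):
    """Accuracy, sensitivity and specificity with Clopper-Pearson 95% CIs.

    Accepts a :class:`CVResult` or a plain confusion dict (TP/FN/TN/FP).
    ``stratify_by`` (a per-sample Series, e.g. the oncocytic flag) instead
    returns a dict of per-stratum reports computed on the subsets.
    """
    if stratify_by is not None:
        if not isinstance(cv, CVResult):
            raise ValidationError("stratified metrics require a CVResult")
        out = {}
        strata = stratify_by.loc[cv.per_sample.index]
        for level in sorted(strata.unique(), key=str):
            sub = cv.per_sample[strata == level]
            out[level] = confusion_metrics(CVResult(sub, cv.alpha_grid, cv.cutoff))
        return out

    conf = cv.confusion if isinstance(cv, CVResult) else dict(cv)
    tp, fn, tn, fp = conf["TP"], conf["FN"], conf["TN"], conf["FP"]
    if min(tp, fn, tn, fp) < 0:
        raise ValidationError("confusion counts must be non-negative")
    n = tp + fn + tn + fp
    table = pd.DataFrame({
        "accuracy": _metric_row(tp + tn, n),
        "sensitivity": _metric_row(tp, tp + fn),
        "specificity": _metric_row(tn, tn + fp),
    }).T
    return MetricsReport(table=table, confusion=conf)


@dataclass
class ROCCurve:
    """ROC curve over probability thresholds.

    ``points`` runs from (FPR, TPR) = (0, 0) at threshold +inf to (1, 1);
    ``auc`` is the trapezoidal area, equal to the Mann-Whitney probability
    P(score_FTC > score_FTA) + 0.5 P(tie).
    """

    points: pd.DataFrame  # columns: threshold, fpr, tpr
    auc: float


def roc_auc(cv: CVResult) -> ROCCurve:
    """ROC curve and AUC from the leave-one-out class probabilities."""
    t = cv.per_sample
    pos = (t["true_label"] == POSITIVE).to_numpy()
    if pos.all() or (~pos).all():
        raise ValidationError("ROC needs both classes among the true labels")
    scores = t["prob_ftc"].to_numpy(dtype=float)
    order = np.argsort(-scores, kind="stable")
    scores_sorted = scores[order]
    pos_sorted = pos[order]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())

    thresholds = [np.inf]
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    while i < len(scores_sorted):
        thr = scores_sorted[i]
        while i < len(scores_sorted) and scores_sorted[i] == thr:
            if pos_sorted[i]:
                tp += 1
            else:
                fp += 1
            i += 1
        thresholds.append(thr)
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    auc = float(np.trapezoid(points["tpr"], points["fpr"]))
    return ROCCurve(points=points, auc=auc)
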