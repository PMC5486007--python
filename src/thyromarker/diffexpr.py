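"""Two-group differential expression with outlier exclusion and FDR.

The validation-cohort workflow: flag extreme-outlier samples with the
Q3 + k*IQR rule (k = 6 by default), test each gene with a two-sample
Student t-test on log2 expression, report linear FTC/FTA fold changes,
adjust p-values with Benjamini-Hochberg, and re-test with an additive
two-way ANOVA (malignancy + oncocytic feature, Type II sums of squares) to
adjust for the Hurthle-cell covariate.  Also provides the two-set marker
filter used for microarray candidate selection and a PCA projection of
samples on a chosen gene subset.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .datatypes import LOG2, ExpressionMatrix, SampleAnnotation, ValidationError


@dataclass
class OutlierReport:
    """Cells exceeding the per-gene Q3 + k*IQR threshold.

    Advisory: the report lists flagged (sample, gene) cells and the samples
    that would be excluded (flagged in at least one gene); the caller applies
    the exclusion.
    """

    flags: list  # (sample, gene) pairs
    excluded_samples: list
    per_gene: pd.DataFrame  # Q1, Q3, IQR, threshold per gene
    k: float


def flag_extreme_outliers(matrix: ExpressionMatrix, k: float = 6.0) -> OutlierReport:
    """Flag cells whose expression exceeds Q3 + k*IQR for their gene.

    Quartiles are computed per gene over all samples with linear
    interpolation between order statistics.  A sample is listed for
    exclusion if flagged in one or more genes.
    """
    if k < 0:
        raise ValidationError("outlier multiplier k must be >= 0")
    values = matrix.values
    if values.shape[1] < 4:
        raise ValidationError("outlier flagging needs >= 4 samples")
    arr = values.to_numpy(dtype=float)
    q1 = np.nanquantile(arr, 0.25, axis=1)
    q3 = np.nanquantile(arr, 0.75, axis=1)
    iqr = q3 - q1
    threshold = q3 + k * iqr
    exceed = arr > threshold[:, None]
    flags = [(str(values.columns[c]), str(values.index[r]))
             for r, c in zip(*np.nonzero(exceed))]
    excluded = list(dict.fromkeys(s for s, _g in flags))
    per_gene = pd.DataFrame({"Q1": q1, "Q3": q3, "IQR": iqr, "threshold": threshold},
                            index=values.index)
    return OutlierReport(flags=flags, excluded_samples=excluded, per_gene=per_gene, k=k)


@dataclass
class DEResult:
    """Per-gene differential-expression results.

    ``table`` has one row per tested gene: class means (log2), linear
    ``fold_change`` (FTC/FTA), raw and BH-adjusted t-test p-values, raw and
    BH-adjusted malignancy p-values from the two-way ANOVA when computed,
    and per-class sample counts.  ``dropped_genes`` lists genes excluded
    before testing (all values missing, e.g. failed amplification).
    """

    table: pd.DataFrame
    dropped_genes: list = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def _split_classes(matrix: ExpressionMatrix, annot: SampleAnnotation):
    annot = annot.aligned_to(matrix.samples)
    diag = annot.diagnosis
    ftc = [s for s in matrix.samples if diag[s] == "FTC"]
    fta = [s for s in matrix.samples if diag[s] == "FTA"]
    return ftc, fta


def ttest_fdr(matrix: ExpressionMatrix, annot: SampleAnnotation,
              equal_var: bool = True) -> DEResult:
    """Per-gene two-sample t-test on log2 values with BH adjustment.

    Uses the classical equal-variance Student t-test by default (``equal_var
    =False`` switches to Welch).  The linear fold change is ``2 ** (mean_FTC
    - mean_FTA)``.  Genes with all values missing are dropped and reported;
    partially missing values are omitted per gene (``n_ftc``/``n_fta``
    record the counts actually used).
    """
    if matrix.scale != LOG2:
        raise ValidationError("ttest_fdr expects a log2-scale matrix")
    ftc, fta = _split_classes(matrix, annot)
    if len(ftc) < 2 or len(fta) < 2:
        raise ValidationError(f"need >= 2 samples per class, got FTC={len(ftc)}, FTA={len(fta)}")

    values = matrix.values
    all_missing = values.isna().all(axis=1)
    dropped = list(values.index[all_missing])
    values = values[~all_missing]

    a = values[ftc].to_numpy(dtype=float)
    b = values[fta].to_numpy(dtype=float)
    res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var, nan_policy="omit")
    mean_ftc = np.nanmean(a, axis=1)
    mean_fta = np.nanmean(b, axis=1)
    with np.errstate(invalid="ignore"):
        pooled = np.concatenate([a, b], axis=1)
    table = pd.DataFrame({
        "mean_ftc": mean_ftc,
        "mean_fta": mean_fta,
        "mean_overall": np.nanmean(pooled, axis=1),
        "var_overall": np.nanvar(pooled, axis=1, ddof=1),
        "fold_change": 2.0 ** (mean_ftc - mean_fta),
        "t_stat": np.asarray(res.statistic),
        "t_p": np.asarray(res.pvalue),
        "n_ftc": (~np.isnan(a)).sum(axis=1),
        "n_fta": (~np.isnan(b)).sum(axis=1),
    }, index=values.index)
    table["t_q"] = bh_adjust(table["t_p"].to_numpy())
    return DEResult(table=table, dropped_genes=dropped)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _check_two_factor_design(diag: pd.Series, onc: pd.Series) -> None:
    if onc.nunique() < 2:
        raise ValidationError("oncocytic factor is constant; two-way ANOVA is degenerate")
    if diag.nunique() < 2:
        raise ValidationError("diagnosis factor is constant")
    # perfect aliasing: oncocytic status determined by (or determining) diagnosis
    ct = pd.crosstab(diag, onc)
    if (ct.to_numpy() == 0).sum() >= 2:
        raise ValidationError("design is confounded: malignancy and oncocytic factors are aliased")


def anova_adjusted(matrix: ExpressionMatrix, annot: SampleAnnotation) -> DEResult:
    """Two-way additive ANOVA per gene: malignancy adjusted for oncocytic status.

    Fits ``expression ~ malignancy + oncocytic`` (no interaction) per gene
    and reports the malignancy-factor p-value from Type II sums of squares
    — the convention robust to the unbalanced oncocytic distribution —
    BH-adjusted across genes.
    """
    if matrix.scale != LOG2:
        raise ValidationError("anova_adjusted expects a log2-scale matrix")
    annot = annot.aligned_to(matrix.samples)
    diag = annot.diagnosis.loc[matrix.samples]
    onc = annot.oncocytic.loc[matrix.samples]
    _check_two_factor_design(diag, onc)

    values = matrix.values
    all_missing = values.isna().all(axis=1)
    dropped = list(values.index[all_missing])
    values = values[~all_missing]

    frame = pd.DataFrame({"malignancy": (diag == "FTC").to_numpy().astype(int),
                          "oncocytic": onc.to_numpy().astype(int)})
    pvals, fvals = [], []
    for gene in values.index:
        frame["y"] = values.loc[gene].to_numpy(dtype=float)
        sub = frame.dropna()
        fit = ols("y ~ C(malignancy) + C(oncocytic)", data=sub).fit()
        a2 = anova_lm(fit, typ=2)
        pvals.append(float(a2.loc["C(malignancy)", "PR(>F)"]))
        fvals.append(float(a2.loc["C(malignancy)", "F"]))
    table = pd.DataFrame({"anova_F": fvals, "anova_p": pvals}, index=values.index)
    table["anova_q"] = bh_adjust(table["anova_p"].to_numpy())
    return DEResult(table=table, dropped_genes=dropped)


@dataclass
class MarkerFilterCriteria:
    """Thresholds of the two-set marker filter.

    Primary set: mean expression above ``min_mean`` (log2 units), gene
    variance above the ``var_percentile``-th percentile of gene variances,
    raw t-test p below ``p_primary``, and fold change at least ``min_fold``
    in either direction.  Secondary set: raw t-test p below ``p_secondary``.
    """

    min_mean: float = 4.5
    var_percentile: float = 20.0
    p_primary: float = 0.001
    min_fold: float = 1.5
    p_secondary: float = 0.05


def two_set_marker_filter(primary_de: DEResult, secondary_de: DEResult,
                          criteria: MarkerFilterCriteria | None = None) -> list[str]:
    """Genes passing all four primary criteria and the secondary p criterion.

    The fold-change criterion is two-sided: FC >= min_fold or
    FC <= 1/min_fold.  Both result tables must cover the same gene universe.
    """
    criteria = criteria or MarkerFilterCriteria()
    prim, sec = primary_de.table, secondary_de.table
    if set(prim.index) != set(sec.index):
        only_p = sorted(set(prim.index) - set(sec.index))[:5]
        only_s = sorted(set(sec.index) - set(prim.index))[:5]
        raise ValidationError(
            f"gene universes differ: only-primary={only_p}, only-secondary={only_s}")
    var_cut = np.percentile(prim["var_overall"].to_numpy(dtype=float),
                            criteria.var_percentile)
    fc = prim["fold_change"]
    keep = (
        (prim["mean_overall"] > criteria.min_mean)
        & (prim["var_overall"] > var_cut)
        & (prim["t_p"] < criteria.p_primary)
        & ((fc >= criteria.min_fold) | (fc <= 1.0 / criteria.min_fold))
        & (sec["t_p"].reindex(prim.index) < criteria.p_secondary)
    )
    return list(prim.index[keep])


@dataclass
class PCAProjection:
    """First-two-component sample scores and explained-variance fractions."""

    scores: pd.DataFrame  # samples x (PC1, PC2)
    explained_variance_fraction: np.ndarray
    loadings: pd.DataFrame  # genes x (PC1, PC2)


def pca_project(matrix: ExpressionMatrix, gene_subset) -> PCAProjection:
    """Project samples onto the first two principal components of a gene subset.

    Genes are centered across samples; components come from the singular
    value decomposition of the centered matrix.  Sign convention: for each
    component the gene with the largest absolute loading gets a positive
    loading.
    """
    gene_subset = list(gene_subset)
    if len(gene_subset) < 2:
        raise ValidationError("PCA needs a gene subset of >= 2 genes")
    sub = matrix.subset_genes(gene_subset)
    x = sub.values.to_numpy(dtype=float).T  # samples x genes
    if np.isnan(x).any():
        raise ValidationError("PCA input contains missing values")
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    n_comp = min(2, len(s))
    scores = u[:, :n_comp] * s[:n_comp]
    loadings = vt[:n_comp].T
    for j in range(n_comp):
        top = np.argmax(np.abs(loadings[:, j]))
        if loadings[top, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAProjection(
        scores=pd.DataFrame(scores, index=sub.values.columns, columns=cols),
        explained_variance_fraction=frac[:n_comp],
        loadings=pd.DataFrame(loadings, index=gene_subset, columns=cols),
    )
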