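"""Efficiency-corrected qPCR quantification and reference-gene diagnostics.

Implements the Pfaffl relative-quantification model: for each assay the
quantity recovered in a sample is ``E ** (Ct_cal - Ct)``, where ``E`` is the
per-cycle amplification efficiency (2.0 = perfect doubling) and ``Ct_cal``
a calibrator cycle threshold.  Target quantities are divided by a per-sample
normalization factor, the geometric mean of the reference-gene quantities
(the multi-reference convention introduced with the geNorm stability
framework).  The geNorm stability measure M and its stepwise exclusion
ranking are provided as a diagnostic for candidate reference genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import LINEAR, LOG2, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

MEAN_CALIBRATOR = "mean"


@dataclass
class QPCRDataset:
    """Cycle-threshold table plus per-assay efficiencies and reference set.

    ``ct`` is gene x sample.  ``efficiency`` maps each gene to its assay
    efficiency E in (1, 2]; genes absent from the mapping default to 2.0
    (perfect doubling) with a logged warning.  Technical replicates, if a
    sample appears as several columns with the same identifier, must be
    collapsed by :func:`collapse_replicates` before construction.
    """

    ct: pd.DataFrame
    efficiency: pd.Series | dict | None = None
    reference_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.ct, pd.DataFrame):
            self.ct = pd.DataFrame(self.ct)
        if self.ct.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers in Ct table")
        arr = self.ct.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr <= 0).any():
            bad = ~np.isfinite(arr) | (arr <= 0)
            rows, cols = np.nonzero(bad)
            cells = [(str(self.ct.index[r]), str(self.ct.columns[c]))
                     for r, c in zip(rows[:10], cols[:10])]
            raise ValidationError(f"Ct values must be finite and positive; offending cells: {cells}")
        eff = pd.Series(2.0, index=self.ct.index, dtype=float)
        if self.efficiency is not None:
            given = pd.Series(self.efficiency, dtype=float)
            unknown = [g for g in given.index if g not in self.ct.index]
            if unknown:
                raise ValidationError(f"efficiency given for genes absent from Ct table: {unknown}")
            eff.loc[given.index] = given
            missing = [g for g in self.ct.index if g not in given.index]
            if missing:
                logger.warning("no measured efficiency for %d assay(s) %s; defaulting to 2.0",
                               len(missing), missing[:5])
        else:
            logger.warning("no efficiencies supplied; defaulting all assays to 2.0")
        if ((eff <= 1.0) | (eff > 2.0)).any():
            bad = eff[(eff <= 1.0) | (eff > 2.0)].index.tolist()
            raise ValidationError(f"efficiencies must lie in (1, 2]: {bad}")
        self.efficiency = eff
        self.reference_genes = tuple(self.reference_genes)
        missing_refs = [g for g in self.reference_genes if g not in self.ct.index]
        if missing_refs:
            raise ValidationError(f"reference genes absent from Ct table: {missing_refs}")

    @property
    def genes(self) -> list[str]:
        return list(self.ct.index)

    @property
    def samples(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.ct.index if g not in self.reference_genes]


def collapse_replicates(ct: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical-replicate columns by arithmetic mean of Ct."""
    return ct.T.groupby(level=0, sort=False).mean().T


@dataclass
class GenormReport:
    """Stability ranking of candidate reference genes.

    ``m_values`` holds the initial stability measure M of every candidate
    (lower = more stable); ``exclusion_order`` the genes removed stepwise,
    least stable first, until two remain; ``stability_ranking`` all genes
    from most to least stable; ``pairwise_variation`` the advisory V(k/k+1)
    statistics for including a (k+1)-th reference gene.
    """

    m_values: pd.Series
    exclusion_order: list[str]
    stability_ranking: list[str]
    pairwise_variation: pd.Series | None = None


def pfaffl_relative_quantity(data: QPCRDataset,
                             calibrator: str = MEAN_CALIBRATOR) -> ExpressionMatrix:
    """Efficiency-corrected relative quantities, normalized per sample.

    For gene g and sample s the raw quantity is ``Q(g,s) = E_g ** (Ct_cal(g)
    - Ct(g,s))``.  The calibrator Ct is either the per-gene arithmetic mean
    over all samples (default) or the Ct of a named sample.  Target-gene rows
    are divided by the per-sample normalization factor NF(s), the geometric
    mean of Q over the reference genes; reference rows are retained
    unnormalized and listed in ``reference_genes`` of the result.
    """
    if len(data.reference_genes) == 0:
        raise ValidationError("reference gene set is empty")
    if data.ct.isna().any().any():
        na = data.ct.isna()
        rows, cols = np.nonzero(na.to_numpy())
        cells = [(str(data.ct.index[r]), str(data.ct.columns[c]))
                 for r, c in zip(rows[:10], cols[:10])]
        raise ValidationError(f"missing Ct values: {cells}")

    ct = data.ct.astype(float)
    if calibrator == MEAN_CALIBRATOR:
        ct_cal = ct.mean(axis=1)
    else:
        if calibrator not in ct.columns:
            raise ValidationError(f"calibrator sample {calibrator!r} not in Ct table")
        ct_cal = ct[calibrator]

    eff = data.efficiency.to_numpy()[:, None]
    delta = ct_cal.to_numpy()[:, None] - ct.to_numpy()
    quantity = pd.DataFrame(eff ** delta, index=ct.index, columns=ct.columns)

    refs = list(data.reference_genes)
    nf = np.exp(np.log(quantity.loc[refs]).mean(axis=0))
    nf.name = "NF"

    normalized = quantity.copy()
    targets = data.target_genes
    normalized.loc[targets] = quantity.loc[targets] / nf

    return ExpressionMatrix(normalized, scale=LINEAR,
                            provenance=f"pfaffl(calibrator={calibrator})",
                            nf=nf, reference_genes=tuple(refs))


def _m_values(logq: np.ndarray, genes: list[str]) -> pd.Series:
    """geNorm M for each gene: mean over other genes of the across-sample
    standard deviation of the pairwise log2 ratio."""
    n = len(genes)
    m = np.empty(n)
    for i in range(n):
        sds = [np.std(logq[i] - logq[j], ddof=1) for j in range(n) if j != i]
        m[i] = float(np.mean(sds))
    return pd.Series(m, index=genes, name="M")


def genorm_rank(matrix: ExpressionMatrix, genes=None) -> GenormReport:
    """Rank candidate reference genes by the geNorm stability measure.

    Candidates are ranked by M (mean pairwise log2-ratio standard deviation);
    the least stable gene is removed and M recomputed until two genes remain.
    Also reports the pairwise variation V(k/k+1) between normalization
    factors built from the k and k+1 most stable genes — the classical
    (advisory) criterion for how many reference genes are worth using.
    """
    if matrix.scale != LINEAR:
        raise ValidationError("genorm_rank requires linear-relative quantities")
    values = matrix.values if genes is None else matrix.subset_genes(genes).values
    cand = list(values.index)
    if len(cand) < 3:
        raise ValidationError(f"geNorm needs >=3 candidate genes, got {len(cand)}")
    if values.shape[1] < 2:
        raise ValidationError("geNorm needs >=2 samples")
    arr = values.to_numpy(dtype=float)
    if (arr <= 0).any() or np.isnan(arr).any():
        raise ValidationError("geNorm requires strictly positive, non-missing quantities")

    logq_full = np.log2(arr)
    m_initial = _m_values(logq_full, cand)

    remaining = list(cand)
    logq = logq_full.copy()
    exclusion: list[str] = []
    while len(remaining) > 2:
        m = _m_values(logq, remaining)
        # tie-break on gene name for a deterministic trace
        worst = min(m.index[m == m.max()])
        idx = remaining.index(worst)
        exclusion.append(worst)
        del remaining[idx]
        logq = np.delete(logq, idx, axis=0)

    ranking = list(remaining) + exclusion[::-1]

    # Pairwise variation: NF_k from the k most stable genes, V = sd of
    # log2(NF_k / NF_{k+1}) across samples, for k = 2 .. n-1.
    pv = None
    n = len(cand)
    if n >= 3:
        order = [cand.index(g) for g in ranking]
        vs, labels = [], []
        for k in range(2, n):
            nf_k = logq_full[order[:k]].mean(axis=0)
            nf_k1 = logq_full[order[:k + 1]].mean(axis=0)
            vs.append(float(np.std(nf_k - nf_k1, ddof=1)))
            labels.append(f"V{k}/{k + 1}")
        pv = pd.Series(vs, index=labels, name="V")

    return GenormReport(m_values=m_initial, exclusion_order=exclusion,
                        stability_ranking=ranking, pairwise_variation=pv)


def log_transform(matrix: ExpressionMatrix, base: float = 2.0) -> ExpressionMatrix:
    """Elementwise log of a linear-relative matrix (default base 2)."""
    if matrix.scale != LINEAR:
        raise ValidationError("log_transform expects a linear-relative matrix")
    arr = matrix.values.to_numpy(dtype=float)
    bad = (arr <= 0) & ~np.isnan(arr)
    if bad.any():
        rows, cols = np.nonzero(bad)
        cells = [(str(matrix.values.index[r]), str(matrix.values.columns[c]))
                 for r, c in zip(rows[:10], cols[:10])]
        raise ValidationError(f"non-positive values cannot be log-transformed: {cells}")
    out = np.log(arr) / np.log(base)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, scale=LOG2,
                            provenance=matrix.provenance + f" -> log{base:g}",
                            nf=matrix.nf, reference_genes=matrix.reference_genes)
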