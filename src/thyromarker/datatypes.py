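"""Shared containers for the FTC/FTA marker pipeline.

Two objects travel through every stage: a gene-by-sample expression matrix
with an explicit scale flag, and the per-sample clinical annotation
(diagnosis, oncocytic status, covariates).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIAGNOSES = ("FTC", "FTA")

LINEAR = "linear"
LOG2 = "log2"


class ValidationError(ValueError):
    """Raised when an input object violates its documented invariants."""


@dataclass
class ExpressionMatrix:
    """Gene x sample value table with an explicit scale.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.
    scale
        ``"linear"`` for relative quantities (strictly positive) or
        ``"log2"`` for log2-transformed values.
    provenance
        Free-text note on how the matrix was produced.
    nf
        Optional per-sample normalization factor recorded by the
        normalization step (geometric mean of reference-gene quantities).
    reference_genes
        Genes whose rows were kept unnormalized by the normalization step.
    """

    values: pd.DataFrame
    scale: str = LINEAR
    provenance: str = ""
    nf: pd.Series | None = None
    reference_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValidationError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups}")
        if self.scale == LINEAR:
            arr = self.values.to_numpy(dtype=float)
            bad = (arr <= 0) & ~np.isnan(arr)
            if bad.any():
                cells = _cells(self.values, bad)
                raise ValidationError(f"linear-scale values must be strictly positive; offending cells: {cells}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes not present in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.scale, self.provenance,
                                self.nf, self.reference_genes)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not present in matrix: {missing}")
        nf = self.nf.loc[list(samples)] if self.nf is not None else None
        return ExpressionMatrix(self.values[list(samples)], self.scale, self.provenance,
                                nf, self.reference_genes)


def _cells(df: pd.DataFrame, mask: np.ndarray, limit: int = 10) -> list[tuple[str, str]]:
    rows, cols = np.nonzero(mask)
    return [(str(df.index[r]), str(df.columns[c])) for r, c in zip(rows[:limit], cols[:limit])]


@dataclass
class SampleAnnotation:
    """Per-sample clinical annotation.

    ``table`` is indexed by sample id and carries at least a ``diagnosis``
    column (FTC = follicular carcinoma, FTA = follicular adenoma).  An
    ``oncocytic`` boolean column marks Hurthle-cell tumours; optional columns
    (``tier``, ``age``, ``sex``, ``ras_status``) are passed through untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "diagnosis" not in self.table.columns:
            raise ValidationError("sample annotation requires a 'diagnosis' column")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        bad = set(self.table["diagnosis"]) - set(DIAGNOSES)
        if bad:
            raise ValidationError(f"diagnosis must be one of {DIAGNOSES}; found {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def diagnosis(self) -> pd.Series:
        return self.table["diagnosis"]

    @property
    def oncocytic(self) -> pd.Series:
        if "oncocytic" not in self.table.columns:
            raise ValidationError("sample annotation has no 'oncocytic' column")
        return self.table["oncocytic"].astype(bool)

    def aligned_to(self, samples) -> "SampleAnnotation":
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples missing from annotation: {missing}")
        return SampleAnnotation(self.table.loc[list(samples)])

    def subset(self, samples) -> "SampleAnnotation":
        return self.aligned_to(samples)
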