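"""Readers and writers for the pipeline's tabular artifacts.

One dialect everywhere: tab-separated UTF-8 text with '.' decimals, gene
ids in the first column and sample ids in the header row for matrices.
Writers use 6-significant-digit floats and stable column orders so a rerun
on the same input is byte-identical.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import CVResult, MetricsReport
from .datatypes import ExpressionMatrix, SampleAnnotation, ValidationError
from .diffexpr import DEResult, OutlierReport
from .meta import IdMap, StudyGeneListCollection, StudyRecord, VoteTable
from .qpcr import QPCRDataset

_NA_STRINGS = {"", "NA", "NaN", "nan"}

FLOAT_FORMAT = "%.6g"


def _parse_table(path) -> tuple[list[str], list[tuple[int, str, list[str]]]]:
    """Split a TSV into header and (line_number, row_id, cells) rows,
    enforcing rectangular shape."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    width = len(header)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != width:
            raise ValidationError(
                f"{path}:{lineno}: ragged row ({len(cells)} fields, expected {width})")
        rows.append((lineno, cells[0], cells[1:]))
    return header[1:], rows


def _numeric_frame(path, index_name: str = "gene") -> pd.DataFrame:
    samples, rows = _parse_table(path)
    seen = {}
    data, index = [], []
    n_missing = 0
    for lineno, rid, cells in rows:
        if rid in seen:
            raise ValidationError(
                f"{path}:{lineno}: duplicate {index_name} id {rid!r} (first at line {seen[rid]})")
        seen[rid] = lineno
        values = []
        for col, cell in zip(samples, cells):
            if cell.strip() in _NA_STRINGS:
                values.append(np.nan)
                n_missing += 1
                continue
            try:
                values.append(float(cell))
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column {col!r}") from None
        index.append(rid)
        data.append(values)
    frame = pd.DataFrame(data, index=pd.Index(index, name=index_name), columns=samples)
    frame.attrs["n_missing"] = n_missing
    return frame


def read_expression_table(path, scale: str = "log2",
                          orientation: str = "genes_by_samples") -> ExpressionMatrix:
    """Read a gene x sample expression TSV.

    ``orientation="samples_by_genes"`` transposes after reading.  Missing
    cells (empty or NA) are preserved as NaN and counted in
    ``values.attrs["n_missing"]``.
    """
    frame = _numeric_frame(path, index_name="gene")
    if orientation == "samples_by_genes":
        frame = frame.T
    elif orientation != "genes_by_samples":
        raise ValidationError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(frame, scale=scale, provenance=f"read:{path}")


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                         index_label="gene", lineterminator="\n")


def read_sample_sheet(path) -> SampleAnnotation:
    """Read the per-sample annotation TSV (sample_id, diagnosis, ...)."""
    table = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    if "oncocytic" in table.columns:
        table["oncocytic"] = table["oncocytic"].str.lower().map(
            {"true": True, "false": False, "1": True, "0": False})
        if table["oncocytic"].isna().any():
            raise ValidationError(f"{path}: oncocytic column must be boolean")
    for col in ("age",):
        if col in table.columns:
            table[col] = pd.to_numeric(table[col])
    return SampleAnnotation(table)


def write_sample_sheet(annot: SampleAnnotation, path) -> None:
    annot.table.to_csv(path, sep="\t", index_label="sample_id", lineterminator="\n")


def read_qpcr_dataset(ct_path, efficiency_path=None, reference_genes=()) -> QPCRDataset:
    """Assemble a QPCRDataset from a Ct TSV and an optional efficiency TSV
    (columns: gene, efficiency)."""
    ct = _numeric_frame(ct_path, index_name="gene")
    eff = None
    if efficiency_path is not None:
        table = pd.read_csv(efficiency_path, sep="\t")
        if not {"gene", "efficiency"} <= set(table.columns):
            raise ValidationError(f"{efficiency_path}: need columns gene, efficiency")
        eff = table.set_index("gene")["efficiency"].astype(float)
    return QPCRDataset(ct=ct, efficiency=eff, reference_genes=tuple(reference_genes))


def write_qpcr_dataset(data: QPCRDataset, ct_path, efficiency_path=None) -> None:
    data.ct.to_csv(ct_path, sep="\t", float_format=FLOAT_FORMAT,
                   index_label="gene", lineterminator="\n")
    if efficiency_path is not None:
        eff = data.efficiency.rename("efficiency").rename_axis("gene").reset_index()
        eff.to_csv(efficiency_path, sep="\t", index=False,
                   float_format=FLOAT_FORMAT, lineterminator="\n")


def read_study_lists(path) -> StudyGeneListCollection:
    """Read per-study gene lists (study_id, raw_id, namespace, direction)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"study_id", "raw_id", "namespace", "direction"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = [StudyRecord(study_id=r.study_id, raw_id=r.raw_id,
                           namespace=r.namespace, direction=r.direction)
               for r in table.itertuples()]
    return StudyGeneListCollection(records=records, canonical=False)


def write_study_lists(collection: StudyGeneListCollection, path) -> None:
    rows = [{"study_id": r.study_id, "raw_id": r.raw_id,
             "namespace": r.namespace, "direction": r.direction}
            for r in collection.records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_idmap(path) -> IdMap:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return IdMap(table)


def write_idmap(idmap: IdMap, path) -> None:
    idmap.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


# --------------------------------------------------------------------------
# Result writers (stable column order, 6 significant digits)

_DE_COLUMNS = ["mean_ftc", "mean_fta", "fold_change", "t_stat", "t_p", "t_q",
               "anova_F", "anova_p", "anova_q", "mean_overall", "var_overall",
               "n_ftc", "n_fta"]
_CV_COLUMNS = ["true_label", "prob_ftc", "predicted", "alpha", "n_genes", "fallback"]


def write_results(result, path) -> None:
    """Write a DEResult, VoteTable, CVResult, MetricsReport or OutlierReport
    as a TSV with a stable layout."""
    if isinstance(result, DEResult):
        cols = [c for c in _DE_COLUMNS if c in result.table.columns]
        cols += [c for c in result.table.columns if c not in cols]
        result.table[cols].to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                                  index_label="gene", lineterminator="\n")
    elif isinstance(result, VoteTable):
        t = result.table.copy()
        t["studies"] = [",".join(s) for s in t["studies"]]
        t["directions"] = [",".join(d) for d in t["directions"]]
        t["consensus_direction"] = t["consensus_direction"].fillna("discordant")
        cols = ["symbol", "count", "consensus_direction", "concordant",
                "studies", "directions"]
        t[cols].to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")
    elif isinstance(result, CVResult):
        result.per_sample[_CV_COLUMNS].to_csv(
            path, sep="\t", float_format=FLOAT_FORMAT,
            index_label="sample", lineterminator="\n")
    elif isinstance(result, MetricsReport):
        result.table.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                            index_label="metric", lineterminator="\n")
    elif isinstance(result, OutlierReport):
        t = result.per_gene.copy()
        flagged = {}
        for sample, gene in result.flags:
            flagged.setdefault(gene, []).append(sample)
        t["flagged_samples"] = [",".join(flagged.get(g, [])) for g in t.index]
        t.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                 index_label="gene", lineterminator="\n")
    else:
        raise ValidationError(f"write_results does not handle {type(result).__name__}")


def read_cv_result(path) -> CVResult:
    """Read back a CVResult per-sample table written by :func:`write_results`."""
    t = pd.read_csv(path, sep="\t").set_index("sample")
    t["fallback"] = t["fallback"].astype(bool)
    return CVResult(per_sample=t, alpha_grid=())


# --------------------------------------------------------------------------
# Configuration

@dataclass
class PipelineConfig:
    """Declarative run configuration; CLI flags override these values."""

    reference_genes: tuple = ("EIF3A", "EIF5", "HADHA")
    outlier_k: float = 6.0
    alpha_grid: tuple = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05)
    fdr_cutoff: float = 0.05
    marker_min_mean: float = 4.5
    marker_var_percentile: float = 20.0
    marker_p_primary: float = 0.001
    marker_min_fold: float = 1.5
    marker_p_secondary: float = 0.05
    priors: str = "empirical"
    seed: int = 0

    def __post_init__(self):
        if self.outlier_k < 0:
            raise ValidationError("outlier_k must be >= 0")
        if not 0 < self.fdr_cutoff <= 1:
            raise ValidationError("fdr_cutoff must lie in (0, 1]")
        if not all(0 < a <= 1 for a in self.alpha_grid):
            raise ValidationError("alpha grid values must lie in (0, 1]")
        if int(self.seed) != self.seed:
            raise ValidationError("seed must be an integer")

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a YAML config file, applying keyword overrides."""
    values = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            values = yaml.safe_load(fh) or {}
        unknown = set(values) - set(PipelineConfig.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    values.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("reference_genes", "alpha_grid"):
        if key in values and not isinstance(values[key], tuple):
            values[key] = tuple(values[key])
    return PipelineConfig(**values)
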