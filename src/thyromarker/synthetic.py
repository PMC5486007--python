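"""Synthetic data generators with known ground truth.

Three generators mirror the three kinds of input the pipeline consumes:

* a qPCR cycle-threshold dataset emulating an FFPE validation cohort
  (two diagnosis groups, a handful of target genes with programmed linear
  fold changes, near-constant reference genes, an oncocytic covariate, and
  optional planted extreme-outlier spikes);
* a log2 expression matrix (microarray-like) with a programmed set of
  informative genes;
* a multi-study gene-list collection with planted vote counts and
  direction patterns for the meta-analysis machinery.

Noise is Gaussian on the Ct scale, hence log-normal on quantities — the
standard error model for qPCR.  Every generator is a pure function of its
parameters plus one master seed; sub-streams are derived from the master
seed by fixed offsets so adding a generator never perturbs earlier streams.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import LOG2, ExpressionMatrix, SampleAnnotation, ValidationError
from .meta import StudyGeneListCollection, StudyRecord
from .qpcr import QPCRDataset

# Seed offsets for independent sub-streams (fixed; see module docstring).
_OFF_BASELINE = 101
_OFF_ONCOCYTIC = 211
_OFF_NOISE = 307
_OFF_EXPR = 401
_OFF_STUDIES = 503

#: Default per-target-gene linear FTC/FTA fold changes: the 15 markers that
#: amplified in the FFPE validation cohort (carcinoma-vs-adenoma ratios
#: between 0.48 and 1.49).
DEFAULT_FOLD_CHANGES = {
    "CPQ": 0.49, "PLVAP": 0.51, "TFF3": 0.48, "ACVRL1": 0.58,
    "ZFYVE21": 0.69, "FAM189A2": 0.68, "CLEC3B": 0.75, "ZMYND11": 0.81,
    "LIMK2": 0.79, "DIP2B": 0.86, "MAFB": 0.89, "GDF15": 1.49,
    "CKS2": 1.07, "ASNS": 1.02, "EGR2": 0.97,
}

DEFAULT_REFERENCE_GENES = ("EIF3A", "EIF5", "HADHA")


@dataclass
class QPCRSimParams:
    """Parameters of the simulated qPCR validation cohort.

    Defaults reproduce the emulated study design: 31 carcinomas vs 40
    adenomas, 15 target genes with the fold changes above, 3 stable
    reference genes, oncocytic tumours in 61.3% of FTC and 15% of FTA,
    and Ct noise of 0.25 cycles.
    """

    n_ftc: int = 31
    n_fta: int = 40
    fold_changes: dict = field(default_factory=lambda: dict(DEFAULT_FOLD_CHANGES))
    reference_genes: tuple = DEFAULT_REFERENCE_GENES
    oncocytic_frac_ftc: float = 0.613
    oncocytic_frac_fta: float = 0.15
    oncocytic_effect: dict = field(default_factory=dict)  # per-gene log2 shift
    ct_noise_sd: float = 0.25
    efficiencies: dict = field(default_factory=dict)  # per-assay E, default 2.0
    outlier_spec: list = field(default_factory=list)  # (sample_id, gene, ct_shift)
    seed: int = 0

    def validate(self) -> None:
        if self.n_ftc < 2 or self.n_fta < 2:
            raise ValidationError("n_ftc and n_fta must each be >= 2")
        if not self.fold_changes:
            raise ValidationError("fold_changes must name at least one target gene")
        if any(fc <= 0 for fc in self.fold_changes.values()):
            raise ValidationError("fold_changes must be strictly positive")
        if len(self.reference_genes) < 1:
            raise ValidationError("reference_genes must be non-empty")
        for frac_name in ("oncocytic_frac_ftc", "oncocytic_frac_fta"):
            frac = getattr(self, frac_name)
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{frac_name} must lie in [0, 1]")
        if self.ct_noise_sd < 0:
            raise ValidationError("ct_noise_sd must be >= 0")
        genes = set(self.fold_changes) | set(self.reference_genes)
        for g, e in self.efficiencies.items():
            if g not in genes:
                raise ValidationError(f"efficiency given for unknown gene {g!r}")
            if not 1.0 < e <= 2.0:
                raise ValidationError(f"efficiencies must lie in (1, 2]; gene {g!r} has {e}")
        for sample, gene, _shift in self.outlier_spec:
            if gene not in genes:
                raise ValidationError(f"outlier_spec references unknown gene {gene!r}")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    true_fold_change: pd.Series | None = None
    true_de_flag: pd.Series | None = None
    true_outlier_samples: tuple = ()
    planted_votes: dict = field(default_factory=dict)  # gene -> (count, directions)


def _sample_ids(n_ftc: int, n_fta: int) -> tuple[list[str], list[str]]:
    ftc = [f"FTC{i + 1:02d}" for i in range(n_ftc)]
    fta = [f"FTA{i + 1:02d}" for i in range(n_fta)]
    return ftc, fta


def simulate_qpcr_dataset(params: QPCRSimParams):
    """Simulate a Ct table for a two-group qPCR cohort.

    The Ct of gene g in sample s is ``baseline_g - log_E(q(g, s)) + noise``,
    where the true relative quantity ``q`` is the programmed fold change for
    FTC samples (1 for FTA and for reference genes), times the per-gene
    oncocytic shift when the sample is oncocytic.  Per-gene baselines are
    drawn uniform in [20, 30] (they cancel in efficiency-corrected ratios).
    Planted outlier Ct shifts are applied last.

    Returns ``(QPCRDataset, SampleAnnotation, GroundTruth)``.
    """
    params.validate()
    targets = list(params.fold_changes)
    refs = list(params.reference_genes)
    genes = targets + refs
    ftc_ids, fta_ids = _sample_ids(params.n_ftc, params.n_fta)
    samples = ftc_ids + fta_ids
    is_ftc = np.array([1] * params.n_ftc + [0] * params.n_fta, dtype=bool)

    rng_base = np.random.default_rng(params.seed + _OFF_BASELINE)
    rng_onc = np.random.default_rng(params.seed + _OFF_ONCOCYTIC)
    rng_noise = np.random.default_rng(params.seed + _OFF_NOISE)

    baseline = rng_base.uniform(20.0, 30.0, size=len(genes))

    onc = np.empty(len(samples), dtype=bool)
    onc[is_ftc] = rng_onc.random(params.n_ftc) < params.oncocytic_frac_ftc
    onc[~is_ftc] = rng_onc.random(params.n_fta) < params.oncocytic_frac_fta

    fc = np.array([params.fold_changes[g] for g in targets] + [1.0] * len(refs))
    onc_shift = np.array([params.oncocytic_effect.get(g, 0.0) for g in genes])

    # log2 true quantity per gene x sample
    log2q = np.outer(np.log2(fc), is_ftc.astype(float))
    log2q += np.outer(onc_shift, onc.astype(float))

    eff = np.array([params.efficiencies.get(g, 2.0) for g in genes])
    ct = baseline[:, None] - log2q / np.log2(eff)[:, None]
    if params.ct_noise_sd > 0:
        ct = ct + rng_noise.normal(0.0, params.ct_noise_sd, size=ct.shape)

    ct = pd.DataFrame(ct, index=genes, columns=samples)
    outlier_samples = []
    for sample, gene, shift in params.outlier_spec:
        if sample not in ct.columns:
            raise ValidationError(f"outlier_spec references unknown sample {sample!r}")
        ct.loc[gene, sample] += shift
        outlier_samples.append(sample)

    dataset = QPCRDataset(ct=ct, efficiency=pd.Series(eff, index=genes),
                          reference_genes=tuple(refs))
    annot = SampleAnnotation(pd.DataFrame(
        {"diagnosis": ["FTC"] * params.n_ftc + ["FTA"] * params.n_fta,
         "oncocytic": onc, "tier": "validation"},
        index=pd.Index(samples, name="sample_id")))
    truth = GroundTruth(
        true_fold_change=pd.Series(fc, index=genes),
        true_de_flag=pd.Series([params.fold_changes[g] != 1.0 for g in targets]
                               + [False] * len(refs), index=genes),
        true_outlier_samples=tuple(dict.fromkeys(outlier_samples)),
    )
    return dataset, annot, truth


def simulate_expression_matrix(n_per_group=(26, 26), n_genes: int = 1000,
                               n_informative: int = 50, effect_log2: float = 1.0,
                               noise_sd: float = 1.0, seed: int = 0):
    """Simulate a log2-scale (microarray-like) expression matrix.

    The first ``n_informative`` genes are shifted by ``effect_log2`` in the
    FTC group (alternating sign); the rest are null.  Per-gene baselines are
    uniform in [4, 12] on the log2 scale, noise is Gaussian.

    Returns ``(ExpressionMatrix, SampleAnnotation, GroundTruth)``.
    """
    if n_informative > n_genes:
        raise ValidationError("n_informative must be <= n_genes")
    n_ftc, n_fta = n_per_group
    if n_ftc < 2 or n_fta < 2:
        raise ValidationError("need >= 2 samples per group")
    rng = np.random.default_rng(seed + _OFF_EXPR)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    ftc_ids, fta_ids = _sample_ids(n_ftc, n_fta)
    samples = ftc_ids + fta_ids
    is_ftc = np.array([1.0] * n_ftc + [0.0] * n_fta)

    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    effect = np.zeros(n_genes)
    signs = np.where(np.arange(n_informative) % 2 == 0, 1.0, -1.0)
    effect[:n_informative] = effect_log2 * signs

    values = baseline[:, None] + np.outer(effect, is_ftc)
    values = values + rng.normal(0.0, noise_sd, size=values.shape)
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                              scale=LOG2, provenance=f"simulate_expression_matrix(seed={seed})")
    annot = SampleAnnotation(pd.DataFrame(
        {"diagnosis": ["FTC"] * n_ftc + ["FTA"] * n_fta, "oncocytic": False,
         "tier": "primary"},
        index=pd.Index(samples, name="sample_id")))
    truth = GroundTruth(
        true_fold_change=pd.Series(2.0 ** effect, index=genes),
        true_de_flag=pd.Series(effect != 0.0, index=genes),
    )
    return matrix, annot, truth


def simulate_study_collection(n_studies: int = 14, universe_size: int = 100,
                              overlap_spec: dict | None = None, seed: int = 0
                              ) -> tuple[StudyGeneListCollection, GroundTruth]:
    """Simulate per-study differential gene lists with planted vote counts.

    ``overlap_spec`` maps a gene name to either ``(count, direction)`` — the
    gene appears in ``count`` studies, all with that direction — or
    ``(count, [directions])`` with one direction per contributing study.
    Unplanted genes from the universe are each assigned to exactly one
    random study with a random direction, so their vote count is 1.
    """
    if n_studies < 1:
        raise ValidationError("n_studies must be >= 1")
    overlap_spec = dict(overlap_spec or {})
    for gene, (count, directions) in overlap_spec.items():
        if count > n_studies:
            raise ValidationError(f"planted count {count} for {gene!r} exceeds n_studies")
        if isinstance(directions, (list, tuple)) and len(directions) != count:
            raise ValidationError(f"{gene!r}: need one direction per contributing study")
    rng = np.random.default_rng(seed + _OFF_STUDIES)
    study_ids = [f"S{i + 1:02d}" for i in range(n_studies)]
    records: list[StudyRecord] = []

    planted = {}
    for gene, (count, directions) in sorted(overlap_spec.items()):
        if not isinstance(directions, (list, tuple)):
            directions = [directions] * count
        chosen = rng.choice(n_studies, size=count, replace=False)
        for study_idx, direction in zip(sorted(chosen), directions):
            records.append(StudyRecord(study_id=study_ids[study_idx], raw_id=gene,
                                       namespace="symbol", direction=direction,
                                       gene_id=gene, symbol=gene))
        planted[gene] = (count, tuple(directions))

    n_fill = universe_size - len(overlap_spec)
    for i in range(max(n_fill, 0)):
        gene = f"BG{i + 1:04d}"
        study_idx = int(rng.integers(n_studies))
        direction = "up" if rng.random() < 0.5 else "down"
        records.append(StudyRecord(study_id=study_ids[study_idx], raw_id=gene,
                                   namespace="symbol", direction=direction,
                                   gene_id=gene, symbol=gene))
        planted[gene] = (1, (direction,))

    collection = StudyGeneListCollection(records=records, canonical=True)
    return collection, GroundTruth(planted_votes=planted)
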