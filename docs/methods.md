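# Methods

## Problem and data model

The pipeline discriminates follicular thyroid carcinoma (FTC) from
follicular adenoma (FTA) using gene-expression measurements.  Two data
modalities are handled: qRT-PCR cycle-threshold (Ct) tables with per-assay
amplification efficiencies, typical of FFPE validation cohorts, and
already-normalized log2 expression matrices, typical of microarray
discovery cohorts.  Samples carry a diagnosis (FTC/FTA) and a binary
oncocytic (Hürthle-cell) flag; oncocytic tumours have a distinct
expression profile and are treated as a nuisance covariate, not excluded.

## qPCR relative quantification

For gene *g* with amplification efficiency *E<sub>g</sub>* ∈ (1, 2]
(2.0 = perfect doubling per cycle), the relative quantity in sample *s* is

> Q(g, s) = E<sub>g</sub><sup>Ct_cal(g) − Ct(g, s)</sup>

The calibrator Ct is, by default, the per-gene arithmetic mean over all
samples: the study this pipeline reconstructs names no calibrator sample,
and a mean calibrator avoids privileging any one specimen.  The choice only
rescales each gene's row by a constant and cancels in all group contrasts
(tested).  Target quantities are divided by the per-sample normalization
factor NF(s), the geometric mean of the reference-gene quantities — the
multi-reference convention of the geNorm framework, which is the standard
reconciliation when the Pfaffl ratio (defined for a single reference) is
used with several reference genes.  Reference rows are retained
unnormalized and flagged, since dividing a reference by an NF containing
itself is not meaningful.  Technical replicates are collapsed by arithmetic
mean of Ct before any ratio.  Assays without a measured efficiency default
to 2.0 with a logged warning.

geNorm ranks candidate reference genes by the stability measure
M(g) = mean over other candidates *h* of SD across samples of
log2(Q(g,·)/Q(h,·)); the least stable gene is removed and M recomputed
until two remain.  Because the reconstructed workflow fixed its three
reference genes a priori, geNorm here is a diagnostic ranking, not an
automatic selector; the pairwise-variation statistic V(k/k+1) (literature
cutoff 0.15) is reported as advisory only.  Ties in M are broken
alphabetically for a deterministic trace.

## Outlier rule and differential expression

A cell is an extreme outlier when its expression exceeds Q3 + k·IQR for
its gene (default k = 6); quartiles use linear interpolation between order
statistics — documented deliberately, since the quantile convention feeds a
hard exclusion rule.  A sample flagged in ≥ 1 gene is listed for exclusion
(the minimal reading of "extreme in two distinct genes" describing two
excluded samples); the report is advisory and the caller applies it.

Per-gene testing uses the classical equal-variance Student *t*-test on
log2 values (a Welch switch is provided), with the linear fold change
2^(mean_FTC − mean_FTA) and Benjamini–Hochberg step-up adjustment.  The
oncocytic adjustment is an additive two-factor linear model
(expression ~ malignancy + oncocytic) with the malignancy *p*-value from
Type II sums of squares — no interaction term, matching a "two factors"
design, and Type II because the oncocytic margin is heavily unbalanced
(≈ 61% of FTC vs 15% of FTA).  BH is applied separately per family
(*t*-test family; ANOVA family), mirroring reporting conventions with two
adjusted columns.  All-missing genes (failed amplification in FFPE) are
dropped and reported, never imputed.  Confounded designs (oncocytic level
aliased with diagnosis) are rejected with an error.

The two-set marker filter for microarray screens retains genes passing all
primary-set criteria (mean log2 expression > 4.5, gene variance above the
20th percentile of gene variances, raw *t*-test *p* < 0.001, fold change
≥ 1.5 in either direction) *and* the secondary-set criterion (raw *p* <
0.05).  PCA projection centers genes and uses the SVD; component signs are
fixed by making the largest-|loading| gene positive.

## Vote-counting meta-analysis

Per-study differential gene lists are harmonized to canonical Entrez-style
ids through a static mapping snapshot (never a live lookup, for
reproducibility).  Within a study, aliases of one gene collapse to a single
record; a within-study direction conflict (same gene up and down) makes the
gene unusable for that study and both records are dropped with a log line —
the source literature is silent on this case.  Votes are tallied per gene;
direction is binary relative to FTC (up = higher in carcinoma); a gene is
concordant iff all reporting studies agree, and discordant genes never
receive a consensus direction.  Ordering is deterministic: count
descending, then canonical id ascending (numeric when possible).
`thyromarker.corpus` bundles the 50 concordant multi-study genes of the
published 14-study corpus with their supporting studies; genes reported
once, or discordantly, are not recoverable from the published table, so
whole-universe tallies (the 600-gene list) are out of reach by design.

## DLDA and doubly nested LOOCV

DLDA models class *c* as a Gaussian with per-gene means μ<sub>cg</sub> and
a shared diagonal covariance: pooled within-class variances with
denominator (n − 2), floored at 1e-8 × their median to avoid degeneracy
from constant genes.  Priors default to empirical class proportions (the
cohort is unbalanced); an equal-prior option exists because the original
implementation's convention is not documented.  The posterior
P(FTC | x) is computed in log space.

Gene selection keeps genes with raw *t*-test *p* < α; if none pass, the
single smallest-*p* gene is used and flagged, so a model always exists.
The α grid defaults to {0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05}.
Validation is doubly nested leave-one-out: for each held-out sample the
inner leave-one-out loop on the remaining n − 1 scores every α with gene
selection recomputed inside every inner training fold; the α maximizing
inner accuracy wins, ties going to the smallest α (most parsimonious gene
set, favouring stability).  Genes are then reselected on all n − 1 at that
α, DLDA is trained, and the held-out probability recorded.  The held-out
sample therefore never touches selection, tuning, or training — verified
by tests that corrupt the held-out sample and check the fold's tuning is
unchanged.

The inner loop is computed with leave-one-out sufficient-statistic updates
vectorised over held-out samples rather than literal refitting; a test
verifies exact agreement (≤ 1e-12) with a naive nested refit.  Suite-level
simulations use 15-gene, 70-sample cohorts and 100–200 replicates, sizes
at which each property estimate is stable to well under its tolerance.

Classification uses the 50% posterior cutoff.  Accuracy, sensitivity and
specificity carry exact Clopper–Pearson 95% intervals (beta quantiles);
this interval type uniquely reproduces all published interval pairs for
this cohort, which Wilson and normal approximations do not — an inference
from the numbers, not a documented statement.  Reported percentages are
rounded half-away-from-zero to whole percent; unrounded values are
retained.  Subgroup metrics (e.g. oncocytic vs non-oncocytic accuracy) are
a stratification option.  The ROC curve sweeps thresholds at the distinct
observed probabilities with (0,0)/(1,1) sentinels; trapezoidal AUC equals
the Mann–Whitney statistic P(score_FTC > score_FTA) + ½ P(tie) (tested to
1e-12).

### Null behaviour of the nested procedure

On label-permuted null data the selected genes are pure noise, and the
evidence contribution of an overfit selected gene (apparent |t| ≈ 3–4)
dominates the small empirical-prior log-odds (≈ −0.32 for 29 vs 40).  Mean
null LOOCV accuracy therefore sits at chance (≈ 50%), not at the
majority-class rate (57%); the tests assert the chance band and, in
particular, the absence of any optimistic bias — the signature of
information leaking from the held-out sample would be null accuracy well
above it.

## Synthetic-data generators

The qPCR generator emulates an FFPE validation cohort: 31 FTC vs 40 FTA;
15 target genes with programmed linear fold changes 0.48–1.49 (the
validated marker panel's values, e.g. CPQ 0.49, PLVAP 0.51, TFF3 0.48);
3 stable reference genes; oncocytic status drawn Bernoulli per class
(61.3% of FTC, 15% of FTA); per-gene baseline Ct uniform in [20, 30]
(arbitrary; cancels in Pfaffl ratios); Gaussian noise on the Ct scale
(default SD 0.25 cycles — per-gene Ct variance for FFPE material is not
published, so this default is chosen, not fitted), hence log-normal noise
on quantities; optional planted outlier Ct shifts applied last.  One
master seed; sub-generators derive child streams by fixed offsets so
adding a generator never perturbs earlier streams.

What the generator does *not* model: biological between-tumour
heterogeneity (only technical Ct noise), RNA degradation gradients,
amplification dropout, or correlated gene modules.  Consequently synthetic
cohorts at the default noise are close to linearly separable and the
classifier reaches near-100% LOOCV accuracy on them — passing tests
demonstrate correctness of the machinery and calibration of its null
behaviour, not that real FFPE material supports that accuracy (the
realistic ceiling reported for this problem is ≈ 80%).

The expression-matrix generator plants `n_informative` genes shifted by
`effect_log2` (alternating sign) on log2-uniform baselines; the study-list
generator realizes exact planted vote counts and direction patterns, with
unplanted universe genes assigned to exactly one study each.

## Numerical and interface choices

* TSV (UTF-8, '.' decimal) is the single I/O dialect; floats at 6
  significant digits; writers are byte-stable across reruns.
* Gene identifiers are opaque strings at the I/O boundary; Entrez-style
  integer ids appear only inside the meta-analysis after harmonization.
* Errors are raised early and name the offending field, gene, sample or
  file line; non-positive values are never silently floored before a log.
* Standard statistical steps go through scipy/statsmodels (t-tests, OLS +
  Type II ANOVA, BH adjustment, beta-quantile intervals); the pipeline's
  own algorithms (Pfaffl/geNorm, the outlier rule, vote counting, DLDA,
  nested LOOCV, ROC/AUC, PCA projection) are implemented here and checked
  against independent oracles in the tests.

## Known limitations

* The bundled corpus snapshot covers only the concordant multi-study
  genes; single-study and discordant genes are not reconstructable.
* geNorm is diagnostic; the pipeline does not auto-select the number of
  reference genes.
* The ANOVA adjustment is additive-only; malignancy × oncocytic
  interactions are not modelled (and would be weakly identified at these
  group sizes).
* Raw microarray preprocessing (probe-level normalization, array QC) is
  out of scope; the pipeline consumes already-normalized matrices.
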