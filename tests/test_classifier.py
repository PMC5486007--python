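"""DLDA, nested leave-one-out cross-validation, exact CIs and ROC."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_annotation, make_matrix
from thyromarker.classify import (CVResult, DEFAULT_ALPHA_GRID, _ttest_pvals,
                                  clopper_pearson, confusion_metrics, dlda_posterior,
                                  dlda_train, nested_loocv, roc_auc,
                                  select_genes_ttest)
from thyromarker.datatypes import LOG2, ExpressionMatrix, ValidationError


def _cv_from_probs(probs, labels):
    per_sample = pd.DataFrame({
        "true_label": labels,
        "prob_ftc": probs,
        "predicted": ["FTC" if p > 0.5 else "FTA" for p in probs],
        "alpha": 0.05, "n_genes": 1, "fallback": False,
    }, index=[f"s{i}" for i in range(len(probs))])
    return CVResult(per_sample=per_sample, alpha_grid=(0.05,))


class TestGeneSelection:
    def test_alpha_one_selects_everything(self, two_group_matrix):
        matrix, annot = two_group_matrix
        sel = select_genes_ttest(matrix, annot, alpha=1.0)
        assert sel.genes == matrix.genes and not sel.fallback

    def test_fallback_to_single_best_gene(self, two_group_matrix):
        matrix, annot = two_group_matrix
        sel = select_genes_ttest(matrix, annot, alpha=1e-30)
        assert len(sel.genes) == 1 and sel.fallback
        x = matrix.values.to_numpy().T
        y = (annot.diagnosis == "FTC").to_numpy()
        assert sel.genes[0] == matrix.genes[int(np.argmin(_ttest_pvals(x, y)))]


class TestDlda:
    def test_hand_computed_two_gene_model(self):
        values = np.array([[1.0, 3.0, 5.0, 7.0],
                           [2.0, 2.0, 4.0, 4.0]])
        matrix = make_matrix(values)
        annot = make_annotation(2, 2)
        model = dlda_train(matrix, annot)
        assert model.mu.loc["FTC"].tolist() == [2.0, 2.0]
        assert model.mu.loc["FTA"].tolist() == [6.0, 4.0]
        # pooled SS: gene1 (1-2)^2*2 + (5-6)^2*2 = 4; gene2 = 0; denominator n-2 = 2
        assert model.sigma2["g1"] == pytest.approx(2.0)
        # gene2 has zero pooled variance: floored at 1e-8 x median (median of
        # pooled variances {2, 0} is 1)
        assert model.sigma2["g2"] == pytest.approx(1e-8)
        assert model.priors == {"FTC": 0.5, "FTA": 0.5}

    def test_single_class_errors(self):
        matrix = make_matrix(np.ones((2, 4)) + np.arange(4))
        with pytest.raises(ValidationError, match="both classes"):
            dlda_train(matrix, make_annotation(4, 0))

    def test_duplicating_samples_preserves_means(self, two_group_matrix):
        matrix, annot = two_group_matrix
        model = dlda_train(matrix, annot)
        doubled = pd.concat([matrix.values, matrix.values.add_suffix("_b", axis=1)],
                            axis=1)
        annot2 = annot.table.copy()
        annot2b = annot2.rename(index=lambda s: s + "_b")
        from thyromarker.datatypes import SampleAnnotation
        big = SampleAnnotation(pd.concat([annot2, annot2b]))
        model2 = dlda_train(ExpressionMatrix(doubled, scale=LOG2), big)
        pd.testing.assert_frame_equal(model.mu, model2.mu)
        # variance changes only through the (n-2) denominator
        n = matrix.values.shape[1]
        expected = model.sigma2 * 2 * (n - 2) / (2 * n - 2)
        assert np.allclose(model2.sigma2, expected, rtol=1e-10)

    def test_posterior_symmetry_and_monotone_limit(self):
        matrix = make_matrix([[-2.0, 0.0, 0.0, 2.0]])
        model = dlda_train(matrix, make_annotation(2, 2))
        mid = float(model.mu.to_numpy().mean())
        assert dlda_posterior(model, np.array([mid])) == pytest.approx(0.5)
        direction = np.sign(model.mu.loc["FTC", "g1"] - model.mu.loc["FTA", "g1"])
        probs = [dlda_posterior(model, np.array([mid + direction * t]))
                 for t in (0.5, 1, 2, 5, 20)]
        assert np.all(np.diff(probs) >= 0) and probs[-1] > 0.999

    def test_posterior_matches_diagonal_bayes_oracle(self):
        for seed in range(200):
            r = np.random.default_rng(seed)
            g = 5
            mu1, mu0 = r.normal(0, 2, g), r.normal(0, 2, g)
            s2 = r.uniform(0.2, 3.0, g)
            pi1 = r.uniform(0.2, 0.8)
            genes = [f"g{i}" for i in range(g)]
            from thyromarker.classify import DldaModel
            model = DldaModel(genes=genes,
                              mu=pd.DataFrame([mu1, mu0], index=["FTC", "FTA"],
                                              columns=genes),
                              sigma2=pd.Series(s2, index=genes),
                              priors={"FTC": pi1, "FTA": 1 - pi1})
            x = r.normal(0, 2, g)
            num = np.log(pi1) + stats.norm.logpdf(x, mu1, np.sqrt(s2)).sum()
            den = np.log(1 - pi1) + stats.norm.logpdf(x, mu0, np.sqrt(s2)).sum()
            expected = 1.0 / (1.0 + np.exp(den - num))
            assert abs(dlda_posterior(model, x) - expected) < 1e-10

    def test_class_probabilities_sum_to_one(self):
        matrix = make_matrix([[-1.0, -0.5, 0.5, 1.0], [0.0, 1.0, 0.0, 1.0]])
        annot = make_annotation(2, 2)
        model = dlda_train(matrix, annot)
        for x in ([-3, 0.2], [0.0, 0.5], [4, -1]):
            p1 = dlda_posterior(model, np.array(x))
            swapped = model.mu.loc[["FTA", "FTC"]]
            swapped.index = ["FTC", "FTA"]
            from thyromarker.classify import DldaModel
            flipped = DldaModel(model.genes, swapped, model.sigma2,
                                {"FTC": model.priors["FTA"], "FTA": model.priors["FTC"]})
            assert p1 + dlda_posterior(flipped, np.array(x)) == pytest.approx(1.0)


class TestNestedLoocv:
    def test_perfect_separation_classified_perfectly(self, rng):
        values = rng.normal(0, 0.3, (5, 12))
        values[0, :6] += 10.0  # 10-sd separation on one gene
        matrix = make_matrix(values)
        annot = make_annotation(6, 6)
        cv = nested_loocv(matrix, annot)
        assert (cv.per_sample["true_label"] == cv.per_sample["predicted"]).all()
        correct_side = np.where(cv.per_sample["true_label"] == "FTC",
                                cv.per_sample["prob_ftc"] > 0.5,
                                cv.per_sample["prob_ftc"] < 0.5)
        assert correct_side.all()

    def test_matches_naive_nested_refit(self, rng):
        """The sufficient-statistic inner loop must agree with literal
        refitting of selection + DLDA in every fold."""
        values = rng.normal(0, 1, (4, 12))
        values[0, :5] += 1.2
        matrix = make_matrix(values)
        annot = make_annotation(5, 7)
        grid = (0.01, 0.2, 0.9)
        cv = nested_loocv(matrix, annot, alpha_grid=grid)
        naive = _naive_nested_loocv(matrix, annot, grid)
        assert np.allclose(cv.per_sample["prob_ftc"], naive["prob_ftc"], atol=1e-12)
        assert list(cv.per_sample["alpha"]) == list(naive["alpha"])

    def test_held_out_sample_cannot_influence_tuning(self, rng):
        """Corrupting the held-out sample's values must not change the alpha
        or gene count chosen for its fold."""
        values = rng.normal(0, 1, (6, 14))
        values[0, :7] += 1.0
        matrix = make_matrix(values)
        annot = make_annotation(7, 7)
        cv = nested_loocv(matrix, annot)
        corrupted = matrix.values.copy()
        corrupted.iloc[:, 3] = 1e3
        cv2 = nested_loocv(ExpressionMatrix(corrupted, scale=LOG2), annot)
        held = matrix.samples[3]
        assert cv.per_sample.loc[held, "alpha"] == cv2.per_sample.loc[held, "alpha"]
        assert cv.per_sample.loc[held, "n_genes"] == cv2.per_sample.loc[held, "n_genes"]

    def test_guards(self, rng):
        matrix = make_matrix(rng.normal(size=(3, 5)))
        with pytest.raises(ValidationError, match="n >= 6"):
            nested_loocv(matrix, make_annotation(2, 3))
        matrix2 = make_matrix(rng.normal(size=(3, 8)))
        with pytest.raises(ValidationError, match="grid"):
            nested_loocv(matrix2, make_annotation(4, 4), alpha_grid=())


def _naive_nested_loocv(matrix, annot, grid):
    """Reference doubly nested LOOCV: literal refit in every fold."""
    x = matrix.values.to_numpy().T
    y = (annot.diagnosis.loc[matrix.samples] == "FTC").to_numpy()
    genes = np.array(matrix.genes)
    samples = np.array(matrix.samples)
    rows = []
    for j in range(len(y)):
        outer = np.arange(len(y)) != j
        accs = []
        for alpha in sorted(grid):
            correct = 0
            idx = np.nonzero(outer)[0]
            for i in idx:
                tr = outer & (np.arange(len(y)) != i)
                p = _ttest_pvals(x[tr], y[tr])
                keep = np.nonzero(p < alpha)[0]
                if keep.size == 0:
                    keep = np.array([int(np.nanargmin(p))])
                sub = ExpressionMatrix(pd.DataFrame(x[tr][:, keep].T,
                                                    index=genes[keep],
                                                    columns=samples[tr]), scale=LOG2)
                model = dlda_train(sub, pd.Series(np.where(y[tr], "FTC", "FTA"),
                                                  index=samples[tr]))
                prob = dlda_posterior(model, x[i, keep])
                correct += (prob > 0.5) == y[i]
            accs.append(correct / len(idx))
        alpha = sorted(grid)[int(np.argmax(accs))]
        p = _ttest_pvals(x[outer], y[outer])
        keep = np.nonzero(p < alpha)[0]
        if keep.size == 0:
            keep = np.array([int(np.nanargmin(p))])
        sub = ExpressionMatrix(pd.DataFrame(x[outer][:, keep].T, index=genes[keep],
                                            columns=samples[outer]), scale=LOG2)
        model = dlda_train(sub, pd.Series(np.where(y[outer], "FTC", "FTA"),
                                          index=samples[outer]))
        rows.append({"prob_ftc": dlda_posterior(model, x[j, keep]), "alpha": alpha})
    return pd.DataFrame(rows, index=samples)


class TestConfusionMetrics:
    def test_reconstructed_cohort_counts(self):
        """29 carcinomas + 40 adenomas with 22 and 32 correct calls."""
        report = confusion_metrics({"TP": 22, "FN": 7, "TN": 32, "FP": 8})
        t = report.table
        assert t.loc["accuracy", "x"] == 54 and t.loc["accuracy", "n"] == 69
        assert t.loc["accuracy", "percent"] == 78
        assert t.loc["sensitivity", "percent"] == 76
        assert t.loc["specificity", "percent"] == 80

    def test_all_correct_boundary(self):
        report = confusion_metrics({"TP": 10, "FN": 0, "TN": 10, "FP": 0})
        row = report.table.loc["accuracy"]
        assert row["percent"] == 100 and row["percent_ci_high"] == 100

    def test_zero_denominator_reported_missing(self):
        report = confusion_metrics({"TP": 0, "FN": 0, "TN": 5, "FP": 1})
        assert np.isnan(report.table.loc["sensitivity", "proportion"])

    @pytest.mark.parametrize("x, n", [(22, 29), (32, 40), (54, 69), (0, 10), (10, 10)])
    def test_clopper_pearson_matches_beta_quantile_oracle(self, x, n):
        lo, hi = clopper_pearson(x, n)
        exp_lo = stats.beta.ppf(0.025, x, n - x + 1) if x > 0 else 0.0
        exp_hi = stats.beta.ppf(0.975, x + 1, n - x) if x < n else 1.0
        assert lo == pytest.approx(exp_lo, abs=1e-12)
        assert hi == pytest.approx(exp_hi, abs=1e-12)

    def test_ci_contains_point_and_narrows_with_n(self):
        widths = []
        for n in (20, 69, 200):
            x = int(round(0.78 * n))
            lo, hi = clopper_pearson(x, n)
            assert lo <= x / n <= hi
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_stratified_by_oncocytic_flag(self):
        probs = [0.9, 0.9, 0.1, 0.2, 0.8, 0.1]
        labels = ["FTC", "FTC", "FTC", "FTA", "FTA", "FTA"]
        cv = _cv_from_probs(probs, labels)
        strata = pd.Series([True, True, False, True, False, False],
                           index=cv.per_sample.index)
        by = confusion_metrics(cv, stratify_by=strata)
        assert by[True].table.loc["accuracy", "x"] == 3  # 2 TP + 1 TN
        assert by[False].table.loc["accuracy", "x"] == 1


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        cv = _cv_from_probs([0.9, 0.8, 0.2, 0.1], ["FTC", "FTC", "FTA", "FTA"])
        curve = roc_auc(cv)
        assert curve.auc == pytest.approx(1.0)

    def test_pure_ties_give_auc_half(self):
        cv = _cv_from_probs([0.4] * 6, ["FTC", "FTA"] * 3)
        assert roc_auc(cv).auc == pytest.approx(0.5)

    def test_curve_shape_invariants(self, rng):
        probs = rng.random(20)
        labels = ["FTC" if rng.random() < 0.5 else "FTA" for _ in range(19)] + ["FTC"]
        labels[0] = "FTA"
        curve = roc_auc(_cv_from_probs(probs, labels))
        pts = curve.points
        assert (pts.iloc[0][["fpr", "tpr"]] == 0).all()
        assert (pts.iloc[-1][["fpr", "tpr"]] == 1).all()
        assert (pts["fpr"].diff().dropna() >= 0).all()
        assert (pts["tpr"].diff().dropna() >= 0).all()

    def test_trapezoid_equals_mann_whitney_count(self, rng):
        for _ in range(20):
            n = 20
            probs = np.round(rng.random(n), 2)  # induce ties
            labels = np.where(rng.random(n) < 0.4, "FTC", "FTA")
            if len(set(labels)) < 2:
                continue
            curve = roc_auc(_cv_from_probs(probs, list(labels)))
            pos = probs[labels == "FTC"]
            neg = probs[labels == "FTA"]
            pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
                pos[:, None] == neg[None, :]).sum()
            assert abs(curve.auc - pairs / (len(pos) * len(neg))) < 1e-12

    def test_monotone_transform_invariance(self, rng):
        probs = rng.random(15)
        labels = ["FTC"] * 7 + ["FTA"] * 8
        base = roc_auc(_cv_from_probs(probs, labels)).auc
        squashed = 1 / (1 + np.exp(-5 * (probs - 0.3)))
        assert roc_auc(_cv_from_probs(squashed, labels)).auc == pytest.approx(base)

    def test_single_class_errors(self):
        cv = _cv_from_probs([0.2, 0.4], ["FTC", "FTC"])
        with pytest.raises(ValidationError, match="both classes"):
            roc_auc(cv)
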