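"""Diagnostic metrics, confidence intervals, association and comparison tests."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, strategies as st

from gmdhscreen.evaluation import (
    ConfusionMatrix,
    auc_from_scores,
    binary_metrics,
    association_measure,
    chi_square_test,
    cochran_q,
    compare_classifiers,
    cross_validate,
    macro_metrics,
    mcnemar_test,
    proportion_ci,
    stratified_kfold,
)
from gmdhscreen.fixtures import count_table, load_marginal_counts

cm_strategy = st.builds(
    ConfusionMatrix,
    tp=st.integers(1, 200), fp=st.integers(1, 200),
    tn=st.integers(1, 200), fn=st.integers(1, 200),
)


class TestBinaryMetrics:
    def test_perfect_classifier(self):
        rep = binary_metrics(ConfusionMatrix(tp=50, fp=0, tn=50, fn=0))
        for name in ("se", "sp", "pr", "acc", "mcc", "kappa"):
            assert rep.value(name) == 1.0

    def test_mcc_known_matrix(self):
        rep = binary_metrics(ConfusionMatrix(tp=79, fn=21, fp=3, tn=97))
        expected = 7600 / math.sqrt(82 * 100 * 100 * 118)
        assert rep.value("mcc") == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.7726, abs=5e-5)

    @given(cm_strategy)
    def test_dor_dp_identities(self, cm):
        """DOR = LR+/LR- and DP = (sqrt3/pi) ln DOR hold identically."""
        rep = binary_metrics(cm)
        lr_ratio = rep.value("lr_pos") / rep.value("lr_neg")
        assert rep.value("dor") == pytest.approx(lr_ratio, rel=1e-12)
        assert rep.value("dp") == pytest.approx(
            math.sqrt(3) / math.pi * math.log(rep.value("dor")), rel=1e-12)

    @given(cm_strategy)
    def test_mcc_invariant_under_label_swap(self, cm):
        """Swapping the positive class leaves MCC fixed and exchanges
        Se with Sp and Pr with NPV."""
        rep = binary_metrics(cm)
        swapped = binary_metrics(
            ConfusionMatrix(tp=cm.tn, fp=cm.fn, tn=cm.tp, fn=cm.fp))
        assert rep.value("mcc") == pytest.approx(swapped.value("mcc"), abs=1e-12)
        assert rep.value("se") == pytest.approx(swapped.value("sp"), abs=1e-12)
        assert rep.value("pr") == pytest.approx(swapped.value("npv"), abs=1e-12)

    def test_zero_denominators_flagged_not_zero(self):
        rep = binary_metrics(ConfusionMatrix(tp=0, fp=0, tn=80, fn=20))
        assert not rep["pr"].defined and rep["pr"].value is None
        assert not rep["dor"].defined

    def test_printed_dor_rows_recomputed_from_se_sp(self, performance_table):
        """DOR recomputed from the published Se/Sp matches the published DOR
        to one decimal for the depression and worriedness GMDH rows."""
        t = performance_table.set_index(["outcome", "classifier"])
        for outcome, printed in [("depression", 121.6), ("worriedness", 15.0)]:
            row = t.loc[(outcome, "GMDH")]
            se, sp = row["se"] / 100, row["sp"] / 100
            dor = (se / (1 - se)) * (sp / (1 - sp))
            assert round(dor, 1) == printed == row["dor"]


class TestProportionCI:
    def test_published_sensitivity_interval(self):
        # Se = 0.79 among the cohort's 2,080 positive subjects
        lo, hi = proportion_ci(0.79, 2080)
        assert (round(100 * lo), round(100 * hi)) == (77, 81)

    def test_zero_proportion_lower_bound(self):
        lo, hi = proportion_ci(0.0, 10)
        assert lo == 0.0 and hi > 0

    def test_half_at_n100(self):
        lo, hi = proportion_ci(0.5, 100)
        assert (round(lo, 3), round(hi, 3)) == (0.404, 0.596)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_from_scores([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).value == 1.0

    def test_constant_scores(self):
        assert auc_from_scores(np.ones(10), [0, 1] * 5).value == 0.5

    def test_tied_scores_match_pair_count_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(6, 25)
            s = rng.integers(0, 4, n).astype(float)  # heavy ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            oracle = wins / (pos.size * neg.size)
            assert auc_from_scores(s, y).value == pytest.approx(oracle,
                                                                abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_from_scores([0.1, 0.2], [1, 1])


class TestStratifiedKFold:
    def test_balanced_small_case(self):
        y = [1] * 6 + [0] * 6
        folds = stratified_kfold(y, 3, seed=0)
        for f in range(3):
            mask = folds == f
            assert sum(mask) == 4
            assert np.sum(np.asarray(y)[mask]) == 2

    def test_seed_reproducibility(self):
        y = np.random.default_rng(0).integers(0, 2, 100)
        assert np.array_equal(stratified_kfold(y, 3, seed=5),
                              stratified_kfold(y, 3, seed=5))

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold([0, 0, 0, 1, 1], 3)

    @given(st.integers(0, 10_000))
    def test_per_fold_class_counts_within_one(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 3, rng.integers(30, 120))
        if np.min(np.bincount(y, minlength=3)[np.unique(y)]) < 3:
            return
        folds = stratified_kfold(y, 3, seed=seed)
        for c in np.unique(y):
            per_fold = [np.sum((folds == f) & (y == c)) for f in range(3)]
            assert max(per_fold) - min(per_fold) <= 1


class TestCrossValidate:
    def _data(self, n=90):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = rng.integers(0, 2, n)
        return X, y

    def test_memorizing_stub_scores_perfectly(self):
        X, y = self._data()

        def memorize(X_tr, y_tr, X_te, fold_seed):
            labels = y[X_te.index.to_numpy()]
            return labels, labels.astype(float)

        res = cross_validate(memorize, X, y, k=3, seed=0)
        assert res.pooled_report.value("acc") == 1.0

    def test_majority_stub_has_zero_sensitivity(self):
        X, y = self._data()

        def majority(X_tr, y_tr, X_te, fold_seed):
            lab = np.zeros(len(X_te), dtype=int)
            return lab, lab.astype(float)

        res = cross_validate(majority, X, y, k=3, seed=0)
        assert res.pooled_report.value("se") == 0.0
        assert res.pooled_report.value("sp") == 1.0

    def test_pooled_matrix_is_sum_of_folds(self):
        X, y = self._data()

        def random_clf(X_tr, y_tr, X_te, fold_seed):
            lab = np.random.default_rng(fold_seed).integers(0, 2, len(X_te))
            return lab, lab.astype(float)

        res = cross_validate(random_clf, X, y, k=3, seed=0)
        total = ConfusionMatrix(0, 0, 0, 0)
        for cm in res.fold_cms:
            total = total + cm
        assert total == res.pooled_cm
        assert res.pooled_cm.n == len(y)

    def test_test_fold_outcomes_not_visible_to_fit(self):
        """Altering the outcomes of a held-out fold cannot change that
        fold's predictions (no stage reads test-fold outcomes)."""
        X, y = self._data()
        folds = stratified_kfold(y, 3, seed=0)

        def learner(X_tr, y_tr, X_te, fold_seed):
            coef = float(np.mean(y_tr))
            scores = X_te["a"].to_numpy() * coef
            return (scores > 0).astype(int), scores

        res1 = cross_validate(learner, X, y, k=3, seed=0, folds=folds)
        y2 = y.copy()
        y2[folds == 0] = 1 - y2[folds == 0]
        res2 = cross_validate(learner, X, y2, k=3, seed=0, folds=folds)
        m = folds == 0
        assert np.array_equal(res1.pooled_labels[m], res2.pooled_labels[m])


class TestComparison:
    def test_identical_predictions_give_p_one(self):
        y = np.array([0, 1] * 20)
        pred = {"a": y.copy(), "b": y.copy()}
        out = compare_classifiers(pred, y)
        assert out["pairwise"].loc[0, "p_raw"] == 1.0

    def test_exact_binomial_value(self):
        res = mcnemar_test(10, 2)
        assert res["p"] == pytest.approx(158 / 4096, abs=1e-15)
        assert res["method"] == "exact"

    def test_two_classifiers_q_equals_uncorrected_mcnemar(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 200)
        pa = np.where(rng.random(200) < 0.8, y, 1 - y)
        pb = np.where(rng.random(200) < 0.6, y, 1 - y)
        out = compare_classifiers({"a": pa, "b": pb}, y)
        ok_a, ok_b = pa == y, pb == y
        b = int(np.sum(ok_a & ~ok_b))
        c = int(np.sum(~ok_a & ok_b))
        assert out["cochran_q"]["Q"] == pytest.approx(
            (b - c) ** 2 / (b + c), rel=1e-12)

    def test_exact_and_chi2_agree_near_switch_point(self):
        """At b+c = 25 discordant pairs the two McNemar variants agree."""
        for b in range(0, 26):
            c = 25 - b
            chi2_p = mcnemar_test(b, c)["p"]  # b+c = 25 -> chi2 branch
            k = min(b, c)
            exact_p = 1.0 if b == c else min(
                1.0, 2 * scipy.stats.binom.cdf(k, 25, 0.5))
            assert abs(chi2_p - exact_p) < 0.01

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            compare_classifiers({"a": np.zeros(5), "b": np.zeros(6)},
                                np.zeros(5))

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 120)
        preds = {n: np.where(rng.random(120) < q, y, 1 - y)
                 for n, q in [("a", 0.9), ("b", 0.7), ("c", 0.5)]}
        out = compare_classifiers(preds, y)
        pw = out["pairwise"]
        assert len(pw) == 3
        assert (pw["p_adjusted"] >= pw["p_raw"]).all()
        assert (pw["p_adjusted"] <= 1.0).all()


class TestChiSquare:
    def test_published_table_pvalues(self):
        counts = load_marginal_counts("all")
        p1 = chi_square_test(
            count_table(counts, "abdominal_obesity", "worriedness"))["p"]
        assert abs(p1 - 0.042) <= 0.002
        p2 = chi_square_test(count_table(counts, "bmi_cat", "depression"))["p"]
        assert abs(p2 - 0.041) <= 0.003

    def test_proportional_rows_give_zero(self):
        out = chi_square_test([[10, 20], [30, 60]])
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [5, 5]])


class TestAssociation:
    def test_perfect_diagonal_phi(self):
        x = np.array([1, 1, 0, 0] * 5)
        assert association_measure(x, x, "phi", ci=False).value == 1.0

    def test_phi_known_table(self):
        # a=30, b=10, c=10, d=50
        x = np.array([1] * 40 + [0] * 60)
        y = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 50)
        m = association_measure(x, y, "phi", ci=False)
        assert m.value == pytest.approx(1400 / 2400, abs=1e-12)

    def test_monotone_rank_coefficients(self):
        x = np.arange(10.0)
        for kind in ("spearman", "kendall_tau_b"):
            assert association_measure(
                x, x**3, kind, ci=False).value == pytest.approx(1.0)
            assert association_measure(
                x, -x, kind, ci=False).value == pytest.approx(-1.0)

    def test_rank_biserial_sign_and_magnitude(self):
        binary = np.array([0] * 5 + [1] * 5)
        ordinal = np.arange(10.0)  # group 1 strictly higher
        m = association_measure(binary, ordinal, "rank_biserial", ci=False)
        assert m.value == 1.0

    def test_constant_column_flagged(self):
        m = association_measure(np.ones(10), np.arange(10), "phi", ci=False)
        assert not m.defined

    def test_bootstrap_ci_contains_point_and_shrinks(self):
        rng = np.random.default_rng(0)
        widths = []
        for n in (100, 1000):
            x = rng.integers(0, 2, n)
            y = np.where(rng.random(n) < 0.8, x, 1 - x)
            m = association_measure(x, y, "phi", n_boot=300, seed=1)
            lo, hi = m.ci
            assert lo <= m.value <= hi
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestMacroMetrics:
    def test_diagonal_matrix_is_perfect(self):
        rep = macro_metrics(np.diag([10, 20, 30]))
        assert rep["macro_f1"] == 1.0 and rep["kappa"] == 1.0

    def test_uniform_confusion_gives_zero_kappa(self):
        rep = macro_metrics(np.full((3, 3), 7))
        assert rep["kappa"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_per_class_reduction_oracle(self):
        M = np.array([[50, 5, 5], [10, 30, 10], [2, 8, 40]])
        rep = macro_metrics(M)
        f1s, prs, ses = [], [], []
        for c in range(3):
            tp = M[c, c]
            fp = M[:, c].sum() - tp
            fn = M[c, :].sum() - tp
            pr, se = tp / (tp + fp), tp / (tp + fn)
            prs.append(pr), ses.append(se)
            f1s.append(2 * pr * se / (pr + se))
        assert rep["macro_pr"] == pytest.approx(np.mean(prs), abs=1e-12)
        assert rep["macro_se"] == pytest.approx(np.mean(ses), abs=1e-12)
        assert rep["macro_f1"] == pytest.approx(np.mean(f1s), abs=1e-12)
        assert rep["micro"] == pytest.approx(M.trace() / M.sum(), abs=1e-12)

    def test_empty_class_column_flagged(self):
        M = np.array([[10, 5, 0], [3, 12, 0], [1, 4, 0]])
        rep = macro_metrics(M)
        assert rep["has_undefined_class"]
        assert rep["per_class"][2]["pr"] is None
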