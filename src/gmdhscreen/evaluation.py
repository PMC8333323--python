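"""Cross-validated diagnostic-accuracy reporting and classifier comparison.

Implements the full validation protocol: stratified k-fold assignment (the
same test folds are reused by every classifier), per-fold and pooled
confusion matrices, the diagnostic-index battery (sensitivity, specificity,
precision, NPV, accuracy, F1, likelihood ratios, diagnostic odds ratio,
discriminant power, MCC, Cohen's kappa) with 95% confidence intervals
(Wilson for proportions, log-normal for the DOR, Hanley-McNeil for the AUC),
association coefficients with bootstrap CIs, Pearson chi-square tests, and
Cochran's Q with McNemar post-hoc pairwise comparisons under Bonferroni
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionMatrix",
    "Metric",
    "MetricReport",
    "CVResult",
    "stratified_kfold",
    "binary_metrics",
    "proportion_ci",
    "auc_from_scores",
    "cross_validate",
    "compare_classifiers",
    "cochran_q",
    "mcnemar_test",
    "chi_square_test",
    "association_measure",
    "macro_metrics",
]

SQRT3_OVER_PI = math.sqrt(3.0) / math.pi
Z95 = scipy.stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true).astype(int)
        p = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((t == 1) & (p == 1))),
            fp=int(np.sum((t == 0) & (p == 1))),
            tn=int(np.sum((t == 0) & (p == 0))),
            fn=int(np.sum((t == 1) & (p == 0))),
        )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class Metric:
    value: float | None
    ci: tuple[float, float] | None = None
    defined: bool = True

    def __float__(self):
        return float("nan") if self.value is None else float(self.value)


_UNDEFINED = Metric(value=None, ci=None, defined=False)

#: order of the scalar indices in a metric report
METRIC_NAMES = ("se", "sp", "pr", "npv", "acc", "f1", "lr_pos", "lr_neg",
                "dor", "dp", "mcc", "kappa")


@dataclass
class MetricReport:
    metrics: dict[str, Metric]
    cm: ConfusionMatrix | None = None

    def __getitem__(self, name: str) -> Metric:
        return self.metrics[name]

    def value(self, name: str) -> float:
        return float(self.metrics[name])

    def to_dict(self) -> dict:
        out = {}
        for k, m in self.metrics.items():
            out[k] = m.value
            if m.ci is not None:
                out[f"{k}_lo"], out[f"{k}_hi"] = m.ci
        return out


def proportion_ci(p_hat: float, n: int) -> tuple[float, float]:
    """Wilson score 95% interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    count = p_hat * n
    lo, hi = proportion_confint(count, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _prop_metric(num: int, den: int) -> Metric:
    if den == 0:
        return _UNDEFINED
    p = num / den
    return Metric(p, proportion_ci(p, den))


def binary_metrics(cm: ConfusionMatrix) -> MetricReport:
    """The diagnostic-index battery for one 2x2 confusion matrix.

    Ratios with a zero denominator are reported as undefined (flagged), not
    silently zero.  DOR = LR+/LR- and DP = (sqrt(3)/pi) * ln(DOR) hold
    identically whenever defined; the DOR interval uses the log-normal
    approximation on ln(DOR).
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    m: dict[str, Metric] = {}
    m["se"] = _prop_metric(tp, tp + fn)
    m["sp"] = _prop_metric(tn, tn + fp)
    m["pr"] = _prop_metric(tp, tp + fp)
    m["npv"] = _prop_metric(tn, tn + fn)
    m["acc"] = _prop_metric(tp + tn, cm.n)

    se, sp, pr = m["se"], m["sp"], m["pr"]
    if se.defined and pr.defined and (se.value + pr.value) > 0:
        m["f1"] = Metric(2 * se.value * pr.value / (se.value + pr.value))
    else:
        m["f1"] = _UNDEFINED

    if se.defined and sp.defined and sp.value < 1:
        m["lr_pos"] = Metric(se.value / (1 - sp.value))
    else:
        m["lr_pos"] = _UNDEFINED
    if se.defined and sp.defined and sp.value > 0:
        m["lr_neg"] = Metric((1 - se.value) / sp.value)
    else:
        m["lr_neg"] = _UNDEFINED

    if min(tp, fp, tn, fn) > 0:
        dor = (tp / fn) * (tn / fp)
        se_log = math.sqrt(1 / tp + 1 / fp + 1 / tn + 1 / fn)
        dor_ci = (dor * math.exp(-Z95 * se_log), dor * math.exp(Z95 * se_log))
        m["dor"] = Metric(dor, dor_ci)
        m["dp"] = Metric(
            SQRT3_OVER_PI * math.log(dor),
            (SQRT3_OVER_PI * math.log(dor_ci[0]), SQRT3_OVER_PI * math.log(dor_ci[1])),
        )
    else:
        m["dor"] = _UNDEFINED
        m["dp"] = _UNDEFINED

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom > 0:
        m["mcc"] = Metric((tp * tn - fp * fn) / math.sqrt(denom))
    else:
        m["mcc"] = _UNDEFINED

    po = (tp + tn) / cm.n
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / cm.n**2
    m["kappa"] = Metric((po - pe) / (1 - pe)) if pe < 1 else _UNDEFINED

    return MetricReport(metrics=m, cm=cm)


def auc_from_scores(scores, labels) -> Metric:
    """Tie-aware rank AUC (normalized Mann-Whitney U) with Hanley-McNeil CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes are required to compute an AUC")
    ranks = scipy.stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    half = Z95 * math.sqrt(max(var, 0.0))
    return Metric(float(auc), (max(0.0, auc - half), min(1.0, auc + half)))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def stratified_kfold(labels, k: int, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1 per subject) by per-class round robin.

    Each class's members are shuffled with the seed and dealt round-robin, so
    per-fold class counts differ from n_class/k by at most 1.  Classes
    smaller than k raise.
    """
    y = np.asarray(labels)
    folds = np.empty(y.size, dtype=int)
    rng = np.random.default_rng([seed, 23])
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if idx.size < k:
            raise ValueError(f"class {c!r} has {idx.size} members < k={k}")
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


@dataclass
class CVResult:
    folds: np.ndarray
    fold_cms: list[ConfusionMatrix]
    fold_reports: list[MetricReport]
    pooled_cm: ConfusionMatrix
    pooled_report: MetricReport
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    y: np.ndarray
    auc: Metric

    def fold_mean_sd(self, name: str) -> tuple[float, float]:
        vals = np.array([r.value(name) for r in self.fold_reports], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return float("nan"), float("nan")
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        return float(np.mean(vals)), sd


def cross_validate(
    fit_predict: Callable,
    covariates,
    outcome,
    k: int = 3,
    seed: int = 0,
    folds: np.ndarray | None = None,
) -> CVResult:
    """Stratified k-fold evaluation of a train/predict procedure.

    ``fit_predict(X_train, y_train, X_test, fold_seed)`` must return
    ``(labels, scores)`` for the test rows; any preprocessing that looks at
    the outcome (WoE, feature selection) must happen inside it, on the
    training rows only.  Passing precomputed ``folds`` lets several
    classifiers share identical test folds.
    """
    X = covariates
    y = np.asarray(outcome).astype(int)
    if folds is None:
        folds = stratified_kfold(y, k, seed)
    pooled_scores = np.empty(y.size, dtype=float)
    pooled_labels = np.empty(y.size, dtype=int)
    fold_cms, fold_reports = [], []
    for f in range(k):
        test = folds == f
        train = ~test
        X_tr = X.iloc[train] if isinstance(X, pd.DataFrame) else X[train]
        X_te = X.iloc[test] if isinstance(X, pd.DataFrame) else X[test]
        labels, scores = fit_predict(X_tr, y[train], X_te, int(seed * 1000 + f))
        pooled_labels[test] = np.asarray(labels).astype(int)
        pooled_scores[test] = np.asarray(scores, dtype=float)
        cm = ConfusionMatrix.from_labels(y[test], labels)
        fold_cms.append(cm)
        fold_reports.append(binary_metrics(cm))
    pooled_cm = fold_cms[0]
    for cm in fold_cms[1:]:
        pooled_cm = pooled_cm + cm
    return CVResult(
        folds=folds,
        fold_cms=fold_cms,
        fold_reports=fold_reports,
        pooled_cm=pooled_cm,
        pooled_report=binary_metrics(pooled_cm),
        pooled_scores=pooled_scores,
        pooled_labels=pooled_labels,
        y=y,
        auc=auc_from_scores(pooled_scores, y),
    )


# ---------------------------------------------------------------------------
# Classifier comparison
# ---------------------------------------------------------------------------

def mcnemar_test(b: int, c: int, exact_threshold: int = 25) -> dict:
    """Two-sided McNemar test from the discordant-pair counts.

    Exact binomial when b + c < ``exact_threshold``; otherwise chi-square
    with continuity correction.
    """
    n_disc = b + c
    if n_disc == 0:
        return {"b": b, "c": c, "statistic": 0.0, "p": 1.0, "method": "exact"}
    if n_disc < exact_threshold:
        k = min(b, c)
        p = 2.0 * scipy.stats.binom.cdf(k, n_disc, 0.5)
        if b == c:  # both tails coincide
            p = 1.0
        return {"b": b, "c": c, "statistic": float(k), "p": min(1.0, float(p)),
                "method": "exact"}
    stat = (abs(b - c) - 1) ** 2 / n_disc
    p = scipy.stats.chi2.sf(stat, df=1)
    return {"b": b, "c": c, "statistic": float(stat), "p": float(p),
            "method": "chi2_cc"}


def cochran_q(correct: np.ndarray) -> dict:
    """Cochran's Q on an n x k 0/1 correctness matrix."""
    U = np.asarray(correct).astype(int)
    n, k = U.shape
    if k < 2:
        raise ValueError("need >= 2 classifiers")
    T = U.sum(axis=0)
    R = U.sum(axis=1)
    denom = k * R.sum() - np.sum(R**2)
    if denom == 0:
        return {"Q": 0.0, "df": k - 1, "p": 1.0}
    Q = (k - 1) * (k * np.sum(T**2) - T.sum() ** 2) / denom
    return {"Q": float(Q), "df": k - 1, "p": float(scipy.stats.chi2.sf(Q, k - 1))}


def compare_classifiers(
    prediction_sets: Mapping[str, np.ndarray], labels
) -> dict:
    """Cochran's Q plus Bonferroni-adjusted pairwise McNemar tests.

    ``prediction_sets`` maps classifier name to its pooled test-fold
    predictions over the *same* subjects in the same order.
    """
    y = np.asarray(labels).astype(int)
    names = list(prediction_sets)
    preds = {}
    for name in names:
        p = np.asarray(prediction_sets[name]).astype(int)
        if p.size != y.size:
            raise ValueError(f"classifier {name!r}: prediction length mismatch")
        preds[name] = p
    correct = np.column_stack([preds[n] == y for n in names]).astype(int)
    q = cochran_q(correct)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a_ok, b_ok = correct[:, i].astype(bool), correct[:, j].astype(bool)
            b_cnt = int(np.sum(a_ok & ~b_ok))
            c_cnt = int(np.sum(~a_ok & b_ok))
            res = mcnemar_test(b_cnt, c_cnt)
            rows.append({
                "classifier_a": names[i], "classifier_b": names[j],
                "b": b_cnt, "c": c_cnt, "p_raw": res["p"],
                "p_adjusted": min(1.0, res["p"] * m), "method": res["method"],
            })
    return {"cochran_q": q, "pairwise": pd.DataFrame(rows)}


# ---------------------------------------------------------------------------
# Association statistics
# ---------------------------------------------------------------------------

def chi_square_test(count_table) -> dict:
    """Pearson chi-square (no continuity correction) on an r x c table."""
    obs = np.asarray(count_table, dtype=float)
    if obs.min() < 0:
        raise ValueError("counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    stat, p, df, _ = scipy.stats.chi2_contingency(obs, correction=False)
    return {"statistic": float(stat), "df": int(df), "p": float(p)}


def _phi(x: np.ndarray, y: np.ndarray) -> float:
    a = np.sum((x == 1) & (y == 1))
    b = np.sum((x == 1) & (y == 0))
    c = np.sum((x == 0) & (y == 1))
    d = np.sum((x == 0) & (y == 0))
    denom = math.sqrt(float((a + b) * (c + d) * (a + c) * (b + d)))
    if denom == 0:
        raise ZeroDivisionError("degenerate 2x2 margins: phi undefined")
    return float((a * d - b * c) / denom)


def _rank_biserial(binary: np.ndarray, ordinal: np.ndarray) -> float:
    g1 = ordinal[binary == 1]
    g0 = ordinal[binary == 0]
    if g1.size == 0 or g0.size == 0:
        raise ZeroDivisionError("a binary group is empty")
    u = scipy.stats.mannwhitneyu(g1, g0, alternative="two-sided").statistic
    # r_rb = 2 * (U / (n1 n0)) - 1 in [-1, 1], positive when group 1 is higher
    return float(2.0 * u / (g1.size * g0.size) - 1.0)


_ASSOC_FUNCS = {
    "phi": _phi,
    "rank_biserial": _rank_biserial,
    "spearman": lambda x, y: float(scipy.stats.spearmanr(x, y).statistic),
    "kendall_tau_b": lambda x, y: float(
        scipy.stats.kendalltau(x, y, variant="b").statistic),
}


def association_measure(
    x, y, kind: str, ci: bool = True, n_boot: int = 2000, seed: int = 0
) -> Metric:
    """Association coefficient with a percentile-bootstrap 95% CI.

    ``kind``: "phi" (binary-binary), "rank_biserial" (binary-ordinal),
    "spearman" (interval-ordinal), "kendall_tau_b" (ordinal-ordinal).
    Constant columns make the coefficient undefined (flagged).
    """
    if kind not in _ASSOC_FUNCS:
        raise ValueError(f"unknown association kind {kind!r}")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.unique(xa).size < 2 or np.unique(ya).size < 2:
        return Metric(value=None, ci=None, defined=False)
    fn = _ASSOC_FUNCS[kind]
    point = fn(xa, ya)
    if not ci:
        return Metric(point)
    rng = np.random.default_rng([seed, 31])
    boots = []
    n = xa.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            boots.append(fn(xa[idx], ya[idx]))
        except ZeroDivisionError:
            continue
    if not boots:
        return Metric(point)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return Metric(point, (float(lo), float(hi)))


# ---------------------------------------------------------------------------
# Multiclass indices
# ---------------------------------------------------------------------------

def macro_metrics(cm3: np.ndarray) -> dict:
    """Macro/micro precision-recall-F1 and Cohen's kappa for a k x k table.

    Rows are true classes, columns predicted.  Per-class values with a zero
    denominator are undefined; macro averages skip them and set a flag.
    """
    M = np.asarray(cm3, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = M.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    k = M.shape[0]
    per_class = []
    any_undefined = False
    for c in range(k):
        tp = M[c, c]
        col = M[:, c].sum()
        row = M[c, :].sum()
        pr = tp / col if col > 0 else None
        se = tp / row if row > 0 else None
        if pr is None or se is None:
            any_undefined = True
            f1 = None
        else:
            f1 = 2 * pr * se / (pr + se) if (pr + se) > 0 else 0.0
        per_class.append({"pr": pr, "se": se, "f1": f1})
    macro = {
        key: float(np.mean([p[key] for p in per_class if p[key] is not None]))
        for key in ("pr", "se", "f1")
    }
    tp_total = np.trace(M)
    micro = tp_total / n  # for single-label k-class, micro Pr = Se = F1 = Acc
    pe = float(np.sum(M.sum(axis=0) * M.sum(axis=1)) / n**2)
    kappa = (tp_total / n - pe) / (1 - pe) if pe < 1 else None
    return {
        "per_class": per_class,
        "macro_pr": macro["pr"],
        "macro_se": macro["se"],
        "macro_f1": macro["f1"],
        "micro": float(micro),
        "accuracy": float(tp_total / n),
        "kappa": None if kappa is None else float(kappa),
        "has_undefined_class": any_undefined,
    }
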