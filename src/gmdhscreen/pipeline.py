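"""End-to-end experiment orchestration and report rendering.

Composes the stages — data (synthetic generator or CSV), per-fold
weight-of-evidence encoding and stability selection, classifier training,
stratified cross-validation with shared test folds, significance comparison
— into a single seeded, reproducible run, and renders the pooled /
per-fold / multiclass report tables.

All preprocessing that looks at the outcome is refit inside each training
fold; test rows are only ever transformed and predicted.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema as _schema
from .baselines import BaselineConfig, make_baseline
from .evaluation import (
    compare_classifiers,
    cross_validate,
    macro_metrics,
    stratified_kfold,
)
from .gmdh import GMDHConfig, classify, feature_importance, train_multiclass, train_network
from .preprocessing import (
    StabilitySelectionConfig,
    fit_woe_maps,
    stability_select,
    woe_transform,
)
from .synthetic import GeneratorConfig, generate_dataset

__all__ = [
    "ExperimentConfig",
    "ExperimentError",
    "run_experiment",
    "render_report",
    "make_fold_runner",
]

OUTCOME_VOCABULARY = ("depression", "worriedness", "mild_moderate",
                      "psychiatric", "extended")
CLASSIFIER_VOCABULARY = ("gmdh", "lda", "svm", "mlp")


class ExperimentError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentConfig:
    data: GeneratorConfig | str | Path
    outcomes: tuple[str, ...]
    classifiers: tuple[str, ...] = ("gmdh", "lda")
    k: int = 3
    seed: int = 0
    woe_smoothing: float = 0.5
    use_stability_selection: bool = True
    stability: StabilitySelectionConfig = field(
        default_factory=StabilitySelectionConfig)
    gmdh: GMDHConfig = field(default_factory=GMDHConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    out_dir: str | Path | None = None

    def validate(self) -> None:
        for o in self.outcomes:
            if o not in OUTCOME_VOCABULARY:
                raise ExperimentError(
                    f"unknown outcome {o!r}; expected one of {OUTCOME_VOCABULARY}")
        for c in self.classifiers:
            if c not in CLASSIFIER_VOCABULARY:
                raise ExperimentError(
                    f"unknown classifier {c!r}; expected one of "
                    f"{CLASSIFIER_VOCABULARY}")
        if self.k < 2:
            raise ExperimentError("k must be >= 2")


def _load_data(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (categorical feature table, outcome table)."""
    if isinstance(config.data, GeneratorConfig):
        ds = generate_dataset(config.data)
        return ds.features, ds.outcomes
    df = pd.read_csv(config.data, dtype=str)
    outcome_cols = [c for c in df.columns if c in OUTCOME_VOCABULARY]
    feats = df.drop(columns=outcome_cols + [c for c in ("subject_id",)
                                            if c in df.columns])
    outs = df[outcome_cols].apply(
        lambda c: c if c.name == "extended" else c.astype(int))
    return feats, outs


def _declared_levels(features: pd.DataFrame) -> dict[str, list[str]]:
    """Level sets per column: from the schema registry when the column is a
    registered feature, otherwise the observed values (sorted)."""
    registry = _schema.feature_registry()
    out = {}
    for c in features.columns:
        if c in registry:
            out[c] = list(registry[c].levels)
        else:
            out[c] = sorted(features[c].dropna().unique())
    return out


def make_fold_runner(config: ExperimentConfig, classifier: str, levels):
    """Build the per-fold train/transform/predict closure for one classifier.

    The closure fits WoE maps and (optionally) stability selection on the
    training rows only, then trains the classifier and predicts the test
    rows, returning (labels, scores).
    """

    def fold_fn(X_tr: pd.DataFrame, y_tr, X_te: pd.DataFrame, fold_seed: int):
        maps = fit_woe_maps(X_tr, y_tr, smoothing=config.woe_smoothing,
                            levels=levels)
        Z_tr = woe_transform(X_tr, maps)
        Z_te = woe_transform(X_te, maps)
        cols = list(Z_tr.columns)
        if config.use_stability_selection and len(cols) > 2:
            sel = stability_select(
                Z_tr, y_tr, replace(config.stability, seed=fold_seed))
            if len(sel.selected) >= 2:
                cols = sel.selected
        if classifier == "gmdh":
            net = train_network(Z_tr[cols], y_tr,
                                replace(config.gmdh, seed=fold_seed))
            return classify(net, Z_te[cols])
        model = make_baseline(
            replace(config.baseline, kind=classifier.upper(), seed=fold_seed))
        model.fit(Z_tr[cols], y_tr)
        return model.predict(Z_te[cols]), model.decision_scores(Z_te[cols])

    return fold_fn


def _run_multiclass(config, features, y_labels, levels) -> dict:
    """Three-class cross-validation of the GMDH network (macro-F1 fitness)."""
    classes = np.array(sorted(pd.unique(y_labels)))
    y_idx = np.searchsorted(classes, y_labels)
    folds = stratified_kfold(y_idx, config.k, config.seed)
    cms = []
    for f in range(config.k):
        test = folds == f
        X_tr, X_te = features.loc[~test], features.loc[test]
        y_tr, y_te = y_idx[~test], y_idx[test]
        # multiclass WoE: encode against "high burden vs rest"
        maps = fit_woe_maps(X_tr, (y_tr == y_tr.max()).astype(int),
                            smoothing=config.woe_smoothing, levels=levels)
        Z_tr, Z_te = woe_transform(X_tr, maps), woe_transform(X_te, maps)
        net = train_multiclass(Z_tr, y_tr,
                               replace(config.gmdh, seed=config.seed * 1000 + f))
        pred, _ = classify(net, Z_te)
        cm = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_te, pred):
            cm[int(t), int(p)] += 1
        cms.append(cm)
    pooled = np.sum(cms, axis=0)
    return {"classes": classes, "fold_cms": cms, "pooled_cm": pooled,
            "report": macro_metrics(pooled)}


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the configured experiment; deterministic given (config, seed).

    Returns a bundle with per-(outcome, classifier) cross-validation results,
    the pairwise significance comparison (when >= 2 classifiers), GMDH
    feature-importance rankings, and a run log.  When ``out_dir`` is set,
    metric tables (CSV), the comparison matrix, serialized networks (JSON)
    and the log are written there.
    """
    config.validate()
    t0 = time.perf_counter()
    features, outcome_table = _load_data(config)
    levels = _declared_levels(features)
    log: list[str] = [f"n_subjects={len(features)} features={len(features.columns)}"]

    bundle: dict = {"config": config, "cv": {}, "comparisons": {},
                    "importance": {}, "multiclass": {}, "log": log}
    for outcome in config.outcomes:
        if outcome not in outcome_table.columns:
            raise ExperimentError(f"outcome {outcome!r} not present in data")
        if outcome == "extended":
            bundle["multiclass"][outcome] = _run_multiclass(
                config, features, outcome_table[outcome].to_numpy(), levels)
            continue
        y = outcome_table[outcome].to_numpy(int)
        folds = stratified_kfold(y, config.k, config.seed)
        preds = {}
        for clf in config.classifiers:
            runner = make_fold_runner(config, clf, levels)
            res = cross_validate(runner, features, y, k=config.k,
                                 seed=config.seed, folds=folds)
            bundle["cv"][(outcome, clf)] = res
            preds[clf] = res.pooled_labels
            log.append(f"{outcome}/{clf}: pooled MCC="
                       f"{res.pooled_report.value('mcc'):.3f} "
                       f"AUC={res.auc.value:.3f}")
        if len(preds) >= 2:
            bundle["comparisons"][outcome] = compare_classifiers(preds, y)
        if "gmdh" in config.classifiers:
            # final interpretable network on all rows (internal 75/25 split)
            maps = fit_woe_maps(features, y, smoothing=config.woe_smoothing,
                                levels=levels)
            Z = woe_transform(features, maps)
            net = train_network(Z, y, replace(config.gmdh, seed=config.seed))
            bundle["importance"][outcome] = feature_importance(net)
            bundle.setdefault("networks", {})[outcome] = net
    log.append(f"elapsed={time.perf_counter() - t0:.2f}s seed={config.seed}")

    if config.out_dir is not None:
        _write_outputs(bundle, Path(config.out_dir))
    return bundle


def _write_outputs(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (outcome, clf), res in bundle["cv"].items():
        row = {"outcome": outcome, "classifier": clf,
               **{k: v for k, v in res.pooled_report.to_dict().items()},
               "auc": res.auc.value}
        rows.append(row)
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "pooled_metrics.csv", index=False)
    for outcome, comp in bundle["comparisons"].items():
        comp["pairwise"].to_csv(out_dir / f"comparison_{outcome}.csv", index=False)
    for outcome, net in bundle.get("networks", {}).items():
        (out_dir / f"network_{outcome}.json").write_text(net.to_json())
    (out_dir / "run.log").write_text("\n".join(bundle["log"]) + "\n")
    (out_dir / "report.txt").write_text(render_report(bundle))


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _pct(x, nd=1) -> str:
    if x is None:
        return "NA*"
    return f"{100 * x:.{nd}f}"


def _coef(x, nd=2) -> str:
    if x is None:
        return "NA*"
    return f"{x:.{nd}f}"


def render_report(bundle: dict) -> str:
    """Human-readable per-fold, pooled and multiclass tables.

    Percents are printed to one decimal and coefficients to two; undefined
    metrics (zero denominators) appear as the flagged placeholder ``NA*``.
    """
    if not bundle.get("cv") and not bundle.get("multiclass"):
        raise ExperimentError("empty result bundle")
    lines: list[str] = []
    if bundle.get("cv"):
        lines.append("Per-fold performance (mean +/- SD over test folds, %)")
        lines.append(f"{'outcome':<15}{'clf':<6}{'Se':>14}{'Sp':>14}"
                     f"{'Pr':>14}{'Acc':>14}")
        for (outcome, clf), res in bundle["cv"].items():
            cells = []
            for name in ("se", "sp", "pr", "acc"):
                mean, sd = res.fold_mean_sd(name)
                cells.append(f"{100 * mean:.1f} +/- {100 * sd:.1f}")
            lines.append(f"{outcome:<15}{clf:<6}" + "".join(f"{c:>14}" for c in cells))
        lines.append("")
        lines.append("Pooled cross-validated performance (CI 95%)")
        header = (f"{'outcome':<15}{'clf':<6}{'Se':>16}{'Sp':>16}{'Pr':>16}"
                  f"{'NPV':>16}{'Acc':>16}{'AUC':>8}{'DOR':>8}{'DP':>7}"
                  f"{'MCC':>7}{'kappa':>7}")
        lines.append(header)
        for (outcome, clf), res in bundle["cv"].items():
            rep = res.pooled_report
            cells = []
            for name in ("se", "sp", "pr", "npv", "acc"):
                metr = rep[name]
                if not metr.defined:
                    cells.append("NA*")
                else:
                    lo, hi = metr.ci
                    cells.append(f"{_pct(metr.value)} ({_pct(lo, 0)}, {_pct(hi, 0)})")
            dor = rep["dor"]
            row = (f"{outcome:<15}{clf:<6}"
                   + "".join(f"{c:>16}" for c in cells)
                   + f"{_coef(res.auc.value):>8}"
                   + f"{(_coef(dor.value, 1) if dor.defined else 'NA*'):>8}"
                   + f"{(_coef(rep['dp'].value) if rep['dp'].defined else 'NA*'):>7}"
                   + f"{(_coef(rep['mcc'].value) if rep['mcc'].defined else 'NA*'):>7}"
                   + f"{(_coef(rep['kappa'].value) if rep['kappa'].defined else 'NA*'):>7}")
            lines.append(row)
        lines.append("")
    for outcome, comp in bundle.get("comparisons", {}).items():
        q = comp["cochran_q"]
        lines.append(f"Classifier comparison for {outcome}: Cochran's Q="
                     f"{q['Q']:.2f} (df={q['df']}, p={q['p']:.4g})")
        for _, r in comp["pairwise"].iterrows():
            lines.append(f"  {r['classifier_a']} vs {r['classifier_b']}: "
                         f"b={r['b']} c={r['c']} adj. p={r['p_adjusted']:.4g} "
                         f"({r['method']})")
        lines.append("")
    for outcome, imp in bundle.get("importance", {}).items():
        top = ", ".join(f"{k} ({v})" for k, v in list(imp.items())[:5])
        lines.append(f"Top interacting features for {outcome}: {top}")
    if bundle.get("importance"):
        lines.append("")
    for outcome, mc in bundle.get("multiclass", {}).items():
        rep = mc["report"]
        lines.append(f"Three-class report for {outcome} "
                     f"(classes {list(mc['classes'])}):")
        for cls, pc in zip(mc["classes"], rep["per_class"]):
            lines.append(f"  {cls}: Pr={_pct(pc['pr'])} Se={_pct(pc['se'])}")
        lines.append(f"  macro Pr={_pct(rep['macro_pr'])} "
                     f"Se={_pct(rep['macro_se'])} F1={_pct(rep['macro_f1'])} "
                     f"Acc={_pct(rep['accuracy'])} kappa={_coef(rep['kappa'])}")
    return "\n".join(lines) + "\n"
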