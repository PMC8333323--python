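"""Categorical feature encoding and stability feature selection.

Weight-of-evidence (WoE) turns each categorical feature into a continuous
covariate per binary outcome: a category's code is the log ratio of its
class-conditional shares, with Haldane-style smoothing so empty cells stay
finite.  Stability selection then scores each encoded feature by how often an
L1-penalized logistic model keeps it across many half-sample refits, which is
far more robust to noise than a single lasso fit.

WoE maps are outcome-specific and must be fitted on training rows only (the
cross-validation driver refits them inside each fold to avoid target
leakage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "WoEMap",
    "StabilitySelectionConfig",
    "StabilitySelectionResult",
    "woe_fit",
    "woe_transform",
    "fit_woe_maps",
    "information_value",
    "stability_select",
]


@dataclass
class WoEMap:
    """Per-category weight-of-evidence values for one feature and outcome."""

    feature: str
    outcome: str
    smoothing: float
    mapping: dict[str, float]
    event_counts: dict[str, int]
    nonevent_counts: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def woe_fit(
    column: pd.Series,
    outcome: np.ndarray | pd.Series,
    smoothing: float = 0.5,
    levels: Sequence[str] | None = None,
    outcome_name: str = "y",
) -> WoEMap:
    """Fit WoE values for one categorical column against a binary outcome.

    For category c with e_c events among E and n_c non-events among N over K
    categories and smoothing s:

        WoE(c) = ln((e_c + s) / (E + s K)) - ln((n_c + s) / (N + s K))

    so equal class-conditional shares give WoE 0 and s > 0 keeps every
    category finite.  Raises if the outcome is single-class.
    """
    y = np.asarray(outcome).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class: WoE undefined")
    col = pd.Series(column).astype(object)
    cats = list(levels) if levels is not None else sorted(pd.unique(col.dropna()))
    K = len(cats)
    E, N = int(y.sum()), int((1 - y).sum())
    mapping, ev, nev = {}, {}, {}
    for c in cats:
        in_c = (col == c).to_numpy()
        e_c = int(y[in_c].sum())
        n_c = int((1 - y[in_c]).sum())
        if smoothing == 0 and (e_c == 0 or n_c == 0):
            raise ZeroDivisionError(
                f"category {c!r} has an empty class and smoothing=0; "
                "use smoothing > 0"
            )
        woe = np.log((e_c + smoothing) / (E + smoothing * K)) - np.log(
            (n_c + smoothing) / (N + smoothing * K)
        )
        mapping[c] = float(woe)
        ev[c], nev[c] = e_c, n_c
    return WoEMap(
        feature=str(column.name) if column.name is not None else "feature",
        outcome=outcome_name,
        smoothing=smoothing,
        mapping=mapping,
        event_counts=ev,
        nonevent_counts=nev,
    )


def fit_woe_maps(
    table: pd.DataFrame,
    outcome,
    smoothing: float = 0.5,
    levels: Mapping[str, Sequence[str]] | None = None,
    outcome_name: str = "y",
) -> dict[str, WoEMap]:
    """Fit one WoE map per column of a categorical feature table."""
    maps = {}
    for name in table.columns:
        lv = levels.get(name) if levels is not None else None
        m = woe_fit(table[name], outcome, smoothing=smoothing, levels=lv,
                    outcome_name=outcome_name)
        m.feature = name
        maps[name] = m
    return maps


def woe_transform(
    table: pd.DataFrame, maps: Mapping[str, WoEMap]
) -> pd.DataFrame:
    """Replace each categorical cell by its category's WoE value.

    Raises ``KeyError`` for an unfitted feature or an unseen category, naming
    both, rather than silently imputing.
    """
    out = {}
    for name in table.columns:
        if name not in maps:
            raise KeyError(f"no WoE map fitted for feature {name!r}")
        m = maps[name]
        col = table[name]
        unseen = set(col.dropna().unique()) - set(m.mapping)
        if unseen:
            raise KeyError(
                f"feature {name!r}: unseen categor{'y' if len(unseen)==1 else 'ies'} "
                f"{sorted(unseen)}"
            )
        out[name] = col.map(m.mapping).astype(float)
    return pd.DataFrame(out, index=table.index)


def information_value(woe_map: WoEMap) -> float:
    """Information value: sum_c (event share - nonevent share) * WoE(c)."""
    E = sum(woe_map.event_counts.values())
    N = sum(woe_map.nonevent_counts.values())
    iv = 0.0
    for c, w in woe_map.mapping.items():
        iv += (woe_map.event_counts[c] / E - woe_map.nonevent_counts[c] / N) * w
    return iv


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilitySelectionConfig:
    n_subsamples: int = 100          # complementary half-sample pairs count as 2
    subsample_fraction: float = 0.5
    threshold: float = 0.6
    n_penalties: int = 20            # geometric grid, all-zero point -> noise floor
    max_model_size: int | None = None  # default: ceil(sqrt(p))
    seed: int = 0


@dataclass
class StabilitySelectionResult:
    frequencies: pd.Series           # max admissible-penalty frequency per feature
    selected: list[str]
    per_penalty: pd.DataFrame        # feature x penalty frequency matrix
    admissible: np.ndarray           # penalties with mean model size <= q
    config: StabilitySelectionConfig

    def to_json(self) -> str:
        return json.dumps(
            {
                "frequencies": self.frequencies.round(6).to_dict(),
                "selected": self.selected,
                "threshold": self.config.threshold,
                "n_subsamples": self.config.n_subsamples,
            },
            indent=2,
            sort_keys=True,
        )


def stability_select(
    covariates: pd.DataFrame,
    outcome,
    config: StabilitySelectionConfig = StabilitySelectionConfig(),
) -> StabilitySelectionResult:
    """Score features by selection frequency over half-sample lasso refits.

    Over B subsamples of floor(n/2) rows (drawn as complementary pairs so
    both halves of each random split are used), an L1-penalized logistic
    model is fitted along a geometric penalty grid running from the
    all-coefficients-zero point down to a universal-threshold noise floor
    (the penalty level at which chance correlations start entering the
    path).  A feature's score is its selection frequency maximized over
    *admissible* grid points — those whose average model size stays at or
    below q (default ceil(sqrt(p))), which bounds false selections in the
    usual stability-selection sense.  Features with score >= threshold are
    selected.
    """
    X = covariates.to_numpy(dtype=float)
    y = np.asarray(outcome).astype(int)
    n, p = X.shape
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    if int(np.floor(n * config.subsample_fraction)) < 4:
        raise ValueError("too few rows for half-sample subsampling")
    names = list(covariates.columns)
    q = config.max_model_size or int(np.ceil(np.sqrt(p)))

    # standardize so the penalty treats features symmetrically
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd

    rng = np.random.default_rng(config.seed)
    m = int(np.floor(n * config.subsample_fraction))

    # Penalty grid on the half-sample scale.  A feature enters the
    # liblinear L1 path once C * |x_j'(y - ybar)| >= 1, so the grid runs
    # from the (expected) all-zero point down to a universal-threshold
    # floor sqrt(2 ln p * m * var(y)) — the level at which pure-noise
    # scores start to enter.  Penalties below the floor would admit chance
    # correlations and are never visited.
    score_full = np.abs(Xs.T @ (y - y.mean()))
    lam_max = max(score_full.max() * (m / n), 1e-12)
    lam_floor = np.sqrt(2.0 * np.log(max(p, 2)) * m * y.mean() * (1 - y.mean()))
    lam_hi = max(lam_max, lam_floor)
    grid = 1.0 / np.geomspace(lam_hi, lam_floor, config.n_penalties)
    halves = []
    while len(halves) < config.n_subsamples:
        perm = rng.permutation(n)
        halves.append(perm[:m])
        if len(halves) < config.n_subsamples:
            halves.append(perm[m:2 * m])

    nonzero = np.zeros((config.n_penalties, p))
    for idx in halves:
        Xi, yi = Xs[idx], y[idx]
        if yi.min() == yi.max():  # degenerate subsample: nothing selectable
            continue
        clf = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", warm_start=True,
            fit_intercept=True, tol=1e-4, max_iter=200, C=grid[0],
        )
        for gi, C in enumerate(grid):
            clf.C = C
            clf.fit(Xi, yi)
            nonzero[gi] += np.abs(clf.coef_[0]) > 1e-8
    freq = nonzero / len(halves)
    mean_size = freq.sum(axis=1)
    admissible = mean_size <= q
    if not admissible.any():
        admissible = np.zeros_like(admissible)
        admissible[0] = True  # fall back to the most regularized point
    scores = freq[admissible].max(axis=0)
    series = pd.Series(scores, index=names, name="selection_frequency")
    selected = [f for f, s in series.items() if s >= config.threshold]
    per_penalty = pd.DataFrame(freq.T, index=names,
                               columns=[f"C={c:.4g}" for c in grid])
    return StabilitySelectionResult(series, selected, per_penalty,
                                    admissible, config)
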