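"""Synthetic survey populations with known ground truth.

Generates categorical feature tables shaped like the 25-variable school
survey, with binary outcomes drawn from a logistic model whose main effects
and pure pairwise interactions are configured explicitly.  The intercept is
calibrated so the realized prevalence matches a target; missingness is
injected completely at random (MCAR).  Because the ground truth is known, the
Bayes-optimal classifier (and its MCC) is computable in closed form, which
gives downstream classifiers an absolute yardstick.

Features are drawn independently of each other; the outcome is the only
source of dependence.  That is the simplest design under which a planted
interaction with zero main effects is *marginally* invisible (each feature
alone carries no signal) while being jointly predictive — the regime the
interaction network is built to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import schema as _schema
from . import fixtures as _fixtures

__all__ = [
    "FeatureSpec",
    "Interaction",
    "OutcomeSpec",
    "GeneratorConfig",
    "SyntheticDataset",
    "CalibrationError",
    "generate_dataset",
    "inject_missingness",
    "complete_case_filter",
    "calibrate_intercept",
    "cell_distribution",
    "bayes_optimal_mcc",
    "xor_interaction",
    "xor_config",
    "survey_generator_config",
]


class CalibrationError(RuntimeError):
    """The target prevalence could not be reached by intercept calibration."""


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self):
        if len(self.levels) != len(self.probs):
            raise ValueError(f"feature {self.name!r}: levels/probs length mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(f"feature {self.name!r}: marginal must sum to 1")


@dataclass(frozen=True)
class Interaction:
    """Pure pairwise effect: log-odds added per (level_a, level_b) cell."""

    feature_a: str
    feature_b: str
    weights: Mapping[tuple[str, str], float]


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    prevalence: float
    main_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    interactions: tuple[Interaction, ...] = ()

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(
                f"outcome {self.name!r}: target prevalence must be in (0, 1)"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int
    features: tuple[FeatureSpec, ...]
    outcomes: tuple[OutcomeSpec, ...]
    missing_rate: float = 0.0
    seed: int = 0

    def feature(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"unknown feature {name!r}")

    def outcome(self, name: str) -> OutcomeSpec:
        for o in self.outcomes:
            if o.name == name:
                return o
        raise KeyError(f"unknown outcome {name!r}")


@dataclass
class SyntheticDataset:
    features: pd.DataFrame
    outcomes: pd.DataFrame
    config: GeneratorConfig
    intercepts: dict[str, float]

    @property
    def n(self) -> int:
        return len(self.features)


# Stage tags for the counter-based substreams: each stage gets its own
# generator seeded by (seed, stage), so e.g. missingness injection never
# perturbs the feature or outcome draws.
_STAGE_FEATURES = 1
_STAGE_OUTCOME = 2
_STAGE_MISSING = 3


def _rng(seed: int, stage: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, stage, index])


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def _involved_features(spec: OutcomeSpec) -> list[str]:
    names: list[str] = []
    for fname, _level in spec.main_effects:
        if fname not in names:
            names.append(fname)
    for inter in spec.interactions:
        for fname in (inter.feature_a, inter.feature_b):
            if fname not in names:
                names.append(fname)
    return names


def _cell_eta(spec: OutcomeSpec, cell: Mapping[str, str]) -> float:
    eta = 0.0
    for (fname, level), w in spec.main_effects.items():
        if cell[fname] == level:
            eta += w
    for inter in spec.interactions:
        pair = (cell[inter.feature_a], cell[inter.feature_b])
        eta += inter.weights.get(pair, 0.0)
    return eta


def cell_distribution(
    config: GeneratorConfig, outcome: str
) -> tuple[np.ndarray, np.ndarray]:
    """(mass, eta) over the joint cells of features that carry effects.

    Features are independent, so the joint probability of a cell is the
    product of its level probabilities; only features referenced by the
    outcome's effects need enumeration.  For an effect-free outcome this is a
    single cell of mass 1 and eta 0.
    """
    spec = config.outcome(outcome)
    involved = _involved_features(spec)
    if not involved:
        return np.array([1.0]), np.array([0.0])
    specs = [config.feature(name) for name in involved]
    masses, etas = [], []
    for combo in product(*(range(len(s.levels)) for s in specs)):
        mass = 1.0
        cell = {}
        for s, li in zip(specs, combo):
            mass *= s.probs[li]
            cell[s.name] = s.levels[li]
        masses.append(mass)
        etas.append(_cell_eta(spec, cell))
    return np.asarray(masses), np.asarray(etas)


def calibrate_intercept(
    config: GeneratorConfig, outcome: str, tol: float = 1e-10, max_iter: int = 200
) -> float:
    """Intercept b0 with population prevalence equal to the target.

    The population prevalence sum_cells mass * sigmoid(b0 + eta_cell) is
    exact under feature independence, so bisection converges to machine
    precision.  Raises :class:`CalibrationError` if no bracket is found
    within the iteration budget (cannot happen for targets inside (0, 1)
    unless effects are non-finite).
    """
    spec = config.outcome(outcome)
    mass, eta = cell_distribution(config, outcome)

    def prev(b0: float) -> float:
        return float(np.sum(mass * _sigmoid(b0 + eta)))

    lo, hi = -1.0, 1.0
    it = 0
    while prev(lo) > spec.prevalence:
        lo *= 2.0
        it += 1
        if it > max_iter or not np.isfinite(lo):
            raise CalibrationError(f"no lower bracket for {outcome!r}")
    while prev(hi) < spec.prevalence:
        hi *= 2.0
        it += 1
        if it > max_iter or not np.isfinite(hi):
            raise CalibrationError(f"no upper bracket for {outcome!r}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if prev(mid) < spec.prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _linear_predictor(spec: OutcomeSpec, features: pd.DataFrame) -> np.ndarray:
    eta = np.zeros(len(features))
    for (fname, level), w in spec.main_effects.items():
        eta += w * (features[fname] == level).to_numpy()
    for inter in spec.interactions:
        a = features[inter.feature_a].to_numpy()
        b = features[inter.feature_b].to_numpy()
        for (la, lb), w in inter.weights.items():
            eta += w * ((a == la) & (b == lb))
    return eta


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a reproducible synthetic population from the configured model."""
    rng = _rng(config.seed, _STAGE_FEATURES)
    cols = {}
    for spec in config.features:
        codes = rng.choice(len(spec.levels), size=config.n_subjects, p=spec.probs)
        cols[spec.name] = np.asarray(spec.levels, dtype=object)[codes]
    features = pd.DataFrame(cols)

    outcomes = {}
    intercepts = {}
    for idx, ospec in enumerate(config.outcomes):
        b0 = calibrate_intercept(config, ospec.name)
        intercepts[ospec.name] = b0
        p = _sigmoid(b0 + _linear_predictor(ospec, features))
        orng = _rng(config.seed, _STAGE_OUTCOME, idx)
        outcomes[ospec.name] = (orng.random(config.n_subjects) < p).astype(int)
    outcomes_df = pd.DataFrame(outcomes)

    ds = SyntheticDataset(features, outcomes_df, config, intercepts)
    if config.missing_rate > 0:
        ds = inject_missingness(ds, config.missing_rate)
    return ds


def inject_missingness(
    dataset: SyntheticDataset,
    rate: float,
    protected_columns: Sequence[str] = (),
) -> SyntheticDataset:
    """Delete feature cells independently with the given probability (MCAR).

    Outcomes are always protected; ``protected_columns`` additionally shields
    named feature columns.  Returns a new dataset; the input is not mutated.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("missing rate must be in [0, 1]")
    unknown = set(protected_columns) - set(dataset.features.columns)
    if unknown:
        raise KeyError(f"protected columns not in schema: {sorted(unknown)}")
    feats = dataset.features.copy()
    rng = _rng(dataset.config.seed, _STAGE_MISSING)
    for col in feats.columns:
        mask = rng.random(len(feats)) < rate
        if col in protected_columns:
            continue
        feats.loc[mask, col] = np.nan
    return SyntheticDataset(feats, dataset.outcomes.copy(), dataset.config,
                            dict(dataset.intercepts))


def complete_case_filter(
    dataset: SyntheticDataset,
) -> tuple[SyntheticDataset, int]:
    """Restrict to rows with every feature observed; returns (subset, n_removed)."""
    keep = dataset.features.notna().all(axis=1)
    n_removed = int((~keep).sum())
    sub = SyntheticDataset(
        dataset.features.loc[keep].reset_index(drop=True),
        dataset.outcomes.loc[keep].reset_index(drop=True),
        dataset.config,
        dict(dataset.intercepts),
    )
    return sub, n_removed


# ---------------------------------------------------------------------------
# Ground-truth yardsticks
# ---------------------------------------------------------------------------

def bayes_optimal_mcc(config: GeneratorConfig, outcome: str) -> float:
    """MCC of the Bayes-optimal deterministic classifier for this outcome.

    The optimal rule thresholds the posterior P(y=1 | cell), so it suffices
    to sort cells by posterior and scan prefix rules, computing the exact
    population confusion mass of each.
    """
    b0 = calibrate_intercept(config, outcome)
    mass, eta = cell_distribution(config, outcome)
    post = _sigmoid(b0 + eta)
    order = np.argsort(-post, kind="stable")
    mass, post = mass[order], post[order]
    pos = mass * post          # P(cell, y=1)
    neg = mass * (1.0 - post)  # P(cell, y=0)
    P, N = pos.sum(), neg.sum()
    best = 0.0
    tp = fp = 0.0
    for i in range(len(mass)):  # predict positive on cells 0..i
        tp += pos[i]
        fp += neg[i]
        fn, tn = P - tp, N - fp
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom > 0:
            mcc = (tp * tn - fp * fn) / np.sqrt(denom)
            best = max(best, mcc)
    return float(best)


def xor_interaction(
    feature_a: str, feature_b: str, weight: float, levels: Sequence[str] = ("0", "1")
) -> Interaction:
    """Interaction adding ``weight`` log-odds when the two levels differ."""
    weights = {
        (la, lb): (weight if la != lb else 0.0)
        for la in levels
        for lb in levels
    }
    return Interaction(feature_a, feature_b, weights)


def xor_config(
    n_subjects: int,
    n_noise: int = 8,
    weight: float = 2.0,
    prevalence: float = 0.2,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GeneratorConfig:
    """Planted-interaction benchmark: one XOR pair, zero main effects.

    Two balanced binary features ``a`` and ``b`` carry a pure pairwise effect
    (``weight`` log-odds when they disagree) plus ``n_noise`` balanced binary
    noise features.  Marginally each feature is independent of the outcome.
    """
    feats = [
        FeatureSpec("a", ("0", "1"), (0.5, 0.5)),
        FeatureSpec("b", ("0", "1"), (0.5, 0.5)),
    ]
    feats += [
        FeatureSpec(f"noise{i}", ("0", "1"), (0.5, 0.5)) for i in range(n_noise)
    ]
    outcome = OutcomeSpec(
        "y",
        prevalence=prevalence,
        interactions=(xor_interaction("a", "b", weight),),
    )
    return GeneratorConfig(
        n_subjects=n_subjects,
        features=tuple(feats),
        outcomes=(outcome,),
        missing_rate=missing_rate,
        seed=seed,
    )


def _survey_marginals() -> list[FeatureSpec]:
    """Feature marginals estimated from the packaged cohort count tables."""
    counts = _fixtures.load_marginal_counts("all")
    specs = []
    for feat in _schema.FEATURES:
        sub = counts[(counts["feature"] == feat.name)
                     & (counts["outcome"] == "worriedness")]
        sizes = (sub["count_no"] + sub["count_yes"]).to_numpy(float)
        by_cat = dict(zip(sub["category"], sizes / sizes.sum()))
        probs = np.array([by_cat[lv] for lv in feat.levels])
        probs = probs / probs.sum()
        specs.append(FeatureSpec(feat.name, feat.levels, tuple(probs)))
    return specs


#: Default main effects for the survey emulation: the features whose
#: category shares differ most strongly between outcome groups in the count
#: tables, with modest log-odds so the outcome stays noisy and realistic.
_SURVEY_EFFECTS = {
    "worriedness": {
        ("life_satisfaction_cat", "low"): 1.8,
        ("age_cat", "6-10"): -0.8,
        ("age_cat", "15-19"): 0.4,
        ("sex", "girl"): 0.3,
        ("breakfast_cat", "skipper"): 0.3,
        ("physical_activity", "severe"): -0.3,
    },
    "depression": {
        ("life_satisfaction_cat", "low"): 1.6,
        ("srh", "bad"): 1.5,
        ("age_cat", "6-10"): -0.7,
        ("sex", "girl"): 0.2,
        ("breakfast_cat", "skipper"): 0.4,
        ("screen_cat", ">4h"): 0.2,
    },
    "mild_moderate": {
        ("life_satisfaction_cat", "low"): 1.3,
        ("srh", "bad"): 1.2,
        ("age_cat", "6-10"): -1.0,
        ("sex", "girl"): 0.4,
        ("sleep_cat", "<=5h"): 0.5,
    },
}

#: Complete-case outcome prevalences observed in the cohort tables.
SURVEY_PREVALENCE = {
    "worriedness": 0.237,
    "depression": 0.201,
    "mild_moderate": 0.111,
}


def survey_generator_config(
    n_subjects: int, seed: int = 0, missing_rate: float = 0.0
) -> GeneratorConfig:
    """25-feature survey emulation at the cohort's marginals and prevalences."""
    outcomes = tuple(
        OutcomeSpec(name, SURVEY_PREVALENCE[name],
                    main_effects=dict(_SURVEY_EFFECTS[name]))
        for name in ("worriedness", "depression", "mild_moderate")
    )
    return GeneratorConfig(
        n_subjects=n_subjects,
        features=tuple(_survey_marginals()),
        outcomes=outcomes,
        missing_rate=missing_rate,
        seed=seed,
    )
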