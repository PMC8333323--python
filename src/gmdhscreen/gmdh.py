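"""Regularized GMDH polynomial interaction network.

The Group Method of Data Handling builds a self-organizing network out of
second-order polynomial "neurons": each neuron models the outcome from one
pair of inputs as

    y ~ a0 + a1*u + a2*v + a3*u^2 + a4*v^2 + a5*u*v

with coefficients estimated by ridge (regularized least squares),
A = (X'X + lambda*I6)^-1 X'Y, on an estimation subset.  The ridge strength is
brute-force tuned per neuron to maximize validation fitness — the Matthews
correlation coefficient (MCC) for binary outcomes (each neuron's decision
cut is fitted on the estimation scores, so the validation MCC is an honest
external criterion), macro-averaged F1 for the three-class problem.  Layers
are grown by
pairing the previous layer's retained neurons (at most 10, each required to
beat the previous layer's best) and growth stops as soon as a new layer fails
to improve validation fitness; the best neuron at the stop is the network
output.  The wiring that survives is an interpretable interaction graph:
features that appear often in it are the ones whose interactions matter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "GMDHConfig",
    "Neuron",
    "GMDHNetwork",
    "GMDHTrainingError",
    "default_lambda_grid",
    "design_matrix",
    "fit_neuron_rls",
    "neuron_predict",
    "best_mcc_threshold",
    "mcc_from_counts",
    "macro_f1",
    "tune_lambda",
    "build_layer",
    "train_network",
    "train_multiclass",
    "classify",
    "feature_importance",
    "GMDHClassifier",
]


class GMDHTrainingError(RuntimeError):
    pass


def default_lambda_grid() -> tuple[float, ...]:
    """0 plus 25 log-spaced ridge strengths in [1e-4, 1e2]."""
    return (0.0, *np.logspace(-4, 2, 25))


@dataclass(frozen=True)
class GMDHConfig:
    max_neurons_per_layer: int = 10
    lambda_grid: tuple[float, ...] = field(default_factory=default_lambda_grid)
    fitness: str = "mcc"               # "mcc" (binary) or "macro_f1" (3-class)
    estimation_fraction: float = 0.75  # estimation/validation split of training
    max_layers: int | None = None      # default ceil(p/2)+1 for p inputs
    seed: int = 0


# Node references: ("x", j) is input feature j; ("n", layer, pos) is the
# pos-th retained neuron of a layer (layers are 0-indexed internally).
NodeRef = tuple


@dataclass
class Neuron:
    parents: tuple[NodeRef, NodeRef]
    coef: np.ndarray            # [a0..a5]
    lam: float
    fitness: float
    threshold: float | None     # None for the macro-F1 (regression) fitness
    layer: int


@dataclass
class GMDHNetwork:
    layers: list[list[Neuron]]
    output_ref: NodeRef
    threshold: float | None
    fitness_trajectory: list[float]
    config: GMDHConfig
    feature_names: list[str]
    classes: np.ndarray | None = None   # set for the multiclass variant
    est_indices: np.ndarray | None = None
    est_scores: np.ndarray | None = None

    @property
    def output(self) -> Neuron:
        _, layer, pos = self.output_ref
        return self.layers[layer][pos]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        def ref(r):
            return list(r)

        payload = {
            "feature_names": self.feature_names,
            "output_ref": ref(self.output_ref),
            "threshold": self.threshold,
            "fitness_trajectory": self.fitness_trajectory,
            "classes": None if self.classes is None else self.classes.tolist(),
            "config": {
                "max_neurons_per_layer": self.config.max_neurons_per_layer,
                "lambda_grid": list(self.config.lambda_grid),
                "fitness": self.config.fitness,
                "estimation_fraction": self.config.estimation_fraction,
                "max_layers": self.config.max_layers,
                "seed": self.config.seed,
            },
            "layers": [
                [
                    {
                        "parents": [ref(n.parents[0]), ref(n.parents[1])],
                        "coef": n.coef.tolist(),
                        "lam": n.lam,
                        "fitness": n.fitness,
                        "threshold": n.threshold,
                        "layer": n.layer,
                    }
                    for n in layer
                ]
                for layer in self.layers
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GMDHNetwork":
        d = json.loads(text)

        def ref(r):
            return tuple(r)

        layers = [
            [
                Neuron(
                    parents=(ref(n["parents"][0]), ref(n["parents"][1])),
                    coef=np.asarray(n["coef"], dtype=float),
                    lam=n["lam"],
                    fitness=n["fitness"],
                    threshold=n["threshold"],
                    layer=n["layer"],
                )
                for n in layer
            ]
            for layer in d["layers"]
        ]
        cfg = GMDHConfig(
            max_neurons_per_layer=d["config"]["max_neurons_per_layer"],
            lambda_grid=tuple(d["config"]["lambda_grid"]),
            fitness=d["config"]["fitness"],
            estimation_fraction=d["config"]["estimation_fraction"],
            max_layers=d["config"]["max_layers"],
            seed=d["config"]["seed"],
        )
        return cls(
            layers=layers,
            output_ref=ref(d["output_ref"]),
            threshold=d["threshold"],
            fitness_trajectory=d["fitness_trajectory"],
            config=cfg,
            feature_names=d["feature_names"],
            classes=None if d["classes"] is None else np.asarray(d["classes"]),
        )

    def to_graph(self) -> list[tuple[str, str]]:
        """Wiring as (parent, child) edges with readable node names."""
        def name(r):
            if r[0] == "x":
                return self.feature_names[r[1]]
            return f"N{r[1] + 1}.{r[2] + 1}"

        edges = []
        for layer in self.layers:
            for pos, neuron in enumerate(layer):
                child = name(("n", neuron.layer, pos))
                for par in neuron.parents:
                    edges.append((name(par), child))
        return edges


# ---------------------------------------------------------------------------
# Neuron-level operations
# ---------------------------------------------------------------------------

def design_matrix(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """N x 6 matrix with columns [1, u, v, u^2, v^2, u*v]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return np.column_stack([np.ones_like(u), u, v, u * u, v * v, u * v])


def fit_neuron_rls(u, v, y, lam: float = 0.0) -> np.ndarray:
    """Ridge solution A = (X'X + lam*I6)^-1 X'Y for one neuron.

    With ``lam = 0`` this is ordinary least squares on the quadratic design;
    a singular Gram matrix then raises a ``LinAlgError`` with guidance to use
    lam > 0.
    """
    X = design_matrix(u, v)
    y = np.asarray(y, dtype=float)
    G = X.T @ X + lam * np.eye(6)
    b = X.T @ y
    try:
        with warnings.catch_warnings():
            # an ill-conditioned Gram matrix is as unusable as a singular one
            warnings.simplefilter("error", scipy.linalg.LinAlgWarning)
            return scipy.linalg.solve(G, b, assume_a="pos")
    except (scipy.linalg.LinAlgError, scipy.linalg.LinAlgWarning) as err:
        raise np.linalg.LinAlgError(
            "singular normal equations (collinear neuron inputs); "
            "use a ridge parameter lam > 0"
        ) from err


def _eval_poly(coef: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    # single evaluation routine shared by training and prediction so that
    # re-predicting stored inputs is bit-for-bit reproducible
    return (coef[0] + coef[1] * u + coef[2] * v
            + coef[3] * u * u + coef[4] * v * v + coef[5] * u * v)


def neuron_predict(neuron: Neuron, u, v) -> np.ndarray:
    """Evaluate one neuron's quadratic on its two (already computed) inputs."""
    return _eval_poly(neuron.coef, np.asarray(u, float), np.asarray(v, float))


def mcc_from_counts(tp, tn, fp, fn):
    """MCC with the 0-on-degenerate-denominator convention (array-safe)."""
    tp, tn, fp, fn = (np.asarray(a, dtype=float) for a in (tp, tn, fp, fn))
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    num = tp * tn - fp * fn
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    return out if out.ndim else float(out)


def best_mcc_threshold(scores, y) -> tuple[float, float]:
    """(threshold, MCC) maximizing MCC of ``score >= threshold`` over all cuts.

    Candidate cuts sit between consecutive distinct sorted scores (plus the
    all-negative and all-positive rules).  Ties in MCC are broken toward the
    larger threshold (fewer predicted positives), which makes the choice
    deterministic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    P = int(y.sum())
    N = y.size - P
    cum_tp = np.concatenate([[0], np.cumsum(y_sorted)])
    cum_fp = np.concatenate([[0], np.cumsum(1 - y_sorted)])
    # valid cut positions: after i elements where s[i-1] > s[i] (plus ends)
    boundary = np.ones(y.size + 1, dtype=bool)
    boundary[1:-1] = s_sorted[:-1] > s_sorted[1:]
    idx = np.flatnonzero(boundary)
    mcc = mcc_from_counts(cum_tp[idx], N - cum_fp[idx], cum_fp[idx],
                          P - cum_tp[idx])
    best = int(np.argmax(mcc))  # argmax keeps the first (largest threshold)
    cut = idx[best]
    if cut == 0:
        thr = s_sorted[0] + 1.0
    elif cut == y.size:
        thr = s_sorted[-1]
    else:
        thr = 0.5 * (s_sorted[cut - 1] + s_sorted[cut])
    return float(thr), float(mcc[best])


def macro_f1(y_true, y_pred, classes: Sequence | None = None) -> float:
    """Unweighted mean of per-class one-vs-rest F1 scores."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(y_true)
    f1s = []
    for c in classes:
        tp = np.sum((y_true == c) & (y_pred == c))
        fp = np.sum((y_true != c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0)
    return float(np.mean(f1s))


def mcc_at_threshold(scores, y, threshold: float) -> float:
    s = np.asarray(scores, dtype=float)
    yy = np.asarray(y).astype(int)
    pred = s >= threshold
    tp = np.sum(pred & (yy == 1))
    fp = np.sum(pred & (yy == 0))
    fn = np.sum(~pred & (yy == 1))
    tn = np.sum(~pred & (yy == 0))
    return float(mcc_from_counts(tp, tn, fp, fn))


def _fitness_binary(scores_est, y_est, scores_val, y_val) -> tuple[float, float]:
    """Validation MCC at the estimation-fitted decision threshold.

    The cut is part of the fitted neuron (chosen on the estimation scores),
    so the validation MCC is an honest external assessment: a neuron that
    overfits the estimation set is penalized rather than rescued by
    re-tuning its cut on the validation data.
    """
    thr, _ = best_mcc_threshold(scores_est, y_est)
    return mcc_at_threshold(scores_val, y_val, thr), thr


def _make_fitness(kind: str, classes: np.ndarray | None):
    if kind == "mcc":
        return _fitness_binary
    if kind == "macro_f1":
        k = len(classes) if classes is not None else 3

        def fn(scores_est, y_est, scores_val, y_val):
            pred = np.clip(np.rint(scores_val), 0, k - 1)
            return macro_f1(y_val, pred, classes=range(k)), None

        return fn
    raise ValueError(f"unknown fitness kind {kind!r}")


def tune_lambda(
    u_est, v_est, y_est, u_val, v_val, y_val,
    grid: Sequence[float] = None,
    fitness: Callable = _fitness_binary,
):
    """Brute-force ridge search maximizing validation fitness.

    Returns (lam, coef, fitness, threshold).  Ties are broken toward the
    smaller ridge strength; a singular lam=0 fit is skipped rather than
    fatal.  Raises if the validation outcome is single-class.
    """
    y_val_arr = np.asarray(y_val)
    if np.unique(y_val_arr).size < 2:
        raise GMDHTrainingError("validation split has a single outcome class")
    if grid is None:
        grid = default_lambda_grid()
    y_est_arr = np.asarray(y_est)
    best = None
    for lam in sorted(grid):
        try:
            coef = fit_neuron_rls(u_est, v_est, y_est, lam)
        except np.linalg.LinAlgError:
            continue
        scores_est = _eval_poly(coef, np.asarray(u_est, float),
                                np.asarray(v_est, float))
        scores_val = _eval_poly(coef, np.asarray(u_val, float),
                                np.asarray(v_val, float))
        fit, thr = fitness(scores_est, y_est_arr, scores_val, y_val_arr)
        if best is None or fit > best[2]:
            best = (lam, coef, fit, thr)
    if best is None:
        raise GMDHTrainingError("no ridge value produced a well-posed fit")
    return best


# ---------------------------------------------------------------------------
# Layer construction and network training
# ---------------------------------------------------------------------------

def build_layer(
    inputs_est: np.ndarray,
    inputs_val: np.ndarray,
    y_est,
    y_val,
    config: GMDHConfig,
    prev_best: float | None = None,
    layer_index: int = 0,
    parent_refs: Sequence[NodeRef] | None = None,
    fitness: Callable | None = None,
):
    """Fit one neuron per unordered input pair and retain the survivors.

    Candidates are ranked by validation fitness (ties by lexicographic input
    indices).  At most ``max_neurons_per_layer`` are retained; past the first
    layer a candidate must strictly beat ``prev_best``.  Degenerate neurons
    (constant output on the estimation set) are discarded before ranking.

    Returns (neurons, est_outputs, val_outputs) with outputs column-aligned
    to the retained neurons.
    """
    m = inputs_est.shape[1]
    if m < 2:
        raise GMDHTrainingError("need at least 2 candidate inputs for a layer")
    if parent_refs is None:
        parent_refs = [("x", j) for j in range(m)]
    if fitness is None:
        fitness = _fitness_binary
    candidates = []
    for j, k in combinations(range(m), 2):
        lam, coef, fit, thr = tune_lambda(
            inputs_est[:, j], inputs_est[:, k], y_est,
            inputs_val[:, j], inputs_val[:, k], y_val,
            grid=config.lambda_grid, fitness=fitness,
        )
        out_est = _eval_poly(coef, inputs_est[:, j], inputs_est[:, k])
        if np.ptp(out_est) == 0:
            continue  # degenerate: constant on the estimation set
        candidates.append((fit, j, k, lam, coef, thr))
    if not candidates:
        return [], np.empty((inputs_est.shape[0], 0)), np.empty((inputs_val.shape[0], 0))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    if prev_best is not None:
        candidates = [c for c in candidates if c[0] > prev_best]
    candidates = candidates[: config.max_neurons_per_layer]
    neurons = [
        Neuron(parents=(parent_refs[j], parent_refs[k]), coef=coef, lam=lam,
               fitness=fit, threshold=thr, layer=layer_index)
        for fit, j, k, lam, coef, thr in candidates
    ]
    est_out = np.column_stack(
        [_eval_poly(n.coef, inputs_est[:, c[1]], inputs_est[:, c[2]])
         for n, c in zip(neurons, candidates)]
    ) if neurons else np.empty((inputs_est.shape[0], 0))
    val_out = np.column_stack(
        [_eval_poly(n.coef, inputs_val[:, c[1]], inputs_val[:, c[2]])
         for n, c in zip(neurons, candidates)]
    ) if neurons else np.empty((inputs_val.shape[0], 0))
    return neurons, est_out, val_out


def _stratified_split(y: np.ndarray, fraction: float, seed: int):
    """Per-class seeded shuffle, first ``fraction`` to estimation."""
    rng = np.random.default_rng([seed, 11])
    est_idx, val_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_est = int(round(fraction * idx.size))
        n_est = min(max(n_est, 1), idx.size - 1)
        est_idx.append(idx[:n_est])
        val_idx.append(idx[n_est:])
    return np.sort(np.concatenate(est_idx)), np.sort(np.concatenate(val_idx))


def _as_matrix(covariates) -> tuple[np.ndarray, list[str]]:
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), [str(c) for c in covariates.columns]
    X = np.asarray(covariates, dtype=float)
    return X, [f"x{j + 1}" for j in range(X.shape[1])]


def train_network(covariates, outcome, config: GMDHConfig = GMDHConfig()) -> GMDHNetwork:
    """Grow a GMDH network with validation-based selection and early stopping.

    The training rows are split (stratified, seeded) into an estimation part
    — used for the ridge fits — and a validation part — used for ridge
    tuning, neuron ranking, retention, the stopping rule and the decision
    threshold.  Growth stops when a new layer's best validation fitness does
    not exceed the running best; the best neuron at that point is the output.
    """
    X, names = _as_matrix(covariates)
    y = np.asarray(outcome).astype(int)
    if X.shape[1] < 2:
        raise GMDHTrainingError("need at least 2 features")
    classes = np.unique(y)
    if config.fitness == "mcc" and classes.size != 2:
        raise GMDHTrainingError("MCC fitness requires a binary outcome")
    if np.min(np.bincount(np.searchsorted(classes, y))) < 2:
        raise GMDHTrainingError("every class needs >= 2 members to split")

    est_idx, val_idx = _stratified_split(y, config.estimation_fraction, config.seed)
    y_est, y_val = y[est_idx], y[val_idx]
    if np.unique(y_est).size < classes.size or np.unique(y_val).size < classes.size:
        raise GMDHTrainingError("a class is absent from the estimation or "
                                "validation split")
    fitness = _make_fitness(config.fitness, classes)

    p = X.shape[1]
    max_layers = config.max_layers or (int(np.ceil(p / 2)) + 1)

    layers: list[list[Neuron]] = []
    trajectory: list[float] = []
    inputs_est, inputs_val = X[est_idx], X[val_idx]
    refs: list[NodeRef] = [("x", j) for j in range(p)]
    best_fit: float | None = None
    est_out_best: np.ndarray | None = None
    val_out_best: np.ndarray | None = None

    for L in range(max_layers):
        neurons, est_out, val_out = build_layer(
            inputs_est, inputs_val, y_est, y_val, config,
            prev_best=best_fit, layer_index=L, parent_refs=refs,
            fitness=fitness,
        )
        if not neurons:
            if L == 0:
                raise GMDHTrainingError("all first-layer neurons are degenerate")
            break  # no candidate beat the running best: early stop
        layers.append(neurons)
        trajectory.append(neurons[0].fitness)
        best_fit = neurons[0].fitness
        est_out_best = est_out[:, 0]
        val_out_best = val_out[:, 0]
        inputs_est, inputs_val = est_out, val_out
        refs = [("n", L, pos) for pos in range(len(neurons))]
        if len(neurons) < 2:
            break  # a single retained neuron cannot form another pair

    if not layers:
        raise GMDHTrainingError("training produced no usable neurons "
                                "(all first-layer candidates degenerate)")
    output_ref = ("n", len(layers) - 1, 0)
    out_neuron = layers[-1][0]
    if config.fitness == "mcc":
        # final decision threshold: validation-MCC-optimal cut of the
        # output neuron's validation scores
        val_scores_out = val_out_best
        final_threshold, _ = best_mcc_threshold(val_scores_out, y_val)
    else:
        final_threshold = None
    net = GMDHNetwork(
        layers=layers,
        output_ref=output_ref,
        threshold=final_threshold,
        fitness_trajectory=trajectory,
        config=config,
        feature_names=names,
        classes=classes if config.fitness == "macro_f1" else None,
        est_indices=est_idx,
        est_scores=est_out_best,
    )
    return net


def train_multiclass(covariates, class_labels, config: GMDHConfig = GMDHConfig()) -> GMDHNetwork:
    """Three-class variant: regress the ordinal class index, macro-F1 fitness.

    A single network regresses the class index {0, 1, 2}; prediction snaps
    the continuous output to the nearest index.  With only two classes this
    delegates to the binary MCC path so the two entry points agree.
    """
    y_raw = np.asarray(class_labels)
    classes = np.unique(y_raw)
    y_idx = np.searchsorted(classes, y_raw)
    if classes.size == 2:
        net = train_network(covariates, y_idx, replace(config, fitness="mcc"))
        net.classes = classes
        return net
    net = train_network(covariates, y_idx, replace(config, fitness="macro_f1"))
    net.classes = classes
    return net


# ---------------------------------------------------------------------------
# Prediction and interpretation
# ---------------------------------------------------------------------------

def _node_values(network: GMDHNetwork, X: np.ndarray, ref: NodeRef, cache: dict):
    if ref in cache:
        return cache[ref]
    if ref[0] == "x":
        val = X[:, ref[1]]
    else:
        neuron = network.layers[ref[1]][ref[2]]
        u = _node_values(network, X, neuron.parents[0], cache)
        v = _node_values(network, X, neuron.parents[1], cache)
        val = _eval_poly(neuron.coef, u, v)
    cache[ref] = val
    return val


def classify(network: GMDHNetwork, covariates) -> tuple[np.ndarray, np.ndarray]:
    """(labels, continuous scores) from the composed network output.

    Binary networks threshold the score at the validation-chosen cut; the
    multiclass variant snaps to the nearest class index and maps back to the
    original class labels.
    """
    if isinstance(covariates, pd.DataFrame):
        missing = set(network.feature_names) - set(map(str, covariates.columns))
        if missing:
            raise KeyError(f"covariates missing network features: {sorted(missing)}")
        covariates = covariates[network.feature_names]
    X, names = _as_matrix(covariates)
    if len(names) != len(network.feature_names):
        raise KeyError(
            f"covariates have {len(names)} columns; network expects "
            f"{len(network.feature_names)}"
        )
    scores = _node_values(network, np.asarray(X, float), network.output_ref, {})
    if network.config.fitness == "macro_f1":
        k = len(network.classes)
        idx = np.clip(np.rint(scores), 0, k - 1).astype(int)
        labels = network.classes[idx]
    elif network.classes is not None:  # binary trained through the multiclass API
        labels = network.classes[(scores >= network.threshold).astype(int)]
    else:
        labels = (scores >= network.threshold).astype(int)
    return labels, scores


def feature_importance(network: GMDHNetwork) -> dict[str, int]:
    """Per-feature interaction count in the subnetwork feeding the output.

    Walks the wiring from the output neuron; every reachable neuron is
    visited once and contributes its direct feature inputs.  Features used by
    more retained interactions rank higher.  Returned in descending count
    order (ties by feature position).
    """
    if not network.layers:
        raise GMDHTrainingError("network has no trained layers")
    counts: dict[int, int] = {}
    seen: set[NodeRef] = set()
    stack = [network.output_ref]
    while stack:
        ref = stack.pop()
        if ref in seen:
            continue
        seen.add(ref)
        if ref[0] == "x":
            counts[ref[1]] = counts.get(ref[1], 0) + 1
            continue
        neuron = network.layers[ref[1]][ref[2]]
        for par in neuron.parents:
            if par[0] == "x":
                counts[par[1]] = counts.get(par[1], 0) + 1
            elif par not in seen:
                stack.append(par)
    ordered = sorted(counts.items(), key=lambda it: (-it[1], it[0]))
    return {network.feature_names[j]: c for j, c in ordered}


class GMDHClassifier:
    """Train/predict wrapper with the shared classifier contract."""

    def __init__(self, config: GMDHConfig = GMDHConfig()):
        self.config = config
        self.network_: GMDHNetwork | None = None

    def fit(self, X, y):
        self.network_ = train_network(X, y, self.config)
        return self

    def predict(self, X) -> np.ndarray:
        labels, _ = classify(self.network_, X)
        return labels

    def decision_scores(self, X) -> np.ndarray:
        _, scores = classify(self.network_, X)
        return scores
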