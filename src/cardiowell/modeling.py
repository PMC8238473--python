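"""Candidate classifier training, cross-validation and composite ranking.

Five technique families are trained under two feature scenarios:

- Scenario I: every usable risk attribute;
- Scenario II ("AS"-prefixed results): only the subset chosen by
  correlation-based feature-subset selection (symmetric-uncertainty merit
  with greedy forward search).

Models are compared by the composite score (sensitivity + accuracy) / 2,
pooled over the confusion matrices of a stratified k-fold, with Disease as
the positive class throughout.

Tuned-hyperparameter mapping (framework equivalents of the reference
configuration; exact reproduction of the original toolkit's internals is a
non-goal):

===========  ==================================================================
family       scikit-learn estimator
===========  ==================================================================
J48          DecisionTreeClassifier(min_samples_leaf=20, ccp_alpha=1e-4)
             (confidence-factor/reduced-error pruning has no direct analogue;
             cost-complexity pruning plus the leaf-size floor is the nearest)
RF           RandomForestClassifier(n_estimators=80, max_depth=25)
NB           GaussianNB (no kernel estimator; supervised discretization has
             no sklearn analogue)
KNN          KNeighborsClassifier(n_neighbors=20, weights="uniform",
             algorithm="kd_tree"), standardized inputs
MLP          MLPClassifier(one hidden layer of (n_features + n_classes) / 2
             units, sgd, learning_rate_init=0.1, momentum=0.05, no decay,
             max_iter=100), standardized inputs
===========  ==================================================================
"""

from __future__ import annotations

import math
import os
import pickle
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from cardiowell.synth import COHORT_NOMINAL, COHORT_NUMERIC, DISEASE, EXERCISE_LEVELS

__all__ = [
    "FAMILIES", "MODEL_FEATURES", "TechniqueSpec", "EvalResult",
    "TrainedClassifier", "default_specs", "encode_features", "select_features",
    "cross_validate", "score", "rank_models", "holdout_evaluate",
    "select_best", "select_best_from_results", "metrics_from_confusion",
]

FAMILIES = ("J48", "RF", "NB", "KNN", "MLP")

# Usable model inputs: the record date is bookkeeping and the diabetes marker
# is dropped by cleansing (missing everywhere in the raw feed).
MODEL_FEATURES: list[str] = COHORT_NUMERIC + COHORT_NOMINAL

_YESNO = {"Yes": 1.0, "No": 0.0}
_EXERCISE = {name: float(i) for i, name in enumerate(EXERCISE_LEVELS)}


@dataclass(frozen=True)
class TechniqueSpec:
    family: str
    scenario: str = "I"
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.scenario not in ("I", "II"):
            raise ValueError("scenario must be 'I' or 'II'")

    @property
    def name(self) -> str:
        return ("AS" if self.scenario == "II" else "") + self.family


def default_specs(scenario: str = "I") -> list[TechniqueSpec]:
    """The five tuned candidates for one scenario."""
    return [TechniqueSpec(f, scenario) for f in FAMILIES]


@dataclass(frozen=True)
class EvalResult:
    name: str
    sensitivity: float
    accuracy: float
    score: float
    confusion: tuple[int, int, int, int] | None = None  # (tp, fn, tn, fp)


def encode_features(frame: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    """Numeric design matrix for the given feature columns.

    Yes/No -> 1/0, gender Male -> 1, exercise levels ordinal 0..3. A missing
    smoking status is encoded as the midpoint 0.5 (its own information-free
    value) rather than imputed.
    """
    cols = []
    for name in features:
        col = frame[name]
        if name in COHORT_NUMERIC:
            cols.append(pd.to_numeric(col, errors="coerce").to_numpy(dtype=float))
        elif name == "physical_exercise":
            cols.append(col.map(_EXERCISE).to_numpy(dtype=float))
        elif name == "gender":
            cols.append((col == "Male").to_numpy(dtype=float))
        elif pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            cols.append(col.map(_YESNO).fillna(0.5).to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.isnan(X).any():  # stray numeric holes: midpoint of observed values
        means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), means, X)
    return X


def build_estimator(spec: TechniqueSpec, n_features: int, seed: int = 0):
    """Instantiate the scikit-learn estimator mapped from a technique spec."""
    p = dict(spec.params)
    if spec.family == "J48":
        return DecisionTreeClassifier(
            min_samples_leaf=p.get("min_samples_leaf", 20),
            ccp_alpha=p.get("ccp_alpha", 1e-4),
            random_state=seed)
    if spec.family == "RF":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 80),
            max_depth=p.get("max_depth", 25),
            random_state=seed)
    if spec.family == "NB":
        return GaussianNB()
    if spec.family == "KNN":
        return Pipeline([
            ("scale", StandardScaler()),
            ("knn", KNeighborsClassifier(
                n_neighbors=p.get("n_neighbors", 20),
                weights="uniform", algorithm="kd_tree")),
        ])
    if spec.family == "MLP":
        hidden = p.get("hidden", max(2, (n_features + 2) // 2))
        return Pipeline([
            ("scale", StandardScaler()),
            ("mlp", MLPClassifier(
                hidden_layer_sizes=(hidden,), solver="sgd",
                learning_rate_init=p.get("learning_rate_init", 0.1),
                momentum=p.get("momentum", 0.05), nesterovs_momentum=False,
                max_iter=p.get("max_iter", 100), random_state=seed)),
        ])
    raise ValueError(spec.family)


# ---------------------------------------------------------------------------
# Feature-subset selection (correlation-based merit, greedy forward search)

def _discretize(values: np.ndarray, bins: int = 10) -> np.ndarray:
    v = values.astype(float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi <= lo:
        return np.zeros(len(v), dtype=int)
    edges = np.linspace(lo, hi, bins + 1)[1:-1]
    return np.digitize(np.nan_to_num(v, nan=lo), edges)


def _entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _symmetric_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    hx, hy = _entropy(x), _entropy(y)
    if hx + hy == 0:
        return 0.0
    joint = x.astype(np.int64) * (int(y.max()) + 1) + y.astype(np.int64)
    info_gain = hx + hy - _entropy(joint)
    return 2.0 * info_gain / (hx + hy)


def select_features(cohort: pd.DataFrame, target: str = "class",
                    features: Sequence[str] | None = None) -> list[str]:
    """Choose a strict, non-empty feature subset.

    Merit of a subset S: ``k * mean SU(f, class) / sqrt(k + k(k-1) * mean
    SU(f, f'))`` where SU is symmetric uncertainty over discretized columns
    — redundant (duplicated) features are penalized, irrelevant ones add
    nothing. Greedy forward search stops when no single addition improves
    the merit. Deterministic given the data.
    """
    feats = list(features) if features is not None else [
        f for f in MODEL_FEATURES if f in cohort.columns]
    if len(feats) < 2:
        raise ValueError("need at least 2 candidate features")
    classes = cohort[target].dropna().unique()
    if len(classes) < 2:
        raise ValueError("both classes must be present")

    y = pd.Categorical(cohort[target]).codes.astype(np.int64)
    X = encode_features(cohort, feats)
    disc = {f: _discretize(X[:, i]) for i, f in enumerate(feats)}
    su_class = {f: _symmetric_uncertainty(disc[f], y) for f in feats}
    su_ff_cache: dict[tuple[str, str], float] = {}

    def su_ff(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in su_ff_cache:
            su_ff_cache[key] = _symmetric_uncertainty(disc[a], disc[b])
        return su_ff_cache[key]

    def merit(subset: list[str]) -> float:
        k = len(subset)
        rcf = sum(su_class[f] for f in subset) / k
        if k == 1:
            return rcf
        rff = (sum(su_ff(a, b) for i, a in enumerate(subset)
                   for b in subset[i + 1:]) / (k * (k - 1) / 2))
        return k * rcf / math.sqrt(k + k * (k - 1) * rff)

    subset: list[str] = []
    best = 0.0
    remaining = sorted(feats, key=lambda f: -su_class[f])
    while True:
        gains = [(merit(subset + [f]), f) for f in remaining if f not in subset]
        if not gains:
            break
        m, f = max(gains)
        if m <= best + 1e-12:
            break
        subset.append(f)
        best = m
    if not subset:
        subset = [remaining[0]]
    if len(subset) >= len(feats):  # the scenario-II subset must be strict
        subset = sorted(subset, key=lambda f: -su_class[f])[: len(feats) - 1]
    return [f for f in feats if f in subset]


# ---------------------------------------------------------------------------
# Evaluation

def score(sensitivity: float, accuracy: float) -> float:
    """Composite selection score: the arithmetic mean of both metrics."""
    for v in (sensitivity, accuracy):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"metric {v} outside [0, 1]")
    return (sensitivity + accuracy) / 2.0


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int,
                           ) -> tuple[float, float]:
    """(sensitivity, accuracy) from pooled confusion counts."""
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty confusion matrix")
    sens = tp / (tp + fn) if tp + fn else 0.0
    return sens, (tp + tn) / n


def cross_validate(cohort: pd.DataFrame, spec: TechniqueSpec, k: int = 10,
                   seed: int = 0, features: Sequence[str] | None = None,
                   ) -> EvalResult:
    """Stratified k-fold evaluation with a pooled confusion matrix."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(cohort) < k:
        raise ValueError("fewer records than folds")
    feats = list(features) if features is not None else [
        f for f in MODEL_FEATURES if f in cohort.columns]
    y = (cohort["class"] == DISEASE).to_numpy()
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    X = encode_features(cohort, feats)

    estimator = build_estimator(spec, len(feats), seed)
    tp = fn = tn = fp = 0
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        model = clone(estimator)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        truth = y[test_idx]
        tp += int(np.sum(pred & truth))
        fn += int(np.sum(~pred & truth))
        tn += int(np.sum(~pred & ~truth))
        fp += int(np.sum(pred & ~truth))
    sens, acc = metrics_from_confusion(tp, fn, tn, fp)
    return EvalResult(spec.name, sens, acc, score(sens, acc), (tp, fn, tn, fp))


def rank_models(results: Sequence[EvalResult]) -> list[EvalResult]:
    """Descending by score; ties by higher sensitivity, then by name."""
    if not results:
        raise ValueError("nothing to rank")
    return sorted(results, key=lambda r: (-r.score, -r.sensitivity, r.name))


@dataclass
class TrainedClassifier:
    """A fitted model plus the bookkeeping needed to score new records."""

    estimator: object
    features: list[str]
    scenario: str
    seed: int

    def predict_disease_proba(self, frame: pd.DataFrame) -> np.ndarray:
        X = encode_features(frame, self.features)
        proba = self.estimator.predict_proba(X)
        classes = list(getattr(self.estimator, "classes_", [False, True]))
        return np.clip(proba[:, classes.index(True)], 0.0, 1.0)


def fit_classifier(cohort: pd.DataFrame, spec: TechniqueSpec, seed: int = 0,
                   features: Sequence[str] | None = None) -> TrainedClassifier:
    feats = list(features) if features is not None else [
        f for f in MODEL_FEATURES if f in cohort.columns]
    X = encode_features(cohort, feats)
    y = (cohort["class"] == DISEASE).to_numpy()
    model = build_estimator(spec, len(feats), seed)
    model.fit(X, y)
    return TrainedClassifier(model, feats, spec.scenario, seed)


def holdout_evaluate(model: TrainedClassifier, test: pd.DataFrame,
                     threshold: float = 0.5) -> EvalResult:
    """Metrics of a fitted model on a held-out table."""
    missing = [f for f in model.features if f not in test.columns]
    if missing:
        raise KeyError(f"test table lacks features: {missing}")
    p = model.predict_disease_proba(test)
    pred = p >= threshold
    truth = (test["class"] == DISEASE).to_numpy()
    tp = int(np.sum(pred & truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    sens, acc = metrics_from_confusion(tp, fn, tn, fp)
    return EvalResult("holdout", sens, acc, score(sens, acc), (tp, fn, tn, fp))


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def select_best_from_results(results: Sequence[EvalResult],
                             name_file) -> EvalResult:
    """Rank pre-computed results and persist the winner's name (atomically)."""
    winner = rank_models(results)[0]
    path = Path(name_file)
    path.parent.mkdir(parents=True, exist_ok=True)
    _atomic_write_text(path, winner.name + "\n")
    return winner


def select_best(cohort: pd.DataFrame, seed: int, out_dir,
                specs: Sequence[TechniqueSpec] | None = None, k: int = 10,
                ) -> tuple[str, TrainedClassifier, list[EvalResult]]:
    """Run both scenarios, rank, refit the winner on all data, persist.

    Writes ``best_model.txt`` (one line, the winner's name),
    ``metrics.csv`` (algorithm, sensitivity, accuracy, score) and
    ``model.pkl`` under ``out_dir``. Reruns overwrite atomically.
    """
    if specs is None:
        specs = default_specs("I") + default_specs("II")
    if not specs:
        raise ValueError("at least one technique spec is required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scenario_features: dict[str, list[str]] = {
        "I": [f for f in MODEL_FEATURES if f in cohort.columns]}
    if any(s.scenario == "II" for s in specs):
        scenario_features["II"] = select_features(cohort)

    results = [cross_validate(cohort, s, k=k, seed=seed,
                              features=scenario_features[s.scenario])
               for s in specs]
    ranked = rank_models(results)
    winner_spec = next(s for s in specs if s.name == ranked[0].name)
    model = fit_classifier(cohort, winner_spec, seed=seed,
                           features=scenario_features[winner_spec.scenario])

    _atomic_write_text(out / "best_model.txt", ranked[0].name + "\n")
    pd.DataFrame([{"algorithm": r.name, "sensitivity": r.sensitivity,
                   "accuracy": r.accuracy, "score": r.score}
                  for r in ranked]).to_csv(out / "metrics.csv", index=False)
    with open(out / "model.pkl", "wb") as fh:
        pickle.dump(model, fh)
    return ranked[0].name, model, ranked
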