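"""Leakage-guarded repeated stratified cross-validation with a top-k sweep.

The evaluation contract: for every feature-subset size k, every repetition
and every fold, the entire preprocessing chain — z-scaling, elastic-net
coefficient-magnitude feature ranking, top-k truncation, classifier fitting
— is fitted on the training fold alone and only then applied to the held-out
fold. 5 folds x 20 repetitions give 100 resampled evaluations per (model, k).

Folds are drawn once per repetition (stratified by the outcome, shuffled by a
seed derived deterministically from the base seed) and shared across all k
and both models, so the k-curves differ only by feature count. The ranking
does not depend on k either — it is a full ordering truncated to the top k —
so it is computed once per (repetition, fold) and reused.

Two classifier backends are evaluated: elastic-net logistic regression
(``enet_lr``) and histogram-based gradient boosting (``hist_gb``), both with
balanced sample weights. The learners are established implementations; the
bespoke content of this module is the framework around them.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .pose_model import GaitPipeError

MODELS = ("enet_lr", "hist_gb")


class EvaluationError(GaitPipeError):
    pass


class SingleClassFoldError(EvaluationError):
    """A test fold (or truth vector) contains only one class; AUC undefined."""


def derive_seed(*parts: int) -> int:
    """Deterministic child seed from integer parts, below 2**31."""
    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclasses.dataclass(frozen=True)
class CVPlan:
    n_folds: int = 5
    n_repetitions: int = 20
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")

    @property
    def n_evaluations(self) -> int:
        return self.n_folds * self.n_repetitions


@dataclasses.dataclass(frozen=True)
class RankingSpec:
    """Elastic-net logistic regression used only to order features.

    ``regularization_strength`` is the inverse of sklearn's ``C`` and applies
    in z-scaled feature units; the defaults are documented reconstructions,
    not published values.
    """

    l1_ratio: float = 0.5
    regularization_strength: float = 1.0
    class_weighting: str = "balanced"
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ValueError("l1_ratio must lie in [0, 1]")
        if not self.regularization_strength > 0:
            raise ValueError("regularization_strength must be > 0")
        if self.class_weighting != "balanced":
            raise ValueError("only balanced class weighting is supported")


@dataclasses.dataclass(frozen=True)
class MetricSet:
    auc_roc: float
    accuracy: float
    mcc: float
    sensitivity_class0: float
    sensitivity_class1: float
    f1_class0: float
    f1_class1: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


METRIC_NAMES = tuple(f.name for f in dataclasses.fields(MetricSet))


@dataclasses.dataclass(frozen=True)
class EvalResult:
    """One (model, k, repetition, fold) cell of the sweep."""

    model: str
    k: int
    repetition: int
    fold: int
    selected_features: tuple[str, ...]
    test_ids: tuple[str, ...]
    y_true: np.ndarray
    test_probabilities: np.ndarray
    metrics: MetricSet


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold id per sample; within each class, sizes differ by at most one."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise EvaluationError("stratified folds need at least two classes")
    too_small = classes[counts < n_folds]
    if too_small.size:
        raise EvaluationError(
            f"class {too_small[0]!r} has fewer members than n_folds={n_folds}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        assignment[test_idx] = fold
    return assignment


@dataclasses.dataclass(frozen=True)
class ZScaler:
    """Per-feature train statistics; constant features map to 0 everywhere."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        inv = np.where(self.sd > 0, 1.0 / np.where(self.sd > 0, self.sd, 1.0), 0.0)
        return (np.asarray(matrix, float) - self.mean) * inv


def zscale(train_matrix: np.ndarray) -> tuple[ZScaler, np.ndarray]:
    """Fit population-SD z-scaling on the training matrix and apply it."""
    train = np.asarray(train_matrix, dtype=float)
    if train.size == 0:
        raise ValueError("train matrix must be nonempty")
    scaler = ZScaler(mean=train.mean(axis=0), sd=train.std(axis=0))
    return scaler, scaler.transform(train)


def apply_zscale(scaler: ZScaler, matrix: np.ndarray) -> np.ndarray:
    return scaler.transform(matrix)


def balanced_weights(labels: np.ndarray) -> np.ndarray:
    """Per-sample weights n_total / (n_classes * n_class)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise EvaluationError("balanced weights need at least two classes")
    per_class = {c: len(labels) / (classes.size * n) for c, n in zip(classes, counts)}
    return np.array([per_class[c] for c in labels], dtype=float)


def _fit_enet(X: np.ndarray, y: np.ndarray, spec: RankingSpec,
              sample_weight: np.ndarray | None = None,
              class_weight: str | None = None) -> LogisticRegression:
    for max_iter in (spec.max_iter, spec.max_iter * 10):
        model = LogisticRegression(
            C=1.0 / spec.regularization_strength,
            l1_ratio=spec.l1_ratio,
            solver="saga",
            class_weight=class_weight,
            max_iter=max_iter,
            tol=1e-4,
            random_state=0,  # saga shuffles; pin it so reruns are identical
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, y, sample_weight=sample_weight)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            return model
    raise EvaluationError(
        f"elastic-net optimizer failed to converge within {spec.max_iter * 10} iterations"
    )


def rank_features(
    scaled_train: np.ndarray,
    labels: np.ndarray,
    feature_names: Sequence[str],
    spec: RankingSpec = RankingSpec(),
) -> list[str]:
    """All features ordered by |elastic-net coefficient| descending.

    Ties break lexicographically on the feature name so top-k truncation is
    reproducible even under exact coefficient symmetry.
    """
    model = _fit_enet(scaled_train, labels, spec, class_weight="balanced")
    coefs = np.abs(model.coef_.ravel())
    names = np.asarray(feature_names)
    order = np.lexsort((names, -coefs))
    return [str(n) for n in names[order]]


def fit_predict(
    model: str,
    train: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    test: np.ndarray,
    ranking_spec: RankingSpec = RankingSpec(),
    seed: int = 0,
) -> np.ndarray:
    """Train the named classifier with sample weights; class-1 probabilities."""
    train = np.asarray(train, float)
    test = np.asarray(test, float)
    if train.shape[1] != test.shape[1]:
        raise EvaluationError(
            f"train has {train.shape[1]} feature columns but test has {test.shape[1]}"
        )
    if model == "enet_lr":
        clf = _fit_enet(train, labels, ranking_spec, sample_weight=weights)
    elif model == "hist_gb":
        clf = HistGradientBoostingClassifier(
            max_bins=255, learning_rate=0.1, early_stopping=False, random_state=seed
        )
        clf.fit(train, labels, sample_weight=weights)
    else:
        raise EvaluationError(f"unknown model {model!r}; expected one of {MODELS}")
    return clf.predict_proba(test)[:, 1]


def auc_roc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann–Whitney (rank) AUC with half credit for score ties."""
    y = np.asarray(y_true)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise SingleClassFoldError("AUC undefined with a single-class truth vector")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_metrics(
    y_true: np.ndarray,
    probabilities: np.ndarray,
    threshold: float = 0.5,
) -> MetricSet:
    """AUC plus threshold metrics from the explicit confusion-matrix formulas.

    MCC is defined as 0 when any marginal of the confusion matrix is 0.
    """
    y = np.asarray(y_true).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise EvaluationError("probabilities must lie in [0, 1]")
    auc = auc_roc(y, p)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((y == 1) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    sens1 = tp / (tp + fn) if tp + fn else 0.0
    sens0 = tn / (tn + fp) if tn + fp else 0.0
    f1_1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    f1_0 = 2 * tn / (2 * tn + fn + fp) if 2 * tn + fn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricSet(
        auc_roc=auc, accuracy=acc, mcc=float(mcc),
        sensitivity_class0=sens0, sensitivity_class1=sens1,
        f1_class0=f1_0, f1_class1=f1_1,
    )


@dataclasses.dataclass(frozen=True)
class SweepOutput:
    results: tuple[EvalResult, ...]
    discarded: tuple[tuple[int, int], ...]  # (repetition, fold) with single-class truth


def run_topk_sweep(
    features: pd.DataFrame,
    labels: pd.Series,
    k_values: Iterable[int] = range(1, 51),
    plan: CVPlan = CVPlan(),
    models: Sequence[str] = MODELS,
    ranking_spec: RankingSpec = RankingSpec(),
) -> SweepOutput:
    """The full top-k sweep; see the module docstring for the contract.

    ``features`` is indexed by recording id; ``labels`` shares that index
    with values in {0, 1}.
    """
    k_values = sorted(set(int(k) for k in k_values))
    if not k_values or k_values[0] < 1:
        raise EvaluationError("k values must be positive")
    if k_values[-1] > features.shape[1]:
        raise EvaluationError(
            f"k_max={k_values[-1]} exceeds the {features.shape[1]} available features"
        )
    if len(features) < 2 * plan.n_folds:
        raise EvaluationError("need at least 2 samples per fold")
    for m in models:
        if m not in MODELS:
            raise EvaluationError(f"unknown model {m!r}")
    X = features.to_numpy(dtype=float)
    y = labels.loc[features.index].to_numpy().astype(int)
    ids = np.asarray(features.index.astype(str))
    names = list(features.columns)
    name_to_col = {n: i for i, n in enumerate(names)}

    results: list[EvalResult] = []
    discarded: list[tuple[int, int]] = []
    for rep in range(plan.n_repetitions):
        fold_ids = stratified_folds(y, plan.n_folds, derive_seed(plan.base_seed, rep))
        for fold in range(plan.n_folds):
            test_mask = fold_ids == fold
            train_mask = ~test_mask
            y_train, y_test = y[train_mask], y[test_mask]
            if np.unique(y_test).size < 2:
                discarded.append((rep, fold))
                continue
            scaler, X_train_s = zscale(X[train_mask])
            X_test_s = apply_zscale(scaler, X[test_mask])
            ranking = rank_features(X_train_s, y_train, names, ranking_spec)
            weights = balanced_weights(y_train)
            model_seed = derive_seed(plan.base_seed, rep, fold)
            for k in k_values:
                cols = [name_to_col[n] for n in ranking[:k]]
                tr, te = X_train_s[:, cols], X_test_s[:, cols]
                for model in models:
                    probs = fit_predict(
                        model, tr, y_train, weights, te, ranking_spec, seed=model_seed
                    )
                    results.append(
                        EvalResult(
                            model=model, k=k, repetition=rep, fold=fold,
                            selected_features=tuple(ranking[:k]),
                            test_ids=tuple(ids[test_mask]),
                            y_true=y_test.copy(),
                            test_probabilities=probs,
                            metrics=compute_metrics(y_test, probs),
                        )
                    )
    return SweepOutput(results=tuple(results), discarded=tuple(discarded))


def results_to_frame(output: SweepOutput) -> pd.DataFrame:
    """One row per (model, k, repetition, fold) with the metric columns."""
    rows = [
        {
            "model": r.model, "k": r.k, "repetition": r.repetition, "fold": r.fold,
            **r.metrics.as_dict(),
        }
        for r in output.results
    ]
    return pd.DataFrame(rows)


def aggregate_curves(output: SweepOutput | pd.DataFrame) -> pd.DataFrame:
    """Mean and population SD of every metric per (model, k)."""
    frame = output if isinstance(output, pd.DataFrame) else results_to_frame(output)
    if frame.empty:
        raise EvaluationError("no results to aggregate")
    grouped = frame.groupby(["model", "k"])[list(METRIC_NAMES)]
    mean = grouped.mean()
    sd = grouped.std(ddof=0)
    n = grouped.size().rename("n_evaluations")
    out = mean.join(sd, lsuffix="_mean", rsuffix="_sd").join(n).reset_index()
    return out.sort_values(["model", "k"]).reset_index(drop=True)
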