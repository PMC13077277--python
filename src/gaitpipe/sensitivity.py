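"""Exploratory analyses over the cross-validation output.

Five views of the sweep results: performance-vs-k curves (via
``model_eval.aggregate_curves``), metrics stratified by a covariate such as
BMI, complete re-runs on site subgroups, the best/worst-predicted
individuals, and feature-selection frequencies with per-class feature
distributions.

Stratum metrics pool the out-of-fold predictions across repetitions before
computing metrics — strata can be small, and per-fold strata would often be
single-class. "Good/poor performance" for an individual is operationalized
as the mean out-of-fold probability assigned to the individual's true class.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .model_eval import (
    CVPlan,
    EvaluationError,
    MetricSet,
    RankingSpec,
    SingleClassFoldError,
    SweepOutput,
    compute_metrics,
    run_topk_sweep,
)


@dataclasses.dataclass(frozen=True)
class StratumSpec:
    """A named boolean membership over recording ids."""

    name: str
    membership: pd.Series  # bool, indexed by recording_id


@dataclasses.dataclass(frozen=True)
class IndividualScore:
    recording_id: str
    mean_correct_class_probability: float
    n_predictions: int


def bmi_strata(meta: pd.DataFrame, threshold: float = 25.0) -> list[StratumSpec]:
    """The two body-shape strata used throughout: BMI >= threshold and below."""
    bmi = meta.set_index("recording_id")["bmi"] if "recording_id" in meta else meta["bmi"]
    return [
        StratumSpec(name=f"bmi_ge_{threshold:g}", membership=bmi >= threshold),
        StratumSpec(name=f"bmi_lt_{threshold:g}", membership=bmi < threshold),
    ]


def pooled_predictions(output: SweepOutput, model: str, k: int) -> pd.DataFrame:
    """Out-of-fold predictions pooled over repetitions for one (model, k).

    One row per (recording_id, repetition) with the class-1 probability and
    the true label.
    """
    rows = []
    for r in output.results:
        if r.model != model or r.k != k:
            continue
        for rid, yt, p in zip(r.test_ids, r.y_true, r.test_probabilities):
            rows.append({"recording_id": rid, "repetition": r.repetition,
                         "y_true": int(yt), "probability": float(p)})
    if not rows:
        raise EvaluationError(f"no results for model={model!r}, k={k}")
    return pd.DataFrame(rows)


def stratum_metrics(
    predictions: pd.DataFrame,
    strata: Sequence[StratumSpec],
) -> pd.DataFrame:
    """Metrics on pooled out-of-fold predictions restricted to each stratum.

    Single-class strata report threshold metrics with AUC marked undefined
    (NaN); empty strata are reported with zero counts, not raised.
    """
    rows = []
    for spec in strata:
        member_ids = set(spec.membership.index[spec.membership])
        sub = predictions[predictions["recording_id"].isin(member_ids)]
        row: dict[str, object] = {
            "stratum": spec.name,
            "n_samples": sub["recording_id"].nunique(),
            "n_predictions": len(sub),
        }
        if len(sub):
            try:
                m = compute_metrics(sub["y_true"].to_numpy(), sub["probability"].to_numpy())
                row.update(m.as_dict())
            except SingleClassFoldError:
                m = _threshold_only_metrics(sub["y_true"].to_numpy(),
                                            sub["probability"].to_numpy())
                row.update(m)
                row["auc_roc"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _threshold_only_metrics(y: np.ndarray, p: np.ndarray, threshold: float = 0.5) -> dict:
    pred = (p >= threshold).astype(int)
    y = y.astype(int)
    tp = int(np.sum((y == 1) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    n = len(y)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return {
        "accuracy": (tp + tn) / n,
        "mcc": (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0,
        "sensitivity_class0": tn / (tn + fp) if tn + fp else 0.0,
        "sensitivity_class1": tp / (tp + fn) if tp + fn else 0.0,
        "f1_class0": 2 * tn / (2 * tn + fn + fp) if 2 * tn + fn + fp else 0.0,
        "f1_class1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
    }


def subgroup_rerun(
    features: pd.DataFrame,
    labels: pd.Series,
    member_ids: Sequence[str],
    k_values,
    plan: CVPlan,
    models=("enet_lr", "hist_gb"),
    ranking_spec: RankingSpec = RankingSpec(),
) -> SweepOutput:
    """Re-execute the complete pipeline on a subset of recordings.

    This refits scaling, ranking, selection and models on the subset — it is
    not a filtering of pooled results.
    """
    idx = [i for i in features.index if i in set(member_ids)]
    return run_topk_sweep(features.loc[idx], labels.loc[idx], k_values, plan,
                          models, ranking_spec)


def rank_individuals(
    predictions: pd.DataFrame,
    n_top: int = 10,
) -> tuple[list[IndividualScore], list[IndividualScore]]:
    """(best, worst) individuals by mean out-of-fold true-class probability.

    Ties break on recording id; if the cohort has fewer than ``n_top``
    members the lists are truncated.
    """
    df = predictions.copy()
    df["p_correct"] = np.where(df["y_true"] == 1, df["probability"], 1 - df["probability"])
    agg = (
        df.groupby("recording_id")["p_correct"]
        .agg(mean_p="mean", n_pred="size")
        .reset_index()
        .sort_values(["mean_p", "recording_id"], ascending=[False, True])
    )
    scores = [
        IndividualScore(recording_id=str(row.recording_id),
                        mean_correct_class_probability=float(row.mean_p),
                        n_predictions=int(row.n_pred))
        for row in agg.itertuples(index=False)
    ]
    n_top = min(n_top, len(scores))
    best = scores[:n_top]
    worst = sorted(scores, key=lambda s: (s.mean_correct_class_probability, s.recording_id))[:n_top]
    return best, worst


def selection_frequency(output: SweepOutput, model: str, k: int) -> pd.Series:
    """Fraction of (repetition, fold) cells whose top-k contained each feature.

    Summing the frequencies over features gives exactly k when no folds were
    discarded.
    """
    cells = [r for r in output.results if r.model == model and r.k == k]
    if not cells:
        raise EvaluationError(f"no results for model={model!r}, k={k}")
    counts: dict[str, int] = {}
    for r in cells:
        for name in r.selected_features:
            counts[name] = counts.get(name, 0) + 1
    freq = pd.Series(counts, dtype=float) / len(cells)
    return freq.sort_values(ascending=False)


def feature_distributions(
    features: pd.DataFrame,
    labels: pd.Series,
    feature_names: Sequence[str],
) -> pd.DataFrame:
    """Per-class summaries plus a standardized mean difference per feature.

    The SMD is (mean_1 - mean_0) / pooled within-class population SD; a
    zero pooled SD with distinct means is reported as +/-inf (degenerate
    separation), flagged rather than masked.
    """
    missing = [n for n in feature_names if n not in features.columns]
    if missing:
        raise EvaluationError(f"unknown feature names: {missing[:5]}")
    y = labels.loc[features.index].to_numpy().astype(int)
    rows = []
    for name in feature_names:
        x = features[name].to_numpy(dtype=float)
        row: dict[str, object] = {"feature": name}
        stats = {}
        for cls in (0, 1):
            xc = x[y == cls]
            stats[cls] = (xc.mean(), xc.std(), len(xc))
            row.update({
                f"mean_class{cls}": xc.mean(),
                f"sd_class{cls}": xc.std(),
                f"q25_class{cls}": np.percentile(xc, 25),
                f"q50_class{cls}": np.percentile(xc, 50),
                f"q75_class{cls}": np.percentile(xc, 75),
            })
        (m0, s0, n0), (m1, s1, n1) = stats[0], stats[1]
        pooled = np.sqrt((n0 * s0**2 + n1 * s1**2) / (n0 + n1))
        if pooled == 0:
            smd = 0.0 if m1 == m0 else np.inf * np.sign(m1 - m0)
        else:
            smd = (m1 - m0) / pooled
        row["smd"] = float(smd)
        rows.append(row)
    return pd.DataFrame(rows)
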