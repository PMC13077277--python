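"""End-to-end orchestration: simulate → segment → extract → evaluate → explore.

`run_pipeline` executes the whole chain from a validated `RunConfig` and
writes plain CSV/JSON artifacts plus a manifest with content hashes, so two
runs with the same config and seed produce byte-identical result files.
`render_report` turns the result CSVs into performance-vs-k plots and a
short markdown summary; plots are conveniences — the CSVs are the tested
surface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .cycle_segmentation import (
    CycleSegment,
    SegmentationParams,
    extract_second_cycle,
)
from .feature_extraction import (
    AngleTripletSet,
    DistancePairSet,
    extract_features,
    feature_names,
)
from .model_eval import (
    CVPlan,
    RankingSpec,
    SweepOutput,
    aggregate_curves,
    results_to_frame,
    run_topk_sweep,
)
from .pose_model import AgeGroup, GaitPipeError, RecordingMeta, Sex, write_metadata
from .sensitivity import (
    bmi_strata,
    feature_distributions,
    pooled_predictions,
    rank_individuals,
    selection_frequency,
    stratum_metrics,
)
from .synthetic_gait import ClassBalance, EffectConfig, NoiseConfig, sample_cohort

FLOAT_FORMAT = "%.10g"

OUTCOMES = ("sex", "age")

LABEL_COLUMNS = ["sex", "age_group", "age_years", "bmi", "site"]


class PipelineError(GaitPipeError):
    pass


class EffectSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    male_stature_mult: float = 1.07
    male_shoulder_mult: float = 1.08
    male_hip_mult: float = 0.95
    male_arm_swing_mult: float = 1.15
    over65_cadence_mult: float = 0.93
    over65_step_length_mult: float = 0.94
    over65_phase_jitter_add: float = 0.02
    effect_scale: float = Field(default=1.0, ge=0.0)

    def to_config(self) -> EffectConfig:
        return EffectConfig(**self.model_dump())


class NoiseSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    jitter_sd_px: float = Field(default=2.0, ge=0.0)
    loose_clothing_mode: bool = False
    loose_clothing_factor: float = 3.0
    failure_rate: float = Field(default=0.0, ge=0.0, le=1.0)

    def to_config(self) -> NoiseConfig:
        return NoiseConfig(**self.model_dump())


class SegmentationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    smoothing_window: int = 5
    min_prominence_frac: float = 0.1
    max_gap_cv: float = 0.2

    def to_params(self) -> SegmentationParams:
        return SegmentationParams(**self.model_dump())


class RunConfig(BaseModel):
    """Validated configuration of one full pipeline run."""

    model_config = ConfigDict(extra="forbid")

    n: int = Field(default=150, ge=10)
    sex_female_frac: float = 94 / 145
    age_over65_frac: float = 55 / 145
    site_thailand_frac: float = 51 / 145
    n_strides: int = Field(default=4, ge=3)
    frame_rate_hz: float = 30.0
    effects: EffectSettings = EffectSettings()
    noise: NoiseSettings = NoiseSettings()
    segmentation: SegmentationSettings = SegmentationSettings()
    k_max: int = Field(default=50, ge=1)
    k_values: list[int] | None = None
    n_folds: int = Field(default=5, ge=2)
    n_repetitions: int = Field(default=20, ge=1)
    models: list[str] = ["enet_lr", "hist_gb"]
    l1_ratio: float = 0.5
    regularization_strength: float = 1.0
    bmi_threshold: float = 25.0
    n_top_individuals: int = 10
    report_k: int = 15
    base_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        n_feat = len(feature_names())
        if self.k_max > n_feat:
            raise ValueError(f"k_max={self.k_max} exceeds the {n_feat} features")
        if self.k_values is not None and max(self.k_values) > n_feat:
            raise ValueError("k_values exceed the available features")
        return self

    def effective_k_values(self) -> list[int]:
        ks = self.k_values if self.k_values is not None else list(range(1, self.k_max + 1))
        if self.report_k not in ks:
            ks = sorted(set(ks) | {self.report_k})
        return ks


def demo_config(**overrides) -> RunConfig:
    """A small configuration that runs the full chain in well under a minute."""
    base = dict(
        n=60,
        n_repetitions=3,
        k_values=[1, 5, 15],
        report_k=15,
        noise={"failure_rate": 0.065},
        base_seed=7,
    )
    base.update(overrides)
    return RunConfig(**base)


def _sex_label(m: RecordingMeta) -> int:
    return int(m.sex is Sex.FEMALE)


def _age_label(m: RecordingMeta) -> int:
    return int(m.age_group is AgeGroup.OVER65EQ)


def build_feature_table(
    cohort,
    seg_params: SegmentationParams = SegmentationParams(),
    pairs: DistancePairSet = DistancePairSet(),
    triplets: AngleTripletSet = AngleTripletSet(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment and featurize a cohort.

    Returns ``(features, segments)``: the feature table (one row per
    successfully extracted recording, indexed by recording id, 109 feature
    columns plus label/covariate columns) and the per-recording segmentation
    record including failures.
    """
    feat_rows, seg_rows = [], []
    for seq, meta in cohort:
        result = extract_second_cycle(seq, seg_params)
        ok = isinstance(result, CycleSegment)
        seg_rows.append({
            "recording_id": meta.recording_id,
            "status": "ok" if ok else result.reason,
            "start_frame": result.start_frame if ok else -1,
            "end_frame": result.end_frame if ok else -1,
            "n_frames": result.n_frames if ok else 0,
            "n_minima": len(result.minima_indices) if ok else result.n_minima,
        })
        if ok:
            fv = extract_features(seq, result, meta, pairs, triplets)
            row = {"recording_id": meta.recording_id, **fv.as_dict()}
            row.update({
                "sex": meta.sex.value,
                "age_group": meta.age_group.value,
                "age_years": meta.age_years,
                "bmi": meta.bmi,
                "site": meta.site.value,
            })
            feat_rows.append(row)
    features = pd.DataFrame(feat_rows)
    if len(features):
        features = features.set_index("recording_id")
    segments = pd.DataFrame(seg_rows)
    return features, segments


def split_feature_table(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate the 109 feature columns from the label/covariate columns."""
    fnames = [c for c in feature_names() if c in table.columns]
    return table[fnames], table[[c for c in table.columns if c not in fnames]]


def outcome_labels(table: pd.DataFrame, outcome: str) -> pd.Series:
    """Binary labels for an outcome: female=1 for sex, >=65=1 for age."""
    if outcome == "sex":
        return (table["sex"] == "female").astype(int)
    if outcome == "age":
        return (table["age_group"] == "over65eq").astype(int)
    raise PipelineError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis chain and write its artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        cohort = sample_cohort(
            n=config.n,
            class_balance=ClassBalance(
                sex_female_frac=config.sex_female_frac,
                age_over65_frac=config.age_over65_frac,
            ),
            effects=config.effects.to_config(),
            noise=config.noise.to_config(),
            site_thailand_frac=config.site_thailand_frac,
            rng_seed=config.base_seed,
            n_strides=config.n_strides,
            frame_rate_hz=config.frame_rate_hz,
        )
        write_metadata([m for _, m in cohort], out / "metadata.csv")

        stage = "segment+extract"
        table, segments = build_feature_table(cohort, config.segmentation.to_params())
        _write_csv(segments, out / "segments.csv")
        if table.empty:
            raise PipelineError("no recording could be segmented")
        _write_csv(table.reset_index(), out / "features.csv")
        n_success = int((segments["status"] == "ok").sum())
        feasibility_prop = n_success / len(segments)

        X, labels_tbl = split_feature_table(table)
        plan = CVPlan(
            n_folds=config.n_folds,
            n_repetitions=config.n_repetitions,
            base_seed=config.base_seed,
        )
        spec = RankingSpec(
            l1_ratio=config.l1_ratio,
            regularization_strength=config.regularization_strength,
        )
        ks = config.effective_k_values()

        counts: dict[str, object] = {
            "n_recordings": config.n,
            "n_extracted": n_success,
            "feasibility_proportion": feasibility_prop,
            "n_feature_columns": X.shape[1],
        }
        for outcome in OUTCOMES:
            stage = f"evaluate[{outcome}]"
            y = outcome_labels(table, outcome)
            sweep = run_topk_sweep(X, y, ks, plan, tuple(config.models), spec)
            _write_csv(results_to_frame(sweep), out / f"eval_results_{outcome}.csv")
            _write_csv(aggregate_curves(sweep), out / f"curves_{outcome}.csv")
            counts[f"n_evaluations_{outcome}"] = len(sweep.results)
            counts[f"n_discarded_folds_{outcome}"] = len(sweep.discarded)

            stage = f"sensitivity[{outcome}]"
            sel_rows, pred_frames, strat_frames, indiv_rows = [], [], [], []
            for model in config.models:
                preds = pooled_predictions(sweep, model, config.report_k)
                preds.insert(0, "model", model)
                pred_frames.append(preds)
                sm = stratum_metrics(
                    preds, bmi_strata(labels_tbl.reset_index(), config.bmi_threshold)
                )
                sm.insert(0, "model", model)
                strat_frames.append(sm)
                best, worst = rank_individuals(
                    preds, n_top=config.n_top_individuals
                )
                for side, lst in (("best", best), ("worst", worst)):
                    for s in lst:
                        indiv_rows.append({
                            "model": model, "group": side,
                            **dataclasses.asdict(s),
                        })
                freq = selection_frequency(sweep, model, config.report_k)
                for rank, (name, f) in enumerate(freq.items(), start=1):
                    sel_rows.append({"model": model, "k": config.report_k,
                                     "rank": rank, "feature": name, "frequency": f})
            _write_csv(pd.concat(pred_frames), out / f"predictions_{outcome}.csv")
            _write_csv(pd.concat(strat_frames), out / f"stratum_metrics_{outcome}.csv")
            _write_csv(pd.DataFrame(indiv_rows), out / f"individuals_{outcome}.csv")
            sel = pd.DataFrame(sel_rows)
            _write_csv(sel, out / f"selection_frequency_{outcome}.csv")
            top_feats = (
                sel.groupby("feature")["frequency"].max().sort_values(ascending=False)
                .head(10).index.tolist()
            )
            _write_csv(
                feature_distributions(X, y, top_feats),
                out / f"feature_distributions_{outcome}.csv",
            )
    except GaitPipeError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    stage = "manifest"
    files = sorted(p.name for p in out.glob("*.csv"))
    manifest = {
        "gaitpipe_version": __version__,
        "config": config.model_dump(),
        "base_seed": config.base_seed,
        "counts": counts,
        "files": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def render_report(run_dir: str | Path) -> Path:
    """Plot performance-vs-k curves and summarize a completed run.

    Regeneration is idempotent; missing artifacts raise with their names.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    required = ["manifest.json"] + [f"curves_{o}.csv" for o in OUTCOMES]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise PipelineError(f"incomplete run; missing artifacts: {missing}")
    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)

    manifest = json.loads((run_dir / "manifest.json").read_text())
    lines = ["# Pipeline report", "",
             f"- package version: {manifest['gaitpipe_version']}",
             f"- base seed: {manifest['base_seed']}"]
    for key, val in manifest["counts"].items():
        lines.append(f"- {key}: {val}")
    for outcome in OUTCOMES:
        curves = pd.read_csv(run_dir / f"curves_{outcome}.csv")
        for metric in ("auc_roc", "accuracy", "mcc"):
            fig, ax = plt.subplots(figsize=(6, 4))
            for model, sub in curves.groupby("model"):
                ax.errorbar(sub["k"], sub[f"{metric}_mean"], yerr=sub[f"{metric}_sd"],
                            marker="o", capsize=2, label=model)
            ax.set_xlabel("number of selected features (k)")
            ax.set_ylabel(metric)
            ax.set_title(f"{outcome} classification")
            ax.legend()
            fig.tight_layout()
            fig.savefig(report_dir / f"{outcome}_{metric}_vs_k.png", dpi=120)
            plt.close(fig)
        at = curves[curves["k"] == curves["k"].max()]
        for row in at.itertuples():
            lines.append(
                f"- {outcome} / {row.model} at k={row.k}: "
                f"AUC {row.auc_roc_mean:.3f} (SD {row.auc_roc_sd:.3f})"
            )
    (report_dir / "report.md").write_text("\n".join(lines) + "\n")
    return report_dir
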