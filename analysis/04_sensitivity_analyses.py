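#!/usr/bin/env python
"""The five exploratory analyses over the evaluation output.

1. performance-vs-k curves (03 already wrote them; re-plotted here),
2. metrics stratified by BMI (>= 25 vs < 25),
3. complete re-runs per site (Thailand / India),
4. the 10 best- and worst-predicted individuals,
5. feature-selection frequency and per-class feature distributions.

Writes one CSV per analysis under results/sensitivity/.
"""

from pathlib import Path

import pandas as pd

from gaitpipe.model_eval import CVPlan, aggregate_curves, run_topk_sweep
from gaitpipe.pipeline import FLOAT_FORMAT, outcome_labels, split_feature_table
from gaitpipe.sensitivity import (
    bmi_strata,
    feature_distributions,
    pooled_predictions,
    rank_individuals,
    selection_frequency,
    stratum_metrics,
    subgroup_rerun,
)

OUT = Path("results/sensitivity")
SEED = 20260923
K = 15

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(Path("results/features.csv")).set_index("recording_id")
    X, labels_tbl = split_feature_table(table)
    plan = CVPlan(n_folds=5, n_repetitions=10, base_seed=SEED)

    for outcome in ("sex", "age"):
        y = outcome_labels(table, outcome)
        sweep = run_topk_sweep(X, y, [K], plan)
        preds = pooled_predictions(sweep, "enet_lr", K)

        sm = stratum_metrics(preds, bmi_strata(labels_tbl.reset_index()))
        sm.to_csv(OUT / f"bmi_strata_{outcome}.csv", index=False,
                  float_format=FLOAT_FORMAT)
        print(f"{outcome} BMI strata:")
        print(sm[["stratum", "n_samples", "auc_roc"]].to_string(index=False))

        rows = []
        for site in ("thailand", "india"):
            ids = list(table.index[table.site == site])
            rerun = subgroup_rerun(X, y, ids, [K], plan)
            c = aggregate_curves(rerun)
            c.insert(0, "site", site)
            rows.append(c)
        sites = pd.concat(rows, ignore_index=True)
        sites.to_csv(OUT / f"site_reruns_{outcome}.csv", index=False,
                     float_format=FLOAT_FORMAT)
        print(f"{outcome} site reruns (AUC at k={K}):")
        print(sites[["site", "model", "auc_roc_mean", "auc_roc_sd"]]
              .to_string(index=False))

        best, worst = rank_individuals(preds, n_top=10)
        pd.DataFrame(
            [{"group": "best", "recording_id": s.recording_id,
              "mean_correct_class_probability": s.mean_correct_class_probability}
             for s in best] +
            [{"group": "worst", "recording_id": s.recording_id,
              "mean_correct_class_probability": s.mean_correct_class_probability}
             for s in worst]
        ).to_csv(OUT / f"individuals_{outcome}.csv", index=False,
                 float_format=FLOAT_FORMAT)

        freq = selection_frequency(sweep, "enet_lr", K)
        freq.rename("frequency").to_csv(OUT / f"selection_frequency_{outcome}.csv",
                                        float_format=FLOAT_FORMAT)
        top10 = list(freq.head(10).index)
        dist = feature_distributions(X, y, top10)
        dist.to_csv(OUT / f"feature_distributions_{outcome}.csv", index=False,
                    float_format=FLOAT_FORMAT)
        print(f"{outcome}: top-5 selected features: {', '.join(top10[:5])}")

if __name__ == "__main__":
    main()
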