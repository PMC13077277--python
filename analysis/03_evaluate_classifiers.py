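#!/usr/bin/env python
"""Top-k sweep: classify sex and age group with both models.

Reads results/features.csv (from 02_segment_and_extract.py), runs the
leakage-guarded repeated stratified 5-fold cross-validation over a k grid
spanning the 1..50 range, and writes per-evaluation results and
performance-vs-k curves per outcome.
"""

from pathlib import Path

import pandas as pd

from gaitpipe.model_eval import CVPlan, aggregate_curves, results_to_frame, run_topk_sweep
from gaitpipe.pipeline import FLOAT_FORMAT, outcome_labels, split_feature_table

OUT = Path("results")
SEED = 20260923
K_GRID = [1, 2, 3, 5, 8, 10, 15, 25, 50]   # plateau after ~10-15 features
N_REPETITIONS = 20

def main() -> None:
    table = pd.read_csv(OUT / "features.csv").set_index("recording_id")
    X, _ = split_feature_table(table)
    plan = CVPlan(n_folds=5, n_repetitions=N_REPETITIONS, base_seed=SEED)
    for outcome in ("sex", "age"):
        y = outcome_labels(table, outcome)
        sweep = run_topk_sweep(X, y, K_GRID, plan)
        results_to_frame(sweep).to_csv(OUT / f"eval_results_{outcome}.csv",
                                       index=False, float_format=FLOAT_FORMAT)
        curves = aggregate_curves(sweep)
        curves.to_csv(OUT / f"curves_{outcome}.csv", index=False,
                      float_format=FLOAT_FORMAT)
        at = curves[curves["k"] == 15]
        print(f"{outcome}: AUC at k=15 " + ", ".join(
            f"{r.model}={r.auc_roc_mean:.3f} (SD {r.auc_roc_sd:.3f})"
            for r in at.itertuples()))

if __name__ == "__main__":
    main()
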