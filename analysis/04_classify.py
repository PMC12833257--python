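"""Nested-CV fusion classification of the synthetic cohort.

Evaluates the 40/35/25 SVM + network + random-forest soft-voting ensemble
with stratified 10×5 nested cross-validation (in-fold top-k selection and
scaling), then repeats with a temporal hold-out of the last 20% of
participants. Only the AR-condition row of each participant enters the
table: with both conditions included, the two rows of one participant could
straddle a train/test boundary and leak participant identity into the fold
estimate. Under the default between-subject spread the four groups overlap
physiologically, so accuracy sits well below the well-separated ceiling —
the informative check is that it is far above the ~29% majority-class floor
while the leakage guards hold.
"""

import json
from pathlib import Path

from neuroadapt.fusion import nested_cv, stratified_folds, temporal_holdout
from neuroadapt.pipeline import feature_table_from_csv

ROOT = Path(__file__).resolve().parents[1]
SEED = 7


def main() -> None:
    table = feature_table_from_csv(ROOT / "results" / "features.csv")
    from neuroadapt.fusion import FeatureTable
    table = FeatureTable(frame=table.frame[table.frame.condition == "AR"]
                         .reset_index(drop=True))
    print(f"AR-condition rows: {table.n_rows}")
    plan = stratified_folds(table.y, k_outer=10, k_inner=5, seed=SEED)
    report = nested_cv(table, plan)
    print(f"nested CV: accuracy {100 * report.accuracy:.1f}% "
          f"(fold SD {100 * report.fold_sd:.1f}%), "
          f"macro AUC {report.macro_auc:.3f}")
    print(report.per_class.round(1))

    dev, hold = temporal_holdout(table, holdout_fraction=0.2, seed=SEED,
                                 k_outer=5)  # 48 dev rows: 5 folds fit every class
    print(f"\ntemporal hold-out: dev {100 * dev.accuracy:.1f}% vs "
          f"hold-out {100 * hold.accuracy:.1f}%")

    out = ROOT / "results"
    (out / "classification.json").write_text(json.dumps({
        "nested_cv": report.to_dict(),
        "temporal_dev": dev.to_dict(),
        "temporal_holdout": hold.to_dict(),
    }, indent=1))
    report.confusion.to_csv(out / "confusion.csv")
    print("wrote", out / "classification.json")


if __name__ == "__main__":
    main()
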