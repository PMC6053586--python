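"""Train the behavior forest on 10% of tracking days and classify the rest.

Per bird, 10% of tracking days (ceiling rule) supply the training rows —
the simulator's regime labels stand in for a human annotator's manual
window labeling.  A 500-tree random forest is fitted on the six features
and its out-of-bag error, per-class errors, and confusion matrix are
reported; all segments are then classified and perched fixes removed.

Reads results/features.csv; writes results/labeled_flying.csv and
results/classifier_report.json.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from soarscape import behavior_classifier as bc
from soarscape.track_features import FEATURE_COLUMNS

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    features = pd.read_csv(ROOT / "features.csv", parse_dates=["timestamp_utc"])
    complete = features.dropna(subset=FEATURE_COLUMNS).reset_index(drop=True)

    days = bc.sample_training_days(complete, fraction=0.10, seed=seed)
    training = bc.build_training_set(complete, days)
    print(f"training on {len(training)} rows from days {days}")

    model, report = bc.train(training, seed=seed)
    (ROOT / "classifier_report.json").write_text(report.to_json())
    print(f"OOB error {report.oob_error:.3f}; per-class "
          f"{ {k: round(v, 3) for k, v in report.per_class_error.items()} }")

    labeled = bc.classify(model, complete)
    agree = float((labeled["behavior"] == labeled["true_label"]).mean())
    print(f"agreement with simulator truth over all segments: {agree:.3f}")

    flying = bc.exclude_perched(labeled)
    print(f"excluded {flying.attrs['n_perched_removed']} perched fixes; "
          f"{len(flying)} flying fixes remain")
    flying.to_csv(ROOT / "labeled_flying.csv", index=False)


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    main(parser.parse_args().seed)
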