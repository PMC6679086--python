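#!/usr/bin/env python
"""Chance-level statistics for the LOOS results of 03_train_eval.py.

Computes each subject's exact binomial accuracy threshold, selects the
well-classified subset (accuracy strictly above threshold), compares the
accuracy distributions of the groups with a Kruskal-Wallis test, and
builds the confusion matrix with sensitivity/specificity over all test
trials.  Writes thresholds.csv and confusion.json under results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from erpdecode.significance import (chance_threshold, confusion_stats,
                                    kruskal_wallis)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    out = ROOT / "results"
    folds = pd.read_csv(out / "folds.csv")
    preds = pd.read_csv(out / "predictions.csv")

    folds["threshold"] = [chance_threshold(int(n), 2, args.alpha)
                          for n in folds.n_trials]
    folds["retained"] = folds.accuracy > folds.threshold
    folds.to_csv(out / "thresholds.csv", index=False)

    groups = [g.accuracy.to_numpy() for _, g in folds.groupby("group")]
    h, p = kruskal_wallis(*groups)

    conf = confusion_stats(preds.true, preds.predicted,
                           labels=["control", "patient"], positive="patient")
    payload = {
        "alpha": args.alpha,
        "n_retained": int(folds.retained.sum()),
        "n_subjects": len(folds),
        "mean_threshold": round(folds.threshold.mean(), 3),
        "kruskal_wallis": {"H": round(h, 3), "p": round(p, 4)},
        "confusion_matrix": {"labels": conf["labels"],
                             "matrix": conf["matrix"].tolist()},
        "sensitivity": round(conf["sensitivity"], 4),
        "specificity": round(conf["specificity"], 4),
    }
    (out / "confusion.json").write_text(json.dumps(payload, indent=1))
    print(json.dumps(payload, indent=1))


if __name__ == "__main__":
    main()
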