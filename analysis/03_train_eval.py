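#!/usr/bin/env python
"""Leave-one-subject-out evaluation of the classifier on the effect cohort.

Trains the compact CNN once per held-out subject (class-weighted
cross-entropy, Adam, validation-based checkpoint selection) and writes
per-subject fold results and per-trial predictions under results/.
Expect roughly five minutes of CPU time at the benchmark scale.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import erpdecode as ed
from erpdecode import benchmark, cohortio
from erpdecode.preprocess import preprocess_recording
from erpdecode.training import results_frame

ROOT = Path(__file__).resolve().parents[1]


def load_or_simulate(path, seed):
    pre = path / "effect_preprocessed"
    if pre.exists():
        recs, _ = cohortio.load_cohort(pre)
        return recs
    cfg = benchmark.effect_cohort_config(seed=seed)
    return [preprocess_recording(r, csd=False)[0]
            for r in ed.simulate_cohort(cfg)]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohorts")
    args = ap.parse_args()

    cohort = load_or_simulate(args.cohort, args.seed)
    spec = benchmark.benchmark_model_spec(2)
    tconf = benchmark.benchmark_train_config(seed=args.seed)
    results, summary = ed.run_loos(
        cohort, ["control", "patient"], spec, tconf,
        progress=lambda k, n, r: print(
            f"fold {k + 1:2d}/{n}: {r.test_subject} {r.accuracy:5.1f}%",
            flush=True))

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    results_frame(results).to_csv(out / "folds.csv", index=False)
    preds = []
    for r in results:
        for j, (pred, probs) in enumerate(zip(r.predictions, r.probabilities)):
            preds.append({"subject": r.test_subject, "trial": j,
                          "true": r.group, "predicted":
                              ["control", "patient"][pred],
                          "p_patient": round(float(probs[1]), 3)})
    pd.DataFrame(preds).to_csv(out / "predictions.csv", index=False)
    (out / "loos_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"mean accuracy {summary['mean_accuracy']:.1f}% "
          f"+- {summary['sd_accuracy']:.1f}% over {summary['n_subjects']} subjects")


if __name__ == "__main__":
    main()
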