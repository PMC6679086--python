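#!/usr/bin/env python
"""Null calibration: LOOS decoding of an effect-free three-group cohort.

With identical generative templates in all groups, mean leave-one-subject-
out accuracy must sit at the 33.3% three-class chance level and only
~alpha of subjects may exceed their binomial threshold.  This is the
pipeline's guard against information leakage.  Expect roughly ten minutes
of CPU time.  Writes null_folds.csv and null_summary.json under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import erpdecode as ed
from erpdecode import benchmark
from erpdecode.preprocess import preprocess_recording
from erpdecode.significance import select_well_classified
from erpdecode.training import results_frame

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = benchmark.null_cohort_config(seed=args.seed)
    cohort = [preprocess_recording(r, csd=False)[0]
              for r in ed.simulate_cohort(cfg)]
    results, summary = ed.run_loos(
        cohort, ["control", "ADD", "ADHD"], benchmark.benchmark_model_spec(3),
        benchmark.benchmark_train_config(seed=args.seed),
        progress=lambda k, n, r: print(
            f"fold {k + 1:2d}/{n}: {r.test_subject} {r.accuracy:5.1f}%",
            flush=True))

    accs = np.array([r.accuracy for r in results])
    retained, table = select_well_classified(results, alpha=0.05)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    results_frame(results).to_csv(out / "null_folds.csv", index=False)
    payload = {
        "mean_accuracy": round(summary["mean_accuracy"], 2),
        "sd_accuracy": round(summary["sd_accuracy"], 2),
        "chance_level": round(100.0 / 3.0, 2),
        "mc_sd_of_mean": round(float(accs.std(ddof=1) / np.sqrt(len(accs))), 2),
        "well_classified_fraction": round(len(retained) / len(table), 3),
    }
    (out / "null_summary.json").write_text(json.dumps(payload, indent=1))
    print(json.dumps(payload, indent=1))


if __name__ == "__main__":
    main()
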