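#!/usr/bin/env python
"""Preprocess the simulated cohorts: band-pass, baseline, rejection.

Reads the cohort directories written by 01_simulate_cohorts.py, runs the
single-trial chain (0.5-20 Hz zero-phase band-pass, -200...0 ms baseline,
automated artifact rejection; CSD optional via --csd) and writes the
processed cohorts next to the raw ones plus a rejection log under
results/.  On the artifact-free default cohorts the log is empty; rerun
01 with an artifact fraction to see rejections.
"""

import argparse
from pathlib import Path

import pandas as pd

from erpdecode import cohortio
from erpdecode.preprocess import preprocess_recording

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="indir", type=Path,
                    default=ROOT / "scratch" / "cohorts")
    ap.add_argument("--csd", action="store_true",
                    help="apply the current-source-density transform")
    ap.add_argument("--low", type=float, default=0.5)
    ap.add_argument("--high", type=float, default=20.0)
    args = ap.parse_args()

    rows = []
    for name in ("effect", "null"):
        src = args.indir / name
        if not src.exists():
            print(f"skipping {src} (not found; run 01_simulate_cohorts.py)")
            continue
        recs, meta = cohortio.load_cohort(src)
        processed = []
        for rec in recs:
            out, log = preprocess_recording(rec, low=args.low, high=args.high,
                                            csd=args.csd)
            processed.append(out)
            rows += [{"cohort": name, "subject": rec.subject_id, **e}
                     for e in log]
        cohortio.save_cohort(args.indir / f"{name}_preprocessed", processed,
                             seed=meta.get("seed"))
        kept = sum(r.n_trials for r in processed)
        total = sum(r.n_trials for r in recs)
        print(f"{name}: kept {kept}/{total} trials")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame(rows, columns=["cohort", "subject", "trial", "channel",
                                "rule"]).to_csv(
        results / "rejection_log.csv", index=False)
    print(f"wrote {results / 'rejection_log.csv'} ({len(rows)} rejections)")


if __name__ == "__main__":
    main()
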