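#!/usr/bin/env python
"""Score the questionnaire responses.

Reads the simulated trial from scratch/trial.csv, computes 0-100 item,
domain, and total scores for every complete respondent, and writes:

* scratch/scores.csv - one row per respondent with all scores;
* results/score_summary.csv - respondent mean (SD) per outcome and arm.
"""

import argparse
from pathlib import Path

import pandas as pd

from pxmode import OUTCOME_NAMES, load_trial, outcome_series, score_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--trial", type=Path, default=ROOT / "scratch" / "trial.csv")
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "scores.csv")
    args = parser.parse_args()

    if not args.trial.exists():
        raise SystemExit(f"{args.trial} not found - run analysis/01_simulate_trial.py first")
    trial = load_trial(args.trial)
    scores = score_dataset(trial)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    scores.to_csv(args.out, index=False)

    rows = []
    for outcome in OUTCOME_NAMES:
        y = outcome_series(trial, scores, outcome)
        for arm in ("telephone", "mobile_web"):
            vals = y[(trial.df["arm"] == arm) & trial.responded]
            rows.append(
                dict(outcome=outcome, arm=arm, n=len(vals),
                     mean=round(vals.mean(), 2), sd=round(vals.std(ddof=1), 2))
            )
    summary = pd.DataFrame(rows)
    out_summary = ROOT / "results" / "score_summary.csv"
    out_summary.parent.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out_summary, index=False)

    print(f"scored {len(scores)} respondents -> {args.out}")
    total = summary[summary["outcome"] == "total"].set_index("arm")
    print(
        f"total score: telephone {total.loc['telephone','mean']:.2f} "
        f"(SD {total.loc['telephone','sd']:.2f}), mobile web "
        f"{total.loc['mobile_web','mean']:.2f} (SD {total.loc['mobile_web','sd']:.2f})"
    )
    print(f"per-outcome summary -> {out_summary}")


if __name__ == "__main__":
    main()
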