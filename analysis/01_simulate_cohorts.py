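#!/usr/bin/env python
"""Generate the two synthetic study cohorts used by the downstream stages.

Cohort A (panel cohort, n = 112): 21-analyte ELISA panel with latent
coagulation/complement/cytokine activations and a cytokine-moderated
interaction on log disease activity.

Cohort B (clinical cohort, n = 2025): D-dimer/C4 concentrations with
uniform quartile codes and activity labels drawn from the built-in
quartile-coded logistic equation.

Full per-patient tables go to scratch/data/ (regenerable); a small summary
is written to results/.
"""

import json
from pathlib import Path

import coagcomp as cc

SEED = 20250926
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    cohort2 = cc.gen_cohort2(n_patients=112, seed=SEED)
    cohort3 = cc.gen_cohort3(n_patients=2025, seed=SEED + 1)
    cohort2.to_csv(DATA / "cohort_panel.csv", index=False)
    cohort3.to_csv(DATA / "cohort_clinical.csv", index=False)

    summary = {
        "seed": SEED,
        "panel_cohort": {
            "n": len(cohort2),
            "sledai_min": int(cohort2["SLEDAI"].min()),
            "sledai_max": int(cohort2["SLEDAI"].max()),
            "sledai_median": float(cohort2["SLEDAI"].median()),
        },
        "clinical_cohort": {
            "n": len(cohort3),
            "prevalence_active": float(cohort3["active"].mean()),
            "sledai_range": [int(cohort3["SLEDAI"].min()), int(cohort3["SLEDAI"].max())],
        },
    }
    (RESULTS / "01_cohort_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"panel cohort: n={summary['panel_cohort']['n']}, "
          f"SLEDAI {summary['panel_cohort']['sledai_min']}-"
          f"{summary['panel_cohort']['sledai_max']}")
    print(f"clinical cohort: n={summary['clinical_cohort']['n']}, "
          f"active prevalence {summary['clinical_cohort']['prevalence_active']:.3f}")


if __name__ == "__main__":
    main()
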