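#!/usr/bin/env python
"""ROC comparison of the two-marker combination against single markers.

Scores the D-dimer + C4 combination by the built-in equation's predicted
probability, computes AUROCs for the single markers and the auxiliary
comparison markers, and tests each single marker against the combination
with DeLong's paired z test.  A C3 + anti-dsDNA combination (two-predictor
logistic with interaction, refit on this cohort) is evaluated the same way.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

import coagcomp as cc
from coagcomp.biomarker import C4_SCHEME, DDIMER_SCHEME, DEFAULT_EQUATION
from coagcomp.roc import auroc, combined_score, compare_aurocs

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def c3_dsdna_combination(c3, dsdna, active):
    """Predicted probability of a logistic fit on C3, anti-dsDNA and their
    product (C3 negated so higher = riskier on both axes)."""
    x1 = -np.asarray(c3, dtype=float)
    x2 = np.asarray(dsdna, dtype=float)
    X = np.column_stack([np.ones_like(x1), x1, x2, x1 * x2])
    res = sm.Logit(np.asarray(active, float), X).fit(disp=0)
    return res.predict(X)


def main() -> None:
    cohort = pd.read_csv(DATA / "cohort_clinical.csv")
    active = cohort["active"].to_numpy()
    code_d = cc.quartile_code(cohort["ddimer"], DDIMER_SCHEME)
    code_c = cc.quartile_code(cohort["c4"], C4_SCHEME)

    combo = combined_score(code_d, code_c, DEFAULT_EQUATION)
    markers: dict[str, tuple[np.ndarray, bool]] = {
        "ddimer": (cohort["ddimer"].to_numpy(), True),
        "c4": (cohort["c4"].to_numpy(), False),
        "c3": (cohort["c3"].to_numpy(), False),
        "anti_dsdna": (cohort["anti_dsdna"].to_numpy(), True),
        "leukopenia": (cohort["leukopenia"].to_numpy(), True),
        "thrombocytopenia": (cohort["thrombocytopenia"].to_numpy(), True),
        "esr": (cohort["esr"].to_numpy(), True),
        "crp": (cohort["crp"].to_numpy(), True),
        "fib": (cohort["fib"].to_numpy(), True),
        "c3_dsdna_combined": (
            c3_dsdna_combination(cohort["c3"], cohort["anti_dsdna"], active), True
        ),
    }

    results = {"ddimer_c4_combined": {"auroc": auroc(combo, active).auroc}}
    for name, (values, higher) in markers.items():
        res = auroc(values, active, higher_is_risk=higher, marker=name)
        oriented = values if higher else -values
        delong = compare_aurocs(combo, oriented, active)
        results[name] = {
            "auroc": res.auroc,
            "delong_vs_combined": {"difference": delong.difference, "p": delong.p},
        }
    (RESULTS / "05_roc_comparison.json").write_text(
        json.dumps(results, indent=2, sort_keys=True) + "\n"
    )
    print(f"D-dimer + C4 combination: AUROC={results['ddimer_c4_combined']['auroc']:.3f}")
    for name in markers:
        r = results[name]
        print(f"  vs {name:<18} AUROC={r['auroc']:.3f}  "
              f"(DeLong diff={r['delong_vs_combined']['difference']:+.3f}, "
              f"p={r['delong_vs_combined']['p']:.2g})")


if __name__ == "__main__":
    main()
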