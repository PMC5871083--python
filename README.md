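# coagcomp

Biostatistical pipeline for studying how the coagulation cascade and the
complement system jointly relate to disease activity in systemic lupus
erythematosus (SLE), and for diagnosing active disease from two routine
blood markers.

The package is aimed at biostatisticians and clinical epidemiologists and
covers three linked analyses:

1. **Pathway scores.** A panel of 21 ELISA analytes is summarized into
   coagulation, complement and cytokine scores: each analyte is
   normalized to a cohort maximum of 1, then summed with sign +1 for
   pathway activators (e.g. C3a, D-dimer, IL-6) and −1 for inhibitors or
   de-activators (e.g. C1q, C4, antithrombin-III).
2. **Effect modification.** Ordinary least squares of log-transformed
   SLEDAI (ltSLEDAI = ln SLEDAI) on both scores, a product-term
   interaction test, median-split 2×2 stratified comparisons (Fisher LSD
   or Tamhane T2, selected by Levene's test), and repetition of the whole
   analysis within cytokine-score halves to ask whether inflammation
   moderates the coagulation×complement interaction.
3. **Diagnostic model.** Plasma D-dimer and serum C4 are coded 1–4 by
   quartile (4 = highest risk: top quartile of D-dimer, bottom quartile
   of C4) and activity (SLEDAI ≥ 8) is modelled as

       z = β₀ + β₁·code_D + β₂·code_C4 + β₃·code_D·code_C4,
       P(active) = 1 / (1 + e^(−z)),

   with built-in reference coefficients (−1.612, 0.361, 0.325, 0.093),
   fixed cut points 0.56/1.20/2.80 ug/mL (D-dimer) and 0.05/0.12/0.20
   mg/mL (C4), a 16-cell odds-ratio grid, a rectangle-rule cut-off
   performance table (sensitivity, specificity, PPV, NPV, Youden), and
   AUROC comparison against single markers via DeLong's paired test.

Synthetic cohort generators with known ground truth
(`gen_cohort2`/`gen_cohort3`) make every stage testable end to end.

## Worked example

```python
import coagcomp as cc

eq = cc.DEFAULT_EQUATION          # (-1.612, 0.361, 0.325, 0.093)
code_d = cc.quartile_code(3.10, cc.DDIMER_SCHEME)   # 3.10 ug/mL -> 4
code_c = cc.quartile_code(0.04, cc.C4_SCHEME)       # 0.04 mg/mL -> 4
print(code_d, code_c)                               # 4 4
print(cc.linear_predictor(eq, code_d, code_c))      # 2.62
print(round(cc.predict_probability(eq, code_d, code_c), 3))  # 0.932
```

A patient in the top-risk quartile of both markers has linear predictor
z = −1.612 + 0.361·4 + 0.325·4 + 0.093·16 = 2.620, hence a 93.2%
model probability of active lupus; a patient in the lowest-risk quartiles
gets P = 0.303.

The full synthetic pipeline:

```bash
python analysis/01_simulate_cohorts.py   # panel (n=112) + clinical (n=2025)
python analysis/02_pathway_scores.py     # normalization + signed scores
python analysis/03_interaction_analysis.py
python analysis/04_diagnostic_model.py
python analysis/05_roc_comparison.py
```

which prints, among other things:

```
joint model (n=112): beta_coag=0.482 [0.362, 0.601], beta_comp=0.520 [0.345, 0.694]
product-term interaction: p=2.2e-06 (pairwise route: lsd)
cytokine subgroups: p_interaction high=2.1e-05, low=0.3 -> interaction
  concentrated in the high-inflammation half
...
fitted equation (n=2025): z = -1.299 + 0.366*code_d + 0.226*code_c + 0.080*code_d*code_c
all-inclusive rule: sens=1.000 spec=0.000 ppv=0.640 (= prevalence) npv=0.000
D-dimer + C4 combination: AUROC=0.701   (every single marker is lower)
```

i.e. both pathway scores carry positive main effects on log disease
activity, their interaction is detectable and concentrated in the
high-cytokine half, and the two-marker combination out-discriminates each
marker alone — the structure the generators encode. Summary tables land
in `results/`, per-patient tables in `scratch/data/`.

There is also a CLI mirroring these stages
(`coagcomp simulate|scores|interaction|diagnostics|roc|all`); see
`coagcomp --help`.

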