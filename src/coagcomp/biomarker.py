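"""Quartile-coded D-dimer + C4 diagnostic model for lupus activity.

Both markers are coded ordinally 1-4 by quartile with 4 the highest-risk
quartile: the top quartile for plasma D-dimer (coagulation activation) and
the bottom quartile for serum C4 (complement consumption).  Lupus activity
(SLEDAI >= 8) is modelled by logistic regression on the two codes and
their product:

    z = b0 + b1 * code_d + b2 * code_c + b3 * code_d * code_c
    P(active) = 1 / (1 + exp(-z))

The module ships a built-in reference coefficient set
(-1.612, 0.361, 0.325, 0.093) together with the fixed quartile cut points
0.56/1.20/2.80 ug/mL (D-dimer) and 0.05/0.12/0.20 mg/mL (C4), and
reproduces the associated cut-off performance table: each row of that
table is a *rectangle rule* "code_d >= d* and code_c >= c*", carrying the
model probability P(d*, c*) as its label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

HIGHER_IS_RISK = "higher_is_risk"
LOWER_IS_RISK = "lower_is_risk"


@dataclass(frozen=True)
class QuartileScheme:
    """Three ascending cut points mapping a marker to risk codes 1-4."""

    marker: str
    cuts: tuple[float, float, float]
    direction: str = HIGHER_IS_RISK
    units: str = ""

    def __post_init__(self) -> None:
        c1, c2, c3 = self.cuts
        if not (c1 < c2 < c3):
            raise ValueError(f"cut points must be strictly ascending, got {self.cuts}")
        if self.direction not in (HIGHER_IS_RISK, LOWER_IS_RISK):
            raise ValueError(f"unknown direction {self.direction!r}")


#: Fixed cohort cut points for plasma D-dimer (ug/mL), top quartile = risk.
DDIMER_SCHEME = QuartileScheme("D-dimer", (0.56, 1.20, 2.80), HIGHER_IS_RISK, "ug/mL")
#: Fixed cohort cut points for serum C4 (mg/mL), bottom quartile = risk.
C4_SCHEME = QuartileScheme("C4", (0.05, 0.12, 0.20), LOWER_IS_RISK, "mg/mL")


def quartile_code(values, scheme: QuartileScheme):
    """Map concentrations to ordinal risk codes in {1, 2, 3, 4}.

    Intervals are left-open/right-closed on the concentration axis, so a
    value exactly on a cut point belongs to the lower concentration
    interval.  For ``higher_is_risk`` code 4 is the top interval; for
    ``lower_is_risk`` the coding is reversed so code 4 is the bottom one.
    """
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError(f"negative {scheme.marker} concentration")
    # np.searchsorted with side="left": value == cut stays in lower interval
    conc_bin = np.searchsorted(np.asarray(scheme.cuts), arr, side="left") + 1
    if scheme.direction == HIGHER_IS_RISK:
        code = conc_bin
    else:
        code = 5 - conc_bin
    return code if code.shape else int(code)


def estimate_quartiles(
    values, marker: str, direction: str = HIGHER_IS_RISK, units: str = ""
) -> QuartileScheme:
    """Empirical quartile scheme from observed concentrations.

    Cut points are the 25th/50th/75th percentiles under the
    linear-interpolation percentile definition.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 8:
        raise ValueError("need at least 8 values to estimate quartiles")
    if np.unique(arr).size < 4:
        raise ValueError("need at least 4 distinct values to estimate quartiles")
    cuts = tuple(np.percentile(arr, [25, 50, 75], method="linear"))
    return QuartileScheme(marker, cuts, direction, units)


@dataclass(frozen=True)
class PredictiveEquation:
    """Logistic coefficients over quartile codes with a product interaction."""

    beta0: float
    beta1: float  # D-dimer code
    beta2: float  # C4 code
    beta3: float  # interaction = code_d * code_c

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.beta0, self.beta1, self.beta2, self.beta3)


#: Built-in reference equation for the D-dimer + C4 quartile model.
DEFAULT_EQUATION = PredictiveEquation(-1.612, 0.361, 0.325, 0.093)


def _check_codes(code_d, code_c):
    d = np.asarray(code_d)
    c = np.asarray(code_c)
    for name, arr in (("code_d", d), ("code_c", c)):
        if not np.isin(arr, [1, 2, 3, 4]).all():
            raise ValueError(f"{name} must be in {{1, 2, 3, 4}}")
    return d.astype(float), c.astype(float)


def linear_predictor(eq: PredictiveEquation, code_d, code_c):
    """z = b0 + b1*code_d + b2*code_c + b3*code_d*code_c."""
    d, c = _check_codes(code_d, code_c)
    z = eq.beta0 + eq.beta1 * d + eq.beta2 * c + eq.beta3 * d * c
    return z if z.shape else float(z)


def predict_probability(eq: PredictiveEquation, code_d, code_c):
    """Logistic probability of activity at the given quartile codes."""
    z = np.asarray(linear_predictor(eq, code_d, code_c))
    p = 1.0 / (1.0 + np.exp(-z))
    return p if p.shape else float(p)


@dataclass
class FittedEquation:
    equation: PredictiveEquation
    se: tuple[float, float, float, float]
    conf_int: list[tuple[float, float]]
    p_interaction: float
    n: int
    converged: bool


def fit_equation(code_d, code_c, active) -> FittedEquation:
    """Maximum-likelihood fit of the quartile-coded logistic model.

    ``active`` is the binary activity label (SLEDAI >= 8).  Raises on
    single-class labels or (quasi-)complete separation.
    """
    d, c = _check_codes(code_d, code_c)
    y = np.asarray(active, dtype=float)
    if y.size < 20:
        raise ValueError("need at least 20 labelled records")
    if y.min() == y.max():
        raise ValueError("labels are single-class; both outcomes required")
    X = np.column_stack([np.ones_like(d), d, c, d * c])
    try:
        res = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # PerfectSeparationError and kin
        raise ValueError(f"logistic fit failed (separation?): {exc}") from exc
    if not res.mle_retvals["converged"]:
        raise ValueError("logistic fit did not converge")
    params = res.params
    return FittedEquation(
        equation=PredictiveEquation(*params),
        se=tuple(res.bse),
        conf_int=[tuple(ci) for ci in res.conf_int()],
        p_interaction=float(res.pvalues[3]),
        n=int(y.size),
        converged=bool(res.mle_retvals["converged"]),
    )


@dataclass
class ORGrid:
    """Odds ratios for the 16 (code_d, code_c) cells vs the (1,1) reference.

    ``or_`` / ``ci_low`` / ``ci_high`` are 4x4 arrays indexed [d-1, c-1];
    cells that are empty in the data hold NaN (reported, never silently
    dropped).  ``p_interaction`` is the product-term p-value of the coded
    model fitted to the same data.
    """

    or_: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    counts: np.ndarray
    p_interaction: float
    empty_cells: list[tuple[int, int]] = field(default_factory=list)


def or_grid(code_d, code_c, active) -> ORGrid:
    """Logistic fit on 15 cell indicators relative to the (1,1) cell."""
    d, c = _check_codes(code_d, code_c)
    y = np.asarray(active, dtype=float)
    if y.min() == y.max():
        raise ValueError("labels are single-class; both outcomes required")
    counts = np.zeros((4, 4), dtype=int)
    for dd in range(1, 5):
        for cc in range(1, 5):
            counts[dd - 1, cc - 1] = int(((d == dd) & (c == cc)).sum())
    if counts[0, 0] == 0:
        raise ValueError("reference cell (code_d=1, code_c=1) is empty")
    cells = [(dd, cc) for dd in range(1, 5) for cc in range(1, 5) if (dd, cc) != (1, 1)]
    present = [cell for cell in cells if counts[cell[0] - 1, cell[1] - 1] > 0]
    empty = [cell for cell in cells if counts[cell[0] - 1, cell[1] - 1] == 0]
    X = np.column_stack(
        [np.ones_like(d)] + [((d == dd) & (c == cc)).astype(float) for dd, cc in present]
    )
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise ValueError(f"OR-grid logistic fit failed: {exc}") from exc
    grid = np.full((4, 4), np.nan)
    lo = np.full((4, 4), np.nan)
    hi = np.full((4, 4), np.nan)
    grid[0, 0], lo[0, 0], hi[0, 0] = 1.0, 1.0, 1.0
    ci = res.conf_int()
    for k, (dd, cc) in enumerate(present, start=1):
        grid[dd - 1, cc - 1] = float(np.exp(res.params[k]))
        lo[dd - 1, cc - 1] = float(np.exp(ci[k][0]))
        hi[dd - 1, cc - 1] = float(np.exp(ci[k][1]))
    p_int = fit_equation(d.astype(int), c.astype(int), y).p_interaction
    return ORGrid(grid, lo, hi, counts, p_int, empty)


#: Rectangle rules (d*, c*) in the canonical order of the printed
#: performance table, from the strictest (4,4) to the all-inclusive (1,1).
RULE_ORDER: list[tuple[int, int]] = [
    (4, 4), (3, 4), (2, 4), (1, 4),
    (4, 3), (4, 2), (4, 1),
    (3, 3), (2, 3), (1, 3),
    (3, 2), (3, 1),
    (2, 2), (1, 2),
    (2, 1),
    (1, 1),
]


def evaluate_rules(
    code_d,
    code_c,
    active,
    eq: PredictiveEquation = DEFAULT_EQUATION,
    *,
    rules: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Cut-off performance table over rectangle rules.

    A patient tests positive under rule (d*, c*) iff
    ``code_d >= d* and code_c >= c*``.  Each row reports the rule's model
    probability P(d*, c*) (its cut-off label), sensitivity, specificity,
    PPV, NPV and the Youden column defined, as printed, as
    sensitivity + specificity (standard Youden J = that value - 1, emitted
    as ``youden_j``).  Metrics with a zero denominator are reported as 0
    and flagged in ``degenerate``.
    """
    d, c = _check_codes(code_d, code_c)
    y = np.asarray(active, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both active and inactive patients")
    rows = []
    for d_star, c_star in rules or RULE_ORDER:
        positive = (d >= d_star) & (c >= c_star)
        tp = int((positive & y).sum())
        fp = int((positive & ~y).sum())
        fn = int((~positive & y).sum())
        tn = int((~positive & ~y).sum())
        sens = tp / n_pos
        spec = tn / n_neg
        ppv = tp / (tp + fp) if tp + fp else 0.0
        npv = tn / (tn + fn) if tn + fn else 0.0
        rows.append(
            {
                "rule_d": d_star,
                "rule_c": c_star,
                "cutoff_p": predict_probability(eq, d_star, c_star),
                "sensitivity": sens,
                "specificity": spec,
                "ppv": ppv,
                "npv": npv,
                "youden": sens + spec,
                "youden_j": sens + spec - 1.0,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "tn": tn,
                "degenerate": (tp + fp == 0) or (tn + fn == 0),
            }
        )
    return pd.DataFrame(rows)
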