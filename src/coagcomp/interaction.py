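"""Effect-modification analysis of pathway scores on log disease activity.

The inferential sequence: ordinary least squares of ltSLEDAI (natural log
of SLEDAI) on the coagulation and complement scores jointly; a two-sided
t test of the product term as the formal interaction test; median
dichotomization of each score into low/high; comparison of ltSLEDAI means
across the four low/high cells with pairwise LSD tests when Levene's test
accepts variance homogeneity, or Tamhane T2 (pairwise Welch t with Sidak
adjustment) otherwise; and repetition of the whole sequence inside the
low- and high-cytokine halves to probe moderation by inflammation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

LOW = "low"
HIGH = "high"


def lt_transform(sledai, offset: float = 0.0):
    """Natural-log transform of SLEDAI: ln(sledai + offset).

    The default (offset 0) requires SLEDAI >= 1; pass ``offset=1`` for
    cohorts where SLEDAI 0 occurs.
    """
    arr = np.asarray(sledai, dtype=float)
    if (arr + offset <= 0).any():
        raise ValueError(
            "SLEDAI + offset must be positive for the log transform; "
            "use offset=1 for cohorts containing SLEDAI 0"
        )
    out = np.log(arr + offset)
    return out if out.shape else float(out)


@dataclass
class InteractionLinearFit:
    """OLS fit of ltSLEDAI on the two scores (optionally with product term)."""

    beta_coag: float
    ci_coag: tuple[float, float]
    p_coag: float
    beta_comp: float
    ci_comp: tuple[float, float]
    p_comp: float
    beta_interaction: float | None
    p_interaction: float | None
    n: int
    r_squared: float


def _validated_xy(coag, comp, lt):
    x1 = np.asarray(coag, dtype=float)
    x2 = np.asarray(comp, dtype=float)
    y = np.asarray(lt, dtype=float)
    if not (x1.size == x2.size == y.size):
        raise ValueError("inputs must have equal length")
    if x1.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise ValueError("predictors must be non-constant")
    r = np.corrcoef(x1, x2)[0, 1]
    if abs(r) >= 1.0 - 1e-12:
        raise ValueError("predictors are perfectly collinear")
    return x1, x2, y


def fit_joint_linear(coag, comp, lt, *, interaction: bool = False) -> InteractionLinearFit:
    """OLS of ltSLEDAI ~ coag + comp (+ coag*comp), 95% t CIs."""
    x1, x2, y = _validated_xy(coag, comp, lt)
    cols = [np.ones_like(x1), x1, x2]
    if interaction:
        prod = x1 * x2
        design = np.column_stack(cols + [prod])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("product term is collinear with main effects")
        cols.append(prod)
    X = np.column_stack(cols)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    return InteractionLinearFit(
        beta_coag=float(res.params[1]),
        ci_coag=tuple(ci[1]),
        p_coag=float(res.pvalues[1]),
        beta_comp=float(res.params[2]),
        ci_comp=tuple(ci[2]),
        p_comp=float(res.pvalues[2]),
        beta_interaction=float(res.params[3]) if interaction else None,
        p_interaction=float(res.pvalues[3]) if interaction else None,
        n=int(y.size),
        r_squared=float(res.rsquared),
    )


def test_interaction(coag, comp, lt) -> float:
    """Two-sided p-value of the product term in the joint OLS model."""
    fit = fit_joint_linear(coag, comp, lt, interaction=True)
    assert fit.p_interaction is not None
    return fit.p_interaction


def dichotomize(scores, method: str = "median"):
    """Split scores into 'low'/'high' groups; ties at the threshold go low.

    Returns ``(labels, threshold)`` where ``labels`` is an array of
    'low'/'high' and high means strictly above the threshold.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 scores to dichotomize")
    if np.ptp(arr) == 0:
        raise ValueError("all scores equal; no split possible")
    if method != "median":
        raise ValueError(f"unknown dichotomization method {method!r}")
    threshold = float(np.median(arr))
    labels = np.where(arr > threshold, HIGH, LOW)
    return labels, threshold


@dataclass
class CellStats:
    n: int
    mean_coag: float
    sd_coag: float
    mean_comp: float
    sd_comp: float
    mean_lt: float
    sd_lt: float


@dataclass
class StratifiedTable:
    """2x2 low/high cell summary of ltSLEDAI with pairwise comparisons.

    ``cells`` is keyed by (coag_level, comp_level); ``pairwise_p`` by
    frozensets of two such keys.  ``route`` records whether the
    equal-variance LSD tests or Tamhane T2 was used, decided by Levene's
    test on ltSLEDAI across the four cells.
    """

    cells: dict[tuple[str, str], CellStats]
    pairwise_p: dict[frozenset, float]
    route: str
    levene_p: float
    n: int

    def p_between(self, cell_a: tuple[str, str], cell_b: tuple[str, str]) -> float:
        return self.pairwise_p[frozenset((cell_a, cell_b))]


_CELLS = [(HIGH, HIGH), (HIGH, LOW), (LOW, HIGH), (LOW, LOW)]


def stratified_means(
    coag,
    comp,
    lt,
    coag_labels=None,
    comp_labels=None,
    *,
    alpha_levene: float = 0.05,
    route: str = "auto",
) -> StratifiedTable:
    """Four-cell stratified comparison of ltSLEDAI.

    Labels default to median dichotomization of the scores.  Pairwise
    p-values across the four cells use Fisher's LSD (pooled-MSE pairwise t
    from the one-way ANOVA, df = N - 4) when Levene's test across the
    cells has p >= ``alpha_levene``, else Tamhane T2 (pairwise Welch t,
    Sidak-adjusted over the 6 comparisons).  ``route`` may force either
    branch ('lsd' / 'tamhane_t2') instead of the Levene decision.
    """
    if route not in ("auto", "lsd", "tamhane_t2"):
        raise ValueError(f"unknown route {route!r}")
    x1 = np.asarray(coag, dtype=float)
    x2 = np.asarray(comp, dtype=float)
    y = np.asarray(lt, dtype=float)
    if coag_labels is None:
        coag_labels, _ = dichotomize(x1)
    if comp_labels is None:
        comp_labels, _ = dichotomize(x2)
    coag_labels = np.asarray(coag_labels)
    comp_labels = np.asarray(comp_labels)

    cells: dict[tuple[str, str], CellStats] = {}
    groups: dict[tuple[str, str], np.ndarray] = {}
    for key in _CELLS:
        mask = (coag_labels == key[0]) & (comp_labels == key[1])
        if not mask.any():
            raise ValueError(f"empty cell (coag={key[0]}, comp={key[1]})")
        groups[key] = y[mask]
        cells[key] = CellStats(
            n=int(mask.sum()),
            mean_coag=float(x1[mask].mean()),
            sd_coag=float(x1[mask].std(ddof=1)) if mask.sum() > 1 else 0.0,
            mean_comp=float(x2[mask].mean()),
            sd_comp=float(x2[mask].std(ddof=1)) if mask.sum() > 1 else 0.0,
            mean_lt=float(y[mask].mean()),
            sd_lt=float(y[mask].std(ddof=1)) if mask.sum() > 1 else 0.0,
        )

    values = list(groups.values())
    if all(np.ptp(v) == 0 for v in values) and np.ptp(y) == 0:
        # all observations identical: no variance, means equal by construction
        pairwise = {
            frozenset((a, b)): 1.0 for a, b in itertools.combinations(_CELLS, 2)
        }
        return StratifiedTable(cells, pairwise, "lsd", 1.0, int(y.size))

    if route == "auto":
        with np.errstate(divide="ignore", invalid="ignore"):
            levene_p = float(stats.levene(*values, center="mean").pvalue)
        route = "lsd" if levene_p >= alpha_levene else "tamhane_t2"
    else:
        levene_p = float("nan")
    pairwise: dict[frozenset, float] = {}
    if route == "lsd":
        n_total = y.size
        k = len(values)
        grand_means = {key: v.mean() for key, v in groups.items()}
        mse = sum(((v - v.mean()) ** 2).sum() for v in values) / (n_total - k)
        df = n_total - k
        for a, b in itertools.combinations(_CELLS, 2):
            va, vb = groups[a], groups[b]
            if mse == 0:
                p = 1.0 if grand_means[a] == grand_means[b] else 0.0
            else:
                t = (grand_means[a] - grand_means[b]) / np.sqrt(
                    mse * (1 / va.size + 1 / vb.size)
                )
                p = float(2 * stats.t.sf(abs(t), df))
            pairwise[frozenset((a, b))] = p
    else:
        m = len(list(itertools.combinations(_CELLS, 2)))
        for a, b in itertools.combinations(_CELLS, 2):
            res = stats.ttest_ind(groups[a], groups[b], equal_var=False)
            p_sidak = float(1.0 - (1.0 - res.pvalue) ** m)
            pairwise[frozenset((a, b))] = min(1.0, p_sidak)
    return StratifiedTable(cells, pairwise, route, levene_p, int(y.size))


@dataclass
class SubgroupModeration:
    """Part-2 pipeline rerun inside cytokine-median subgroups."""

    fits: dict[str, InteractionLinearFit]
    p_interaction: dict[str, float]
    tables: dict[str, StratifiedTable]
    cytokine_threshold: float
    n: dict[str, int] = field(default_factory=dict)


def subgroup_moderation(coag, comp, cytokine, lt) -> SubgroupModeration:
    """Split by the cytokine-score median (ties low) and repeat the
    joint fit, interaction test and stratified comparison in each half.

    Dichotomization thresholds for the coagulation and complement scores
    are recomputed within each subgroup.
    """
    x1 = np.asarray(coag, dtype=float)
    x2 = np.asarray(comp, dtype=float)
    cyt = np.asarray(cytokine, dtype=float)
    y = np.asarray(lt, dtype=float)
    if y.size < 8:
        raise ValueError("need at least 8 observations for subgroup analysis")
    labels, threshold = dichotomize(cyt)
    fits, p_int, tables, ns = {}, {}, {}, {}
    for level in (LOW, HIGH):
        mask = labels == level
        if mask.sum() < 4:
            raise ValueError(f"{level}-cytokine subgroup has fewer than 4 patients")
        fits[level] = fit_joint_linear(x1[mask], x2[mask], y[mask])
        p_int[level] = test_interaction(x1[mask], x2[mask], y[mask])
        tables[level] = stratified_means(x1[mask], x2[mask], y[mask])
        ns[level] = int(mask.sum())
    return SubgroupModeration(fits, p_int, tables, threshold, ns)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation with the two-sided t-based p-value."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector has undefined correlation")
    res = stats.pearsonr(a, b)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(a.size))
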