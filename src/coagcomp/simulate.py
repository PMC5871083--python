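"""Synthetic lupus cohorts with the statistical structure the analyses assume.

Two generators are provided.

``gen_cohort2`` emulates an ELISA-panel cohort: each patient carries three
latent pathway activations (coagulation, complement, cytokine; standard
normal), analyte concentrations are lognormal with activators loading
positively and inhibitors negatively on their pathway's latent, and
log disease activity (ltSLEDAI) follows a linear model with main effects
plus a coagulation x complement interaction whose coefficient switches at
the cytokine latent's median (a hard effect-modification switch mirroring
a median-split subgroup analysis).  SLEDAI is exp(ltSLEDAI) rounded to the
nearest integer and floored at 1.

``gen_cohort3`` emulates a clinical-records cohort: D-dimer and C4
quartile codes marginally uniform on {1..4}, continuous concentrations
uniform within each code's interval, and activity labels Bernoulli with
probability given by a quartile-coded logistic equation.  Optional
comparison markers (C3, anti-dsDNA, cytopenias, ESR, CRP, FIB) are drawn
with activity-dependent distributions for ROC benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import ACTIVATOR, DEFAULT_CATALOG, CatalogEntry
from .biomarker import (
    C4_SCHEME,
    DDIMER_SCHEME,
    DEFAULT_EQUATION,
    PredictiveEquation,
    QuartileScheme,
    predict_probability,
)


@dataclass(frozen=True)
class AnalyteModel:
    """Lognormal concentration model for one analyte.

    log-concentration = log_mean + log_sd * (loading * s * A + sqrt(1 -
    loading^2) * eps), where A is the pathway latent, s = +1 for activators
    and -1 for inhibitors, and eps is standard normal, so log_sd is the
    marginal log-scale standard deviation and |loading| the correlation
    with the (signed) latent.
    """

    log_mean: float = 0.0
    log_sd: float = 0.5
    loading: float = 0.7

    def __post_init__(self) -> None:
        if not 0 <= abs(self.loading) <= 1:
            raise ValueError("loading must lie in [-1, 1]")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")


@dataclass(frozen=True)
class Cohort2Config:
    """Generating model for the ELISA-panel cohort.

    Default effect sizes are of the magnitude seen in lupus panel studies:
    main effects near 0.7 and 0.6 on the log-SLEDAI scale per latent SD, a
    strong interaction (0.8) in the high-cytokine half and none in the low
    half, residual noise SD 0.5, intercept 2.0 (median SLEDAI ~ 7).
    """

    n_patients: int = 112
    seed: int = 0
    catalog: dict[str, CatalogEntry] = field(
        default_factory=lambda: dict(DEFAULT_CATALOG)
    )
    analyte_models: dict[str, AnalyteModel] = field(default_factory=dict)
    intercept: float = 2.0
    beta_coag: float = 0.7
    beta_comp: float = 0.6
    beta_inter_high_cytokine: float = 0.8
    beta_inter_low_cytokine: float = 0.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be at least 4")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def gen_cohort2(config: Cohort2Config | None = None, **overrides) -> pd.DataFrame:
    """Generate an analyte-panel cohort with known ground truth.

    Returns one row per patient with columns: ``patient_id``, one column
    per catalogued analyte (raw concentration), ``SLEDAI``, plus the
    generator's ground truth ``latent_coag``, ``latent_comp``,
    ``latent_cytokine`` and ``ltsledai_true`` (the continuous linear-model
    outcome before exponentiation/rounding), retained so parameter
    recovery can be checked without rounding attenuation.
    """
    if config is None:
        config = Cohort2Config(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    latents = {
        "coagulation": rng.standard_normal(n),
        "complement": rng.standard_normal(n),
        "cytokine": rng.standard_normal(n),
    }
    data: dict[str, np.ndarray] = {
        "patient_id": np.array([f"P{i:05d}" for i in range(1, n + 1)])
    }
    for name, entry in config.catalog.items():
        model = config.analyte_models.get(name, AnalyteModel())
        sign = 1.0 if entry.role == ACTIVATOR else -1.0
        shared = model.loading * sign * latents[entry.pathway]
        unique = np.sqrt(1.0 - model.loading**2) * rng.standard_normal(n)
        data[name] = np.exp(model.log_mean + model.log_sd * (shared + unique))
    a_coag = latents["coagulation"]
    a_comp = latents["complement"]
    a_cyt = latents["cytokine"]
    high_cyt = a_cyt > np.median(a_cyt)
    beta_inter = np.where(
        high_cyt, config.beta_inter_high_cytokine, config.beta_inter_low_cytokine
    )
    lt = (
        config.intercept
        + config.beta_coag * a_coag
        + config.beta_comp * a_comp
        + beta_inter * a_coag * a_comp
        + rng.normal(0.0, config.noise_sd, n)
    )
    # floor at 1 (log transform defined) and cap at the index's theoretical
    # maximum; the uncapped linear outcome is kept in ltsledai_true
    sledai = np.clip(np.rint(np.exp(lt)).astype(int), 1, 105)
    df = pd.DataFrame(data)
    df["SLEDAI"] = sledai
    df["latent_coag"] = a_coag
    df["latent_comp"] = a_comp
    df["latent_cytokine"] = a_cyt
    df["ltsledai_true"] = lt
    return df


@dataclass(frozen=True)
class Cohort3Config:
    """Generating model for the clinical-records cohort.

    Quartile codes are marginally uniform; ``code_correlation`` sets the
    rank correlation between the two codes through a Gaussian copula
    (default 0: independent codes).  ``ddimer_max`` / ``c4_max`` cap the
    open top concentration intervals so continuous values can be drawn
    uniformly within every code's interval.
    """

    n_patients: int = 2025
    seed: int = 0
    equation: PredictiveEquation = DEFAULT_EQUATION
    ddimer_scheme: QuartileScheme = DDIMER_SCHEME
    c4_scheme: QuartileScheme = C4_SCHEME
    code_correlation: float = 0.0
    ddimer_max: float = 8.0
    c4_max: float = 0.40
    enumerate_cells: bool = False
    extra_markers: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not -1.0 <= self.code_correlation <= 1.0:
            raise ValueError("code_correlation must lie in [-1, 1]")
        if self.ddimer_max <= self.ddimer_scheme.cuts[2]:
            raise ValueError("ddimer_max must exceed the top cut point")
        if self.c4_max <= self.c4_scheme.cuts[2]:
            raise ValueError("c4_max must exceed the top cut point")
        if self.enumerate_cells and self.n_patients != 16:
            raise ValueError("enumerate_cells requires n_patients == 16")


def _codes_from_copula(rng: np.random.Generator, n: int, rho: float):
    """Marginally uniform quartile codes with latent Gaussian correlation."""
    if rho == 0.0:
        return rng.integers(1, 5, size=n), rng.integers(1, 5, size=n)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n)
    from scipy.stats import norm

    u = norm.cdf(z)
    codes = np.ceil(u * 4).astype(int)
    return np.clip(codes[:, 0], 1, 4), np.clip(codes[:, 1], 1, 4)


def _uniform_in_interval(rng, codes, edges):
    lo = edges[codes - 1]
    hi = edges[codes]
    return rng.uniform(lo, hi)


def gen_cohort3(config: Cohort3Config | None = None, **overrides) -> pd.DataFrame:
    """Generate a clinical cohort whose labels follow a known equation.

    Returns one row per patient with patient id, D-dimer and C4
    concentrations and quartile codes, SLEDAI, the binary ``active`` label
    (SLEDAI >= 8), the generating probability ``p_true``, and (unless
    disabled) comparison markers for ROC benchmarking.
    """
    if config is None:
        config = Cohort3Config(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if config.enumerate_cells:
        grid = [(d, c) for d in range(1, 5) for c in range(1, 5)]
        code_d = np.array([g[0] for g in grid])
        code_c = np.array([g[1] for g in grid])
    else:
        code_d, code_c = _codes_from_copula(rng, n, config.code_correlation)

    # concentration intervals per code, on the concentration axis
    dd_edges = np.array([0.0, *config.ddimer_scheme.cuts, config.ddimer_max])
    ddimer = _uniform_in_interval(rng, code_d, dd_edges)
    # C4 codes are reversed: code 4 = lowest concentrations
    c4_edges = np.array([0.0, *config.c4_scheme.cuts, config.c4_max])
    c4 = _uniform_in_interval(rng, 5 - code_c, c4_edges)

    p = predict_probability(config.equation, code_d, code_c)
    p = np.atleast_1d(np.asarray(p))
    active = rng.random(n) < p
    sledai = np.where(active, rng.integers(8, 25, size=n), rng.integers(0, 8, size=n))

    df = pd.DataFrame(
        {
            "patient_id": [f"Q{i:05d}" for i in range(1, n + 1)],
            "ddimer": ddimer,
            "c4": c4,
            "code_d": code_d,
            "code_c": code_c,
            "SLEDAI": sledai,
            "active": active.astype(int),
            "p_true": p,
        }
    )
    if config.extra_markers:
        _add_comparison_markers(df, rng, active)
    return df


def _add_comparison_markers(df: pd.DataFrame, rng, active: np.ndarray) -> None:
    """Activity-shifted comparison markers, loosely matching the marginal
    frequencies reported for large lupus cohorts (anti-dsDNA ~ 39%,
    leukopenia ~ 31%, thrombocytopenia ~ 25%)."""
    n = len(df)

    def bernoulli(p_active, p_inactive):
        p = np.where(active, p_active, p_inactive)
        return (rng.random(n) < p).astype(int)

    df["anti_dsdna"] = bernoulli(0.45, 0.28)
    df["leukopenia"] = bernoulli(0.38, 0.24)
    df["thrombocytopenia"] = bernoulli(0.30, 0.20)
    # serum C3 (mg/mL): complement consumption lowers it in active disease;
    # moderate shifts (~0.5 SD) keep every single marker below the
    # two-marker combination's discrimination
    df["c3"] = np.clip(
        rng.normal(np.where(active, 0.88, 1.00), 0.25), 0.05, None
    )
    # acute-phase / coagulation markers: higher in active disease
    df["esr"] = np.exp(rng.normal(np.where(active, 3.15, 2.9), 0.5))  # mm/h
    df["crp"] = np.exp(rng.normal(np.where(active, 1.8, 1.5), 0.8))  # mg/L
    df["fib"] = np.clip(
        rng.normal(np.where(active, 3.8, 3.4), 1.0), 0.5, None
    )  # ug/mL
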