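"""Summary pathway scores from an analyte panel.

Concentrations are first normalized per analyte so that the maximum value
across the cohort is 1 (units cancel), then summed per pathway with
activators entering positively and inhibitors negatively.  With the default
catalog the attainable ranges are: cytokine score in [0, 3], complement
score in [-3, 5], coagulation score in [-4, 6].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import CatalogEntry, DEFAULT_CATALOG, PATHWAYS, pathway_members


def normalize_analytes(panel: pd.DataFrame) -> pd.DataFrame:
    """Divide each analyte column by its maximum over patients.

    Parameters
    ----------
    panel
        Patients x analytes matrix of raw concentrations (non-negative).

    Returns
    -------
    Same-shape DataFrame in which every column has maximum exactly 1.

    Raises
    ------
    ValueError
        If the panel is empty, a concentration is negative, a value is
        missing, or an analyte column is identically zero (the column
        maximum would divide by zero); the offending analyte is named.
    """
    if panel.shape[0] < 1:
        raise ValueError("panel must contain at least one patient")
    values = panel.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = panel.columns[np.isnan(values).any(axis=0)].tolist()
        raise ValueError(f"missing concentrations for analytes: {bad}")
    if (values < 0).any():
        bad = panel.columns[(values < 0).any(axis=0)].tolist()
        raise ValueError(f"negative concentrations for analytes: {bad}")
    col_max = values.max(axis=0)
    zero = col_max == 0
    if zero.any():
        bad = panel.columns[zero].tolist()
        raise ValueError(f"all-zero analyte columns (cannot normalize): {bad}")
    return panel / col_max


def compute_pathway_score(
    normalized: pd.DataFrame,
    catalog: dict[str, CatalogEntry] | None = None,
    pathway: str = "complement",
    *,
    allow_missing: bool = False,
) -> pd.Series:
    """Signed sum of normalized analyte levels for one pathway.

    score = sum(activators) - sum(inhibitors), computed per patient from a
    matrix already normalized so each analyte's maximum is 1.

    ``allow_missing`` drops catalogued analytes absent from the panel (or
    NaN for a patient) instead of raising; dropped analytes simply do not
    contribute, no rescaling is applied.
    """
    catalog = DEFAULT_CATALOG if catalog is None else catalog
    acts, inhs = pathway_members(catalog, pathway)
    if not acts and not inhs:
        raise ValueError(f"pathway {pathway!r} has no catalogued analytes")
    missing = [a for a in acts + inhs if a not in normalized.columns]
    if missing and not allow_missing:
        raise ValueError(
            f"panel lacks {pathway} analytes {missing}; "
            "set allow_missing=True to drop them"
        )
    acts = [a for a in acts if a in normalized.columns]
    inhs = [a for a in inhs if a in normalized.columns]
    pos = normalized[acts].sum(axis=1, min_count=0) if acts else 0.0
    neg = normalized[inhs].sum(axis=1, min_count=0) if inhs else 0.0
    score = pos - neg
    if not allow_missing and normalized[acts + inhs].isna().any().any():
        bad = normalized[acts + inhs].columns[
            normalized[acts + inhs].isna().any()
        ].tolist()
        raise ValueError(f"missing values in {pathway} analytes: {bad}")
    score.name = f"{pathway}_score"
    return score


def score_panel(
    panel: pd.DataFrame,
    catalog: dict[str, CatalogEntry] | None = None,
    *,
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Normalize a raw panel and return all three summary pathway scores.

    Returns a DataFrame indexed like ``panel`` with columns
    ``coagulation_score``, ``complement_score``, ``cytokine_score``.
    """
    catalog = DEFAULT_CATALOG if catalog is None else catalog
    known = [c for c in panel.columns if c in catalog]
    normalized = normalize_analytes(panel[known])
    out = {}
    for pathway in PATHWAYS:
        out[f"{pathway}_score"] = compute_pathway_score(
            normalized, catalog, pathway, allow_missing=allow_missing
        )
    scores = pd.DataFrame(out)
    return scores[["coagulation_score", "complement_score", "cytokine_score"]]
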