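"""Default analyte catalog: pathway membership and activator/inhibitor roles.

The panel covers seven complement proteins (plus nephelometric serum C4),
ten coagulation proteins and three inflammatory cytokines measured by ELISA
in lupus patients.  An *activator* rises with activation of its pathway and
enters the summary score with sign +1; an *inhibitor* (de-activator) falls
with activation and enters with sign -1.
"""

from __future__ import annotations

from dataclasses import dataclass

COMPLEMENT = "complement"
COAGULATION = "coagulation"
CYTOKINE = "cytokine"

ACTIVATOR = "activator"
INHIBITOR = "inhibitor"

PATHWAYS = (COMPLEMENT, COAGULATION, CYTOKINE)
ROLES = (ACTIVATOR, INHIBITOR)


@dataclass(frozen=True)
class CatalogEntry:
    """Pathway membership and signed role of one analyte."""

    pathway: str
    role: str

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def sign(self) -> int:
        return 1 if self.role == ACTIVATOR else -1


#: Default catalog: 21 ELISA analytes plus serum C4 (nephelometric),
#: which joins the complement score on the inhibitor/de-activator side.
DEFAULT_CATALOG: dict[str, CatalogEntry] = {
    # complement activators
    "C3a": CatalogEntry(COMPLEMENT, ACTIVATOR),
    "C4a": CatalogEntry(COMPLEMENT, ACTIVATOR),
    "C5a": CatalogEntry(COMPLEMENT, ACTIVATOR),
    "MASP2": CatalogEntry(COMPLEMENT, ACTIVATOR),
    "C7": CatalogEntry(COMPLEMENT, ACTIVATOR),
    # complement inhibitors / de-activators
    "C1q": CatalogEntry(COMPLEMENT, INHIBITOR),
    "FI": CatalogEntry(COMPLEMENT, INHIBITOR),
    "C4": CatalogEntry(COMPLEMENT, INHIBITOR),
    # coagulation activators
    "VWF": CatalogEntry(COAGULATION, ACTIVATOR),
    "F7": CatalogEntry(COAGULATION, ACTIVATOR),
    "TAT": CatalogEntry(COAGULATION, ACTIVATOR),
    "FIB": CatalogEntry(COAGULATION, ACTIVATOR),
    "F9": CatalogEntry(COAGULATION, ACTIVATOR),
    "D-dimer": CatalogEntry(COAGULATION, ACTIVATOR),
    # coagulation inhibitors
    "PROS": CatalogEntry(COAGULATION, INHIBITOR),
    "F12": CatalogEntry(COAGULATION, INHIBITOR),
    "F13": CatalogEntry(COAGULATION, INHIBITOR),
    "ATIII": CatalogEntry(COAGULATION, INHIBITOR),
    # inflammatory cytokines (all activators)
    "TNF-RII": CatalogEntry(CYTOKINE, ACTIVATOR),
    "IL-6": CatalogEntry(CYTOKINE, ACTIVATOR),
    "IL-8": CatalogEntry(CYTOKINE, ACTIVATOR),
}


def pathway_members(
    catalog: dict[str, CatalogEntry], pathway: str
) -> tuple[list[str], list[str]]:
    """Return (activators, inhibitors) of ``pathway`` in catalog order."""
    acts = [a for a, e in catalog.items() if e.pathway == pathway and e.role == ACTIVATOR]
    inhs = [a for a, e in catalog.items() if e.pathway == pathway and e.role == INHIBITOR]
    return acts, inhs


def catalog_from_mapping(mapping: dict[str, dict[str, str]]) -> dict[str, CatalogEntry]:
    """Build a catalog from a plain mapping (e.g. parsed YAML).

    ``mapping`` maps analyte name -> {"pathway": ..., "role": ...}.
    """
    return {
        name: CatalogEntry(spec["pathway"], spec["role"])
        for name, spec in mapping.items()
    }


def catalog_to_mapping(catalog: dict[str, CatalogEntry]) -> dict[str, dict[str, str]]:
    return {
        name: {"pathway": e.pathway, "role": e.role} for name, e in catalog.items()
    }
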