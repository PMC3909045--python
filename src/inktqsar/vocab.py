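"""Closed vocabularies for markers and test-systems.

Five assay contexts ("test-models") are recognised: species (mice/human)
crossed with in-vivo vs in-vitro, the in-vitro ones split by antigen
presentation (CD1d on cells, "cell-cell", or plate-bound CD1d,
"cell-plate").  Four cytokine markers are tracked: IL-2 and IFN-γ on the
pro-inflammatory (Th1) side, IL-4 and IL-13 on the anti-inflammatory (Th2)
side.  Every analogue can therefore carry at most 5 × 4 = 20 aggregated
responses.
"""

from __future__ import annotations

MARKERS: tuple[str, ...] = ("IL-2", "IFN-γ", "IL-4", "IL-13")

MICE_IN_VIVO = "mice/in-vivo"
MICE_IN_VITRO_CC = "mice/in-vitro/cell-cell"
MICE_IN_VITRO_CP = "mice/in-vitro/cell-plate"
HUMAN_IN_VITRO_CC = "human/in-vitro/cell-cell"
HUMAN_IN_VITRO_CP = "human/in-vitro/cell-plate"

TEST_SYSTEMS: tuple[str, ...] = (
    MICE_IN_VIVO,
    MICE_IN_VITRO_CC,
    MICE_IN_VITRO_CP,
    HUMAN_IN_VITRO_CC,
    HUMAN_IN_VITRO_CP,
)

#: in-vitro systems pooled for desirability/modelling (cell-plate excluded)
IN_VITRO_CC_SYSTEMS: tuple[str, ...] = (MICE_IN_VITRO_CC, HUMAN_IN_VITRO_CC)

N_RESPONSE_SLOTS: int = len(TEST_SYSTEMS) * len(MARKERS)

_MARKER_ALIASES = {
    "il2": "IL-2",
    "il-2": "IL-2",
    "ifng": "IFN-γ",
    "ifn-g": "IFN-γ",
    "ifngamma": "IFN-γ",
    "ifn-gamma": "IFN-γ",
    "ifn-γ": "IFN-γ",
    "ifnγ": "IFN-γ",
    "il4": "IL-4",
    "il-4": "IL-4",
    "il13": "IL-13",
    "il-13": "IL-13",
}

_SPECIES = {"mice": "mice", "mouse": "mice", "human": "human"}
_SETTING = {"in-vivo": "in-vivo", "invivo": "in-vivo", "in vivo": "in-vivo",
            "in-vitro": "in-vitro", "invitro": "in-vitro", "in vitro": "in-vitro"}
_PRESENTATION = {"cell-cell": "cell-cell", "cellcell": "cell-cell",
                 "cell-plate": "cell-plate", "cellplate": "cell-plate",
                 "": "", "na": "", "none": "", "-": ""}


class VocabularyError(ValueError):
    """Raised when a marker or test-system term is not in the closed vocabulary."""


def normalize_marker(raw: str) -> str:
    key = str(raw).strip().lower().replace("_", "-").replace(" ", "")
    if key in _MARKER_ALIASES:
        return _MARKER_ALIASES[key]
    raise VocabularyError(f"unknown marker {raw!r}")


def make_test_system(species: str, setting: str, presentation: str = "") -> str:
    """Build the canonical test-system string from its three components."""
    sp = _SPECIES.get(str(species).strip().lower())
    st = _SETTING.get(str(setting).strip().lower().replace("_", "-"))
    pr = _PRESENTATION.get(str(presentation).strip().lower().replace("_", "-"))
    if sp is None or st is None or pr is None:
        raise VocabularyError(
            f"unknown test-system components {species!r}/{setting!r}/{presentation!r}")
    name = f"{sp}/{st}" if st == "in-vivo" else f"{sp}/{st}/{pr}"
    if name not in TEST_SYSTEMS:
        raise VocabularyError(f"{name!r} is not one of the five recognised test-models")
    return name


def split_test_system(system: str) -> tuple[str, str, str]:
    """Inverse of :func:`make_test_system`; presentation is '' for in-vivo."""
    parts = system.split("/")
    if len(parts) == 2:
        return parts[0], parts[1], ""
    return parts[0], parts[1], parts[2]
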