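"""Diagnosis-code mapping for fracture-site classification.

Case definitions operate on ICD-10-CA-style diagnosis codes. The official
code list is not redistributable, so the mapping from code prefixes to
fracture-site classes is a configuration artifact (``CodeMap``) with
documented defaults covering the sites relevant to fragility fractures:
hip, vertebral (thoracic/lumbar, excluding sacrum and coccyx), wrist
(distal forearm), humerus, multiple sites, and a residual "other" class.
Sites not typically related to osteoporosis (heel, toe, hand, finger,
face, skull) classify to nothing and never produce a case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ConfigurationError

SITE_CLASSES = ("hip", "vertebral", "wrist", "humerus", "multiple", "other")

#: Half-open decade age bands used throughout the pipeline.
AGE_BANDS = ("50-59", "60-69", "70-79", "80-89", "90+")

ADMISSION_SOURCES = (
    "community",
    "rehabilitation",
    "continuing_care",
    "long_term_care",
    "other",
)

DISCHARGE_DESTINATIONS = ADMISSION_SOURCES + ("home_with_homecare", "death")

#: Institutional destinations that take part in net-transfer accounting.
TRANSFER_DESTINATIONS = ("rehabilitation", "continuing_care", "long_term_care")


def _normalize(code: str) -> str:
    return code.replace(".", "").strip().upper()


@dataclass
class CodeMap:
    """Prefix → fracture-site mapping plus trauma/intervention vocabularies.

    ``site_prefixes`` maps each includable site class to diagnosis-code
    prefixes (dots ignored, case-insensitive). ``excluded_site_prefixes``
    are fracture codes at sites unrelated to osteoporosis; records whose
    only fracture codes match them are not cases. ``severe_trauma_prefixes``
    match external-cause codes marking high-energy trauma (excluded in the
    base case). ``fracture_intervention_keywords`` are substrings matched
    against intervention descriptions to satisfy the secondary-code case
    definition.
    """

    site_prefixes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    excluded_site_prefixes: tuple[str, ...] = ()
    severe_trauma_prefixes: tuple[str, ...] = ()
    fracture_intervention_keywords: tuple[str, ...] = (
        "fixation",
        "immobilization",
        "reduction",
        "partial excision",
        "repair",
    )

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for site, prefixes in self.site_prefixes.items():
            if site not in SITE_CLASSES:
                raise ConfigurationError(f"unknown site class {site!r}")
            for p in prefixes:
                p = _normalize(p)
                if p in seen and seen[p] != site:
                    raise ConfigurationError(
                        f"prefix {p!r} maps to both {seen[p]!r} and {site!r}"
                    )
                seen[p] = site
        excluded = {_normalize(p) for p in self.excluded_site_prefixes}
        overlap = excluded & set(seen)
        if overlap:
            raise ConfigurationError(
                f"prefixes both included and excluded: {sorted(overlap)}"
            )

    @property
    def _prefix_table(self) -> dict[str, Optional[str]]:
        table: dict[str, Optional[str]] = {}
        for site, prefixes in self.site_prefixes.items():
            for p in prefixes:
                table[_normalize(p)] = site
        for p in self.excluded_site_prefixes:
            table[_normalize(p)] = None
        return table

    def match_site(self, code: str) -> Optional[str]:
        """Classify one diagnosis code by longest matching prefix.

        Returns the site class, or None when the code matches no prefix
        or matches an excluded-site prefix.
        """
        code = _normalize(code)
        best, best_len = None, -1
        for prefix, site in self._prefix_table.items():
            if code.startswith(prefix) and len(prefix) > best_len:
                best, best_len = site, len(prefix)
        return best

    def is_fracture_code(self, code: str) -> bool:
        """True when the code is an includable fracture code."""
        return self.match_site(code) is not None

    def is_severe_trauma(self, codes: Iterable[str]) -> bool:
        return any(
            _normalize(c).startswith(_normalize(p))
            for c in codes
            for p in self.severe_trauma_prefixes
        )

    def has_fracture_intervention(self, interventions: Iterable[str]) -> bool:
        kws = [k.lower() for k in self.fracture_intervention_keywords]
        return any(k in str(iv).lower() for iv in interventions for k in kws)


def classify_site(codes: Iterable[str], code_map: CodeMap) -> Optional[str]:
    """Site class for a set of diagnosis codes on one record.

    Rules: a multiple-fracture code, or two or more distinct includable
    site classes, yield ``multiple``; exactly one includable class yields
    that class; codes matching only excluded sites (or nothing) yield None.
    """
    sites = {s for s in (code_map.match_site(c) for c in codes) if s is not None}
    if "multiple" in sites:
        return "multiple"
    if len(sites) >= 2:
        return "multiple"
    if len(sites) == 1:
        return next(iter(sites))
    return None


def default_code_map() -> CodeMap:
    """CodeMap with documented default prefixes.

    Hip covers femoral neck, pertrochanteric and subtrochanteric codes;
    vertebral covers thoracic and lumbar vertebra fractures (sacrum and
    coccyx are excluded sites); wrist covers the distal forearm; humerus
    the proximal/shaft/distal humerus. ``T02`` marks multiple-site
    fractures. The residual "other" class lists the remaining axial and
    limb fracture prefixes. Severe trauma defaults to transport accidents
    (``V``) and falls from height.
    """
    return CodeMap(
        site_prefixes={
            "hip": ("S720", "S721", "S722"),
            "vertebral": ("S220", "S221", "S320"),
            "wrist": ("S525", "S526"),
            "humerus": ("S422", "S423", "S424"),
            "multiple": ("T02",),
            "other": (
                "S12",  # cervical spine
                "S222", "S223", "S224",  # sternum, ribs
                "S323", "S324", "S325", "S327", "S328",  # pelvis
                "S420", "S421",  # clavicle, scapula
                "S520", "S521", "S522", "S523", "S524",  # proximal forearm
                "S723", "S724", "S727", "S728", "S729",  # femur, non-hip
                "S82",  # lower leg incl. ankle
                "S921", "S922", "S923",  # foot, excluding heel/toes
                "T08", "T10", "T12",  # level-unspecified long bones/spine
            ),
        },
        excluded_site_prefixes=(
            "S02",  # skull and face
            "S62",  # hand including fingers
            "S920",  # heel (calcaneus)
            "S924", "S925",  # toes
            "S321", "S322",  # sacrum, coccyx
        ),
        severe_trauma_prefixes=("V", "W11", "W12", "W13", "W14"),
    )
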