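"""Closed category vocabularies for beach-litter surveys.

Litter items are classified along two independent axes:

* **material** — hard plastics (``HPl``), other plastics (``OPl``),
  synthetic foams such as polystyrene (``Foam``), and non-plastics such
  as glass, metal, paper, wood or textile (``NPl``);
* **source** — the human activity the object most plausibly came from:
  sewage, fishing/aquaculture, household/leisure, or not attributable.

Attached macrofauna are recorded in six coarse taxonomic groups; for
bryozoans and hydrozoans a colony counts as one individual.
"""

from __future__ import annotations

import enum
import logging

logger = logging.getLogger(__name__)


class Material(str, enum.Enum):
    """Litter material category."""

    HPL = "HPl"
    OPL = "OPl"
    FOAM = "Foam"
    NPL = "NPl"

    @classmethod
    def parse(cls, text: str) -> "Material":
        t = text.strip().lower()
        for m in cls:
            if m.value.lower() == t:
                return m
        raise ValueError(f"unknown material code {text!r}; expected one of "
                         f"{[m.value for m in cls]}")


class Source(str, enum.Enum):
    """Likely source of a litter object."""

    SEWAGE = "Sewage"
    FISHING_AQUACULTURE = "FishingAquaculture"
    HOUSEHOLD_LEISURE = "HouseholdLeisure"
    NOT_ATTRIBUTABLE = "NotAttributable"

    @classmethod
    def parse(cls, text: str) -> "Source":
        t = text.strip().lower().replace("/", "").replace("_", "").replace(" ", "")
        aliases = {
            "sewage": cls.SEWAGE,
            "s": cls.SEWAGE,
            "fishingaquaculture": cls.FISHING_AQUACULTURE,
            "f": cls.FISHING_AQUACULTURE,
            "householdleisure": cls.HOUSEHOLD_LEISURE,
            "hhleisure": cls.HOUSEHOLD_LEISURE,
            "hh": cls.HOUSEHOLD_LEISURE,
            "notattributable": cls.NOT_ATTRIBUTABLE,
            "na": cls.NOT_ATTRIBUTABLE,
            "n/a": cls.NOT_ATTRIBUTABLE,
        }
        if t in aliases:
            return aliases[t]
        raise ValueError(f"unknown source code {text!r}")


class Taxon(str, enum.Enum):
    """Rafting macrofauna group.

    Terrestrial hitch-hikers (e.g. land snails picked up on the beach
    itself) are not part of the vocabulary; input readers drop an
    optional ``other`` column with a logged notice.
    """

    GOOSE_BARNACLES = "goose_barnacles"
    ACORN_BARNACLES = "acorn_barnacles"
    BRYO_HYDRO_COLONIES = "bryo_hydro_colonies"
    DECAPODS = "decapods"
    MOLLUSCS = "molluscs"
    POLYCHAETES = "polychaetes"


MATERIALS: tuple[Material, ...] = tuple(Material)
SOURCES: tuple[Source, ...] = tuple(Source)
TAXA: tuple[Taxon, ...] = tuple(Taxon)

#: Default object-type -> source mapping.  Object types are matched
#: case-insensitively after trimming; anything absent maps to
#: NotAttributable.
DEFAULT_SOURCE_MAP: dict[str, Source] = {
    # sewage-related
    "cotton buds": Source.SEWAGE,
    "menstrual hygiene products": Source.SEWAGE,
    "menstrual hygiene packaging": Source.SEWAGE,
    "wet wipes": Source.SEWAGE,
    # fishing / aquaculture
    "buoys": Source.FISHING_AQUACULTURE,
    "netfloats": Source.FISHING_AQUACULTURE,
    "cage nets": Source.FISHING_AQUACULTURE,
    "jerrycans": Source.FISHING_AQUACULTURE,
    "nets": Source.FISHING_AQUACULTURE,
    "ropes": Source.FISHING_AQUACULTURE,
    # household / leisure
    "sandals": Source.HOUSEHOLD_LEISURE,
    "cosmetics container": Source.HOUSEHOLD_LEISURE,
    "shoes": Source.HOUSEHOLD_LEISURE,
    "shoe soles": Source.HOUSEHOLD_LEISURE,
    "cigarette stubs": Source.HOUSEHOLD_LEISURE,
    "lighters": Source.HOUSEHOLD_LEISURE,
    "paper and carton": Source.HOUSEHOLD_LEISURE,
    "textiles": Source.HOUSEHOLD_LEISURE,
    "drinking straws": Source.HOUSEHOLD_LEISURE,
    # not attributable
    "fragments": Source.NOT_ATTRIBUTABLE,
    "unknown objects": Source.NOT_ATTRIBUTABLE,
    "boxes": Source.NOT_ATTRIBUTABLE,
    "bottles": Source.NOT_ATTRIBUTABLE,
    "buckets": Source.NOT_ATTRIBUTABLE,
    "lids": Source.NOT_ATTRIBUTABLE,
    "beverage crates": Source.NOT_ATTRIBUTABLE,
}


def assign_source(object_type: str,
                  mapping: dict[str, Source] | None = None) -> Source:
    """Map an object-type label to its likely source category.

    The lookup is case-insensitive after trimming whitespace.  Object
    types absent from the mapping are, by design, ``NotAttributable``
    (small unidentifiable fragments dominate real surveys); each such
    fallback is logged once per label.
    """
    table = mapping if mapping is not None else DEFAULT_SOURCE_MAP
    key = object_type.strip().lower()
    normalized = {k.strip().lower(): v for k, v in table.items()}
    if key in normalized:
        return normalized[key]
    logger.debug("object type %r not in source mapping; -> NotAttributable",
                 object_type)
    return Source.NOT_ATTRIBUTABLE
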