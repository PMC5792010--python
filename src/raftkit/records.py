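"""Record types for the two field surveys and whole-dataset validation.

A survey campaign produces two independent record streams per beach:

* **quadrat records** — standardized macro-litter counts in two
  four-quadrat transects (3 x 3 m quadrats, 72 m^2 per beach) laid along
  the upper and lower tidelines;
* **fouled items** — anthropogenic objects found anywhere on the beach
  with visible attached macrofauna, each carrying per-taxon counts of
  attached individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .vocab import Material, Taxon

#: Standard quadrat geometry: 3 x 3 m quadrats, 4 per transect, 2 transects.
QUADRAT_AREA_M2 = 9.0
QUADRATS_PER_BEACH = 8

TRANSECTS = ("upper", "lower")


@dataclass(frozen=True)
class BeachInfo:
    """A sampled beach with its geographic position (degrees, negative = W)."""

    beach_id: str
    name: str
    longitude: float
    latitude: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} out of range")
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} out of range")


@dataclass(frozen=True)
class QuadratRecord:
    """Count of one (object type, material) combination in one quadrat."""

    beach_id: str
    transect: str
    quadrat_index: int
    object_type: str
    material: Material
    count: int

    def __post_init__(self) -> None:
        if self.transect not in TRANSECTS:
            raise ValueError(f"transect must be one of {TRANSECTS}, "
                             f"got {self.transect!r}")
        if not 1 <= self.quadrat_index <= 4:
            raise ValueError(f"quadrat_index must be 1..4, got {self.quadrat_index}")
        if self.count < 0:
            raise ValueError(f"negative count {self.count}")


@dataclass(frozen=True)
class FouledItem:
    """A litter object with attached macrofauna (a raft).

    ``attachments`` maps each taxon group to the number of attached
    individuals (colonies count as individuals).  A fouled item has, by
    definition, at least one attached individual.  Colour and surface
    area are optional pass-through metadata.
    """

    item_id: str
    beach_id: str
    object_type: str
    material: Material
    attachments: dict[Taxon, int] = field(default_factory=dict)
    colour: str | None = None
    surface_area_cm2: float | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.attachments.values()):
            raise ValueError(f"item {self.item_id}: negative attachment count")
        if sum(self.attachments.values()) <= 0:
            raise ValueError(f"item {self.item_id}: a fouled item must carry "
                             "at least one attached individual")
        if self.surface_area_cm2 is not None and self.surface_area_cm2 <= 0:
            raise ValueError(f"item {self.item_id}: non-positive surface area")

    @property
    def n_individuals(self) -> int:
        return sum(self.attachments.values())


@dataclass
class SurveyDataset:
    """A full survey: beaches, standardized quadrat counts, fouled items.

    A beach may have fouled items without quadrat records (some beaches
    carry only the whole-area raft inventory).
    """

    beaches: list[BeachInfo]
    quadrat_records: list[QuadratRecord]
    fouled_items: list[FouledItem]
    metadata: str = ""

    def beach_ids(self) -> list[str]:
        return [b.beach_id for b in self.beaches]

    def quadrat_beaches(self) -> list[str]:
        seen: list[str] = []
        for r in self.quadrat_records:
            if r.beach_id not in seen:
                seen.append(r.beach_id)
        return seen

    def fouled_beaches(self) -> list[str]:
        seen: list[str] = []
        for it in self.fouled_items:
            if it.beach_id not in seen:
                seen.append(it.beach_id)
        return seen


def validate_dataset(dataset: SurveyDataset) -> list[str]:
    """Return human-readable integrity findings; never raises on content.

    Checks referential integrity (every record's beach exists), the
    standard 8-quadrats-per-beach design, and duplicate item ids.
    Deviations from the standard quadrat count are warnings, not errors:
    field data are irregular.
    """
    issues: list[str] = []
    known = set(b.beach_id for b in dataset.beaches)
    ids = [b.beach_id for b in dataset.beaches]
    for bid in set(i for i in ids if ids.count(i) > 1):
        issues.append(f"duplicate beach_id {bid!r}")

    for r in dataset.quadrat_records:
        if r.beach_id not in known:
            issues.append(f"quadrat record references unknown beach {r.beach_id!r}")
            known.add(r.beach_id)  # report once
    seen_items: set[str] = set()
    for it in dataset.fouled_items:
        if it.beach_id not in known:
            issues.append(f"fouled item {it.item_id!r} references unknown "
                          f"beach {it.beach_id!r}")
            known.add(it.beach_id)
        if it.item_id in seen_items:
            issues.append(f"duplicate item_id {it.item_id!r}")
        seen_items.add(it.item_id)

    quadrats: dict[str, set[tuple[str, int]]] = {}
    for r in dataset.quadrat_records:
        quadrats.setdefault(r.beach_id, set()).add((r.transect, r.quadrat_index))
    for bid, qs in sorted(quadrats.items()):
        if len(qs) != QUADRATS_PER_BEACH:
            issues.append(f"warning: beach {bid!r} has {len(qs)} distinct "
                          f"quadrats (standard design is {QUADRATS_PER_BEACH})")
    return issues
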