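"""Per-beach and regional descriptive statistics.

Covers the survey summary layer: material and source compositions per
beach, litter abundance per square metre, classification of beaches by
dominant litter material, and the regional attached-biota profile per
material.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import FouledItem, QuadratRecord, QUADRAT_AREA_M2
from .vocab import Material, Source, Taxon, assign_source

logger = logging.getLogger(__name__)

#: Beaches with fewer litter items than this in the standardized area are
#: classified "Mix" regardless of composition (25 items over 72 m^2 is
#: about 0.35 items/m^2).
MIX_ITEM_THRESHOLD = 25

#: Fixed tie-break order for the dominant material.
_DOMINANCE_ORDER = [Material.HPL, Material.OPL, Material.FOAM, Material.NPL]


@dataclass(frozen=True)
class CompositionVector:
    """Per-beach category fractions along one axis (material or source)."""

    beach_id: str
    axis: str  # "material" | "source"
    fractions: dict  # category -> fraction in [0, 1]
    total_items: int

    def __post_init__(self) -> None:
        if self.total_items > 0:
            s = sum(self.fractions.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"fractions sum to {s}, expected 1")

    def as_series(self) -> pd.Series:
        return pd.Series({getattr(k, "value", k): v
                          for k, v in self.fractions.items()},
                         name=self.beach_id)


@dataclass(frozen=True)
class AbundanceSummary:
    """Litter density for one beach and its per-quadrat spread."""

    beach_id: str
    items_per_m2: float
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    n_quadrats: int


def _items_for_beach(records, beach_id):
    out = [r for r in records if r.beach_id == beach_id]
    if not out:
        raise ValueError(f"no records for beach {beach_id!r}")
    return out


def material_composition(records: list[QuadratRecord] | list[FouledItem],
                         beach_id: str) -> CompositionVector:
    """Fraction of items per material category on one beach.

    Works on quadrat records (weighted by their counts) or fouled items
    (each item counts once, regardless of how many individuals it
    carries).
    """
    recs = _items_for_beach(records, beach_id)
    counts = {m: 0 for m in Material}
    for r in recs:
        counts[r.material] += r.count if isinstance(r, QuadratRecord) else 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"beach {beach_id!r} has no items: "
                         "composition undefined")
    return CompositionVector(beach_id, "material",
                             {m: c / total for m, c in counts.items()}, total)


def source_composition(records: list[QuadratRecord] | list[FouledItem],
                       beach_id: str,
                       mapping: dict[str, Source] | None = None
                       ) -> CompositionVector:
    """Fraction of items per source category on one beach."""
    recs = _items_for_beach(records, beach_id)
    counts = {s: 0 for s in Source}
    for r in recs:
        src = assign_source(r.object_type, mapping)
        counts[src] += r.count if isinstance(r, QuadratRecord) else 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"beach {beach_id!r} has no items: "
                         "composition undefined")
    return CompositionVector(beach_id, "source",
                             {s: c / total for s, c in counts.items()}, total)


def abundance_per_area(records: list[QuadratRecord], beach_id: str,
                       quadrat_area_m2: float = QUADRAT_AREA_M2
                       ) -> AbundanceSummary:
    """Litter density (items/m^2) over all sampled quadrats of a beach."""
    recs = _items_for_beach(records, beach_id)
    per_quadrat: dict[tuple[str, int], int] = {}
    for r in recs:
        key = (r.transect, r.quadrat_index)
        per_quadrat[key] = per_quadrat.get(key, 0) + r.count
    dens = np.array(sorted(per_quadrat.values()), dtype=float) / quadrat_area_m2
    total = sum(per_quadrat.values())
    area = len(per_quadrat) * quadrat_area_m2
    q1, med, q3 = np.percentile(dens, [25, 50, 75])
    return AbundanceSummary(
        beach_id=beach_id, items_per_m2=total / area,
        mean=float(dens.mean()), sd=float(dens.std(ddof=1)) if len(dens) > 1 else 0.0,
        median=float(med), q1=float(q1), q3=float(q3),
        min=float(dens.min()), max=float(dens.max()), n_quadrats=len(dens))


def classify_beach(total_items: int,
                   composition: CompositionVector) -> str:
    """Group a beach by its prevalent litter material.

    Beaches with fewer than 25 items in the standardized area are "Mix".
    Otherwise the plurality material decides: hard plastics ->
    ``HPl_dominant``, other plastics -> ``OPl_dominant``; a foam- or
    non-plastic-led composition falls back to ``Mix`` (no such beach
    occurs in the regional data).  Ties break in fixed material order
    with a logged notice.
    """
    if composition.axis != "material":
        raise ValueError("classify_beach needs a material composition")
    if total_items < MIX_ITEM_THRESHOLD:
        return "Mix"
    best = max(_DOMINANCE_ORDER, key=lambda m: composition.fractions.get(m, 0.0))
    top = composition.fractions.get(best, 0.0)
    ties = [m for m in _DOMINANCE_ORDER
            if composition.fractions.get(m, 0.0) == top]
    if len(ties) > 1:
        logger.info("beach %s: dominance tie between %s; keeping %s",
                    composition.beach_id,
                    [m.value for m in ties], best.value)
    if best is Material.HPL:
        return "HPl_dominant"
    if best is Material.OPL:
        return "OPl_dominant"
    return "Mix"


def biota_profile_by_material(fouled_items: list[FouledItem],
                              mode: str = "pooled") -> pd.DataFrame:
    """Regional attached-biota profile: materials x taxa, rows sum to 1.

    ``mode="pooled"`` (default) pools attached individuals over all
    items of a material before normalizing; ``mode="per_item_mean"``
    averages each item's own taxon shares instead.  Materials with no
    items are omitted from the output with a logged notice.
    """
    if mode not in ("pooled", "per_item_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    taxa = [t.value for t in Taxon]
    rows = {}
    for mat in Material:
        items = [it for it in fouled_items if it.material is mat]
        if not items:
            logger.info("no fouled items of material %s; row omitted",
                        mat.value)
            continue
        if mode == "pooled":
            counts = np.array([[it.attachments.get(t, 0) for t in Taxon]
                               for it in items], dtype=float).sum(axis=0)
            rows[mat.value] = counts / counts.sum()
        else:
            shares = np.array([
                [it.attachments.get(t, 0) for t in Taxon] for it in items],
                dtype=float)
            shares = shares / shares.sum(axis=1, keepdims=True)
            rows[mat.value] = shares.mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=taxa)


def summary_table(dataset, mapping: dict[str, Source] | None = None
                  ) -> pd.DataFrame:
    """Per-beach summary mirroring the published survey table layout.

    One row per beach: litter density and material/source percentages
    for the general (quadrat) litter where standardized counts exist,
    raft totals and material/source percentages for the fouled items,
    plus the material-dominance group label (empty when the beach has no
    standardized counts).
    """
    rows = []
    quadrat_beaches = set(r.beach_id for r in dataset.quadrat_records)
    for beach in dataset.beaches:
        bid = beach.beach_id
        row: dict = {"beach_id": bid, "group": ""}
        if bid in quadrat_beaches:
            ab = abundance_per_area(dataset.quadrat_records, bid)
            mc = material_composition(dataset.quadrat_records, bid)
            sc = source_composition(dataset.quadrat_records, bid, mapping)
            row["litter_per_m2"] = ab.items_per_m2
            row["group"] = classify_beach(mc.total_items, mc)
            for m in Material:
                row[f"gen_{m.value}"] = 100 * mc.fractions[m]
            row["gen_SumPl"] = 100 * sum(
                mc.fractions[m] for m in (Material.HPL, Material.OPL,
                                          Material.FOAM))
            for s, tag in zip(Source, ("S", "F", "HH", "NA")):
                row[f"gen_{tag}"] = 100 * sc.fractions[s]
        fouled = [it for it in dataset.fouled_items if it.beach_id == bid]
        if fouled:
            mc = material_composition(fouled, bid)
            sc = source_composition(fouled, bid, mapping)
            row["raft_total"] = len(fouled)
            for m in Material:
                row[f"raft_{m.value}"] = 100 * mc.fractions[m]
            row["raft_SumPl"] = 100 * sum(
                mc.fractions[m] for m in (Material.HPL, Material.OPL,
                                          Material.FOAM))
            for s, tag in zip(Source, ("S", "F", "HH", "NA")):
                row[f"raft_{tag}"] = 100 * sc.fractions[s]
        rows.append(row)
    return pd.DataFrame(rows).set_index("beach_id")
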