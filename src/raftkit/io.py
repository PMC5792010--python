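"""Delimited-text readers and writers for survey data.

All files are UTF-8 delimited text (comma or tab, auto-detected from the
header line) with one header row.  Readers validate category codes
against the closed vocabularies and report the offending row on
rejection.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .records import BeachInfo, FouledItem, QuadratRecord, SurveyDataset
from .vocab import Material, Source, Taxon

logger = logging.getLogger(__name__)

_QUADRAT_COLUMNS = ["beach_id", "transect", "quadrat_index",
                    "object_type", "material", "count"]
_FOULED_META = ["item_id", "beach_id", "object_type", "material"]


def _detect_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str,
                     keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_quadrat_table(path: str | Path) -> list[QuadratRecord]:
    """Read standardized quadrat counts, one row per
    (beach, transect, quadrat, object type, material)."""
    df = _read_table(path, _QUADRAT_COLUMNS)
    records: list[QuadratRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(QuadratRecord(
                beach_id=row.beach_id.strip(),
                transect=row.transect.strip().lower(),
                quadrat_index=int(row.quadrat_index),
                object_type=row.object_type.strip(),
                material=Material.parse(row.material),
                count=int(row.count),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}, row {row_no}: {exc}") from exc
    return records


def write_quadrat_table(records: list[QuadratRecord],
                        path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(
        [(r.beach_id, r.transect, r.quadrat_index, r.object_type,
          r.material.value, r.count) for r in records],
        columns=_QUADRAT_COLUMNS)
    df.to_csv(path, sep=sep, index=False)


def read_fouled_inventory(path: str | Path) -> list[FouledItem]:
    """Read the fouled-item inventory.

    Accepts wide format (one column per taxon group) or long format
    (columns ``taxon`` and ``count``, one row per item-taxon pair; rows
    for the same item are aggregated).  An optional ``other`` column or
    taxon label collects non-rafting fauna (e.g. terrestrial snails) and
    is dropped with a logged notice.  Items whose attachment counts are
    all zero are rejected — a fouled item carries fauna by definition.
    """
    df = _read_table(path, _FOULED_META)
    taxon_cols = {t.value: t for t in Taxon}
    long_format = "taxon" in df.columns and "count" in df.columns

    items: dict[str, dict] = {}
    order: list[str] = []
    for row_no, row in enumerate(df.to_dict("records"), start=2):
        item_id = row["item_id"].strip()
        try:
            material = Material.parse(row["material"])
        except ValueError as exc:
            raise ValueError(f"{path}, row {row_no}: {exc}") from exc
        meta = dict(
            beach_id=row["beach_id"].strip(),
            object_type=row["object_type"].strip(),
            material=material,
            colour=(row.get("colour") or None),
            surface_area_cm2=(float(row["surface_area_cm2"])
                              if row.get("surface_area_cm2") else None),
        )
        if item_id not in items:
            items[item_id] = {"meta": meta, "attachments": {}}
            order.append(item_id)
        elif items[item_id]["meta"]["material"] is not material:
            raise ValueError(
                f"{path}, row {row_no}: item {item_id!r} repeated with "
                f"conflicting material "
                f"({items[item_id]['meta']['material'].value} vs {material.value})")
        att = items[item_id]["attachments"]
        if long_format:
            label = row["taxon"].strip()
            if label.lower() == "other":
                logger.info("%s row %d: dropping non-rafting 'other' taxon "
                            "count for item %s", path, row_no, item_id)
                continue
            if label not in taxon_cols:
                raise ValueError(f"{path}, row {row_no}: unknown taxon "
                                 f"{label!r}")
            taxon = taxon_cols[label]
            att[taxon] = att.get(taxon, 0) + int(row["count"])
        else:
            known = set(taxon_cols) | set(_FOULED_META) | {
                "colour", "surface_area_cm2"}
            unknown = [c for c in df.columns if c not in known and c != "other"]
            if unknown:
                raise ValueError(f"{path}: unknown taxon column(s) {unknown}")
            if "other" in df.columns and row.get("other") not in ("", "0", None):
                logger.info("%s row %d: dropping non-rafting 'other' count "
                            "for item %s", path, row_no, item_id)
            for label, taxon in taxon_cols.items():
                if label in df.columns and row[label] != "":
                    att[taxon] = att.get(taxon, 0) + int(row[label])

    out: list[FouledItem] = []
    for item_id in order:
        entry = items[item_id]
        attachments = {t: c for t, c in entry["attachments"].items() if c > 0}
        try:
            out.append(FouledItem(item_id=item_id, attachments=attachments,
                                  **entry["meta"]))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return out


def write_fouled_inventory(items: list[FouledItem],
                           path: str | Path, sep: str = ",") -> None:
    """Write fouled items in wide format (one column per taxon group)."""
    rows = []
    for it in items:
        row = {"item_id": it.item_id, "beach_id": it.beach_id,
               "object_type": it.object_type, "material": it.material.value,
               "colour": it.colour or "",
               "surface_area_cm2": (it.surface_area_cm2
                                    if it.surface_area_cm2 is not None else "")}
        for t in Taxon:
            row[t.value] = it.attachments.get(t, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_beaches(path: str | Path) -> list[BeachInfo]:
    df = _read_table(path, ["beach_id", "name", "longitude", "latitude"])
    return [BeachInfo(beach_id=r.beach_id.strip(), name=r.name.strip(),
                      longitude=float(r.longitude), latitude=float(r.latitude))
            for r in df.itertuples(index=False)]


def write_beaches(beaches: list[BeachInfo], path: str | Path,
                  sep: str = ",") -> None:
    pd.DataFrame([(b.beach_id, b.name, b.longitude, b.latitude)
                  for b in beaches],
                 columns=["beach_id", "name", "longitude", "latitude"]
                 ).to_csv(path, sep=sep, index=False)


def read_source_map(path: str | Path) -> dict[str, Source]:
    df = _read_table(path, ["object_type", "source"])
    return {r.object_type.strip(): Source.parse(r.source)
            for r in df.itertuples(index=False)}


def write_dataset(dataset: SurveyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a SurveyDataset as the three standard delimited files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"beaches": out / "beaches.csv",
             "quadrats": out / "quadrat_counts.csv",
             "fouled": out / "fouled_items.csv"}
    write_beaches(dataset.beaches, paths["beaches"])
    write_quadrat_table(dataset.quadrat_records, paths["quadrats"])
    write_fouled_inventory(dataset.fouled_items, paths["fouled"])
    return paths


def read_dataset(in_dir: str | Path, metadata: str = "") -> SurveyDataset:
    """Read a SurveyDataset from a directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    return SurveyDataset(
        beaches=read_beaches(in_dir / "beaches.csv"),
        quadrat_records=read_quadrat_table(in_dir / "quadrat_counts.csv"),
        fouled_items=read_fouled_inventory(in_dir / "fouled_items.csv"),
        metadata=metadata,
    )
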