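"""Loaders for the packaged regional survey fixture.

The package ships an item-level reconstruction of a published survey of
15 Cantabrian-coast beaches (standardized quadrat litter counts on 12 of
them, plus a whole-beach inventory of 94 fouled rafting items), together
with the printed per-beach percentage table that the distance-based
inference runs on.  See ``raftkit/data/README.md`` for how the
item-level files were reconstructed from the printed summaries.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from . import io as rio
from .records import SurveyDataset
from .vocab import Material, Source, Taxon

_MATS = [m.value for m in Material]
_SRCS = ["S", "F", "HH", "NA"]

_SRC_LABEL = {"S": Source.SEWAGE, "F": Source.FISHING_AQUACULTURE,
              "HH": Source.HOUSEHOLD_LEISURE, "NA": Source.NOT_ATTRIBUTABLE}


def _data_path(name: str) -> Path:
    return Path(resources.files("raftkit.data") / name)


def generate_paper_fixture() -> SurveyDataset:
    """The packaged survey dataset (deterministic, no randomness)."""
    return SurveyDataset(
        beaches=rio.read_beaches(_data_path("beaches.csv")),
        quadrat_records=rio.read_quadrat_table(_data_path("quadrat_counts.csv")),
        fouled_items=rio.read_fouled_inventory(_data_path("fouled_items.csv")),
        metadata="packaged regional fixture",
    )


def load_source_map() -> dict[str, Source]:
    return rio.read_source_map(_data_path("source_map.csv"))


def load_litter_summary() -> pd.DataFrame:
    """The printed per-beach percentage table, indexed by beach_id.

    Columns ``gen_*`` describe general beach litter from the
    standardized quadrats (NaN for the three beaches without
    standardized counts), ``raft_*`` the fouled items.  Material columns
    include the printed sum-of-plastics (``SumPl``) column, which
    differs from the sum of the material categories by rounding.
    """
    df = pd.read_csv(_data_path("litter_summary.csv"), index_col="beach_id")
    return df


def load_taxon_profiles() -> pd.DataFrame:
    """Regional attached-biota profile: materials x taxa, rows sum to 1."""
    df = pd.read_csv(_data_path("taxon_profiles.csv"), index_col="material")
    df = df[[t.value for t in Taxon]]
    # stored at 6 decimals; renormalize so each row sums to 1 exactly
    return df.div(df.sum(axis=1), axis=0)


def material_table(which: str = "both") -> tuple[pd.DataFrame, list[str]]:
    """Material analysis matrix (percent units) and its group labels.

    Rows are the 12 standardized beaches, first the general-litter
    vectors then the raft vectors; columns HPl, OPl, Foam, NPl plus the
    printed sum-of-plastics column (the published material comparison
    includes it as a fifth variable).
    """
    return _paired_table([f"{{}}_{m}" for m in _MATS] + ["{}_SumPl"],
                         _MATS + ["SumPl"], which)


def source_table(which: str = "both") -> tuple[pd.DataFrame, list[str]]:
    """Source analysis matrix (percent units over S, F, HH, NA) and labels."""
    return _paired_table([f"{{}}_{s}" for s in _SRCS],
                         [_SRC_LABEL[s].value for s in _SRCS], which)


def _paired_table(col_templates: list[str], out_cols: list[str],
                  which: str) -> tuple[pd.DataFrame, list[str]]:
    summary = load_litter_summary()
    std = summary.dropna(subset=["litter_per_m2"])
    frames = []
    labels: list[str] = []
    if which in ("both", "general"):
        gen = std[[t.format("gen") for t in col_templates]].copy()
        gen.columns = out_cols
        gen.index = [f"{b}:general" for b in std.index]
        frames.append(gen)
        labels += ["General"] * len(std)
    if which in ("both", "rafts"):
        raft = std[[t.format("raft") for t in col_templates]].copy()
        raft.columns = out_cols
        raft.index = [f"{b}:rafts" for b in std.index]
        frames.append(raft)
        labels += ["Rafts"] * len(std)
    if not frames:
        raise ValueError(f"which must be 'both', 'general' or 'rafts', "
                         f"got {which!r}")
    return pd.concat(frames).astype(float), labels
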