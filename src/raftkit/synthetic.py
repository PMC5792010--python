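"""Synthetic survey generator with known ground truth.

Emulates the two-survey field design so every downstream stage is
testable against known parameters: per-beach material compositions
drawn from a Dirichlet law, patchy quadrat counts from a
negative-binomial law (Poisson in the zero-overdispersion limit),
object types drawn from per-material source mixes, and fouled items
whose attached individuals are multinomial draws from material-specific
taxon profiles with a zero-truncated total (a fouled item carries at
least one individual by definition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import BeachInfo, FouledItem, QuadratRecord, SurveyDataset
from .vocab import Material, Source, Taxon

_MATS = [m.value for m in Material]
_TAXA = [t.value for t in Taxon]

#: One representative object type per source, used for generated rows.
_SOURCE_OBJECT = {Source.SEWAGE: "Cotton buds",
                  Source.FISHING_AQUACULTURE: "Buoys",
                  Source.HOUSEHOLD_LEISURE: "Shoes",
                  Source.NOT_ATTRIBUTABLE: "Fragments"}

#: Default source mix per material: fragments dominate everywhere, with
#: a sewage component among hard/other plastics and a fishing component
#: among plastics, mirroring the regional survey's source spectrum.
_DEFAULT_SOURCE_MIX = {
    "HPl": (0.15, 0.10, 0.05, 0.70),
    "OPl": (0.15, 0.15, 0.05, 0.65),
    "Foam": (0.00, 0.20, 0.05, 0.75),
    "NPl": (0.05, 0.05, 0.20, 0.70),
}


def _default_profiles() -> pd.DataFrame:
    from .fixtures import load_taxon_profiles
    return load_taxon_profiles()


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate the regional survey.

    ``material_concentration`` holds Dirichlet concentration parameters
    over (HPl, OPl, Foam, NPl): either one vector shared by all beaches
    or one vector per beach group, cycled over beaches.  Moderate
    concentrations around the regional mean composition give realistic
    between-beach heterogeneity.  ``overdispersion`` is the inverse-size
    parameter of the negative-binomial quadrat-count law (variance
    mean + a * mean^2); 0 is the Poisson limit.  ``individuals_per_item``
    is the mean of a zero-truncated Poisson unless
    ``fixed_individuals_per_item`` makes every item carry exactly
    ``round(individuals_per_item)`` individuals.
    """

    n_beaches: int = 12
    quadrats_per_beach: int = 8
    quadrat_area_m2: float = 9.0
    mean_items_per_quadrat: float = 13.0
    overdispersion: float = 1.0
    material_concentration: np.ndarray = field(
        default_factory=lambda: np.array([2.7, 1.4, 0.5, 0.5]))
    source_mix: dict = field(
        default_factory=lambda: dict(_DEFAULT_SOURCE_MIX))
    n_fouled_items_per_beach: int = 8
    individuals_per_item: float = 35.0
    fixed_individuals_per_item: bool = False
    fouling_propensity: np.ndarray = field(
        default_factory=lambda: np.ones(4))
    taxon_profiles: pd.DataFrame = field(default_factory=_default_profiles)
    seed: int = 0

    def validate(self) -> None:
        if self.n_beaches < 1:
            raise ValueError("n_beaches must be positive")
        if self.quadrats_per_beach < 1:
            raise ValueError("quadrats_per_beach must be positive")
        if self.quadrat_area_m2 <= 0:
            raise ValueError("quadrat_area_m2 must be positive")
        if self.mean_items_per_quadrat <= 0:
            raise ValueError("mean_items_per_quadrat must be positive")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        conc = np.atleast_2d(np.asarray(self.material_concentration, float))
        if conc.shape[1] != 4 or (conc < 0).any() or (conc.sum(axis=1) == 0).any():
            raise ValueError("material_concentration needs non-negative "
                             "parameters (positive sum) over the 4 materials")
        if self.n_fouled_items_per_beach < 0:
            raise ValueError("n_fouled_items_per_beach must be >= 0")
        if self.individuals_per_item <= 0:
            raise ValueError("individuals_per_item must be positive")
        prop = np.asarray(self.fouling_propensity, float)
        if prop.shape != (4,) or (prop < 0).any() or prop.sum() == 0:
            raise ValueError("fouling_propensity must be 4 non-negative "
                             "values with positive sum")
        prof = self.taxon_profiles
        if list(prof.columns) != _TAXA:
            raise ValueError("taxon_profiles columns must be the 6 taxon "
                             "groups in canonical order")
        if not np.allclose(prof.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("taxon_profiles rows must sum to 1")


@dataclass
class GroundTruth:
    """The parameters a generated survey was drawn from."""

    material_composition: pd.DataFrame  # beaches x materials
    taxon_profiles: pd.DataFrame        # materials x taxa
    density_per_beach: pd.Series        # expected items / m^2


def _neg_binomial(rng: np.random.Generator, mean: float, a: float,
                  size: int) -> np.ndarray:
    if a == 0:
        return rng.poisson(mean, size)
    r = 1.0 / a
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def _zero_truncated_poisson(rng: np.random.Generator, mean: float,
                            size: int) -> np.ndarray:
    out = rng.poisson(mean, size)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(mean, int(zero.sum()))


def generate_survey(config: SyntheticConfig,
                    seed: int | None = None
                    ) -> tuple[SurveyDataset, GroundTruth]:
    """Draw a survey dataset; identical (config, seed) gives identical data."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    conc = np.atleast_2d(np.asarray(config.material_concentration, float))
    beach_ids = [f"beach_{i + 1:02d}" for i in range(config.n_beaches)]
    beaches = [BeachInfo(bid, bid.replace("_", " ").title(),
                         longitude=-7.0 + 2.5 * i / max(1, config.n_beaches - 1),
                         latitude=43.5)
               for i, bid in enumerate(beach_ids)]

    # Dirichlet via gamma draws; zero concentration = structural zero
    def _dirichlet(alpha: np.ndarray) -> np.ndarray:
        g = np.where(alpha > 0, rng.gamma(np.where(alpha > 0, alpha, 1.0)), 0.0)
        return g / g.sum()

    compositions = np.vstack([
        _dirichlet(conc[i % conc.shape[0]]) for i in range(config.n_beaches)])

    src_mix = {m: np.asarray(config.source_mix[m], float) for m in _MATS}
    for m, probs in src_mix.items():
        if probs.shape != (4,) or (probs < 0).any() or \
                not np.isclose(probs.sum(), 1.0, atol=1e-9):
            raise ValueError(f"source_mix[{m}] must be a distribution over "
                             "the 4 sources")

    quadrat_records: list[QuadratRecord] = []
    transects = [("upper", q) for q in range(1, 5)] + \
                [("lower", q) for q in range(1, 5)]
    for b, bid in enumerate(beach_ids):
        counts = _neg_binomial(rng, config.mean_items_per_quadrat,
                               config.overdispersion,
                               config.quadrats_per_beach)
        for q in range(config.quadrats_per_beach):
            transect, qidx = transects[q % len(transects)]
            mat_counts = rng.multinomial(counts[q], compositions[b])
            emitted = False
            for mi, mat in enumerate(Material):
                if mat_counts[mi] == 0:
                    continue
                by_source = rng.multinomial(mat_counts[mi],
                                            src_mix[mat.value])
                for si, src in enumerate(Source):
                    if by_source[si] == 0:
                        continue
                    quadrat_records.append(QuadratRecord(
                        beach_id=bid, transect=transect, quadrat_index=qidx,
                        object_type=_SOURCE_OBJECT[src], material=mat,
                        count=int(by_source[si])))
                    emitted = True
            if not emitted:  # keep empty quadrats visible in the design
                quadrat_records.append(QuadratRecord(
                    beach_id=bid, transect=transect, quadrat_index=qidx,
                    object_type="Fragments", material=Material.NPL, count=0))

    profiles = config.taxon_profiles.reindex(_MATS)
    propensity = np.asarray(config.fouling_propensity, float)
    fouled: list[FouledItem] = []
    for b, bid in enumerate(beach_ids):
        n_items = config.n_fouled_items_per_beach
        if n_items == 0:
            continue
        weights = compositions[b] * propensity
        weights = weights / weights.sum()
        mats = rng.choice(4, size=n_items, p=weights)
        if config.fixed_individuals_per_item:
            totals = np.full(n_items, max(1, round(config.individuals_per_item)))
        else:
            totals = _zero_truncated_poisson(rng, config.individuals_per_item,
                                             n_items)
        for k in range(n_items):
            mat = list(Material)[mats[k]]
            row = profiles.loc[mat.value].to_numpy()
            att = rng.multinomial(int(totals[k]), row)
            src_idx = rng.choice(4, p=src_mix[mat.value])
            attachments = {t: int(c) for t, c in zip(Taxon, att) if c > 0}
            fouled.append(FouledItem(
                item_id=f"{bid}_it{k + 1:03d}", beach_id=bid,
                object_type=_SOURCE_OBJECT[list(Source)[src_idx]],
                material=mat, attachments=attachments))

    dataset = SurveyDataset(beaches=beaches, quadrat_records=quadrat_records,
                            fouled_items=fouled,
                            metadata=f"synthetic survey (seed={config.seed if seed is None else seed})")
    truth = GroundTruth(
        material_composition=pd.DataFrame(compositions, index=beach_ids,
                                          columns=_MATS),
        taxon_profiles=profiles.copy(),
        density_per_beach=pd.Series(
            config.mean_items_per_quadrat / config.quadrat_area_m2,
            index=beach_ids))
    return dataset, truth
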