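"""Predicting rafting-taxon counts from beach-litter composition.

The predictor combines three ingredients measured independently:

* ``fM(i, x)`` — the frequency of litter material *i* on beach *x*,
  from the standardized general-litter counts;
* ``fT(B, i)`` — the regional frequency of taxon *B* among individuals
  attached to material *i*, pooled over all fouled items in the region;
* ``Nt(x)`` — the total number of rafting individuals found on beach
  *x*.

The expected number of individuals of taxon *B* on beach *x* is

    T_B(x) = sum_i fM(i, x) * fT(B, i) * Nt(x)

i.e. the regional material-specific biota profiles mixed according to
the beach's own litter composition and scaled to the beach's observed
rafting abundance.  When profile rows and ``fM`` are normalized, the
expected counts conserve the total: sum_B T_B(x) = Nt(x).

Validation is by Spearman rank correlation between expected and
observed counts pooled over (beach, taxon) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .records import FouledItem, SurveyDataset
from .summary import biota_profile_by_material, material_composition
from .vocab import Material, Taxon

logger = logging.getLogger(__name__)

_TAXA = [t.value for t in Taxon]
_MATS = [m.value for m in Material]

#: Longitude of Cape Penas (degrees, negative = W); splits the sampled
#: coastline into its western and eastern halves.
CAPE_PENAS_LONGITUDE = -5.85


@dataclass(frozen=True)
class RaftCensus:
    """Observed rafting individuals on one beach, by taxon group."""

    beach_id: str
    observed: dict[Taxon, int]

    @property
    def n_total(self) -> int:
        return sum(self.observed.values())


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman validation of expected against observed counts."""

    rho: float
    p_value: float
    n_pairs: int
    method: str  # "asymptotic_t" | "permutation"
    scope: str = ""


def estimate_taxon_material_profile(
        fouled_items: list[FouledItem],
        exclude_beach: str | None = None,
        mode: str = "pooled") -> pd.DataFrame:
    """Materials x taxa frequency matrix from a fouled-item inventory.

    Pools attached individuals per material over the whole region
    (optionally excluding one beach for leave-one-beach-out validation)
    and row-normalizes.  Materials left with no items are omitted with a
    logged warning; downstream prediction treats their ``fM`` mass as
    contributing zero expected individuals.
    """
    items = [it for it in fouled_items if it.beach_id != exclude_beach] \
        if exclude_beach is not None else list(fouled_items)
    if not items:
        raise ValueError("no fouled items left to estimate a profile from")
    return biota_profile_by_material(items, mode=mode)


def expected_taxa(fM: pd.Series | dict, profile: pd.DataFrame,
                  n_total: float, tol: float = 1e-6) -> pd.Series:
    """Expected individuals per taxon for one beach.

    ``fM`` maps material codes to frequencies (must be non-negative and
    sum to 1 within ``tol``); ``profile`` is a materials x taxa matrix
    with rows summing to 1; ``n_total`` is the beach's total rafting
    individuals.  Materials absent from the profile contribute zero with
    a logged warning.
    """
    fm = pd.Series(fM, dtype=float)
    fm.index = [getattr(i, "value", i) for i in fm.index]
    if (fm < 0).any() or n_total < 0:
        raise ValueError("negative inputs")
    if abs(fm.sum() - 1.0) > tol:
        raise ValueError(f"material frequencies sum to {fm.sum():.6g}, "
                         "expected 1")
    missing = [m for m in fm.index if m not in profile.index and fm[m] > 0]
    if missing:
        logger.warning("materials %s have no biota profile; their litter "
                       "frequency contributes zero expected individuals",
                       missing)
    out = pd.Series(0.0, index=list(profile.columns))
    for mat in profile.index:
        out += fm.get(mat, 0.0) * profile.loc[mat] * n_total
    return out


class RaftCommunityPredictor(BaseEstimator):
    """Estimator mapping litter composition to expected rafting taxa.

    ``fit`` learns the regional taxon-by-material profile from a
    fouled-item inventory; ``predict`` turns per-beach material
    frequencies and rafting totals into expected per-taxon counts.

    Parameters
    ----------
    profile_mode : "pooled" pools individuals over items per material
        (default); "per_item_mean" averages per-item shares.
    exclude_beach : optional beach id excluded when estimating the
        profile (leave-one-beach-out).

    Attributes
    ----------
    profile_ : materials x taxa DataFrame, rows summing to 1.
    n_items_ : number of fouled items the profile was estimated from.
    """

    def __init__(self, profile_mode: str = "pooled",
                 exclude_beach: str | None = None):
        self.profile_mode = profile_mode
        self.exclude_beach = exclude_beach

    def fit(self, fouled_items: list[FouledItem], y=None
            ) -> "RaftCommunityPredictor":
        self.profile_ = estimate_taxon_material_profile(
            fouled_items, exclude_beach=self.exclude_beach,
            mode=self.profile_mode)
        self.n_items_ = len([it for it in fouled_items
                             if it.beach_id != self.exclude_beach])
        return self

    def predict(self, fM: pd.DataFrame, n_total: pd.Series) -> pd.DataFrame:
        """Expected counts for several beaches.

        ``fM``: beaches x materials frequency table (rows sum to 1);
        ``n_total``: per-beach total rafting individuals, same index.
        """
        if not hasattr(self, "profile_"):
            raise ValueError("predictor is not fitted")
        rows = {}
        for bid in fM.index:
            rows[bid] = expected_taxa(fM.loc[bid], self.profile_,
                                      float(n_total.loc[bid]))
        return pd.DataFrame.from_dict(rows, orient="index")


def spearman(x, y, method: str = "asymptotic_t",
             n_permutations: int = 999,
             seed: int | None = None) -> CorrelationResult:
    """Spearman rank correlation with tie-corrected average ranks.

    ``method="asymptotic_t"`` uses the t transform with n-2 degrees of
    freedom; ``method="permutation"`` permutes ``y`` and reports the
    two-sided permutation p-value (observed arrangement included in
    numerator and denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if method == "asymptotic_t":
        p = float(stats.spearmanr(x, y).pvalue)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        obs = abs(rx_c @ ry_c)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if abs(rx_c @ ry_c[perm]) >= obs - 1e-12 * denom:
                count += 1
        p = (1 + count) / (1 + n_permutations)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(rho=rho, p_value=p, n_pairs=n, method=method)


def _block_permutation_spearman(sub: pd.DataFrame, n_permutations: int,
                                seed: int | None) -> CorrelationResult:
    """Two-sided Spearman test permuting whole beaches.

    The pooled (beach, taxon) pairs are not exchangeable one by one:
    observed counts within a beach share the beach's fixed rafting
    total.  Beaches, however, are the independent survey units, so
    permuting each beach's intact observed taxon vector against the
    expected table gives an exactly valid null distribution.
    """
    from scipy import stats as _stats

    x = sub.expected.to_numpy()
    y = sub.observed.to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    blocks = sub.beach_id.to_numpy()
    beach_order = pd.unique(blocks)
    idx_by_beach = [np.where(blocks == b)[0] for b in beach_order]
    sizes = {len(i) for i in idx_by_beach}
    if len(sizes) != 1:
        raise ValueError("block permutation needs the same number of "
                         "taxa per beach")

    rx = _stats.rankdata(x)
    obs = abs(np.corrcoef(rx, _stats.rankdata(y))[0, 1])
    rho = float(np.corrcoef(rx, _stats.rankdata(y))[0, 1])
    rng = np.random.default_rng(seed)
    y_blocks = np.vstack([y[i] for i in idx_by_beach])
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(beach_order))
        y_perm = y_blocks[perm].ravel()
        if abs(np.corrcoef(rx, _stats.rankdata(y_perm))[0, 1]) >= obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return CorrelationResult(rho=rho, p_value=p, n_pairs=len(x),
                             method="block_permutation")


def census_by_beach(fouled_items: list[FouledItem]) -> dict[str, RaftCensus]:
    """Observed per-taxon rafting counts per beach."""
    per_beach: dict[str, dict[Taxon, int]] = {}
    for it in fouled_items:
        obs = per_beach.setdefault(it.beach_id, {t: 0 for t in Taxon})
        for t, c in it.attachments.items():
            obs[t] += c
    return {bid: RaftCensus(bid, obs) for bid, obs in per_beach.items()}


def scopes_by_longitude(dataset: SurveyDataset,
                        beach_ids: list[str],
                        cape_longitude: float = CAPE_PENAS_LONGITUDE
                        ) -> dict[str, list[str]]:
    """Whole-area / west / east beach scopes split at Cape Penas."""
    lon = {b.beach_id: b.longitude for b in dataset.beaches}
    west = [b for b in beach_ids if lon[b] < cape_longitude]
    east = [b for b in beach_ids if lon[b] >= cape_longitude]
    return {"all": list(beach_ids), "west": west, "east": east}


def evaluate_prediction(dataset: SurveyDataset,
                        profile_mode: str = "pooled",
                        scopes: dict[str, list[str]] | None = None,
                        leave_one_out: bool = False,
                        drop_double_zeros: bool = False,
                        value_mode: str = "counts",
                        p_method: str = "asymptotic_t",
                        n_permutations: int = 999,
                        seed: int | None = None,
                        reference_profile: pd.DataFrame | None = None,
                        ) -> tuple[list[CorrelationResult], pd.DataFrame]:
    """Expected-vs-observed validation of the compositional predictor.

    For every beach with both standardized quadrat counts (for the
    material frequencies) and fouled items (for the census), computes
    the expected per-taxon counts and correlates them with the observed
    counts, pooling (beach, taxon) pairs within each scope.  Returns the
    per-scope correlation results and the full expected/observed table
    (columns beach_id, taxon, expected, observed).

    ``value_mode="shares"`` correlates within-beach frequencies instead
    of counts (divides both sides by the beach total), removing the
    shared abundance scale.

    ``p_method`` is "asymptotic_t" (default; conventional reporting),
    "permutation" (pairwise label permutation of the pooled pairs), or
    "block_permutation" (permutes whole beaches; exactly valid for the
    pooled design, whose within-beach totals make individual pairs
    non-exchangeable).

    By default the taxon-by-material profile is estimated from the
    dataset's own fouled items (region-wide, or leave-one-beach-out with
    ``leave_one_out=True``).  ``reference_profile`` predicts from an
    externally supplied materials x taxa matrix instead; because such a
    profile is independent of every observed attachment, this mode is
    the basis of honest null calibration (in-sample and even
    leave-one-beach-out estimation leak the other beaches' observations
    into the expected values of the pooled correlation).
    """
    if value_mode not in ("counts", "shares"):
        raise ValueError(f"unknown value_mode {value_mode!r}")
    censuses = census_by_beach(dataset.fouled_items)
    eligible = [b for b in dataset.quadrat_beaches() if b in censuses]
    if scopes is None:
        scopes = {"all": eligible}

    rows = []
    for bid in eligible:
        fm = material_composition(dataset.quadrat_records, bid)
        census = censuses[bid]
        if reference_profile is not None:
            profile = reference_profile
        elif leave_one_out:
            profile = estimate_taxon_material_profile(
                dataset.fouled_items, exclude_beach=bid, mode=profile_mode)
        else:
            profile = estimate_taxon_material_profile(
                dataset.fouled_items, mode=profile_mode)
        exp = expected_taxa(fm.as_series(), profile, census.n_total)
        for t in Taxon:
            e = float(exp.get(t.value, 0.0))
            o = float(census.observed.get(t, 0))
            if value_mode == "shares" and census.n_total > 0:
                e /= census.n_total
                o /= census.n_total
            rows.append({"beach_id": bid, "taxon": t.value,
                         "expected": e, "observed": o})
    table = pd.DataFrame(rows)

    results: list[CorrelationResult] = []
    for name, beach_list in scopes.items():
        unknown = [b for b in beach_list if b not in eligible]
        if unknown:
            raise ValueError(f"scope {name!r}: beaches {unknown} lack "
                             "quadrat records or fouled items")
        sub = table[table.beach_id.isin(beach_list)]
        if drop_double_zeros:
            sub = sub[(sub.expected > 0) | (sub.observed > 0)]
        if len(sub) < 3:
            raise ValueError(f"scope {name!r}: fewer than 3 pooled pairs")
        if p_method == "block_permutation":
            res = _block_permutation_spearman(sub, n_permutations, seed)
        else:
            res = spearman(sub.expected.to_numpy(), sub.observed.to_numpy(),
                           method=p_method, n_permutations=n_permutations,
                           seed=seed)
        results.append(CorrelationResult(rho=res.rho, p_value=res.p_value,
                                         n_pairs=res.n_pairs,
                                         method=res.method, scope=name))
    return results, table


def recovery_experiment(config, n_replicates: int, seed: int | None = None,
                        leave_one_out: bool = False,
                        value_mode: str = "counts",
                        p_method: str = "asymptotic_t",
                        n_permutations: int = 199,
                        reference_profile: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Parameter-recovery simulation for the compositional predictor.

    Per replicate: generate a synthetic survey from ``config``, estimate
    the taxon-by-material profile from the generated fouled items,
    predict expected counts, and correlate them with the observed
    counts.  Returns one row per replicate with the Spearman rho, its
    p-value, and the maximum absolute error of the estimated profile
    against the generator's ground truth.  Deterministic given
    ``seed`` (replicate seeds are spawned from it).

    ``reference_profile`` predicts from a fixed external profile instead
    of the per-replicate estimate; combined with a generator whose
    materials share one common taxon profile this yields a genuine
    zero-signal configuration for null calibration of the correlation
    test.
    """
    from .synthetic import generate_survey

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(n_replicates)]
    rows = []
    for rep, rep_seed in enumerate(child_seeds):
        dataset, truth = generate_survey(config, seed=rep_seed)
        results, _ = evaluate_prediction(
            dataset, leave_one_out=leave_one_out, value_mode=value_mode,
            p_method=p_method, n_permutations=n_permutations, seed=rep_seed,
            reference_profile=reference_profile)
        profile = estimate_taxon_material_profile(dataset.fouled_items)
        err = (profile.reindex(index=truth.taxon_profiles.index,
                               columns=truth.taxon_profiles.columns)
               - truth.taxon_profiles).abs().max().max()
        rows.append({"replicate": rep, "seed": rep_seed,
                     "rho": results[0].rho, "p_value": results[0].p_value,
                     "n_pairs": results[0].n_pairs,
                     "profile_max_abs_error": float(err)})
    return pd.DataFrame(rows)
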