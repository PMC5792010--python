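"""Distance-based multivariate inference: Bray-Curtis, PERMANOVA, SIMPER.

One-way PERMANOVA partitions the sum of squared inter-sample
dissimilarities into between- and within-group components:

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    pseudo-F  = (SS_between / df_between) / (SS_within / df_within)

with significance from unrestricted permutation of the sample labels.
SIMPER decomposes the average between-group Bray-Curtis dissimilarity
into additive per-variable contributions.

Sample matrices are pandas DataFrames (rows = samples, columns =
variables); community tables here are typically percentage compositions
on a 0-100 scale, in which case Bray-Curtis dissimilarities are also on
a 0-100 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if d.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = d

    @property
    def shape(self):
        return self.values.shape

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


def _as_matrix(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(i) for i in X.index]
    arr = np.asarray(X, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def bray_curtis_matrix(X: pd.DataFrame | np.ndarray,
                       scale: float = 100.0) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities.

    d(i, j) = scale * sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk).
    With ``scale=100`` dissimilarities are percentages.
    """
    arr, ids = _as_matrix(X)
    if (arr < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    zero_rows = np.where(arr.sum(axis=1) == 0)[0]
    if zero_rows.size:
        raise ValueError("all-zero sample row(s): "
                         f"{[ids[i] for i in zero_rows]} "
                         "(Bray-Curtis undefined)")
    d = squareform(pdist(arr, metric="braycurtis")) * scale
    return DistanceMatrix(ids, d)


def euclidean_matrix(X: pd.DataFrame | np.ndarray) -> DistanceMatrix:
    """Pairwise Euclidean (L2) distances."""
    arr, ids = _as_matrix(X)
    return DistanceMatrix(ids, squareform(pdist(arr, metric="euclidean")))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    df_between: int
    df_within: int
    df_total: int
    ss_between: float
    ss_within: float
    ss_total: float
    ms_between: float
    ms_within: float
    pseudo_F: float
    p_perm: float
    n_permutations: int
    n_unique_perms: int
    seed: int | None

    def as_series(self) -> pd.Series:
        return pd.Series({f: getattr(self, f) for f in (
            "df_between", "df_within", "df_total", "ss_between", "ss_within",
            "ss_total", "ms_between", "ms_within", "pseudo_F", "p_perm",
            "n_permutations", "n_unique_perms")})


def _group_indices(labels: list) -> list[np.ndarray]:
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    return [np.where(labels == g)[0] for g in groups]


def _ss_partition(d2: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float]:
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        sub = d2[np.ix_(g, g)]
        ss_within += sub[np.triu_indices(len(g), 1)].sum() / len(g)
    return ss_total, ss_within


def permanova(D: DistanceMatrix, labels: list,
              n_permutations: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    The permutation p-value counts the observed statistic in both the
    numerator and the denominator:
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    ``n_unique_perms`` reports the number of distinct label arrangements
    encountered (informational; not used in p).
    """
    labels = list(labels)
    if len(labels) != D.shape[0]:
        raise ValueError("one label per sample required")
    groups = _group_indices(labels)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    n = D.shape[0]
    d2 = D.values ** 2
    df_between = len(groups) - 1
    df_total = n - 1
    df_within = df_total - df_between

    ss_total, ss_within = _ss_partition(d2, groups)
    ss_between = ss_total - ss_within
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f_obs = ms_between / ms_within

    label_codes = np.asarray(pd.factorize(np.asarray(labels))[0])
    rng = np.random.default_rng(seed)
    count_ge = 0
    seen: set[bytes] = {label_codes.tobytes()}
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        permuted = label_codes[perm]
        seen.add(permuted.tobytes())
        pg = [np.where(permuted == k)[0] for k in range(len(groups))]
        sst_p, ssw_p = _ss_partition(d2, pg)
        ssb_p = sst_p - ssw_p
        f_perm = (ssb_p / df_between) / (ssw_p / df_within)
        if f_perm >= f_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return PermanovaResult(
        df_between=df_between, df_within=df_within, df_total=df_total,
        ss_between=ss_between, ss_within=ss_within, ss_total=ss_total,
        ms_between=ms_between, ms_within=ms_within, pseudo_F=f_obs,
        p_perm=p, n_permutations=n_permutations,
        n_unique_perms=len(seen), seed=seed)


def permanova_exact(D: DistanceMatrix, labels: list) -> float:
    """Exact permutation p-value by full enumeration of label arrangements.

    Feasible for small n only; intended as an oracle for the sampled
    permutation test.
    """
    from itertools import permutations

    labels = np.asarray(pd.factorize(np.asarray(labels))[0])
    n = D.shape[0]
    d2 = D.values ** 2
    groups = [np.where(labels == k)[0] for k in range(labels.max() + 1)]
    df_between = len(groups) - 1
    df_within = n - 1 - df_between

    def f_stat(lab):
        gs = [np.where(lab == k)[0] for k in range(labels.max() + 1)]
        sst, ssw = _ss_partition(d2, gs)
        return ((sst - ssw) / df_between) / (ssw / df_within)

    f_obs = f_stat(labels)
    seen: set[bytes] = set()
    count_ge = 0
    total = 0
    for perm in permutations(range(n)):
        lab = labels[list(perm)]
        key = lab.tobytes()
        if key in seen:
            continue
        seen.add(key)
        total += 1
        if f_stat(lab) >= f_obs - 1e-12:
            count_ge += 1
    return count_ge / total


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

@dataclass
class SimperResult:
    """Per-variable decomposition of average between-group dissimilarity.

    ``table`` has one row per variable, sorted by descending
    contribution, with columns ``mean_<group>`` (raw group means),
    ``avg_contribution``, ``sd_contribution``, ``diss_sd_ratio`` (NaN
    when the SD is zero), ``percent`` and ``cumulative_percent``.
    """

    overall_avg_dissimilarity: float
    group_names: tuple[str, str]
    table: pd.DataFrame = field(repr=False)


def simper(X: pd.DataFrame, labels: list, scale: float = 100.0) -> SimperResult:
    """Similarity-percentage decomposition for exactly two groups.

    For each between-group pair (i, j), variable k contributes
    ``scale * |x_ik - x_jk| / sum_m (x_im + x_jm)``; contributions are
    averaged over all between-group pairs and sum, by construction, to
    the average between-group Bray-Curtis dissimilarity.
    """
    arr, _ = _as_matrix(X)
    if (arr < 0).any():
        raise ValueError("SIMPER requires non-negative values")
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"SIMPER compares exactly 2 groups, got {len(groups)}")
    a_idx = np.where(labels == groups[0])[0]
    b_idx = np.where(labels == groups[1])[0]

    xa = arr[a_idx]          # (na, p)
    xb = arr[b_idx]          # (nb, p)
    diff = np.abs(xa[:, None, :] - xb[None, :, :])      # (na, nb, p)
    denom = (xa[:, None, :] + xb[None, :, :]).sum(axis=2)  # (na, nb)
    if (denom == 0).any():
        raise ValueError("pair of all-zero samples: dissimilarity undefined")
    contrib = scale * diff / denom[:, :, None]
    contrib = contrib.reshape(-1, arr.shape[1])          # pairs x variables

    avg = contrib.mean(axis=0)
    sd = contrib.std(axis=0, ddof=1) if contrib.shape[0] > 1 else \
        np.zeros(arr.shape[1])
    overall = float(avg.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd > 0, avg / sd, np.nan)
    percent = 100 * avg / overall if overall > 0 else np.zeros_like(avg)

    cols = (list(X.columns) if isinstance(X, pd.DataFrame)
            else [f"v{k}" for k in range(arr.shape[1])])
    table = pd.DataFrame({
        f"mean_{groups[0]}": xa.mean(axis=0),
        f"mean_{groups[1]}": xb.mean(axis=0),
        "avg_contribution": avg,
        "sd_contribution": sd,
        "diss_sd_ratio": ratio,
        "percent": percent,
    }, index=cols).sort_values("avg_contribution", ascending=False)
    table["cumulative_percent"] = table["percent"].cumsum()
    return SimperResult(overall_avg_dissimilarity=overall,
                        group_names=(str(groups[0]), str(groups[1])),
                        table=table)
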