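"""Non-metric multidimensional scaling on a dissimilarity matrix.

Kruskal-style NMDS: alternate a monotone (isotonic) regression of the
configuration distances on the dissimilarity ranks with Guttman-
transform updates of the configuration (SMACOF), minimizing raw stress;
quality is reported as Kruskal stress-1

    stress_1 = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 )

where d are configuration distances and dhat the fitted disparities.
Ties in the dissimilarities follow the primary approach: tied input
values may receive unequal fitted distances.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .inference import DistanceMatrix


class NMDS(BaseEstimator):
    """Non-metric MDS estimator with multiple random starts.

    Parameters
    ----------
    n_components : embedding dimensionality (default 2).
    n_starts : number of random initial configurations; the solution
        with the lowest final stress is kept.
    max_iter : maximum SMACOF iterations per start.
    tol : relative raw-stress decrease below which a start stops.
    random_state : seed for the random initial configurations.

    Attributes (after :meth:`fit`)
    ------------------------------
    embedding_ : (n_samples, n_components) coordinates, centred at the
        origin.
    stress_ : final Kruskal stress-1 of the best start.
    stress_history_ : per-iteration raw stress of the best start
        (non-increasing).
    n_iter_ : iterations used by the best start.
    converged_ : whether the best start met ``tol`` before ``max_iter``.
    """

    def __init__(self, n_components: int = 2, n_starts: int = 8,
                 max_iter: int = 300, tol: float = 1e-7,
                 random_state: int | None = None):
        self.n_components = n_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, D: DistanceMatrix | np.ndarray, y=None) -> "NMDS":
        d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
        if not np.isfinite(d).all():
            raise ValueError("non-finite dissimilarities")
        n = d.shape[0]
        if n < self.n_components + 1:
            raise ValueError(f"need at least {self.n_components + 1} samples "
                             f"for a {self.n_components}-dimensional embedding")
        diss = squareform(d, checks=False)
        order = np.argsort(diss, kind="stable")
        rng = np.random.default_rng(self.random_state)

        best = None
        for _ in range(max(1, self.n_starts)):
            X0 = rng.standard_normal((n, self.n_components))
            result = self._single(diss, order, X0, n)
            if best is None or result[1] < best[1]:
                best = result
        X, stress1, history, n_iter, converged = best
        self.embedding_ = X - X.mean(axis=0)
        self.stress_ = stress1
        self.stress_history_ = history
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        return self.fit(D).embedding_

    def _single(self, diss, order, X, n):
        iso = IsotonicRegression()
        ranks = np.arange(len(diss), dtype=float)
        iu = np.triu_indices(n, 1)
        history = []
        prev_raw = np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            dist = pdist(X)
            # monotone regression of distances on dissimilarity ranks
            disp = np.empty_like(dist)
            disp[order] = iso.fit_transform(ranks, dist[order])
            # fixed-norm disparities keep the majorization monotone
            ssd = (disp ** 2).sum()
            if ssd <= 0:
                break
            disp *= np.sqrt(len(disp) / ssd)
            raw = ((dist - disp) ** 2).sum()
            if np.isfinite(prev_raw) and \
                    prev_raw - raw <= self.tol * max(prev_raw, 1e-30):
                converged = True
                if raw < prev_raw:
                    history.append(raw)
                break
            history.append(raw)
            prev_raw = raw
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, disp / dist, 0.0)
            B = np.zeros((n, n))
            B[iu] = -ratio
            B = B + B.T
            np.fill_diagonal(B, -B.sum(axis=1))
            X = B @ X / n
        dist = pdist(X)
        disp = np.empty_like(dist)
        disp[order] = iso.fit_transform(ranks, dist[order])
        denom = (dist ** 2).sum()
        stress1 = float(np.sqrt(((dist - disp) ** 2).sum() / denom)) \
            if denom > 0 else 0.0
        return X, stress1, np.asarray(history), it, converged


def nmds(D: DistanceMatrix, n_dims: int = 2, n_starts: int = 8,
         max_iter: int = 300, tol: float = 1e-7,
         seed: int | None = None) -> NMDS:
    """Functional wrapper over the :class:`NMDS` estimator."""
    return NMDS(n_components=n_dims, n_starts=n_starts, max_iter=max_iter,
                tol=tol, random_state=seed).fit(D)
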