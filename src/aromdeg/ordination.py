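"""Bray-Curtis dissimilarity and two-dimensional nonmetric MDS.

NMDS minimizes Kruskal stress-1 by alternating an isotonic (monotone)
regression of the embedded distances on the rank order of the input
dissimilarities with a SMACOF (majorization) update of the configuration.
The first restart starts from classical metric scaling of the dissimilarity
matrix; further restarts are random and the lowest-stress solution is kept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .profiles import AbundanceMatrix

__all__ = ["bray_curtis", "nmds", "NMDS"]


def bray_curtis(m: AbundanceMatrix | pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (columns).

    d(u, v) = sum|u_i - v_i| / sum(u_i + v_i); a pair of all-zero samples has
    distance 0 by convention.
    """
    if isinstance(m, AbundanceMatrix):
        data, samples = m.values, m.samples
    elif isinstance(m, pd.DataFrame):
        data, samples = m.to_numpy(dtype=float), m.columns
    else:
        data = np.asarray(m, dtype=float)
        samples = pd.RangeIndex(data.shape[1])
    if data.shape[1] < 2:
        raise ValueError("need at least two samples")
    if (data < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    x = data.T  # samples in rows
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=samples, columns=samples)


class NMDS(BaseEstimator):
    """Nonmetric multidimensional scaling with multiple seeded restarts.

    Parameters
    ----------
    n_components : embedding dimensionality (default 2).
    n_restarts : configurations tried; the best (lowest stress) is returned.
        Restart 1 is classical metric scaling of the input, the rest random.
    max_iter, tol : per-restart SMACOF iteration cap and relative stress
        convergence threshold.
    random_state : seed for the random restarts.

    Attributes
    ----------
    embedding_ : (n_samples, n_components) coordinates of the best restart.
    stress_ : Kruskal stress-1 of the best restart.
    stress_trace_ : stress-1 after each iteration of the best restart.
    """

    def __init__(self, n_components=2, n_restarts=8, max_iter=300, tol=1e-6, random_state=None):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, D, y=None):
        D = self._check_distances(D)
        n = D.shape[0]
        if self.n_components >= n:
            raise ValueError("n_components must be smaller than the number of samples")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        rng = np.random.default_rng(self.random_state)
        best = None
        for r in range(self.n_restarts):
            if r == 0:
                X0 = self._classical_mds(D)
            else:
                X0 = rng.standard_normal((n, self.n_components))
            X, stress, trace = self._smacof(D, X0)
            if best is None or stress < best[1]:
                best = (X, stress, trace)
        self.embedding_, self.stress_, self.stress_trace_ = best
        return self

    def fit_transform(self, D, y=None):
        return self.fit(D).embedding_

    @staticmethod
    def stress1(D, X) -> float:
        """Kruskal stress-1 of a configuration X for dissimilarities D."""
        D = NMDS._check_distances(D)
        n = D.shape[0]
        iu = np.triu_indices(n, k=1)
        d = D[iu]
        e = pdist(np.asarray(X, dtype=float))
        order = np.argsort(d, kind="stable")
        iso = IsotonicRegression(increasing=True)
        dhat = np.empty_like(e)
        dhat[order] = iso.fit_transform(np.arange(len(e)), e[order])
        denom = (e**2).sum()
        return float(np.sqrt(((dhat - e) ** 2).sum() / denom)) if denom > 0 else 0.0

    @staticmethod
    def _check_distances(D) -> np.ndarray:
        if isinstance(D, pd.DataFrame):
            D = D.to_numpy(dtype=float)
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        return D

    def _classical_mds(self, D: np.ndarray) -> np.ndarray:
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1][: self.n_components]
        lam = np.clip(vals[order], 0, None)
        return vecs[:, order] * np.sqrt(lam)[np.newaxis, :]

    def _smacof(self, D: np.ndarray, X: np.ndarray):
        n = D.shape[0]
        iu = np.triu_indices(n, k=1)
        d = D[iu]
        order = np.argsort(d, kind="stable")
        iso = IsotonicRegression(increasing=True)
        X = X.copy()
        trace = []
        prev = np.inf
        for _ in range(self.max_iter):
            e = pdist(X)
            # monotone fit of embedded distances to the dissimilarity ranks
            dhat = np.empty_like(e)
            dhat[order] = iso.fit_transform(np.arange(len(e)), e[order])
            denom = (e**2).sum()
            stress = np.sqrt(((dhat - e) ** 2).sum() / denom) if denom > 0 else 0.0
            if stress > prev + 1e-12:
                # guarded step: never accept a configuration that worsens
                # stress-1 (possible because the normalizer sum(e^2) moves)
                X = X_prev
                break
            trace.append(stress)
            if prev - stress < self.tol * max(prev, 1e-12) and np.isfinite(prev):
                break
            prev = stress
            X_prev = X
            # Guttman transform toward the disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(e > 0, dhat / e, 0.0)
            B = squareform(-ratio)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = (B @ X) / n
        return X, float(trace[-1]), np.asarray(trace)


def nmds(
    D,
    dims: int = 2,
    restarts: int = 8,
    max_iter: int = 300,
    seed: int | None = None,
):
    """Best-of-restarts NMDS; returns (coordinates, stress)."""
    model = NMDS(
        n_components=dims, n_restarts=restarts, max_iter=max_iter, random_state=seed
    ).fit(D)
    coords = model.embedding_
    if isinstance(D, pd.DataFrame):
        coords = pd.DataFrame(
            coords, index=D.index, columns=[f"axis{i+1}" for i in range(dims)]
        )
    return coords, model.stress_
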