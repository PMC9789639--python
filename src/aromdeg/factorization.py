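"""Non-smooth NMF of annotation x sample matrices with consensus rank selection.

The abundance matrix V (annotations x samples) is decomposed as
V ~ W S H, where W is the basis matrix (weight of each annotation on each
component, i.e. sub-metagenome / sub-metatranscriptome), H the coefficient
matrix (component profile across samples) and S a smoothing matrix

    S = (1 - theta) I + (theta / q) * 11'

whose parameter theta in [0, 1] trades approximation accuracy for sparser,
part-like factors (theta = 0 recovers plain multiplicative-update NMF).

Rank selection follows the consensus-clustering convention: many seeded runs
per candidate rank, each sample hard-assigned to its maximal coefficient;
the consensus matrix holds the fraction of runs in which two samples land in
the same component, and the rank maximizing the cophenetic correlation of
the consensus matrix is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .profiles import AbundanceMatrix

__all__ = [
    "NSNMF",
    "FactorizationResult",
    "RankDiagnostics",
    "nsnmf_factorize",
    "multirun_consensus",
    "rank_survey",
    "select_rank",
    "label_components",
]

_EPS = np.finfo(float).tiny


def _as_array(V) -> tuple[np.ndarray, pd.Index | None, pd.Index | None]:
    if isinstance(V, AbundanceMatrix):
        return V.values, V.annotations, V.samples
    if isinstance(V, pd.DataFrame):
        return V.to_numpy(dtype=float), V.index, V.columns
    arr = np.asarray(V, dtype=float)
    return arr, None, None


def smoothing_matrix(rank: int, theta: float) -> np.ndarray:
    return (1.0 - theta) * np.eye(rank) + (theta / rank) * np.ones((rank, rank))


class NSNMF(BaseEstimator, TransformerMixin):
    """Non-smooth non-negative matrix factorization (multiplicative updates).

    Fit on X of shape (n_annotations, n_samples); after fitting,
    ``basis_`` is W (n_annotations x rank), ``components_`` is H
    (rank x n_samples) and ``reconstruction_err_`` the squared Frobenius
    residual ||X - W S H||^2 (the rss of the run).

    Updates alternate the standard Lee-Seung multiplicative rules with the
    smoothing matrix absorbed into the fixed factor: H is updated against
    W S, then W against S H, which keeps the squared-error objective
    non-increasing at every step.
    """

    def __init__(self, n_components=4, theta=0.5, max_iter=2000, tol=1e-5, random_state=None):
        self.n_components = n_components
        self.theta = theta
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None):
        V, rows, cols = _as_array(X)
        if (V < 0).any():
            raise ValueError("NMF input must be non-negative")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must lie in [0, 1], got {self.theta}")
        q = int(self.n_components)
        if q >= min(V.shape):
            raise ValueError(
                f"rank {q} must be smaller than both matrix dimensions {V.shape}"
            )
        if q < 1:
            raise ValueError("rank must be >= 1")
        rng = np.random.default_rng(self.random_state)
        n, m = V.shape
        W = rng.uniform(size=(n, q))
        # H starts flat and becomes data-driven at the first update; keeping
        # the randomness in W alone makes every run equivariant under sample
        # (column) permutations of V
        H = np.ones((q, m))
        S = smoothing_matrix(q, self.theta)
        prev = None
        n_iter = 0
        converged = False
        trace = []
        for n_iter in range(1, self.max_iter + 1):
            WS = W @ S
            H *= (WS.T @ V) / (WS.T @ WS @ H + _EPS)
            SH = S @ H
            W *= (V @ SH.T) / (W @ (SH @ SH.T) + _EPS)
            obj = np.linalg.norm(V - W @ S @ H) ** 2
            trace.append(obj)
            if prev is not None and abs(prev - obj) <= self.tol * max(prev, _EPS):
                converged = True
                prev = obj
                break
            prev = obj
        self.basis_ = W
        self.components_ = H
        self.smoothing_ = S
        self.reconstruction_err_ = float(prev)
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.row_index_ = rows
        self.col_index_ = cols
        return W

    def inverse_transform(self, W=None):
        W = self.basis_ if W is None else W
        return W @ self.smoothing_ @ self.components_


@dataclass
class FactorizationResult:
    """One nsNMF run: basis W, coefficients H, and fit statistics."""

    W: pd.DataFrame
    H: pd.DataFrame
    theta: float
    rank: int
    seed: int | None
    rss: float
    n_iter: int
    converged: bool

    @property
    def components(self) -> list[str]:
        return list(self.H.index)

    def reconstruction(self) -> pd.DataFrame:
        S = smoothing_matrix(self.rank, self.theta)
        return pd.DataFrame(
            self.W.to_numpy() @ S @ self.H.to_numpy(),
            index=self.W.index,
            columns=self.H.columns,
        )

    def sample_assignments(self) -> pd.Series:
        """Hard assignment of each sample to its maximal-coefficient component."""
        return self.H.idxmax(axis=0)


def nsnmf_factorize(
    V,
    rank: int,
    theta: float = 0.5,
    seed: int | None = None,
    max_iter: int = 2000,
    tol: float = 1e-5,
) -> FactorizationResult:
    """Single seeded nsNMF run on an annotation x sample matrix."""
    model = NSNMF(
        n_components=rank, theta=theta, max_iter=max_iter, tol=tol, random_state=seed
    )
    model.fit(V)
    _, rows, cols = _as_array(V)
    comp = [f"component_{k+1}" for k in range(rank)]
    rows = rows if rows is not None else pd.RangeIndex(model.basis_.shape[0])
    cols = cols if cols is not None else pd.RangeIndex(model.components_.shape[1])
    return FactorizationResult(
        W=pd.DataFrame(model.basis_, index=rows, columns=comp),
        H=pd.DataFrame(model.components_, index=comp, columns=cols),
        theta=theta,
        rank=rank,
        seed=seed,
        rss=model.reconstruction_err_,
        n_iter=model.n_iter_,
        converged=model.converged_,
    )


def _run_seeds(seed: int | None, n_runs: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs)]


def multirun_consensus(
    V,
    rank: int,
    n_runs: int = 100,
    theta: float = 0.5,
    seed: int | None = None,
    max_iter: int = 2000,
    tol: float = 1e-5,
) -> tuple[FactorizationResult, pd.DataFrame]:
    """Run nsNMF ``n_runs`` times from independent seeded initializations.

    Returns the minimal-rss run and the sample x sample consensus matrix
    (fraction of runs in which two samples share a hard component
    assignment).
    """
    if n_runs < 2:
        raise ValueError("consensus needs n_runs >= 2")
    _, _, cols = _as_array(V)
    best: FactorizationResult | None = None
    m = None
    agree = None
    for run_seed in _run_seeds(seed, n_runs):
        res = nsnmf_factorize(V, rank, theta=theta, seed=run_seed, max_iter=max_iter, tol=tol)
        assign = res.H.to_numpy().argmax(axis=0)
        if agree is None:
            m = len(assign)
            agree = np.zeros((m, m))
        agree += (assign[:, None] == assign[None, :]).astype(float)
        if best is None or res.rss < best.rss:
            best = res
    consensus = agree / n_runs
    np.fill_diagonal(consensus, 1.0)
    cols = cols if cols is not None else pd.RangeIndex(m)
    return best, pd.DataFrame(consensus, index=cols, columns=cols)


def cophenetic_correlation(consensus: pd.DataFrame) -> float:
    """Correlation between consensus distances and their hierarchical-
    clustering cophenetic distances (average linkage on 1 - consensus)."""
    d = 1.0 - consensus.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    if np.allclose(condensed, condensed[0]):
        return 1.0  # all distances equal: tree reproduces them exactly
    Z = average(condensed)
    c, _ = cophenet(Z, condensed)
    return float(c)


@dataclass
class RankDiagnostics:
    """Per-rank consensus and fit diagnostics from a rank survey."""

    ranks: list[int] = field(default_factory=list)
    consensus: dict[int, pd.DataFrame] = field(default_factory=dict)
    cophenetic: dict[int, float] = field(default_factory=dict)
    rss: dict[int, float] = field(default_factory=dict)
    dispersion: dict[int, float] = field(default_factory=dict)
    residuals: dict[int, float] = field(default_factory=dict)
    best_runs: dict[int, FactorizationResult] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": self.ranks,
                "cophenetic": [self.cophenetic[r] for r in self.ranks],
                "rss": [self.rss[r] for r in self.ranks],
                "dispersion": [self.dispersion[r] for r in self.ranks],
                "residuals": [self.residuals[r] for r in self.ranks],
            }
        ).set_index("rank")


def rank_survey(
    V,
    ranks=range(3, 8),
    n_runs: int = 100,
    theta: float = 0.5,
    seed: int | None = None,
    max_iter: int = 2000,
    tol: float = 1e-5,
) -> RankDiagnostics:
    """Consensus survey over candidate ranks.

    For each rank: cophenetic correlation of the consensus matrix, rss of the
    best run, dispersion 1 - rss / sum(V^2) (explained-variance form), and
    the absolute-residual sum of the best run.
    """
    ranks = [int(r) for r in ranks]
    arr, _, _ = _as_array(V)
    total_sq = float((arr**2).sum())
    diag = RankDiagnostics()
    ss = np.random.SeedSequence(seed)
    for rank, sub in zip(ranks, ss.spawn(len(ranks))):
        rank_seed = int(sub.generate_state(1)[0] % (2**31))
        best, consensus = multirun_consensus(
            V, rank, n_runs=n_runs, theta=theta, seed=rank_seed, max_iter=max_iter, tol=tol
        )
        recon = best.reconstruction().to_numpy()
        diag.ranks.append(rank)
        diag.consensus[rank] = consensus
        diag.cophenetic[rank] = cophenetic_correlation(consensus)
        diag.rss[rank] = best.rss
        diag.dispersion[rank] = 1.0 - best.rss / total_sq if total_sq > 0 else np.nan
        diag.residuals[rank] = float(np.abs(arr - recon).sum())
        diag.best_runs[rank] = best
    return diag


def select_rank(diag: RankDiagnostics) -> int:
    """Rank with maximal cophenetic correlation; ties go to the smallest."""
    if not diag.ranks:
        raise ValueError("no ranks surveyed")
    best = max(sorted(diag.ranks), key=lambda r: (diag.cophenetic[r], -r))
    return int(best)


def label_components(H: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Name each component after the majority water feature of its samples.

    Samples are hard-assigned by maximal coefficient; each component gets the
    majority feature label among its samples ("unlabeled" if none), with ties
    broken lexicographically and flagged.
    """
    feat = meta.set_index("sample_id")["feature"]
    missing = [s for s in H.columns if s not in feat.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    assign = H.idxmax(axis=0)
    rows = []
    for comp in H.index:
        samples = assign.index[assign == comp]
        if len(samples) == 0:
            rows.append((comp, "unlabeled", 0, False))
            continue
        counts = feat.loc[samples].value_counts()
        top = counts.max()
        winners = sorted(counts.index[counts == top])
        rows.append((comp, winners[0], int(top), len(winners) > 1))
    return pd.DataFrame(rows, columns=["component", "label", "n_samples", "tie"]).set_index(
        "component"
    )
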