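"""Per-annotation component-specificity indices and group-comparison tests.

For each annotation (EC number) i and each factorization component k the
index combines three ingredients:

* rho_{i,k} — Spearman rank correlation between the annotation's abundance
  profile across samples and the component's coefficient profile;
* Cos(theta)_{i,k} — cosine of the angle between the two profiles after L2
  normalization (a pure direction match, insensitive to scale);
* Score(i) — an entropy-based specificity of the annotation's basis-matrix
  row: 1 + (1/log2 q) * sum_k p(i,k) log2 p(i,k) with p(i,k) the row-
  normalized basis weight; 1 for an annotation loading a single component,
  0 for one spread uniformly over all q components.

The index I_{i,k} = rho_{i,k} * Cos(theta)_{i,k} * Score(i) lies in [-1, 1];
values near 1 mark annotations specific to, and co-varying with, one
component.  Group contrasts of index distributions use a univariate
permutational ANOVA followed by Student t-tests that reuse the
permutational-ANOVA residual variance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .factorization import FactorizationResult
from .profiles import AbundanceMatrix

__all__ = [
    "spearman_profile_corr",
    "projection_cosine",
    "specificity_score",
    "ec_index",
    "index_table",
    "permanova_oneway",
    "pairwise_t_residual",
    "compare_aromatic_vs_other",
]


def _profiles(A) -> tuple[np.ndarray, pd.Index, pd.Index]:
    if isinstance(A, AbundanceMatrix):
        return A.values, A.annotations, A.samples
    if isinstance(A, pd.DataFrame):
        return A.to_numpy(dtype=float), A.index, A.columns
    arr = np.asarray(A, dtype=float)
    return arr, pd.RangeIndex(arr.shape[0]), pd.RangeIndex(arr.shape[1])


def _align(A, H: pd.DataFrame):
    a, annotations, samples = _profiles(A)
    if isinstance(H, pd.DataFrame):
        missing = [s for s in samples if s not in H.columns]
        if missing:
            raise ValueError(f"components lack samples {missing}")
        h = H[list(samples)].to_numpy(dtype=float)
        comps = H.index
    else:
        h = np.asarray(H, dtype=float)
        if h.shape[1] != a.shape[1]:
            raise ValueError("abundance and coefficient matrices must share samples")
        comps = pd.Index([f"component_{k+1}" for k in range(h.shape[0])])
    return a, h, annotations, comps, samples


def spearman_profile_corr(A, H) -> pd.DataFrame:
    """Spearman correlation between every annotation profile and component.

    Average ranks are used for ties; a constant profile (zero rank variance)
    yields rho = 0, the degenerate-profile convention.
    """
    a, h, annotations, comps, _ = _align(A, H)
    if a.shape[1] < 3:
        raise ValueError("Spearman profiles need at least 3 samples")
    ra = stats.rankdata(a, axis=1)
    rh = stats.rankdata(h, axis=1)
    ra_c = ra - ra.mean(axis=1, keepdims=True)
    rh_c = rh - rh.mean(axis=1, keepdims=True)
    sa = np.sqrt((ra_c**2).sum(axis=1))
    sh = np.sqrt((rh_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra_c @ rh_c.T) / np.outer(sa, sh)
    rho = np.where(np.isfinite(rho), rho, 0.0)
    return pd.DataFrame(rho, index=annotations, columns=comps)


def projection_cosine(A, H) -> pd.DataFrame:
    """Cosine of the angle between L2-normalized annotation and component
    profiles; all-zero profiles map to 0."""
    a, h, annotations, comps, _ = _align(A, H)
    na = np.linalg.norm(a, axis=1)
    nh = np.linalg.norm(h, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (a @ h.T) / np.outer(na, nh)
    cos = np.where(np.isfinite(cos), cos, 0.0)
    return pd.DataFrame(cos, index=annotations, columns=comps)


def specificity_score(W, q: int | None = None) -> pd.Series:
    """Entropy specificity of basis-matrix rows.

    p(i,k) = W_ik / sum_k W_ik; Score(i) = 1 + (1/log2 q) sum p log2 p, with
    0 log 0 = 0.  All-zero rows get score 0 (flagged by NaN-free zero).
    """
    if isinstance(W, pd.DataFrame):
        w = W.to_numpy(dtype=float)
        idx = W.index
    else:
        w = np.asarray(W, dtype=float)
        idx = pd.RangeIndex(w.shape[0])
    if (w < 0).any():
        raise ValueError("basis matrix must be non-negative")
    q = w.shape[1] if q is None else int(q)
    if q < 2:
        raise ValueError("specificity score needs at least 2 components")
    rowsum = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(rowsum > 0, w / rowsum, 0.0)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    score = 1.0 + plogp.sum(axis=1) / math.log2(q)
    score = np.where(rowsum.ravel() > 0, np.clip(score, 0.0, 1.0), 0.0)
    return pd.Series(score, index=idx, name="score")


def ec_index(rho: pd.DataFrame, cos: pd.DataFrame, score: pd.Series) -> pd.DataFrame:
    """I_{i,k} = rho_{i,k} * Cos(theta)_{i,k} * Score(i)."""
    if rho.shape != cos.shape:
        raise ValueError(f"rho {rho.shape} and cosine {cos.shape} shapes differ")
    if len(score) != rho.shape[0]:
        raise ValueError("score length does not match annotation count")
    return rho * cos.values * np.asarray(score)[:, None]


def index_table(
    A,
    result: FactorizationResult,
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-form index table for every (annotation, component) pair."""
    rho = spearman_profile_corr(A, result.H)
    cos = projection_cosine(A, result.H)
    score = specificity_score(result.W)
    idx = ec_index(rho, cos, score)
    long = pd.concat(
        {
            "rho": rho.stack(),
            "cos_theta": cos.stack(),
            "index": idx.stack(),
        },
        axis=1,
    )
    long.index.names = ["annotation", "component"]
    long = long.reset_index()
    long["score"] = score.reindex(long["annotation"]).to_numpy()
    if labels is not None:
        long["component_label"] = labels["label"].reindex(long["component"]).to_numpy()
    cols = ["annotation", "component", "rho", "cos_theta", "score", "index"]
    if labels is not None:
        cols.insert(2, "component_label")
    return long[cols]


# ---------------------------------------------------------------------------
# permutation tests


def _oneway_f(values: np.ndarray, codes: np.ndarray, n_groups: int):
    n = len(values)
    if np.ptp(values) == 0:  # all identical: no variance of any kind
        return 0.0, 0.0, n - n_groups
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        ssb += len(v) * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
    dfb = n_groups - 1
    dfw = n - n_groups
    if ssw <= 0:
        return (np.inf if ssb > 0 else 0.0), ssw, dfw
    return (ssb / dfb) / (ssw / dfw), ssw, dfw


def _distinct_arrangements(counts) -> int:
    n = sum(counts)
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(c)
    return total


def _multiset_arrangements(counts, n):
    """Yield every distinct assignment of n positions to groups with the
    given sizes, as an int array of group codes."""

    def rec(positions, group):
        if group == len(counts) - 1:
            out = np.empty(n, dtype=int)
            out.fill(group)
            for g, pos in enumerate(assigned):
                out[list(pos)] = g
            yield out
            return
        for chosen in itertools.combinations(positions, counts[group]):
            assigned.append(chosen)
            yield from rec(tuple(p for p in positions if p not in chosen), group + 1)
            assigned.pop()

    assigned: list[tuple] = []
    yield from rec(tuple(range(n)), 0)


def permanova_oneway(
    values,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-way permutational ANOVA on univariate values.

    F is the classical between/within mean-square ratio; the p-value is
    obtained by permuting group labels, p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm).  When the number of distinct label arrangements is at most
    10,000 the permutation distribution is enumerated exhaustively and
    p = #{F >= F_obs} / #arrangements.
    """
    values = np.asarray(values, dtype=float)
    codes, uniques = pd.factorize(np.asarray(groups))
    g = len(uniques)
    if g < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes, minlength=g)
    if (counts == 0).any():
        empty = [str(uniques[i]) for i in range(g) if counts[i] == 0]
        raise ValueError(f"empty groups: {empty}")
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    f_obs, _, _ = _oneway_f(values, codes, g)

    n_arr = _distinct_arrangements(counts)
    if n_arr <= 10_000:
        ge = 0
        total = 0
        for arrangement in _multiset_arrangements(counts, len(values)):
            f, _, _ = _oneway_f(values, arrangement, g)
            if f >= f_obs - 1e-12:
                ge += 1
            total += 1
        assert total == n_arr
        p = ge / n_arr
    else:
        rng = np.random.default_rng(seed)
        ge = 0
        perm_codes = codes.copy()
        for _ in range(n_perm):
            rng.shuffle(perm_codes)
            f, _, _ = _oneway_f(values, perm_codes, g)
            if f >= f_obs - 1e-12:
                ge += 1
        p = (1 + ge) / (1 + n_perm)
    return float(f_obs), float(p)


def pairwise_t_residual(values, groups) -> pd.DataFrame:
    """Pairwise Student t-tests with the one-way residual variance pooled
    across all groups (dfw = N - g degrees of freedom); flags p < 0.05."""
    values = np.asarray(values, dtype=float)
    codes, uniques = pd.factorize(np.asarray(groups))
    g = len(uniques)
    if g < 2:
        raise ValueError("need at least two groups")
    _, ssw, dfw = _oneway_f(values, codes, g)
    if dfw <= 0 or ssw <= 0:
        raise ValueError("degenerate data: zero residual variance")
    s2 = ssw / dfw
    rows = []
    for a, b in itertools.combinations(range(g), 2):
        va, vb = values[codes == a], values[codes == b]
        se = math.sqrt(s2 * (1 / len(va) + 1 / len(vb)))
        t = (va.mean() - vb.mean()) / se
        p = 2 * stats.t.sf(abs(t), dfw)
        rows.append((str(uniques[a]), str(uniques[b]), va.mean(), vb.mean(), t, p, p < 0.05))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_a", "mean_b", "t", "p", "significant"]
    )


@dataclass
class ContrastReport:
    component: str
    mean_aromatic: float
    mean_other: float
    n_aromatic: int
    n_other: int
    F: float
    p_permanova: float
    t: float
    p_t: float
    significant: bool


def compare_aromatic_vs_other(
    table: pd.DataFrame,
    aromatic_annotations,
    component: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> ContrastReport:
    """Contrast index values of aromatic-degradation ECs against all other
    ECs within one component's index distribution."""
    sub = table[table["component"] == component]
    if sub.empty:
        raise ValueError(f"unknown component {component!r}")
    aromatic = set(aromatic_annotations)
    is_arom = sub["annotation"].isin(aromatic).to_numpy()
    if is_arom.all() or not is_arom.any():
        raise ValueError("both aromatic and other annotations are required")
    values = sub["index"].to_numpy()
    groups = np.where(is_arom, "aromatic", "other")
    F, p = permanova_oneway(values, groups, n_perm=n_perm, seed=seed)
    try:
        tt = pairwise_t_residual(values, groups).iloc[0]
    except ValueError:  # zero residual variance: identical values everywhere
        tt = pd.Series({"group_a": "aromatic", "t": 0.0, "p": 1.0})
    sign = 1.0 if tt["group_a"] == "aromatic" else -1.0
    return ContrastReport(
        component=component,
        mean_aromatic=float(values[is_arom].mean()),
        mean_other=float(values[~is_arom].mean()),
        n_aromatic=int(is_arom.sum()),
        n_other=int((~is_arom).sum()),
        F=F,
        p_permanova=p,
        t=float(sign * tt["t"]),
        p_t=float(tt["p"]),
        significant=bool(tt["p"] < 0.05),
    )
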