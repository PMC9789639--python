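"""Functional abundance profiles: EC/KO matrix construction and normalization.

The raw input is a gene table: one row per (gene, sample) with a mean
fold-coverage ``depth`` and semicolon-separated EC and KO annotation sets.
The abundance of an annotation in a sample is the sum of the coverage depths
of every gene carrying that annotation; a gene annotated with several ECs
contributes its full depth to each of them.  Raw copy matrices are then
scaled to copies per million reads using TMM-adjusted effective library
sizes, and Hellinger-transformed ahead of ordination and factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "AbundanceMatrix",
    "TMMNormalizer",
    "build_abundance_matrix",
    "tmm_factors",
    "normalize_per_million",
    "hellinger",
    "validate_gene_table",
    "validate_metadata",
]

GENE_TABLE_COLUMNS = [
    "gene_id",
    "sample_id",
    "depth",
    "ec_ids",
    "ko_ids",
    "taxon",
    "variant_cluster",
    "length_bp",
]

METADATA_COLUMNS = ["sample_id", "library_reads", "feature", "assay"]

VALID_STATES = ("raw_copies", "per_million", "hellinger")


@dataclass
class AbundanceMatrix:
    """Annotation x sample matrix with a normalization-state tag.

    ``data`` has annotation ids as index and sample ids as columns; ``state``
    records the provenance of the values (``raw_copies`` coverage sums,
    ``per_million`` copies per million reads, or ``hellinger``).
    """

    data: pd.DataFrame
    state: str = "raw_copies"

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {VALID_STATES}")
        if (self.data.values < 0).any():
            raise ValueError("abundance matrices are non-negative")

    @property
    def annotations(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "annotation"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, state: str = "raw_copies") -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, state=state)


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Coerce a gene table to the canonical column set and check invariants."""
    df = genes.copy()
    for col in GENE_TABLE_COLUMNS:
        if col not in df.columns:
            if col in ("gene_id", "sample_id", "depth"):
                raise ValueError(f"gene table missing required column {col!r}")
            df[col] = "" if col in ("ec_ids", "ko_ids", "taxon", "variant_cluster") else np.nan
    df["depth"] = df["depth"].astype(float)
    if (df["depth"] < 0).any():
        raise ValueError("gene depths must be non-negative")
    for col in ("ec_ids", "ko_ids", "taxon", "variant_cluster"):
        df[col] = df[col].fillna("").astype(str)
    return df[GENE_TABLE_COLUMNS]


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    df = meta.copy()
    for col in ("sample_id", "library_reads", "feature"):
        if col not in df.columns:
            raise ValueError(f"sample metadata missing required column {col!r}")
    if "assay" not in df.columns:
        df["assay"] = "metagenome"
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    if (df["library_reads"] <= 0).any():
        raise ValueError("library_reads must be positive")
    return df[METADATA_COLUMNS]


def _explode_annotations(genes: pd.DataFrame, kind: str) -> pd.DataFrame:
    col = {"EC": "ec_ids", "KO": "ko_ids"}.get(kind.upper())
    if col is None:
        raise ValueError(f"annotation_kind must be 'EC' or 'KO', got {kind!r}")
    sub = genes.loc[genes[col].str.len() > 0, ["sample_id", "depth", col]].copy()
    sub[col] = sub[col].str.split(";")
    sub = sub.explode(col)
    sub[col] = sub[col].str.strip()
    return sub[sub[col].str.len() > 0].rename(columns={col: "annotation"})


def build_abundance_matrix(
    genes: pd.DataFrame,
    meta: pd.DataFrame,
    annotation_kind: str = "EC",
) -> AbundanceMatrix:
    """Sum gene coverage depths into an annotation x sample raw-copy matrix.

    Every sample declared in ``meta`` yields a column even if it has no
    annotated genes; a gene with m annotations of the requested kind
    contributes its full depth to each of the m rows.
    """
    genes = validate_gene_table(genes)
    meta = validate_metadata(meta)
    unknown = set(genes["sample_id"]) - set(meta["sample_id"])
    if unknown:
        raise ValueError(f"gene table references samples absent from metadata: {sorted(unknown)}")
    long = _explode_annotations(genes, annotation_kind)
    if long.empty:
        data = pd.DataFrame(
            0.0, index=pd.Index([], name="annotation"), columns=list(meta["sample_id"])
        )
        return AbundanceMatrix(data, state="raw_copies")
    pivot = long.pivot_table(
        index="annotation", columns="sample_id", values="depth", aggfunc="sum", fill_value=0.0
    )
    pivot = pivot.reindex(columns=list(meta["sample_id"]), fill_value=0.0)
    pivot = pivot.sort_index()
    pivot.columns.name = None
    pivot.index.name = "annotation"
    return AbundanceMatrix(pivot.astype(float), state="raw_copies")


@dataclass
class TMMParams:
    """Trimmed-mean-of-M-values settings (edgeR calcNormFactors defaults)."""

    logratio_trim: float = 0.30
    abs_trim: float = 0.05
    weighted: bool = True

    def __post_init__(self) -> None:
        for name, v in (("logratio_trim", self.logratio_trim), ("abs_trim", self.abs_trim)):
            if not 0 <= v < 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5), got {v}")


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Library-composition normalization by trimmed mean of M-values.

    Fit on a raw-copy :class:`AbundanceMatrix` plus library sizes; exposes the
    per-sample composition factors as ``factors_`` (geometric mean 1) and
    transforms raw copies to copies per million reads of effective library
    size ``library_reads * factor``.

    Parameters follow the canonical TMM definition: sample pairs are compared
    through log-ratios of relative abundances (M) and average log abundance
    (A); the most extreme 2*30% of M values and 2*5% of A values are trimmed
    and the remaining M values averaged with inverse-variance weights.
    """

    def __init__(self, logratio_trim: float = 0.30, abs_trim: float = 0.05, weighted: bool = True):
        self.logratio_trim = logratio_trim
        self.abs_trim = abs_trim
        self.weighted = weighted

    def fit(self, X: AbundanceMatrix, y=None, *, library_reads=None):
        params = TMMParams(self.logratio_trim, self.abs_trim, self.weighted)
        if X.state != "raw_copies":
            raise ValueError(f"TMM expects raw copies, got state {X.state!r}")
        counts = X.values
        if counts.shape[1] < 2:
            raise ValueError("TMM needs at least two samples")
        lib = _as_library_sizes(library_reads, X.samples)
        if (counts.sum(axis=0) <= 0).any():
            bad = [s for s, tot in zip(X.samples, counts.sum(axis=0)) if tot <= 0]
            raise ValueError(f"samples with all-zero profiles: {bad}")
        rel = counts / lib[np.newaxis, :]
        ref = self._pick_reference(rel)
        raw = np.array(
            [self._pair_factor(counts[:, j], lib[j], counts[:, ref], lib[ref], params)
             for j in range(counts.shape[1])]
        )
        factors = raw / np.exp(np.mean(np.log(raw)))
        self.factors_ = pd.Series(factors, index=X.samples, name="tmm_factor")
        self.reference_sample_ = X.samples[ref]
        self.library_reads_ = pd.Series(lib, index=X.samples)
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        return normalize_per_million(X, self.library_reads_, self.factors_)

    @staticmethod
    def _pick_reference(rel: np.ndarray) -> int:
        # upper quartile of each sample's nonzero relative abundances,
        # reference = sample closest to the mean upper quartile
        uq = np.array([
            np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0 for col in rel.T
        ])
        return int(np.argmin(np.abs(uq - uq.mean())))

    @staticmethod
    def _pair_factor(obs, n_obs, ref, n_ref, params: TMMParams) -> float:
        keep = (obs > 0) & (ref > 0)
        if keep.sum() == 0:
            return 1.0
        o, r = obs[keep], ref[keep]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        # asymptotic (delta-method) variance of M under Poisson sampling
        w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        if np.allclose(m, 0, atol=1e-10):
            return 1.0
        n = len(m)
        lo_m = np.floor(n * params.logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * params.abs_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep2.sum() == 0:
            return 1.0
        if params.weighted:
            f = np.nansum(m[keep2] / w[keep2]) / np.nansum(1.0 / w[keep2])
        else:
            f = np.nanmean(m[keep2])
        if not np.isfinite(f):
            return 1.0
        return float(2.0**f)


def _as_library_sizes(library_reads, samples: pd.Index) -> np.ndarray:
    if library_reads is None:
        raise ValueError("library_reads required (pass metadata 'library_reads' per sample)")
    if isinstance(library_reads, pd.DataFrame):
        library_reads = library_reads.set_index("sample_id")["library_reads"]
    if isinstance(library_reads, pd.Series):
        missing = [s for s in samples if s not in library_reads.index]
        if missing:
            raise ValueError(f"missing library sizes for samples: {missing}")
        return library_reads.reindex(samples).to_numpy(dtype=float)
    arr = np.asarray(library_reads, dtype=float)
    if arr.shape != (len(samples),):
        raise ValueError("library_reads length does not match sample count")
    return arr


def tmm_factors(
    counts: AbundanceMatrix,
    meta: pd.DataFrame | pd.Series,
    params: TMMParams | None = None,
) -> pd.Series:
    """Per-sample TMM factors (geometric mean 1) for a raw-copy matrix."""
    params = params or TMMParams()
    est = TMMNormalizer(params.logratio_trim, params.abs_trim, params.weighted)
    est.fit(counts, library_reads=meta)
    return est.factors_


def normalize_per_million(
    raw: AbundanceMatrix,
    meta: pd.DataFrame | pd.Series,
    factors: pd.Series | None = None,
) -> AbundanceMatrix:
    """Scale raw copies to copies per million reads of effective library size.

    entry = raw / (library_reads * factor) * 1e6.  ``factors`` defaults to
    all ones (plain library-size scaling).
    """
    if raw.state != "raw_copies":
        raise ValueError(f"expected raw_copies, got {raw.state!r}")
    lib = _as_library_sizes(meta, raw.samples)
    if factors is None:
        f = np.ones(len(raw.samples))
    else:
        missing = [s for s in raw.samples if s not in factors.index]
        if missing:
            raise ValueError(f"missing TMM factor for samples: {missing}")
        f = factors.reindex(raw.samples).to_numpy(dtype=float)
    eff = lib * f
    data = raw.data / eff * 1e6
    return AbundanceMatrix(data, state="per_million")


def hellinger(m: AbundanceMatrix) -> AbundanceMatrix:
    """Hellinger transformation per sample: value -> sqrt(value / column sum).

    All-zero columns are left at zero; for any other column the transformed
    values have unit sum of squares.
    """
    vals = m.values
    colsum = vals.sum(axis=0)
    safe = np.where(colsum > 0, colsum, 1.0)
    out = np.sqrt(vals / safe[np.newaxis, :])
    data = pd.DataFrame(out, index=m.annotations, columns=m.samples)
    return AbundanceMatrix(data, state="hellinger")
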