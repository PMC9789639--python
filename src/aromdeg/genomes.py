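"""MAG-level analyses: quality filtering, aromatic-capacity enrichment,
ANI genomospecies clustering, recruitment-hit filtering, and RPKG.

A MAG (metagenome-assembled genome) arrives with CheckM-style completeness
and contamination estimates and a multiset of EC/KO annotations.  MAGs with
completeness > 30% and contamination < 10% are retained; a MAG is called
enriched in aromatic-compound degradation when the median of its
completeness-normalized funneling-pathway completeness values exceeds 4%.
MAGs sharing ANI > 95% collapse into one genomospecies (single-linkage
connected components).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin

from .pathways import PathwayCatalog

__all__ = [
    "MAGRecord",
    "filter_mags",
    "mag_pathway_scores",
    "select_enriched_mags",
    "ANIGenomospecies",
    "genomospecies",
    "filter_best_hits",
    "rpkg",
    "comparative_marker_census",
]

HIT_COLUMNS = ["read_id", "target_id", "aln_len_bp", "pct_identity", "bitscore"]


@dataclass
class MAGRecord:
    mag_id: str
    completeness_pct: float
    contamination_pct: float
    size_kbp: float = 0.0
    ecs: tuple[str, ...] = ()  # multiset: repeats = copy number
    kos: tuple[str, ...] = ()
    taxonomy: str = ""

    def __post_init__(self):
        if not 0 <= self.completeness_pct <= 100:
            raise ValueError(f"completeness out of range for {self.mag_id}")
        if self.contamination_pct < 0:
            raise ValueError(f"negative contamination for {self.mag_id}")

    @property
    def ec_set(self) -> set[str]:
        return set(self.ecs)

    def ko_copies(self, ko: str) -> int:
        return sum(1 for k in self.kos if k == ko)


def filter_mags(mags: list[MAGRecord]) -> list[MAGRecord]:
    """Quality filter: completeness strictly above 30%, contamination
    strictly below 10%."""
    return [m for m in mags if m.completeness_pct > 30 and m.contamination_pct < 10]


def mag_pathway_scores(
    mag: MAGRecord,
    catalog: PathwayCatalog,
    cap: bool = True,
) -> tuple[pd.Series, float]:
    """Completeness-normalized funneling-pathway scores for one MAG.

    raw = (distinct pathway ECs present in the MAG) / (reactions in pathway);
    normalized = raw / (MAG completeness / 100), optionally capped at 1 (low
    completeness inflates the ratio).  Returns the per-pathway series and the
    median over all funneling pathways, zeros included.
    """
    if mag.completeness_pct <= 0:
        raise ValueError(f"MAG {mag.mag_id} has zero completeness")
    funneling = catalog.funneling
    if not funneling:
        raise ValueError("catalog has no funneling pathways")
    present = mag.ec_set
    scores = {}
    for p in funneling:
        raw = len(p.ecs & present) / len(p.reactions)
        norm = raw / (mag.completeness_pct / 100.0)
        scores[p.pathway_id] = min(norm, 1.0) if cap else norm
    s = pd.Series(scores, name=mag.mag_id)
    return s, float(s.median())


def select_enriched_mags(
    mags: list[MAGRecord],
    catalog: PathwayCatalog,
    threshold: float = 0.04,
    cap: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """MAGs whose median normalized funneling-pathway completeness strictly
    exceeds ``threshold`` (default 4%).  Returns (selected ids, score table)."""
    rows = []
    for m in mags:
        _, med = mag_pathway_scores(m, catalog, cap=cap)
        rows.append((m.mag_id, med, med > threshold))
    table = pd.DataFrame(rows, columns=["mag_id", "median_score", "selected"]).set_index(
        "mag_id"
    )
    return list(table.index[table["selected"]]), table


class ANIGenomospecies(BaseEstimator, ClusterMixin):
    """Genomospecies clustering: single-linkage components of the ANI graph.

    Two genomes are linked when their average nucleotide identity strictly
    exceeds ``threshold`` (percent); clusters are the connected components,
    so chains of >threshold links merge transitively.
    """

    def __init__(self, threshold: float = 95.0):
        self.threshold = threshold

    def fit(self, ani, y=None):
        if isinstance(ani, pd.DataFrame):
            ids = list(ani.index)
            A = ani.to_numpy(dtype=float)
        else:
            A = np.asarray(ani, dtype=float)
            ids = list(range(A.shape[0]))
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("ANI matrix must be square")
        if not np.allclose(A, A.T, atol=1e-6):
            raise ValueError("ANI matrix must be symmetric")
        adj = csr_matrix((A > self.threshold).astype(int))
        _, labels = connected_components(adj, directed=False)
        self.labels_ = labels
        self.ids_ = ids
        return self

    def fit_predict(self, ani, y=None):
        return self.fit(ani).labels_


def genomospecies(ani, threshold: float = 95.0) -> pd.Series:
    """Cluster label per genome at the ANI > threshold rule."""
    model = ANIGenomospecies(threshold=threshold).fit(ani)
    return pd.Series(model.labels_, index=model.ids_, name="genomospecies")


def filter_best_hits(
    hits: pd.DataFrame,
    min_len: int = 100,
    min_id: float = 98.0,
) -> pd.DataFrame:
    """Best-hit read assignment with recruitment filters.

    Per read the maximal-bitscore hit is kept (ties broken by smallest
    target_id and flagged); the surviving assignment must satisfy
    aln_len >= min_len and pct_identity >= min_id (inclusive minima).
    """
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns {missing}")
    if hits.empty:
        return hits.assign(tie=pd.Series(dtype=bool)).iloc[0:0]
    df = hits.sort_values(["read_id", "bitscore", "target_id"], ascending=[True, False, True])
    top_score = df.groupby("read_id")["bitscore"].transform("max")
    at_top = df[df["bitscore"] == top_score]
    ties = at_top.groupby("read_id")["target_id"].transform("size") > 1
    best = at_top.assign(tie=ties).groupby("read_id", as_index=False).first()
    kept = best[(best["aln_len_bp"] >= min_len) & (best["pct_identity"] >= min_id)]
    return kept.reset_index(drop=True)


def rpkg(
    read_counts: pd.DataFrame | pd.Series,
    mag_sizes_kbp: pd.Series,
    library_sizes_gbp: pd.Series | float,
) -> pd.DataFrame | pd.Series:
    """Reads per kilobase of genome per gigabase of library.

    RPKG = reads / (genome size in kbp x library size in Gbp); accepts a
    target x sample count table or a per-target series with a scalar library
    size.
    """
    sizes = pd.Series(mag_sizes_kbp, dtype=float)
    if (sizes <= 0).any():
        bad = list(sizes.index[sizes <= 0])
        raise ValueError(f"non-positive MAG sizes: {bad}")
    if isinstance(read_counts, pd.Series):
        lib = float(library_sizes_gbp)
        if lib <= 0:
            raise ValueError("library size must be positive")
        return read_counts / (sizes.reindex(read_counts.index) * lib)
    lib = pd.Series(library_sizes_gbp, dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    out = read_counts.div(sizes.reindex(read_counts.index), axis=0)
    return out.div(lib.reindex(read_counts.columns), axis=1)


def comparative_marker_census(
    mag_sets: dict[str, list[MAGRecord]],
    markers: dict[str, tuple[str, str] | None],
    pairing: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Marker-KO copy-number census across two labeled MAG collections.

    Returns a (MAG x marker KO) copy-count table annotated with the
    collection label and, when ``pairing`` maps MAGs of one collection to
    their counterpart in the other, a per-pair contrast listing markers
    present in A but absent in its paired B genome (and vice versa).
    """
    if len(mag_sets) != 2:
        raise ValueError("expected exactly two labeled MAG collections")
    marker_kos = sorted({m[1] for m in markers.values() if m is not None and m[1]})
    rows = []
    for label, mags in mag_sets.items():
        for m in mags:
            counts = {ko: m.ko_copies(ko) for ko in marker_kos}
            rows.append({"mag_id": m.mag_id, "collection": label, **counts})
    census = pd.DataFrame(rows).set_index("mag_id")
    if pairing is None:
        return census, None
    label_a, label_b = mag_sets.keys()
    contrasts = []
    for a_id, b_id in pairing.items():
        if a_id not in census.index or b_id not in census.index:
            raise ValueError(f"unpaired MAG in pairing: {a_id} -> {b_id}")
        a = census.loc[a_id, marker_kos]
        b = census.loc[b_id, marker_kos]
        only_a = [ko for ko in marker_kos if a[ko] > 0 and b[ko] == 0]
        only_b = [ko for ko in marker_kos if b[ko] > 0 and a[ko] == 0]
        contrasts.append(
            {
                "mag_a": a_id,
                "mag_b": b_id,
                f"{label_a}_only": ";".join(only_a),
                f"{label_b}_only": ";".join(only_b),
                "n_markers_a": int((a > 0).sum()),
                "n_markers_b": int((b > 0).sum()),
                "copies_a": int(a.sum()),
                "copies_b": int(b.sum()),
            }
        )
    return census, pd.DataFrame(contrasts)
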