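"""Pathway catalog handling: marker selection, completeness, gene fractions.

A catalog holds aromatic-compound-degradation pathways split into two
classes — funneling pathways, which convert a substituted aromatic compound
into one of the few central ring-fission substrates, and ring-fission
pathways, which open the aromatic ring toward central metabolism.  Each
pathway is a list of reactions tagged with reaction types; one reaction per
pathway may be promoted to a marker whose EC/KO uniquely represents the
pathway in downstream censuses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import (
    AbundanceMatrix,
    build_abundance_matrix,
    normalize_per_million,
    validate_gene_table,
)

__all__ = [
    "Reaction",
    "Pathway",
    "PathwayCatalog",
    "select_markers",
    "pathway_completeness",
    "aromatic_gene_fraction",
    "genome_fraction",
    "marker_abundance",
]

REACTION_TYPES = (
    "ring-opening",
    "ring-oxidation",
    "ring-reduction",
    "CoA-addition",
    "side-chain-oxidoreduction",
    "other",
)

# ring-attacking reactions take precedence as pathway markers; CoA-addition
# and side-chain steps are the fallback
PRIORITY_1 = ("ring-opening", "ring-oxidation", "ring-reduction")
PRIORITY_2 = ("CoA-addition", "side-chain-oxidoreduction")


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    ec: str
    types: tuple[str, ...] = ("other",)
    ko: str = ""

    def __post_init__(self):
        bad = set(self.types) - set(REACTION_TYPES)
        if bad:
            raise ValueError(f"unknown reaction types {sorted(bad)}")


@dataclass
class Pathway:
    pathway_id: str
    name: str
    pathway_class: str  # funneling | ring_fission
    origin: str = "lignin_derived"  # lignin_derived | other
    reactions: list[Reaction] = field(default_factory=list)
    marker: tuple[str, str] | None = None  # (ec, ko)

    def __post_init__(self):
        if self.pathway_class not in ("funneling", "ring_fission"):
            raise ValueError(f"bad pathway class {self.pathway_class!r}")
        if not self.reactions:
            raise ValueError(f"pathway {self.pathway_id} has no reactions")

    @property
    def ecs(self) -> set[str]:
        return {r.ec for r in self.reactions}


@dataclass
class PathwayCatalog:
    pathways: list[Pathway]

    def __post_init__(self):
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            raise ValueError("pathway ids must be unique")

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self):
        return len(self.pathways)

    def get(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    @property
    def funneling(self) -> list[Pathway]:
        return [p for p in self.pathways if p.pathway_class == "funneling"]

    @property
    def all_ecs(self) -> set[str]:
        return set().union(*(p.ecs for p in self.pathways)) if self.pathways else set()

    def ec_pathway_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.pathways:
            for ec in p.ecs:
                counts[ec] = counts.get(ec, 0) + 1
        return counts

    def to_json(self, path) -> None:
        payload = {
            "pathways": [
                {
                    "pathway_id": p.pathway_id,
                    "name": p.name,
                    "class": p.pathway_class,
                    "origin": p.origin,
                    "reactions": [
                        {"reaction_id": r.reaction_id, "ec": r.ec, "ko": r.ko,
                         "types": list(r.types)}
                        for r in p.reactions
                    ],
                    "marker": list(p.marker) if p.marker else None,
                }
                for p in self.pathways
            ]
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PathwayCatalog":
        with open(path) as fh:
            payload = json.load(fh)
        pathways = []
        for p in payload["pathways"]:
            pathways.append(
                Pathway(
                    pathway_id=p["pathway_id"],
                    name=p["name"],
                    pathway_class=p["class"],
                    origin=p.get("origin", "lignin_derived"),
                    reactions=[
                        Reaction(r["reaction_id"], r["ec"], tuple(r["types"]), r.get("ko", ""))
                        for r in p["reactions"]
                    ],
                    marker=tuple(p["marker"]) if p.get("marker") else None,
                )
            )
        return cls(pathways)


def select_markers(catalog: PathwayCatalog) -> dict[str, tuple[str, str] | None]:
    """Choose at most one marker reaction (EC, KO) per pathway.

    Priority 1: ring-opening / ring-oxidation / ring-reduction reactions
    whose EC occurs in no other catalog pathway.  Priority 2: CoA-addition or
    side-chain-oxidoreduction reactions under the same uniqueness rule.  An
    EC shared by exactly two pathways and found nowhere else is assigned to
    the lexicographically smallest of the two.  Pathways with no qualifying
    reaction get no marker.
    """
    counts = catalog.ec_pathway_counts()
    ec_to_paths: dict[str, list[str]] = {}
    for p in catalog:
        for ec in p.ecs:
            ec_to_paths.setdefault(ec, []).append(p.pathway_id)

    def candidates(p: Pathway, types: tuple[str, ...]):
        # deterministic order: reactions as listed in the pathway
        return [r for r in p.reactions if set(r.types) & set(types)]

    markers: dict[str, tuple[str, str] | None] = {}
    used_ecs: set[str] = set()
    for p in sorted(catalog, key=lambda q: q.pathway_id):
        chosen = None
        for tier in (PRIORITY_1, PRIORITY_2):
            for r in candidates(p, tier):
                if r.ec in used_ecs:
                    continue
                if counts[r.ec] == 1:
                    chosen = r
                    break
                if counts[r.ec] == 2:
                    # shared by exactly one other pathway and nowhere else:
                    # goes to the lexicographically smallest of the pair
                    if min(ec_to_paths[r.ec]) == p.pathway_id:
                        chosen = r
                        break
            if chosen:
                break
        if chosen:
            markers[p.pathway_id] = (chosen.ec, chosen.ko)
            used_ecs.add(chosen.ec)
        else:
            markers[p.pathway_id] = None
    return markers


def pathway_completeness(
    catalog: PathwayCatalog,
    matrix: AbundanceMatrix,
    presence_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-sample pathway completeness: fraction of a pathway's distinct ECs
    whose abundance exceeds ``presence_threshold`` in the sample."""
    if matrix.state not in ("raw_copies", "per_million"):
        raise ValueError("completeness expects raw or per-million abundances")
    rows = {}
    for p in catalog:
        ecs = sorted(p.ecs)
        if not ecs:
            continue
        present = (
            matrix.data.reindex(ecs).fillna(0.0) > presence_threshold
        ).sum(axis=0)
        rows[p.pathway_id] = present / len(ecs)
    return pd.DataFrame(rows).T.reindex(columns=matrix.samples)


def aromatic_gene_fraction(genes: pd.DataFrame, catalog: PathwayCatalog) -> pd.Series:
    """Percentage of EC-annotated gene copies that carry an aromatic-
    degradation EC, per sample.

    Numerator: summed depth of genes whose EC set intersects the catalog;
    denominator: summed depth of genes with any EC annotation.  Samples with
    no EC-annotated genes report NaN.
    """
    genes = validate_gene_table(genes)
    aromatic = catalog.all_ecs
    has_ec = genes["ec_ids"].str.len() > 0
    annotated = genes[has_ec]
    denom = annotated.groupby("sample_id")["depth"].sum()

    def hits_catalog(ids: str) -> bool:
        return any(e.strip() in aromatic for e in ids.split(";"))

    is_arom = annotated["ec_ids"].map(hits_catalog)
    numer = annotated[is_arom].groupby("sample_id")["depth"].sum()
    numer = numer.reindex(denom.index, fill_value=0.0)
    frac = 100.0 * numer / denom
    frac.name = "aromatic_gene_pct"
    return frac


def genome_fraction(
    genes: pd.DataFrame,
    ko: str,
    recA_ko: str = "K03553",
) -> pd.Series:
    """Estimated percentage of genomes carrying a KO, per sample.

    Counts distinct dereplicated gene variants annotated with the KO and
    divides by the count of distinct variants of the single-copy recA gene
    (K03553).  Assumes a single copy per genome, so values can exceed 100
    when paralogs are common; samples without recA variants report NaN.
    """
    genes = validate_gene_table(genes)
    if (genes["variant_cluster"].str.len() == 0).all():
        raise ValueError("genome_fraction requires variant_cluster ids")

    def count_variants(target: str) -> pd.Series:
        has = genes["ko_ids"].str.split(";").map(lambda ids: target in [i.strip() for i in ids])
        sub = genes[has & (genes["variant_cluster"].str.len() > 0)]
        return sub.groupby("sample_id")["variant_cluster"].nunique()

    num = count_variants(ko)
    den = count_variants(recA_ko)
    samples = sorted(set(genes["sample_id"]))
    num = num.reindex(samples, fill_value=0)
    den = den.reindex(samples, fill_value=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 100.0 * num / den.replace(0, np.nan)
    frac.name = f"pct_genomes_{ko}"
    return frac


def marker_abundance(
    genes: pd.DataFrame,
    markers: dict[str, tuple[str, str] | None],
    meta: pd.DataFrame,
    factors: pd.Series | None = None,
) -> AbundanceMatrix:
    """Per-million abundance matrix restricted to marker KOs.

    Marker KOs absent from every sample keep an explicit zero row so the
    census shape is stable across datasets.
    """
    marker_kos = sorted({m[1] for m in markers.values() if m is not None and m[1]})
    raw = build_abundance_matrix(genes, meta, annotation_kind="KO")
    pm = normalize_per_million(raw, meta, factors)
    data = pm.data.reindex(marker_kos, fill_value=0.0)
    data.index.name = "annotation"
    return AbundanceMatrix(data, state="per_million")
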