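"""Seeded synthetic-community generators with planted, recoverable structure.

The generators emulate the statistical shape of a stratified water-column
survey: K water features (sample groups), each sampled several times, with a
heavy-tailed (log-normal) background of enzyme-function abundances on which
each feature's disjoint set of signature functions is multiplicatively
enriched.  Companion generators produce a pathway catalog with funneling and
ring-fission pathways, MAGs with planted pathway gene content and
block-structured ANI, and recruitment hit tables with controlled
identity/length mass around the (100 bp, 98%) filter.  Every generator is
deterministic given its seed, and ground truth of the planting is returned
so downstream stages can be scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathways import REACTION_TYPES, Pathway, PathwayCatalog, Reaction
from .genomes import HIT_COLUMNS, MAGRecord

__all__ = [
    "CommunityConfig",
    "GroundTruth",
    "simulate_community",
    "simulate_pathway_catalog",
    "simulate_mags",
    "simulate_recruitment",
    "DEFAULT_FEATURES",
]

DEFAULT_FEATURES = ("surface", "SCM", "FDOMmax", "deep")

TAXON_VOCAB = (
    "Alphaproteobacteria",
    "Gammaproteobacteria",
    "Dehalococcoidia",
    "Flavobacteriia",
    "Actinobacteria",
    "Nitrososphaeria",
)

RECA_KO = "K03553"


@dataclass(frozen=True)
class CommunityConfig:
    """Study design of the synthetic community.

    Defaults emulate a four-water-feature survey: 4 groups x 6 samples, 300
    enzyme functions of which 15 per feature are signatures enriched
    ``effect_size``-fold in their home feature, log-normal background
    abundances, fixed library size per sample, multiplicative log-normal
    per-cell noise.
    """

    n_features: int = 4
    samples_per_feature: int = 6
    n_annotations: int = 300
    n_signature_per_feature: int = 15
    effect_size: float = 8.0
    background_mu: float = 1.0
    background_sigma: float = 1.0
    signature_sigma: float = 0.3
    leakage: float = 0.15
    library_reads: float = 1_000_000.0
    noise_sigma: float = 0.7
    n_recA_variants: int = 20
    seed: int | None = None

    def __post_init__(self):
        for name in ("n_features", "samples_per_feature", "n_annotations",
                     "n_signature_per_feature"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.library_reads <= 0:
            raise ValueError("library_reads must be positive")
        if self.noise_sigma < 0 or self.background_sigma < 0 or self.signature_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        if not 0 <= self.leakage < 1:
            raise ValueError("leakage must lie in [0, 1)")
        if self.n_features * self.n_signature_per_feature > self.n_annotations:
            raise ValueError("more signature annotations than annotations")
        if self.seed is None:
            raise ValueError("a seed is required for reproducible simulation")

    @property
    def features(self) -> tuple[str, ...]:
        if self.n_features == len(DEFAULT_FEATURES):
            return DEFAULT_FEATURES
        return tuple(f"feature_{i+1}" for i in range(self.n_features))


@dataclass
class GroundTruth:
    """What was planted: signature homes, intended rank, MAG flags."""

    annotation_home: dict[str, str] = field(default_factory=dict)
    planted_rank: int = 0
    enriched_mags: dict[str, bool] = field(default_factory=dict)
    mag_genomospecies: dict[str, int] = field(default_factory=dict)

    @property
    def signature_annotations(self) -> list[str]:
        return sorted(self.annotation_home)


def _annotation_ids(n: int) -> list[str]:
    return [f"EC{i+1:04d}" for i in range(n)]


def _ko_for(annotation: str) -> str:
    return "K" + annotation[2:].zfill(5)


def simulate_community(config: CommunityConfig):
    """Generate (gene table, sample metadata, ground truth).

    One gene per (annotation, sample); depth = background(annotation) x
    effect x exp(noise).  Signature annotations are disjoint across features
    and enriched ``effect_size``-fold in their home feature's samples; the
    water column is a gradient, so signatures are also mildly elevated
    (``effect_size ** leakage``) in the two adjacent features.  Signature
    backgrounds use the narrower ``signature_sigma`` spread — pathway genes
    sit in the mid-range of abundance, not in the heavy housekeeping tail.
    Each sample additionally carries single-copy recA variants so
    genome-fraction estimates are exercised end to end.
    """
    rng = np.random.default_rng(config.seed)
    features = config.features
    feature_order = {f: i for i, f in enumerate(features)}
    annotations = _annotation_ids(config.n_annotations)
    taxa = rng.choice(TAXON_VOCAB, size=config.n_annotations)

    # disjoint signature blocks, chosen from a shuffled pool
    pool = rng.permutation(config.n_annotations)
    truth = GroundTruth(planted_rank=config.n_features)
    for f_idx, feature in enumerate(features):
        lo = f_idx * config.n_signature_per_feature
        for a_idx in pool[lo: lo + config.n_signature_per_feature]:
            truth.annotation_home[annotations[a_idx]] = feature

    background = rng.lognormal(config.background_mu, config.background_sigma,
                               size=config.n_annotations)
    home_idx = {}  # annotation array position -> home feature position
    for ann, feature in truth.annotation_home.items():
        a_idx = annotations.index(ann)
        background[a_idx] = rng.lognormal(config.background_mu, config.signature_sigma)
        home_idx[a_idx] = feature_order[feature]

    sample_ids, sample_features = [], []
    for feature in features:
        for r in range(config.samples_per_feature):
            sample_ids.append(f"{feature}_{r+1}")
            sample_features.append(feature)

    records = []
    sub_seeds = np.random.SeedSequence(config.seed).spawn(len(sample_ids))
    for sid, feature, sub in zip(sample_ids, sample_features, sub_seeds):
        srng = np.random.default_rng(sub)
        noise = srng.lognormal(0.0, config.noise_sigma, size=config.n_annotations)
        f_pos = feature_order[feature]
        for a_idx, ann in enumerate(annotations):
            if a_idx in home_idx:
                dist = abs(home_idx[a_idx] - f_pos)
                if dist == 0:
                    effect = config.effect_size
                elif dist == 1:
                    effect = config.effect_size**config.leakage
                else:
                    effect = 1.0
            else:
                effect = 1.0
            depth = background[a_idx] * effect * noise[a_idx]
            records.append(
                {
                    "gene_id": f"g_{ann}_{sid}",
                    "sample_id": sid,
                    "depth": depth,
                    "ec_ids": ann,
                    "ko_ids": _ko_for(ann),
                    "taxon": taxa[a_idx],
                    "variant_cluster": f"vc_{ann}",
                    "length_bp": 900,
                }
            )
        # single-copy universal marker variants (recA analog)
        for v in range(config.n_recA_variants):
            records.append(
                {
                    "gene_id": f"g_recA_{v+1}_{sid}",
                    "sample_id": sid,
                    "depth": float(srng.lognormal(config.background_mu, 0.2)),
                    "ec_ids": "",
                    "ko_ids": RECA_KO,
                    "taxon": taxa[v % len(taxa)],
                    "variant_cluster": f"vc_recA_{v+1}",
                    "length_bp": 1050,
                }
            )
    genes = pd.DataFrame(records)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "library_reads": config.library_reads,
            "feature": sample_features,
            "assay": "metagenome",
        }
    )
    return genes, meta, truth


def simulate_pathway_catalog(
    n_pathways: int = 46,
    reactions_per_pathway: int = 5,
    seed: int | None = None,
    ec_pool: list[str] | None = None,
) -> PathwayCatalog:
    """Generate a pathway catalog with funneling and ring-fission classes.

    Each pathway's first reaction carries a ring-attacking type so marker
    selection has priority-1 candidates; when n_pathways >= 5 a handful of
    ECs are deliberately shared between pathway pairs to exercise the
    marker-selection fallback and tie rules.  ``ec_pool`` optionally supplies
    the EC identifiers (e.g. a simulated community's signature annotations)
    instead of fresh synthetic ones.
    """
    if n_pathways < 2:
        raise ValueError("need at least 2 pathways")
    if reactions_per_pathway < 1:
        raise ValueError("reactions_per_pathway must be >= 1")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    n_ecs = n_pathways * reactions_per_pathway
    if ec_pool is None:
        ecs = [f"AEC{i+1:04d}" for i in range(n_ecs)]
    else:
        if len(ec_pool) < n_ecs:
            ecs = [ec_pool[i % len(ec_pool)] for i in range(n_ecs)]
        else:
            ecs = list(ec_pool[:n_ecs])
    ring_types = ("ring-opening", "ring-oxidation", "ring-reduction")
    pathways = []
    for p in range(n_pathways):
        pid = f"PWY{p+1:03d}"
        klass = "funneling" if p % 2 == 0 else "ring_fission"
        origin = "lignin_derived" if rng.random() < 0.8 else "other"
        reactions = []
        for r in range(reactions_per_pathway):
            ec = ecs[p * reactions_per_pathway + r]
            if r == 0:
                types = (str(rng.choice(ring_types)),)
            else:
                types = (str(rng.choice(REACTION_TYPES)),)
            reactions.append(
                Reaction(
                    reaction_id=f"{pid}_RXN{r+1}",
                    ec=ec,
                    types=types,
                    ko="K" + f"{p * reactions_per_pathway + r + 1:05d}",
                )
            )
        pathways.append(
            Pathway(pathway_id=pid, name=f"synthetic pathway {p+1}",
                    pathway_class=klass, origin=origin, reactions=reactions)
        )
    if n_pathways >= 5 and reactions_per_pathway >= 2:
        # plant shared ECs: the last reaction of every third pathway reuses
        # the first EC of its predecessor, forcing marker fallbacks
        for p in range(1, n_pathways, 3):
            donor = pathways[p - 1].reactions[0].ec
            old = pathways[p].reactions[-1]
            pathways[p].reactions[-1] = Reaction(
                reaction_id=old.reaction_id, ec=donor, types=old.types, ko=old.ko
            )
    return PathwayCatalog(pathways)


def simulate_mags(
    config: CommunityConfig,
    catalog: PathwayCatalog,
    seed: int | None = None,
    n_enriched: int = 4,
    n_background: int = 8,
    block_sizes: list[int] | None = None,
):
    """Generate (MAG records, ANI matrix, ground truth).

    Enriched MAGs carry the complete EC sets of most funneling pathways and
    comfortably pass the quality filter; background MAGs carry ECs from
    fewer than half the funneling pathways (median normalized completeness
    0) and straddle the completeness/contamination thresholds.  The ANI
    matrix is block-structured: within planted genomospecies blocks ANI is
    drawn above 95, between blocks below 90.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if not catalog.funneling:
        raise ValueError("catalog has no funneling pathways")
    rng = np.random.default_rng(seed)
    funneling = catalog.funneling
    n_fun = len(funneling)
    truth = GroundTruth(planted_rank=config.n_features)
    mags: list[MAGRecord] = []

    for i in range(n_enriched):
        mag_id = f"MAG_E{i+1:02d}"
        n_complete = max(rng.integers(max(1, math.ceil(0.6 * n_fun)), n_fun + 1), 1)
        chosen = rng.choice(n_fun, size=n_complete, replace=False)
        ecs: list[str] = []
        kos: list[str] = []
        for ci in chosen:
            ecs.extend(sorted(funneling[ci].ecs))
            kos.extend(r.ko for r in funneling[ci].reactions if r.ko)
        # occasional paralogs: duplicate a few annotations
        for _ in range(int(rng.integers(0, 3))):
            ecs.append(str(rng.choice(ecs)))
        mags.append(
            MAGRecord(
                mag_id=mag_id,
                completeness_pct=float(rng.uniform(70, 95)),
                contamination_pct=float(rng.uniform(0, 5)),
                size_kbp=float(rng.uniform(1500, 4500)),
                ecs=tuple(ecs),
                kos=tuple(kos),
                taxonomy=str(rng.choice(TAXON_VOCAB)),
            )
        )
        truth.enriched_mags[mag_id] = True

    max_touched = (n_fun - 1) // 2  # strictly under half keeps the median at 0
    for i in range(n_background):
        mag_id = f"MAG_B{i+1:02d}"
        if i == 0:
            completeness, contamination = 25.0, 2.0  # fails completeness filter
        elif i == 1:
            completeness, contamination = 60.0, 12.0  # fails contamination filter
        else:
            completeness = float(rng.uniform(35, 90))
            contamination = float(rng.uniform(0, 8))
        ecs = []
        kos = []
        if max_touched > 0:
            n_touch = int(rng.integers(0, max_touched + 1))
            for ci in rng.choice(n_fun, size=n_touch, replace=False):
                members = sorted(funneling[ci].ecs)
                take = rng.integers(1, len(members) + 1)
                ecs.extend(members[: int(take)])
        mags.append(
            MAGRecord(
                mag_id=mag_id,
                completeness_pct=completeness,
                contamination_pct=contamination,
                size_kbp=float(rng.uniform(1200, 5000)),
                ecs=tuple(ecs),
                kos=tuple(kos),
                taxonomy=str(rng.choice(TAXON_VOCAB)),
            )
        )
        truth.enriched_mags[mag_id] = False

    n_mags = len(mags)
    if block_sizes is None:
        block_sizes = []
        remaining = n_mags
        while remaining > 0:
            s = int(min(remaining, rng.integers(1, 4)))
            block_sizes.append(s)
            remaining -= s
    if sum(block_sizes) != n_mags:
        raise ValueError("block sizes must sum to the number of MAGs")
    labels = np.concatenate([[b] * s for b, s in enumerate(block_sizes)])
    ani = rng.uniform(80, 88, size=(n_mags, n_mags))
    same = labels[:, None] == labels[None, :]
    within = rng.uniform(96, 99.5, size=(n_mags, n_mags))
    ani = np.where(same, within, ani)
    ani = np.triu(ani, 1)
    ani = ani + ani.T
    np.fill_diagonal(ani, 100.0)
    ids = [m.mag_id for m in mags]
    for m, lab in zip(mags, labels):
        truth.mag_genomospecies[m.mag_id] = int(lab)
    return mags, pd.DataFrame(ani, index=ids, columns=ids), truth


def simulate_recruitment(
    n_reads: int,
    targets: list[str],
    p_pass: float = 0.5,
    multi_target_frac: float = 0.2,
    inject_ties: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a recruitment hit table.

    Every hit independently passes the (>=100 bp, >=98% identity) filter
    with probability ``p_pass``; a ``multi_target_frac`` fraction of reads
    get a second hit against another target with a strictly lower bitscore
    (equal bitscore when ``inject_ties``).
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    rows = []

    def draw_hit(read_id, target, bitscore):
        if rng.random() < p_pass:
            aln = int(rng.integers(100, 161))
            ident = float(rng.uniform(98.0, 100.0))
        else:
            if rng.random() < 0.5:
                aln = int(rng.integers(40, 100))  # too short
                ident = float(rng.uniform(90.0, 100.0))
            else:
                aln = int(rng.integers(100, 161))
                ident = float(rng.uniform(90.0, 97.99))  # too divergent
        rows.append(
            {
                "read_id": read_id,
                "target_id": target,
                "aln_len_bp": aln,
                "pct_identity": ident,
                "bitscore": float(bitscore),
            }
        )

    for i in range(n_reads):
        read_id = f"read_{i+1:06d}"
        primary = str(rng.choice(targets))
        score = float(rng.uniform(100, 200))
        draw_hit(read_id, primary, score)
        if len(targets) > 1 and rng.random() < multi_target_frac:
            others = [t for t in targets if t != primary]
            secondary = str(rng.choice(others))
            sec_score = score if inject_ties else score - float(rng.uniform(5, 50))
            draw_hit(read_id, secondary, sec_score)
    return pd.DataFrame(rows, columns=HIT_COLUMNS)
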