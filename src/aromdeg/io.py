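"""Readers and writers for the pipeline's tab-separated file dialects."""

from __future__ import annotations

import pandas as pd

from .genomes import HIT_COLUMNS, MAGRecord
from .profiles import GENE_TABLE_COLUMNS, validate_gene_table, validate_metadata

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "read_metadata",
    "write_metadata",
    "read_hits",
    "write_hits",
    "read_mags",
    "write_mags",
    "read_ani",
    "write_ani",
]


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str},
                     keep_default_na=False, na_values=[])
    df["depth"] = pd.to_numeric(df["depth"])
    if "length_bp" in df.columns:
        df["length_bp"] = pd.to_numeric(df["length_bp"], errors="coerce")
    return validate_gene_table(df)


def write_gene_table(genes: pd.DataFrame, path) -> None:
    validate_gene_table(genes).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False,
                     na_values=[])
    df["library_reads"] = pd.to_numeric(df["library_reads"])
    return validate_metadata(df)


def write_metadata(meta: pd.DataFrame, path) -> None:
    validate_metadata(meta).to_csv(path, sep="\t", index=False)


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "target_id": str})
    return df[HIT_COLUMNS]


def write_hits(hits: pd.DataFrame, path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_mags(path) -> list[MAGRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    mags = []
    for _, row in df.iterrows():
        ecs = tuple(e for e in str(row.get("ec_ids", "")).split(";") if e)
        kos = tuple(k for k in str(row.get("ko_ids", "")).split(";") if k)
        mags.append(
            MAGRecord(
                mag_id=str(row["mag_id"]),
                completeness_pct=float(row["completeness"]),
                contamination_pct=float(row["contamination"]),
                size_kbp=float(row.get("size_kbp", 0.0) or 0.0),
                ecs=ecs,
                kos=kos,
                taxonomy=str(row.get("taxonomy", "")),
            )
        )
    return mags


def write_mags(mags: list[MAGRecord], path) -> None:
    pd.DataFrame(
        {
            "mag_id": [m.mag_id for m in mags],
            "completeness": [m.completeness_pct for m in mags],
            "contamination": [m.contamination_pct for m in mags],
            "size_kbp": [m.size_kbp for m in mags],
            "ec_ids": [";".join(m.ecs) for m in mags],
            "ko_ids": [";".join(m.kos) for m in mags],
            "taxonomy": [m.taxonomy for m in mags],
        }
    ).to_csv(path, sep="\t", index=False)


def read_ani(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_ani(ani: pd.DataFrame, path) -> None:
    out = ani.copy()
    out.index.name = "mag_id"
    out.to_csv(path, sep="\t")
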