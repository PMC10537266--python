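"""Tab-separated I/O for metadata, virus counts and gene counts.

Gene counts follow the featureCounts layout: a ``Geneid`` column followed
by one column per library.  Virus counts are libraries x viruses with a
``total_reads`` column.  All tables are plain TSV with header rows.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_metadata",
    "write_metadata",
    "read_virus_counts",
    "write_virus_counts",
    "read_gene_counts",
    "write_gene_counts",
    "read_calls",
    "write_calls",
]

META_COLUMNS = ["library_id", "project", "genotype", "tissue", "lane", "sex", "duplicate_id"]


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ("library_id", "project") if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required column(s): {missing}")
    if meta["library_id"].duplicated().any():
        raise ValueError("metadata library_id values must be unique")
    return meta.set_index("library_id", drop=False).rename_axis(None)


def write_metadata(meta: pd.DataFrame, path) -> None:
    cols = [c for c in META_COLUMNS if c in meta.columns]
    meta[cols].to_csv(path, sep="\t", index=False)


def read_virus_counts(path) -> pd.DataFrame:
    vc = pd.read_csv(path, sep="\t", index_col=0)
    return vc


def write_virus_counts(vc: pd.DataFrame, path) -> None:
    vc.rename_axis("library_id").to_csv(path, sep="\t")


def read_gene_counts(path) -> pd.DataFrame:
    gc = pd.read_csv(path, sep="\t")
    if "Geneid" not in gc.columns:
        raise ValueError("gene count table must carry a 'Geneid' column")
    return gc.set_index("Geneid").rename_axis(None)


def write_gene_counts(gc: pd.DataFrame, path) -> None:
    gc.rename_axis("Geneid").to_csv(path, sep="\t")


def read_calls(path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", index_col=0)
    return calls.astype(bool)


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.astype(int).rename_axis("library_id").to_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
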