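"""Readers and writers for the plain-text formats the pipeline consumes and emits.

Internal convention is 0-based, half-open coordinates everywhere.  Bisulfite
coverage files (as written by methylation extractors) are 1-based inclusive and
are converted on read/write; BED is already 0-based half-open.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "read_coverage_file",
    "write_coverage_file",
    "read_bed",
    "write_bed",
    "read_gmt",
    "write_gmt",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
]

_COVERAGE_COLUMNS = ["chrom", "start", "end", "percent", "count_methylated", "count_unmethylated"]


def read_coverage_file(path: str | Path) -> pd.DataFrame:
    """Read a 6-column bisulfite coverage file into 0-based half-open coordinates.

    Columns on disk: chrom, start(1-based), end(inclusive), percent methylation,
    count methylated, count unmethylated.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_COVERAGE_COLUMNS)
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)  # inclusive end == half-open end after start shift
    return df


def write_coverage_file(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-sample coverage file, converting back to 1-based inclusive."""
    out = df[_COVERAGE_COLUMNS].copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file (0-based half-open); extra columns are kept if present."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = names[: df.shape[1]] + [f"col{i}" for i in range(6, df.shape[1])]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str | Path, columns: Sequence[str] | None = None) -> None:
    cols = list(columns) if columns is not None else [c for c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV matrix with the feature id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a CSV sample sheet indexed by sample id (columns e.g. group, total_reads)."""
    return pd.read_csv(path, index_col=0)


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, quoting=csv.QUOTE_MINIMAL)
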