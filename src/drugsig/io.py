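"""Readers and writers for the plain-text formats used throughout the package.

All tabular data travel as TSV/CSV with explicit headers; gene-set
signatures use the GMT convention (one set per line: name, description,
then member genes, tab-separated); fitted models serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_gene_lengths_tsv",
    "write_gene_lengths_tsv",
    "read_auc_tsv",
    "write_auc_tsv",
    "read_gmt",
    "write_gmt",
    "read_growth_curves_csv",
    "write_growth_curves_csv",
    "read_json",
    "write_json",
]


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix; first column holds gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_gene_lengths_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0]
    s.index.name = "gene_id"
    s.name = "length_bp"
    return s


def write_gene_lengths_tsv(lengths: pd.Series, path: str | Path) -> None:
    out = lengths.rename("length_bp")
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_auc_tsv(path: str | Path) -> pd.DataFrame:
    """Per-sample drug response (AUC / activity area), samples in rows."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample_id"
    return df


def write_auc_tsv(auc: pd.DataFrame | pd.Series, path: str | Path) -> None:
    out = auc.to_frame() if isinstance(auc, pd.Series) else auc
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping of set name -> gene list."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *map(str, genes)]) + "\n")


GROWTH_CURVE_COLUMNS = [
    "mouse_id", "model_id", "arm", "day", "volume_mm3", "first_injection_day",
]


def read_growth_curves_csv(path: str | Path) -> pd.DataFrame:
    """Long-format growth curves: one row per (mouse, day) measurement."""
    df = pd.read_csv(path)
    missing = set(GROWTH_CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"growth-curve CSV missing columns: {sorted(missing)}")
    return df


def write_growth_curves_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, GROWTH_CURVE_COLUMNS].to_csv(path, index=False)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
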