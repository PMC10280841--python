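"""Readers and writers for the plain-text formats used across the pipeline.

Expression matrices are genes x samples TSV files whose first column is
``gene_id``; sample metadata is one row per sample; gene sets travel as GMT
(one set per line: name, description, then member genes, tab-separated).
All tables round-trip through :mod:`pandas`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "read_json",
    "write_json",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata TSV indexed by ``sample_id``."""
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    if meta.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> Dict[str, List[str]]:
    """Read a GMT file into ``{set name: member genes}`` (order preserved)."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line in {path}: {line!r}")
            name, _desc, *genes = fields
            sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    """Write JSON with sorted keys so identical objects give identical bytes."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
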