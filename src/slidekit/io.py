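"""Readers and writers for the plain-text interchange formats.

Everything is UTF-8 and tab-delimited: matrices carry a header row of gene
symbols with the first column holding sample identifiers; survival tables
have ``sample_id``/``time``/``event`` columns; pathway collections use the
standard GMT dialect (name, description, genes...).  Numeric output is
written with 6 significant digits.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    GenePair,
    PathwayCollection,
    SurvivalRecord,
    VariantRecord,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_survival",
    "write_survival",
    "read_gmt",
    "write_gmt",
    "read_variants",
    "read_pairs",
    "write_pairs",
    "read_target_map",
    "write_target_map",
    "write_results",
    "read_results",
]

FLOAT_FORMAT = "%.6g"


def read_matrix(path) -> pd.DataFrame:
    """TSV with header of gene symbols and first column of sample ids."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    genes = header[1:]
    if len(set(genes)) != len(genes):
        dups = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"{path}: duplicate gene columns {dups[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample rows {dups[:5]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="sample_id")


def read_survival(path) -> list[SurvivalRecord]:
    """TSV with columns sample_id, time (months), event (0/1)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: survival table needs columns {sorted(required)}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                SurvivalRecord(str(row.sample_id), float(row.time), int(row.event))
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_survival(records: list[SurvivalRecord], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_gmt(path, universe_size: int | None = None) -> PathwayCollection:
    """MSigDB-dialect GMT: name <tab> description <tab> gene1 <tab> gene2..."""
    pathways: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 gene ({len(fields)} fields found)"
                )
            name = fields[0]
            if name in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
            pathways[name] = genes
    return PathwayCollection(pathways, universe_size=universe_size)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.pathways.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_variants(path) -> list[VariantRecord]:
    """Simplified variant TSV: sample_id, gene, consequence and up to five
    predictor columns (``pred1``..``pred5``, 0/1, empty for non-missense)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    required = {"sample_id", "gene", "consequence"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: variant table needs columns {sorted(required)}")
    pred_cols = [c for c in df.columns if c.startswith("pred")]
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        flags: tuple[bool, ...] | None = None
        raw = [getattr(row, c) for c in pred_cols]
        present = [v for v in raw if not (isinstance(v, float) and math.isnan(v))]
        if present:
            flags = tuple(bool(int(v)) for v in present)
        try:
            records.append(
                VariantRecord(str(row.sample_id), str(row.gene), row.consequence, flags)
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def read_pairs(path, series: str | None = None) -> list[GenePair]:
    """TSV with columns gene_a, gene_b and optional series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"}.issubset(df.columns):
        raise ValueError(f"{path}: pair list needs columns gene_a, gene_b")
    has_series = "series" in df.columns
    pairs = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        s = series or (row.series if has_series else "focus")
        try:
            pairs.append(GenePair(row.gene_a, row.gene_b, s))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return pairs


def write_pairs(pairs: list[GenePair], path) -> None:
    pd.DataFrame(
        {
            "gene_a": [p.gene_a for p in pairs],
            "gene_b": [p.gene_b for p in pairs],
            "series": [p.series for p in pairs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_target_map(path) -> dict[str, frozenset[str]]:
    """Long-format TSV: one (drug, target_gene) row per annotation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"drug", "target_gene"}.issubset(df.columns):
        raise ValueError(f"{path}: target map needs columns drug, target_gene")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.drug, set()).add(row.target_gene)
    return {d: frozenset(t) for d, t in out.items()}


def write_target_map(target_map, path) -> None:
    rows = [(d, g) for d, targets in target_map.items() for g in sorted(targets)]
    pd.DataFrame(rows, columns=["drug", "target_gene"]).to_csv(
        path, sep="\t", index=False
    )


def write_results(results: pd.DataFrame, path) -> None:
    """Per-pair results table; stable column order, 6 significant digits."""
    results.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
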