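"""Readers and writers for the pipeline's plain-text formats.

* expression: TSV, genes in rows; first column ``gene_id``, optional second
  column ``gene_symbol``, remaining columns one per sample.
* clinical: CSV with the fixed column set of :class:`~bistrat.types.ClinicalTable`;
  missing values written as ``NA``.
* biclusters: TSV with one record per bicluster
  (``id  score  sample_ids  gene_ids``, id lists comma-separated).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bicluster import Bicluster, BiclusterSet
from .types import ClinicalTable, ExpressionMatrix, FormatError, CLINICAL_COLUMNS

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_biclusters",
    "write_biclusters",
]


def read_expression(path) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "gene_id":
        raise FormatError(f"{path}: first header column must be 'gene_id', got {header[:1]}")
    has_symbol = len(header) > 1 and header[1] == "gene_symbol"
    sample_ids = header[2:] if has_symbol else header[1:]
    dup = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dup:
        raise FormatError(f"{path}: duplicated sample id(s) in header: {sorted(dup)}")

    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_ids = df["gene_id"].tolist()
    symbols = df["gene_symbol"].tolist() if has_symbol else None
    data_cols = df.columns[2:] if has_symbol else df.columns[1:]
    values = np.empty((len(df), len(sample_ids)), dtype=float)
    for j, col in enumerate(data_cols):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or converted.isna().any():
            i = int(np.flatnonzero(converted.isna())[0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} at gene "
                f"{gene_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(gene_ids, sample_ids, values, symbols)


def write_expression(x: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        cols = ["gene_id"] + (["gene_symbol"] if x.gene_symbols is not None else [])
        fh.write("\t".join(cols + list(map(str, x.sample_ids))) + "\n")
        for i, g in enumerate(x.gene_ids):
            row = [str(g)]
            if x.gene_symbols is not None:
                row.append(str(x.gene_symbols[i]))
            row.extend(format(v, ".10g") for v in x.values[i])
            fh.write("\t".join(row) + "\n")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: clinical CSV missing columns {missing}")
    for col in ["size_mm", "age_years", "dfs_time_years"]:
        df[col] = pd.to_numeric(df[col].replace("NA", np.nan), errors="raise")
    df["dfs_event"] = pd.to_numeric(df["dfs_event"], errors="raise")
    return ClinicalTable(df)


def write_clinical(t: ClinicalTable, path) -> None:
    df = t.df.copy()
    for col in ["size_mm", "age_years"]:
        df[col] = df[col].map(lambda v: "NA" if pd.isna(v) else format(v, ".10g"))
    df["dfs_time_years"] = df["dfs_time_years"].map(lambda v: format(v, ".10g"))
    df.to_csv(path, index=False)


_BC_HEADER = "id\tscore\tsample_ids\tgene_ids"


def write_biclusters(bcs: BiclusterSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(_BC_HEADER + "\n")
        for b in bcs:
            fh.write(
                f"{b.id}\t{format(b.score, '.10g')}\t"
                f"{','.join(sorted(map(str, b.sample_ids)))}\t"
                f"{','.join(sorted(map(str, b.gene_ids)))}\n"
            )


def read_biclusters(path, expression: ExpressionMatrix | None = None) -> BiclusterSet:
    """Read a bicluster record file; optionally validate ids against a matrix."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _BC_HEADER:
            raise FormatError(f"{path}: unexpected bicluster file header {header!r}")
        bcs = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
            bid, score, samples, genes = parts
            bcs.append(
                Bicluster(
                    id=int(bid),
                    sample_ids=frozenset(samples.split(",")) if samples else frozenset(),
                    gene_ids=frozenset(genes.split(",")) if genes else frozenset(),
                    score=float(score),
                )
            )
    result = BiclusterSet(bcs)
    if expression is not None:
        known_s = set(map(str, expression.sample_ids))
        known_g = set(map(str, expression.gene_ids))
        for b in result:
            bad_s = set(b.sample_ids) - known_s
            bad_g = set(b.gene_ids) - known_g
            if bad_s:
                raise FormatError(
                    f"bicluster {b.id} references unknown sample id(s): {sorted(bad_s)[:5]}"
                )
            if bad_g:
                raise FormatError(
                    f"bicluster {b.id} references unknown gene id(s): {sorted(bad_g)[:5]}"
                )
    return result
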