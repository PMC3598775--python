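"""Core in-memory containers: expression matrices and clinical tables.

An :class:`ExpressionMatrix` holds log2 intensities with genes in rows and
samples in columns (microarray convention). A :class:`ClinicalTable` wraps a
pandas DataFrame of per-sample clinico-pathological covariates plus
disease-free-survival (DFS) outcome, with controlled vocabularies for the
categorical columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "ClinicalTable", "FormatError", "CLINICAL_VOCAB"]


class FormatError(ValueError):
    """A file or table violates the expected format or vocabulary."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Dense genes x samples matrix of log2 intensities."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    gene_symbols: list | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if self.gene_symbols is not None:
            self.gene_symbols = list(self.gene_symbols)
            if len(self.gene_symbols) != len(self.gene_ids):
                raise FormatError("gene_symbols length does not match gene_ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown gene id {e.args[0]!r}") from None

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def subset_genes(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx],
            self.sample_ids,
            self.values[idx],
            None if self.gene_symbols is None else [self.gene_symbols[i] for i in idx],
        )

    def subset_samples(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            self.gene_ids,
            [self.sample_ids[i] for i in idx],
            self.values[:, idx],
            self.gene_symbols,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def equals(self, other: "ExpressionMatrix", atol: float = 0.0) -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, atol=atol, rtol=0)
        )


#: Allowed categories per clinical column ("NA" = missing).
CLINICAL_VOCAB = {
    "ln_status": ["LN+", "LN-", "NA"],
    "er_status": ["ER+", "ER-", "NA"],
    "pgr_status": ["PgR+", "PgR-", "NA"],
    "grade": ["G1", "G2", "G3", "NA"],
    "subtype": ["Basal", "Her2", "LumA", "LumB", "Normal", "None", "NA"],
}

CLINICAL_COLUMNS = [
    "sample_id",
    "cohort",
    "ln_status",
    "er_status",
    "pgr_status",
    "grade",
    "subtype",
    "size_mm",
    "age_years",
    "dfs_time_years",
    "dfs_event",
]


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation and DFS outcome.

    Columns: sample_id, cohort, ln_status, er_status, pgr_status, grade,
    subtype, size_mm, age_years, dfs_time_years, dfs_event. Categorical
    values are validated against :data:`CLINICAL_VOCAB`; numeric missing
    values are NaN.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        df = df[CLINICAL_COLUMNS].reset_index(drop=True)
        _check_unique(df["sample_id"].tolist(), "sample id")
        for col, vocab in CLINICAL_VOCAB.items():
            vals = df[col].astype(str)
            bad = sorted(set(vals) - set(vocab))
            if bad:
                raise FormatError(
                    f"column {col!r}: value(s) {bad} not in allowed vocabulary {vocab}"
                )
            df[col] = vals
        for col in ["size_mm", "age_years", "dfs_time_years"]:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        for col in ["size_mm", "age_years"]:
            if (df[col].dropna() < 0).any():
                bad_id = df.loc[df[col] < 0, "sample_id"].iloc[0]
                raise FormatError(f"negative {col} for sample {bad_id!r}")
        if df["dfs_time_years"].isna().any():
            bad_id = df.loc[df["dfs_time_years"].isna(), "sample_id"].iloc[0]
            raise FormatError(f"missing dfs_time_years for sample {bad_id!r}")
        if (df["dfs_time_years"] < 0).any():
            bad_id = df.loc[df["dfs_time_years"] < 0, "sample_id"].iloc[0]
            raise FormatError(f"negative dfs_time_years for sample {bad_id!r}")
        ev = pd.to_numeric(df["dfs_event"], errors="raise")
        if not ev.isin([0, 1]).all():
            bad_id = df.loc[~ev.isin([0, 1]), "sample_id"].iloc[0]
            raise FormatError(f"dfs_event not in {{0,1}} for sample {bad_id!r}")
        df["dfs_event"] = ev.astype(int)
        self.df = df

    @property
    def sample_ids(self) -> list:
        return self.df["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.df)

    def row(self, sample_id) -> pd.Series:
        sub = self.df[self.df["sample_id"] == sample_id]
        if sub.empty:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return sub.iloc[0]

    def survival_arrays(self, sample_ids=None):
        """(times, events) for all samples or an ordered id subset.

        Repeated ids are allowed (size-matched random groups are drawn with
        replacement) and yield repeated rows.
        """
        if sample_ids is None:
            sub = self.df
        else:
            indexed = self.df.set_index("sample_id")
            try:
                sub = indexed.loc[list(sample_ids)]
            except KeyError as e:
                raise KeyError(f"unknown sample id in group: {e.args[0]!r}") from None
        return (
            sub["dfs_time_years"].to_numpy(float),
            sub["dfs_event"].to_numpy(int),
        )

    def subset(self, sample_ids) -> "ClinicalTable":
        indexed = self.df.set_index("sample_id", drop=False)
        return ClinicalTable(indexed.loc[list(sample_ids)].reset_index(drop=True))
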