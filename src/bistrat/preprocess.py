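"""Expression preprocessing: noise filter, probe collapse, batch adjustment.

Three steps mirror standard microarray practice for a multi-cohort
compendium: (1) drop genes never expressed above a noise floor in at least
a minimum fraction of arrays; (2) collapse multiple probes per gene symbol
to the probe best correlated with the symbol's per-sample median profile;
(3) remove per-cohort location/scale batch effects gene by gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import ExpressionMatrix

__all__ = ["FilterSpec", "filter_low_expression", "collapse_probes", "adjust_batch",
           "default_noise_threshold"]


@dataclass
class FilterSpec:
    noise_threshold: float
    min_expressed_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not np.isfinite(self.noise_threshold) and self.noise_threshold != -np.inf:
            raise ValueError("noise_threshold must be finite or -inf")
        if not 0 < self.min_expressed_fraction <= 1:
            raise ValueError("min_expressed_fraction must be in (0, 1]")


def default_noise_threshold(x: ExpressionMatrix, quantile: float = 0.20) -> float:
    """Data-driven noise floor: a low quantile of all intensities.

    Stands in for a spike-in-derived floor when control-probe signals are
    not part of the matrix.
    """
    return float(np.quantile(x.values, quantile))


def filter_low_expression(x: ExpressionMatrix, spec: FilterSpec) -> ExpressionMatrix:
    """Keep genes above the noise threshold in at least
    ``ceil(min_expressed_fraction * n_samples)`` samples (boundary
    inclusive: exactly that many samples suffices)."""
    if x.n_genes == 0 or x.n_samples == 0:
        raise ValueError("cannot filter an empty expression matrix")
    need = int(np.ceil(spec.min_expressed_fraction * x.n_samples))
    n_above = (x.values > spec.noise_threshold).sum(axis=1)
    keep = np.flatnonzero(n_above >= need)
    if len(keep) == 0:
        raise ValueError(
            f"noise filter removed all {x.n_genes} genes "
            f"(threshold {spec.noise_threshold}, >= {need} samples required)"
        )
    return x.subset_genes(keep)


def collapse_probes(x: ExpressionMatrix) -> ExpressionMatrix:
    """One probe per gene symbol: the probe most correlated with the
    per-sample median of all probes sharing that symbol.

    Requires ``gene_symbols``; probes without a symbol must already have
    been removed by the caller. Ties (and all-zero-variance symbol groups)
    are broken by lexicographic gene_id. Zero-variance probes get
    correlation -inf so they are never preferred over an informative probe.
    """
    if x.gene_symbols is None:
        raise ValueError("collapse_probes requires gene_symbols")
    by_symbol: dict = {}
    for i, sym in enumerate(x.gene_symbols):
        by_symbol.setdefault(sym, []).append(i)
    keep = []
    for sym, idx in by_symbol.items():
        if len(idx) == 1:
            keep.append(idx[0])
            continue
        block = x.values[idx]
        median = np.median(block, axis=0)
        med_sd = median.std()
        best: tuple = ()
        for i in idx:
            row = x.values[i]
            sd = row.std()
            if sd == 0 or med_sd == 0:
                corr = -np.inf
            else:
                corr = float(np.corrcoef(row, median)[0, 1])
            key = (corr, _NegStr(str(x.gene_ids[i])))
            if not best or key > best[0]:
                best = (key, i)
        keep.append(best[1])
    keep.sort()  # preserve original row order
    return x.subset_genes(keep)


class _NegStr(str):
    """String with reversed ordering, so max() prefers lexicographically
    smaller gene_ids on correlation ties."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def adjust_batch(x: ExpressionMatrix, cohort) -> ExpressionMatrix:
    """Remove per-(gene, cohort) location and scale differences.

    Each gene is standardised within each cohort (subtract cohort mean,
    divide by cohort sd) and restored to the gene's pooled mean and sd, so
    that after adjustment every cohort has the same per-gene mean and
    variance. This is a moment-matching location/scale batch correction
    (no empirical-Bayes shrinkage of the batch parameters); it exactly
    inverts additive-shift plus multiplicative-scale batch effects.
    """
    cohort = np.asarray(cohort)
    if len(cohort) != x.n_samples:
        raise ValueError("cohort labels must match number of samples")
    levels, inv = np.unique(cohort, return_inverse=True)
    counts = np.bincount(inv)
    if (counts < 2).any():
        bad = levels[counts < 2]
        raise ValueError(
            f"cohort(s) {bad.tolist()} have a single sample; merge or exclude "
            "them before batch adjustment"
        )
    vals = x.values
    adjusted = np.empty_like(vals)
    pooled_mean = vals.mean(axis=1, keepdims=True)
    pooled_sd = vals.std(axis=1, keepdims=True)
    for c in range(len(levels)):
        cols = np.flatnonzero(inv == c)
        sub = vals[:, cols]
        m = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        zero = sd[:, 0] == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} gene(s) constant within cohort {levels[c]!r}; "
                "location-only adjustment applied for them"
            )
            sd[zero, 0] = 1.0
        z = (sub - m) / sd
        adjusted[:, cols] = z * np.where(pooled_sd > 0, pooled_sd, 1.0) + pooled_mean
    return ExpressionMatrix(x.gene_ids, x.sample_ids, adjusted, x.gene_symbols)
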