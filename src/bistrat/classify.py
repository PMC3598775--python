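"""Minimal gene classifiers for bicluster pairs.

Nearest-shrunken-centroid classification (PAM): per-gene class-centroid
differences are standardised by the pooled within-class sd (plus a fudge
constant s0) and soft-thresholded by an amount Delta; cross-validation
over a Delta grid picks the sparsest classifier attaining the lowest
misclassification error. Also provides the two-sample t-test /
fold-change volcano screen for differential expression between two
tumour groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ShrunkenCentroidModel",
    "DEResult",
    "fit_shrunken_centroids",
    "predict_class",
    "differential_expression",
    "volcano_select",
    "storey_qvalues",
]


@dataclass
class ShrunkenCentroidModel:
    class_labels: list
    gene_ids: list
    overall_centroid: np.ndarray
    shrunken_centroids: np.ndarray  # genes x 2
    delta: float
    pooled_sd: np.ndarray
    s0: float
    priors: np.ndarray
    surviving_genes: list
    cv_curve: pd.DataFrame = field(repr=False)  # delta, cv_error, n_genes


def _shrink(dbar, mk, sd, s0, delta):
    """Soft-threshold standardised centroid differences by delta."""
    denom = mk[None, :] * (sd + s0)[:, None]
    d = dbar / denom
    d_shr = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    return d_shr * denom


def _centroid_stats(x, y, labels):
    """Centroids and pooled within-class sd for a genes x samples matrix."""
    n = x.shape[1]
    centroids = np.stack([x[:, y == k].mean(axis=1) for k in range(2)], axis=1)
    overall = x.mean(axis=1)
    ss = sum(((x[:, y == k] - centroids[:, [k]]) ** 2).sum(axis=1) for k in range(2))
    sd = np.sqrt(ss / (n - 2))
    nk = np.array([(y == k).sum() for k in range(2)])
    mk = np.sqrt(1.0 / nk - 1.0 / n)
    return centroids, overall, sd, mk, nk


def fit_shrunken_centroids(x, labels, delta_grid=None, gene_ids=None,
                           n_folds: int = 10, priors: str = "equal",
                           seed: int = 0) -> ShrunkenCentroidModel:
    """Fit a two-class nearest-shrunken-centroid classifier.

    ``x`` is genes x samples; ``labels`` holds exactly two classes with at
    least 3 samples each. The selected Delta is the largest value on the
    grid attaining the minimal cross-validated misclassification error
    (fewest surviving genes at the best error). ``s0`` is the median of
    the pooled within-class sds.
    """
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    class_labels = sorted(set(labels.tolist()), key=str)
    if len(class_labels) != 2:
        raise ValueError(f"exactly 2 classes required, got {class_labels}")
    y = np.array([class_labels.index(l) for l in labels])
    nk = np.array([(y == k).sum() for k in range(2)])
    if nk.min() < 3:
        raise ValueError(f"each class needs >= 3 samples, got counts {nk.tolist()}")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(x.shape[0])]

    centroids, overall, sd, mk, nk = _centroid_stats(x, y, class_labels)
    s0 = float(np.median(sd))
    dbar = centroids - overall[:, None]
    if delta_grid is None:
        dmax = float(np.max(np.abs(dbar / (mk[None, :] * (sd + s0)[:, None]))))
        delta_grid = np.linspace(0.0, dmax, 30)
    delta_grid = np.sort(np.asarray(delta_grid, float))

    pri = np.array([0.5, 0.5]) if priors == "equal" else nk / nk.sum()

    # cross-validated error per delta (LOO when a class is small)
    loo = nk.min() < n_folds
    splits = (
        [(np.delete(np.arange(len(y)), i), np.array([i])) for i in range(len(y))]
        if loo
        else list(
            StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed).split(
                np.zeros(len(y)), y
            )
        )
    )
    errors = np.zeros(len(delta_grid))
    for tr, te in splits:
        c_tr, o_tr, sd_tr, mk_tr, _ = _centroid_stats(x[:, tr], y[tr], class_labels)
        s0_tr = float(np.median(sd_tr))
        dbar_tr = c_tr - o_tr[:, None]
        for di, delta in enumerate(delta_grid):
            shr = o_tr[:, None] + _shrink(dbar_tr, mk_tr, sd_tr, s0_tr, delta)
            pred = _discriminant_labels(x[:, te], shr, sd_tr, s0_tr, pri)
            errors[di] += int((pred != y[te]).sum())
    errors /= len(y)

    best_err = errors.min()
    delta = float(delta_grid[np.flatnonzero(errors == best_err).max()])
    shrunk_diff = _shrink(dbar, mk, sd, s0, delta)
    shrunken = overall[:, None] + shrunk_diff
    surviving = [gene_ids[i] for i in np.flatnonzero(np.any(shrunk_diff != 0, axis=1))]
    cv = pd.DataFrame(
        {
            "delta": delta_grid,
            "cv_error": errors,
            "n_genes": [
                int(np.any(_shrink(dbar, mk, sd, s0, d) != 0, axis=1).sum())
                for d in delta_grid
            ],
        }
    )
    return ShrunkenCentroidModel(
        class_labels=class_labels,
        gene_ids=list(gene_ids),
        overall_centroid=overall,
        shrunken_centroids=shrunken,
        delta=delta,
        pooled_sd=sd,
        s0=s0,
        priors=pri,
        surviving_genes=surviving,
        cv_curve=cv,
    )


def _discriminant_labels(x_te, centroids, sd, s0, priors):
    scores = _discriminant_scores(x_te, centroids, sd, s0, priors)
    # ties -> first class (argmin returns the first minimum)
    return np.argmin(scores, axis=1)


def _discriminant_scores(x_te, centroids, sd, s0, priors):
    w = 1.0 / (sd + s0) ** 2
    return np.stack(
        [
            (w[:, None] * (x_te - centroids[:, [k]]) ** 2).sum(axis=0)
            - 2 * np.log(priors[k])
            for k in range(2)
        ],
        axis=1,
    )


def predict_class(model: ShrunkenCentroidModel, sample_profile):
    """Classify one sample profile; returns (label, discriminant scores).

    The profile must cover every model gene (no imputation); the label
    minimises the standardised squared distance to the shrunken centroid
    minus twice the log prior, ties going to the first class label.
    """
    profile = np.asarray(sample_profile, float)
    if profile.shape != (len(model.gene_ids),):
        raise ValueError(
            f"profile must cover the model's {len(model.gene_ids)} genes, "
            f"got shape {profile.shape}"
        )
    if np.any(~np.isfinite(profile)):
        raise ValueError("missing (non-finite) gene value in sample profile")
    scores = _discriminant_scores(
        profile[:, None], model.shrunken_centroids, model.pooled_sd, model.s0, model.priors
    )[0]
    return model.class_labels[int(np.argmin(scores))], scores


@dataclass
class DEResult:
    table: pd.DataFrame = field(repr=False)
    # columns: gene_id, t, p, log2fc, p_bh, q


def storey_qvalues(p, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the single-lambda pi0 plug-in estimate."""
    p = np.asarray(p, float)
    m = len(p)
    if m == 0:
        return p.copy()
    pi0 = min(1.0, (p > lam).sum() / ((1 - lam) * m))
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pi0 * p[i] * m / rank)
        q[i] = prev
    return q


def differential_expression(x, group_a, group_b, gene_ids=None,
                            welch: bool = False) -> DEResult:
    """Per-gene two-sample t-test between sample groups of a genes x
    samples matrix (columns indexed by ``group_a`` / ``group_b``).

    log2 fold change is mean(A) - mean(B) (inputs are log2 intensities).
    p-values are BH-adjusted and Storey q-values added. Genes constant and
    equal in both groups get t = 0, p = 1.
    """
    x = np.asarray(x, float)
    a = x[:, np.asarray(group_a, int)]
    b = x[:, np.asarray(group_b, int)]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(x.shape[0])]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    fc = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    same = degenerate & (np.abs(fc) < 1e-300)
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, p)
    diff_const = degenerate & ~same
    t = np.where(diff_const, np.sign(fc) * np.inf, t)
    p = np.where(diff_const, 0.0, p)
    p_bh = multipletests(p, method="fdr_bh")[1] if len(p) else p
    q = storey_qvalues(p)
    return DEResult(
        pd.DataFrame(
            {"gene_id": gene_ids, "t": t, "p": p, "log2fc": fc, "p_bh": p_bh, "q": q}
        )
    )


def volcano_select(de: DEResult, p_cut: float = 0.05, fc_cut: float = 2.0) -> list:
    """Genes with p < p_cut and at least ``fc_cut``-fold change
    (|log2fc| >= log2(fc_cut), boundary inclusive)."""
    t = de.table
    mask = (t["p"] < p_cut) & (t["log2fc"].abs() >= np.log2(fc_cut))
    return t.loc[mask, "gene_id"].tolist()
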