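"""Bicluster-augmented early-relapse prediction.

Patients are dichotomised into early relapse (event within ``early_cutoff``
years), late relapse (relapse-free through ``late_cutoff`` years) and
intermediate. Clinical covariates are discretised into the standard
categorical classes, bicluster membership enters as one binary indicator
per bicluster, and two predictors are compared with and without the
bicluster indicators:

* a conditional-inference tree (recursive binary partitioning; each split
  is chosen by a Bonferroni-adjusted Monte-Carlo permutation chi-square
  test of covariate-label association), and
* a ridge-penalised Cox model scored by time-dependent (cumulative/dynamic)
  AUC.

Test tumours are assigned to training-derived biclusters by Pearson
correlation with each bicluster's first-principal-component gene profile.
The 50-split stratified cross-validation harness ties these together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from ._rng import stage_rng
from .bicluster import Bicluster, BiclusterSet, run_biclustering
from .config import RunConfig
from .survival import _breslow_quantities, cox_fit, km_estimate
from .types import ClinicalTable, ExpressionMatrix

__all__ = [
    "dichotomize",
    "encode_covariates",
    "ConditionalTree",
    "TreeNode",
    "fit_conditional_tree",
    "predict_tree",
    "render_tree",
    "bicluster_pc1_profile",
    "assign_to_biclusters",
    "AssignResult",
    "ridge_cox_predict",
    "RidgeCoxResult",
    "time_dependent_auc",
    "cross_validate",
    "CVReport",
]

SIZE_CLASSES = ["<10", "10-20", "20-40", ">=40"]
AGE_CLASSES = ["<40", "40-50", "50-60", ">=60"]


def dichotomize(clinical: ClinicalTable, early_cutoff: float = 2.0,
                late_cutoff: float = 8.0) -> pd.Series:
    """Early/late/intermediate relapse label per sample.

    early: relapse event with DFS time <= early_cutoff; late: DFS time >=
    late_cutoff (event or censored); everything else - including patients
    censored before the early cutoff, who are not confirmed relapses - is
    intermediate.
    """
    if not early_cutoff < late_cutoff:
        raise ValueError("early_cutoff must be < late_cutoff")
    t = clinical.df["dfs_time_years"].to_numpy(float)
    e = clinical.df["dfs_event"].to_numpy(int)
    lab = np.where(
        (e == 1) & (t <= early_cutoff), "early", np.where(t >= late_cutoff, "late", "intermediate")
    )
    return pd.Series(lab, index=clinical.sample_ids, name="relapse_label")


def _size_class(v: float) -> str:
    if np.isnan(v):
        return "NA"
    if v < 10:
        return SIZE_CLASSES[0]
    if v < 20:
        return SIZE_CLASSES[1]
    if v < 40:
        return SIZE_CLASSES[2]
    return SIZE_CLASSES[3]


def _age_class(v: float) -> str:
    if np.isnan(v):
        return "NA"
    if v < 40:
        return AGE_CLASSES[0]
    if v < 50:
        return AGE_CLASSES[1]
    if v < 60:
        return AGE_CLASSES[2]
    return AGE_CLASSES[3]


def encode_covariates(clinical: ClinicalTable,
                      membership: pd.DataFrame | None = None) -> pd.DataFrame:
    """Categorical covariate frame per sample (index = sample_id).

    Columns: er_status, pgr_status, ln_status, grade (categorical
    strings, NA kept as an explicit level), size_class and age_class
    (fixed bins), plus one 0/1 column ``bc_<id>`` per bicluster when a
    membership indicator frame is given (rows indexed by sample_id).
    """
    df = clinical.df
    out = pd.DataFrame(
        {
            "er_status": df["er_status"].to_numpy(),
            "pgr_status": df["pgr_status"].to_numpy(),
            "ln_status": df["ln_status"].to_numpy(),
            "grade": df["grade"].to_numpy(),
            "size_class": [_size_class(v) for v in df["size_mm"]],
            "age_class": [_age_class(v) for v in df["age_years"]],
        },
        index=df["sample_id"].tolist(),
    )
    if membership is not None:
        memb = membership.reindex(out.index).fillna(0).astype(int)
        memb.columns = [f"bc_{c}" for c in memb.columns]
        out = pd.concat([out, memb], axis=1)
    return out


# ---------------------------------------------------------------------------
# conditional-inference tree
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    n: int
    class_counts: dict
    majority: object
    depth: int
    covariate: str | None = None
    p_adjusted: float | None = None
    left_categories: frozenset | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    trimmed_candidate: tuple | None = None  # (covariate, p_adj) with alpha <= p < trim

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class ConditionalTree:
    root: TreeNode
    class_labels: list
    alpha: float
    trim_level: float
    min_leaf: int


def _chi2_2xc(counts1: np.ndarray, totals: np.ndarray, total1: int):
    """Pearson chi-square of a (categories x 2) table.

    ``counts1`` holds per-category counts of label 1 (may be a (B, c)
    matrix of permuted counts), ``totals`` the per-category sizes.
    """
    n = totals.sum()
    p1 = total1 / n
    if p1 <= 0 or p1 >= 1:
        return np.zeros(counts1.shape[:-1]) if counts1.ndim > 1 else 0.0
    e1 = totals * p1
    e0 = totals - e1
    w = 1.0 / e1 + 1.0 / e0
    dev = (counts1 - e1) ** 2
    return (dev * w).sum(axis=-1)


def _permutation_p(cov_values: np.ndarray, y: np.ndarray, perm_y: np.ndarray):
    """Monte-Carlo permutation p for label-covariate association."""
    cats, inv = np.unique(cov_values, return_inverse=True)
    if len(cats) < 2:
        return None
    onehot = np.zeros((len(y), len(cats)))
    onehot[np.arange(len(y)), inv] = 1.0
    totals = onehot.sum(axis=0)
    obs = _chi2_2xc(y @ onehot, totals, int(y.sum()))
    perm = _chi2_2xc(perm_y @ onehot, totals, int(y.sum()))
    p = (1.0 + np.sum(perm >= obs - 1e-12)) / (len(perm_y) + 1.0)
    return float(p), float(obs), cats, inv


def _best_subset(cats, inv, y, min_leaf):
    """Binary split of categories maximising the 2x2 chi-square, subject to
    both children having >= min_leaf samples. Exhaustive for <= 8
    categories, else greedy over prefixes of categories ordered by
    label-1 rate."""
    c = len(cats)
    n = len(y)
    counts1 = np.array([y[inv == i].sum() for i in range(c)], float)
    totals = np.array([(inv == i).sum() for i in range(c)], float)
    if c <= 8:
        subsets = [
            [i for i in range(c) if mask >> i & 1]
            for mask in range(1, 2 ** (c - 1))  # canonical: category c-1 stays right
        ]
    else:
        rate = counts1 / np.maximum(totals, 1)
        order = np.argsort(rate)
        subsets = [order[: k + 1].tolist() for k in range(c - 1)]
    best = None
    for sub in subsets:
        n_left = totals[sub].sum()
        if n_left < min_leaf or n - n_left < min_leaf:
            continue
        stat = _chi2_2xc(
            np.array([counts1[sub].sum(), counts1.sum() - counts1[sub].sum()]),
            np.array([n_left, n - n_left]),
            int(y.sum()),
        )
        if best is None or stat > best[0]:
            best = (stat, sub)
    if best is None:
        return None
    return frozenset(cats[i] for i in best[1])


def _grow(cov: pd.DataFrame, y: np.ndarray, labels, alpha, trim, min_leaf, n_perm,
          rng, depth) -> TreeNode:
    counts = {labels[0]: int((y == 0).sum()), labels[1]: int((y == 1).sum())}
    majority = labels[0] if counts[labels[0]] >= counts[labels[1]] else labels[1]
    node = TreeNode(n=len(y), class_counts=counts, majority=majority, depth=depth)
    if len(y) < 2 * min_leaf or len(set(y.tolist())) < 2:
        return node

    perm_y = rng.permuted(np.tile(y.astype(float), (n_perm, 1)), axis=1)
    results = {}
    for col in cov.columns:
        res = _permutation_p(cov[col].to_numpy(), y.astype(float), perm_y)
        if res is not None:
            results[col] = res
    if not results:
        return node
    m = len(results)
    adj = {col: min(1.0, r[0] * m) for col, r in results.items()}
    best_col = min(adj, key=lambda c: (adj[c], c))
    p_adj = adj[best_col]
    if p_adj >= alpha:
        if p_adj < trim:
            node.trimmed_candidate = (best_col, p_adj)
        return node
    _, _, cats, inv = results[best_col]
    left_cats = _best_subset(cats, inv, y, min_leaf)
    if left_cats is None:
        return node
    mask = cov[best_col].isin(left_cats).to_numpy()
    node.covariate = best_col
    node.p_adjusted = p_adj
    node.left_categories = left_cats
    node.left = _grow(cov[mask], y[mask], labels, alpha, trim, min_leaf, n_perm, rng, depth + 1)
    node.right = _grow(cov[~mask], y[~mask], labels, alpha, trim, min_leaf, n_perm, rng,
                       depth + 1)
    return node


def fit_conditional_tree(covariates: pd.DataFrame, labels, alpha: float = 0.05,
                         min_leaf: int = 7, n_permutations: int = 9999,
                         trim_level: float = 0.5, seed: int = 0) -> ConditionalTree:
    """Recursive binary partitioning with permutation-test split selection.

    At each node every categorical covariate is tested against the binary
    label by a Monte-Carlo permutation chi-square test (one shared set of
    ``n_permutations`` label permutations per node); p-values are
    Bonferroni-adjusted over the covariates tested and the node splits on
    the smallest adjusted p if it falls below ``alpha``. Candidates with
    alpha <= p < ``trim_level`` are recorded for display but never split.
    """
    labels = np.asarray(labels)
    class_labels = sorted(set(labels.tolist()), key=str)
    if len(class_labels) == 1:
        y = np.zeros(len(labels), dtype=int)
        class_labels = [class_labels[0], class_labels[0]]
    elif len(class_labels) == 2:
        y = (labels == class_labels[1]).astype(int)
    else:
        raise ValueError(f"binary labels required, got {class_labels}")
    if len(labels) < 2 * min_leaf:
        raise ValueError(f"need >= {2 * min_leaf} samples to fit a tree")
    cov = covariates.astype(str)
    rng = stage_rng(seed, "ctree")
    root = _grow(cov, y, class_labels, alpha, trim_level, min_leaf, n_permutations, rng, 0)
    return ConditionalTree(root, class_labels, alpha, trim_level, min_leaf)


def predict_tree(tree: ConditionalTree, covariates: pd.DataFrame) -> np.ndarray:
    """Leaf-majority label per row; unseen categories route right."""
    cov = covariates.astype(str)
    out = []
    for _, row in cov.iterrows():
        node = tree.root
        while not node.is_leaf:
            node = node.left if row[node.covariate] in node.left_categories else node.right
        out.append(node.majority)
    return np.asarray(out)


def render_tree(tree: ConditionalTree) -> str:
    lines = []

    def walk(node: TreeNode, indent: str, branch: str):
        if node.is_leaf:
            extra = ""
            if node.trimmed_candidate:
                extra = f" [trimmed: {node.trimmed_candidate[0]} p={node.trimmed_candidate[1]:.3g}]"
            lines.append(
                f"{indent}{branch}leaf n={node.n} {node.class_counts} -> {node.majority}{extra}"
            )
            return
        lines.append(
            f"{indent}{branch}{node.covariate} (p={node.p_adjusted:.3g}) "
            f"in {sorted(node.left_categories)}?"
        )
        walk(node.left, indent + "  ", "yes: ")
        walk(node.right, indent + "  ", "no:  ")

    walk(tree.root, "", "")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# bicluster assignment of test tumours
# ---------------------------------------------------------------------------


def bicluster_pc1_profile(x: ExpressionMatrix, b: Bicluster) -> pd.Series:
    """First-principal-component gene profile of a bicluster.

    First right singular vector of the bicluster's samples x genes
    submatrix (samples as observations, genes as variables), sign-fixed to
    correlate non-negatively with the bicluster's mean gene profile,
    indexed by the bicluster's genes. The submatrix is deliberately *not*
    column-centred: member tumours share one expression signature, so the
    leading uncentred axis is that common profile, whereas the centred
    axis would capture only within-group noise for a homogeneous group.
    For an exactly rank-one block ``x_{t,g} = a_t p_g`` the profile is
    proportional to ``p``.
    """
    s_idx = x.sample_index(sorted(b.sample_ids))
    g_idx = x.gene_index(sorted(b.gene_ids))
    if len(s_idx) < 2 or len(g_idx) < 2:
        raise ValueError("bicluster_pc1_profile requires >= 2 samples and >= 2 genes")
    gene_ids = [x.gene_ids[i] for i in g_idx]
    sub = x.values[np.ix_(g_idx, s_idx)].T
    mean_profile = sub.mean(axis=0)
    if np.allclose(sub, 0.0):
        warnings.warn("zero-variance bicluster submatrix; returning mean profile")
        return pd.Series(mean_profile, index=gene_ids)
    _, _, vt = np.linalg.svd(sub, full_matrices=False)
    profile = vt[0]
    if mean_profile.std() > 0 and profile.std() > 0:
        sign = np.corrcoef(profile, mean_profile)[0, 1]
    else:
        sign = float(profile @ mean_profile)
    if sign < 0:
        profile = -profile
    return pd.Series(profile, index=gene_ids)


@dataclass
class AssignResult:
    ids: frozenset
    fallback: bool
    correlations: dict


def assign_to_biclusters(test_profile: pd.Series, biclusters: BiclusterSet,
                         profiles: dict, threshold: float = 0.9) -> AssignResult:
    """Associate one test tumour with biclusters by PC1 correlation.

    Pearson r between the tumour's expression restricted to each
    bicluster's genes and that bicluster's PC1 profile; all biclusters
    with r > threshold are assigned. If none qualify the single best-
    correlated bicluster is assigned and flagged as a fallback.
    """
    corrs = {}
    for b in biclusters:
        prof = profiles[b.id]
        vals = test_profile.reindex(prof.index).to_numpy(float)
        if np.any(np.isnan(vals)):
            raise ValueError(f"test profile missing genes of bicluster {b.id}")
        p = prof.to_numpy(float)
        if vals.std() == 0 or p.std() == 0:
            corrs[b.id] = 0.0
        else:
            corrs[b.id] = float(np.corrcoef(vals, p)[0, 1])
    hits = {i for i, r in corrs.items() if r > threshold}
    if hits:
        return AssignResult(frozenset(hits), False, corrs)
    best = max(sorted(corrs), key=lambda i: corrs[i])
    return AssignResult(frozenset([best]), True, corrs)


# ---------------------------------------------------------------------------
# ridge Cox risk scores and time-dependent AUC
# ---------------------------------------------------------------------------


@dataclass
class RidgeCoxResult:
    risk_scores: np.ndarray
    coefficients: np.ndarray
    ridge_lambda: float
    cv_likelihood: pd.DataFrame = field(repr=False)
    covariate_names: list = field(default_factory=list)


def _dummy_encode(cov: pd.DataFrame, columns: pd.Index | None = None) -> pd.DataFrame:
    cat_cols = [c for c in cov.columns if cov[c].dtype == object]
    num = cov.drop(columns=cat_cols).astype(float)
    dummies = pd.get_dummies(cov[cat_cols], drop_first=True, dtype=float) if cat_cols else None
    enc = pd.concat([x for x in (dummies, num) if x is not None], axis=1)
    if columns is not None:
        enc = enc.reindex(columns=columns, fill_value=0.0)
    return enc


def ridge_cox_predict(train_cov: pd.DataFrame, times, events, test_cov: pd.DataFrame,
                      lambdas=None, n_folds: int = 10, seed: int = 0) -> RidgeCoxResult:
    """Ridge-Cox linear risk scores for test samples.

    Covariates are dummy-encoded and standardised on the training data;
    the penalty is chosen from ``lambdas`` by K-fold cross-validated
    partial likelihood (the difference form ``ll_all(beta_-k) -
    ll_-k(beta_-k)`` summed over folds), then the model is refitted on all
    training samples. Returns the linear predictor per test sample.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if events.sum() == 0:
        raise ValueError("ridge_cox_predict requires events in the training data")
    if lambdas is None:
        lambdas = np.logspace(-2, 3, 8)
    enc_tr = _dummy_encode(train_cov)
    enc_te = _dummy_encode(test_cov, columns=enc_tr.columns)
    mu = enc_tr.mean(axis=0).to_numpy()
    sd = enc_tr.std(axis=0).replace(0.0, 1.0).to_numpy()
    xtr = (enc_tr.to_numpy() - mu) / sd
    xte = (enc_te.to_numpy() - mu) / sd

    rng = stage_rng(seed, "ridge-folds")
    n = len(times)
    n_folds = min(n_folds, max(2, int(events.sum())))
    fold = rng.permuted(np.arange(n) % n_folds)
    cvl = []
    for lam in lambdas:
        total = 0.0
        ok = True
        for k in range(n_folds):
            tr = fold != k
            if events[tr].sum() == 0:
                ok = False
                break
            fit = cox_fit(xtr[tr], times[tr], events[tr], ridge_lambda=lam)
            ll_all = _breslow_quantities(xtr, times, events, fit.coefficients)[0]
            ll_tr = _breslow_quantities(xtr[tr], times[tr], events[tr], fit.coefficients)[0]
            total += ll_all - ll_tr
        cvl.append(total if ok else -np.inf)
    cvl = np.asarray(cvl)
    lam = float(np.asarray(lambdas)[int(np.argmax(cvl))])
    fit = cox_fit(xtr, times, events, ridge_lambda=lam)
    return RidgeCoxResult(
        risk_scores=xte @ fit.coefficients,
        coefficients=fit.coefficients,
        ridge_lambda=lam,
        cv_likelihood=pd.DataFrame({"lambda": list(lambdas), "cv_loglik": cvl}),
        covariate_names=list(enc_tr.columns),
    )


def time_dependent_auc(risk_scores, times, events, horizon: float,
                       censor_times=None, censor_events=None) -> float:
    """Cumulative/dynamic AUC at a horizon with IPCW for censoring.

    Cases are subjects with an event by the horizon, controls those still
    event-free past it; censoring weights come from the Kaplan-Meier
    estimate of the censoring distribution (by default estimated from the
    same data; pass ``censor_times/censor_events`` to use e.g. training
    data). Undefined (raises) when there are no cases or no controls.
    """
    scores = np.asarray(risk_scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    cases = (events == 1) & (times <= horizon)
    controls = times > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError(
            f"time-dependent AUC undefined at t={horizon}: "
            f"{int(cases.sum())} cases, {int(controls.sum())} controls"
        )
    ct = times if censor_times is None else np.asarray(censor_times, float)
    ce = events if censor_events is None else np.asarray(censor_events, int)
    km_c = km_estimate(ct, 1 - ce)

    def g_minus(t):
        idx = np.searchsorted(km_c.event_times, t, side="left") - 1
        return 1.0 if idx < 0 else float(km_c.survival[idx])

    w_case = np.array([1.0 / max(g_minus(t), 1e-12) for t in times[cases]])
    sc = scores[cases]
    so = scores[controls]
    greater = (sc[:, None] > so[None, :]).astype(float)
    ties = (sc[:, None] == so[None, :]).astype(float)
    num = (w_case[:, None] * (greater + 0.5 * ties)).sum()
    den = w_case.sum() * len(so)
    return float(num / den)


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    per_split: pd.DataFrame = field(repr=False)
    summary: dict = field(default_factory=dict)


def membership_frame(bcs: BiclusterSet, sample_ids) -> pd.DataFrame:
    m = pd.DataFrame(0, index=list(sample_ids), columns=[b.id for b in bcs], dtype=int)
    for b in bcs:
        present = [s for s in b.sample_ids if s in m.index]
        m.loc[present, b.id] = 1
    return m


def cross_validate(x: ExpressionMatrix, clinical: ClinicalTable, cfg: RunConfig,
                   auc_horizons=(1.0, 2.0, 3.0, 5.0)) -> CVReport:
    """Stratified 80/20 cross-validation of early-relapse prediction.

    Per split: biclustering runs on the training tumours only, test
    tumours are assigned to the training biclusters via PC1 correlation,
    and both a conditional-inference tree and a ridge-Cox model are fitted
    twice - from clinical covariates only, and from clinical covariates
    plus bicluster indicators. Early-relapse sensitivity (tree) and
    time-dependent AUC (ridge) are reported per split, with intermediate-
    label patients excluded throughout. Deterministic given ``cfg.seed``.
    """
    labels = dichotomize(clinical, cfg.early_cutoff_years, cfg.late_cutoff_years)
    ids = np.asarray(labels.index)
    if (labels == "early").sum() < 2 or (labels == "late").sum() < 2:
        raise ValueError("need at least 2 early and 2 late patients")

    rows = []
    full = x.to_frame()
    for split in range(cfg.n_cv_splits):
        rng = stage_rng(cfg.seed, "cv-split", split)
        for _attempt in range(10):
            # split ALL tumours, stratified on early/late/intermediate so
            # both sides keep the full data's label proportions; biclusters
            # are learned from every training tumour, labels are only used
            # downstream for fitting and evaluation
            tr_ids, te_ids = train_test_split(
                ids,
                test_size=cfg.test_fraction,
                stratify=labels.to_numpy(),
                random_state=int(rng.integers(2**31)),
            )
            if (labels.loc[te_ids] == "early").any():
                break
        else:
            raise RuntimeError(f"split {split}: no early-relapse test samples in 10 draws")

        x_tr = x.subset_samples(x.sample_index(tr_ids))
        bic_seed = int(stage_rng(cfg.seed, "cv-bicluster", split).integers(2**31))
        bcs = run_biclustering(x_tr, cfg, seed=bic_seed)
        profiles = {b.id: bicluster_pc1_profile(x_tr, b) for b in bcs}

        # restrict modelling to labelled (early/late) patients
        tr_ids = tr_ids[(labels.loc[tr_ids] != "intermediate").to_numpy()]
        te_ids = te_ids[(labels.loc[te_ids] != "intermediate").to_numpy()]
        memb_tr = membership_frame(bcs, tr_ids)
        memb_te = pd.DataFrame(0, index=list(te_ids), columns=memb_tr.columns, dtype=int)
        n_fallback = 0
        for s in te_ids:
            res = assign_to_biclusters(full[s], bcs, profiles, cfg.correlation_threshold)
            n_fallback += int(res.fallback)
            memb_te.loc[s, list(res.ids)] = 1

        clin_tr, clin_te = clinical.subset(tr_ids), clinical.subset(te_ids)
        y_tr, y_te = labels.loc[tr_ids].to_numpy(), labels.loc[te_ids].to_numpy()
        cov_tr = encode_covariates(clin_tr)
        cov_te = encode_covariates(clin_te)
        cov_tr_b = encode_covariates(clin_tr, memb_tr)
        cov_te_b = encode_covariates(clin_te, memb_te)

        tree_seed = int(stage_rng(cfg.seed, "cv-tree", split).integers(2**31))
        row = {"split": split, "n_test": len(te_ids),
               "n_test_early": int((y_te == "early").sum()), "n_fallback": n_fallback}
        for tag, ctr, cte in (("clinical", cov_tr, cov_te), ("bicluster", cov_tr_b, cov_te_b)):
            tree = fit_conditional_tree(
                ctr, y_tr, alpha=cfg.split_alpha, min_leaf=cfg.tree_min_leaf,
                n_permutations=cfg.tree_n_permutations, trim_level=cfg.tree_trim_level,
                seed=tree_seed,
            )
            pred = predict_tree(tree, cte)
            early_mask = y_te == "early"
            row[f"sens_{tag}"] = float((pred[early_mask] == "early").mean())
            row[f"spec_{tag}"] = float((pred[~early_mask] == "late").mean())

            t_tr, e_tr = clin_tr.survival_arrays()
            t_te, e_te = clin_te.survival_arrays()
            ridge_seed = int(stage_rng(cfg.seed, "cv-ridge", split).integers(2**31))
            rr = ridge_cox_predict(ctr, t_tr, e_tr, cte, seed=ridge_seed)
            for h in auc_horizons:
                try:
                    auc = time_dependent_auc(
                        rr.risk_scores, t_te, e_te, h, censor_times=t_tr, censor_events=e_tr
                    )
                except ValueError:
                    auc = np.nan
                row[f"auc{h:g}_{tag}"] = auc
        rows.append(row)

    per_split = pd.DataFrame(rows)
    wins = (per_split["sens_bicluster"] > per_split["sens_clinical"]).sum()
    losses = (per_split["sens_bicluster"] < per_split["sens_clinical"]).sum()
    if wins + losses > 0:
        sign_p = float(stats.binomtest(int(wins), int(wins + losses), 0.5,
                                       alternative="greater").pvalue)
    else:
        sign_p = 1.0
    summary = {
        "sensitivity_clinical": float(per_split["sens_clinical"].mean()),
        "sensitivity_with_biclusters": float(per_split["sens_bicluster"].mean()),
        "sign_test_p": sign_p,
        "n_splits": int(cfg.n_cv_splits),
    }
    for h in auc_horizons:
        for tag in ("clinical", "bicluster"):
            summary[f"auc{h:g}_{tag}_median"] = float(
                np.nanmedian(per_split[f"auc{h:g}_{tag}"])
            )
    return CVReport(per_split=per_split, summary=summary)
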