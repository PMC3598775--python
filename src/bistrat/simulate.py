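"""Synthetic expression / clinical / survival data with planted biclusters.

The generator emulates the structure of a multi-cohort, non-adjuvant-treated
breast-tumour microarray compendium: log2 intensities with per-(gene, cohort)
additive batch shifts and multiplicative noise scales, overlapping planted
biclusters that add a constant expression shift on their (sample, gene)
block, clinical covariates whose category probabilities are skewed for
bicluster members, and exponential disease-free-survival times whose
log-hazard is linear in bicluster membership and clinical covariates, with
independent exponential plus administrative censoring.

Expression model for sample t in cohort c(t):

    x_{g,t} = mu_g + cohort_shift_{g,c(t)}
              + sum_{B: g in B} shift_B * a_{B,t} * w_{B,g}
              + scale_{g,c(t)} * eps,   eps ~ N(0, noise_sd^2)

where the module activity ``a_{B,t}`` is exactly 1 for member tumours and
varies continuously, ``Normal(0, module_background_sd_frac^2)``, across
non-members, and the gene loading ``w_{B,g} ~ Normal(1, loading_sd^2)``
gives each block gene its own participation strength. Member tumours thus
share one fixed signature of mean height ``shift_B`` over the block's
genes (the mean block-versus-background contrast is ``shift_B``), while
the same genes fluctuate across the rest of the cohort. Both ingredients
are what make a co-expression module discoverable by a coherence
criterion: a signal that is constant over the block's genes, or absent
outside the block, is exactly absorbed by per-tumour/per-gene centring
and leaves membership unidentifiable.

Survival model:

    T_t ~ Exponential(h_t),
    h_t = baseline_hazard * exp( sum_{B: t in B} hazard_log_ratio_B
                                 + clinical linear predictor )
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .bicluster import Bicluster, BiclusterSet
from .types import ClinicalTable, ExpressionMatrix

__all__ = [
    "PlantedBicluster",
    "SimulationDesign",
    "simulate_dataset",
    "true_membership_matrix",
    "default_design",
    "BACKGROUND_CLINICAL",
    "CLINICAL_LOG_HR",
]

#: Background category probabilities (category order as listed).
BACKGROUND_CLINICAL = {
    "ln_status": (["LN+", "LN-"], [0.10, 0.90]),
    "er_status": (["ER+", "ER-"], [0.70, 0.30]),
    "pgr_status": (["PgR+", "PgR-"], [0.60, 0.40]),
    "grade": (["G1", "G2", "G3"], [0.25, 0.45, 0.30]),
    "subtype": (
        ["Basal", "Her2", "LumA", "LumB", "Normal", "None"],
        [0.15, 0.15, 0.35, 0.20, 0.10, 0.05],
    ),
}

#: Additive log-hazard contributions of clinical categories (reference
#: categories carry 0). Size classes contribute per 20 mm above 20 mm.
CLINICAL_LOG_HR = {
    ("grade", "G1"): -0.2,
    ("grade", "G3"): 0.25,
    ("er_status", "ER-"): 0.15,
    ("ln_status", "LN+"): 0.3,
}
SIZE_LOG_HR_PER_20MM = 0.1


@dataclass
class PlantedBicluster:
    """Ground-truth block: member samples/genes, expression shift (log2
    units added on the block), additive log-hazard effect of membership,
    and optional per-covariate category-probability skews for members."""

    sample_indices: frozenset
    gene_indices: frozenset
    expression_shift: float
    hazard_log_ratio: float
    clinical_skew: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_indices = frozenset(int(i) for i in self.sample_indices)
        self.gene_indices = frozenset(int(i) for i in self.gene_indices)
        if not self.sample_indices or not self.gene_indices:
            raise ValueError("planted bicluster sample/gene sets must be non-empty")
        for cov, probs in self.clinical_skew.items():
            if cov not in BACKGROUND_CLINICAL:
                raise ValueError(f"unknown clinical covariate in skew: {cov!r}")
            cats = BACKGROUND_CLINICAL[cov][0]
            if len(probs) != len(cats):
                raise ValueError(f"skew for {cov!r} must have {len(cats)} probabilities")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"skew probabilities for {cov!r} must sum to 1")


@dataclass
class SimulationDesign:
    n_genes: int
    n_samples: int
    n_cohorts: int
    cohort_shift_sd: float = 0.5
    cohort_scale_sd: float = 0.15
    noise_sd: float = 0.5
    gene_baseline_mean: float = 7.0
    gene_baseline_sd: float = 1.0
    module_background_sd_frac: float = 0.35  # non-member activity sd (members = 1)
    loading_sd: float = 1.0  # per-gene loading sd around mean 1
    baseline_hazard: float = 0.08  # events per year
    censor_rate: float = 0.03  # censorings per year (0 = none)
    follow_up_max: float = 12.0  # years of administrative follow-up
    planted: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.follow_up_max <= 0:
            raise ValueError("follow_up_max must be > 0")
        for b in self.planted:
            if max(b.sample_indices, default=0) >= self.n_samples or min(
                b.sample_indices, default=0
            ) < 0:
                raise ValueError("planted sample index out of range")
            if max(b.gene_indices, default=0) >= self.n_genes or min(
                b.gene_indices, default=0
            ) < 0:
                raise ValueError("planted gene index out of range")


def _sample_ids(n: int) -> list:
    return [f"S{i + 1:04d}" for i in range(n)]


def _gene_ids(n: int) -> list:
    return [f"G{i + 1:05d}" for i in range(n)]


def simulate_dataset(design: SimulationDesign):
    """Draw one dataset; returns (ExpressionMatrix, ClinicalTable, truth).

    ``truth`` is a :class:`BiclusterSet` holding the planted memberships
    (score field set to the planted expression shift). Reproducible bitwise
    for a fixed ``design.seed``.
    """
    rng = stage_rng(design.seed, "simulate")
    n_g, n_s, n_c = design.n_genes, design.n_samples, design.n_cohorts
    gene_ids, sample_ids = _gene_ids(n_g), _sample_ids(n_s)

    cohort_of = rng.integers(n_c, size=n_s)
    mu = rng.normal(design.gene_baseline_mean, design.gene_baseline_sd, size=n_g)
    shift_gc = rng.normal(0.0, design.cohort_shift_sd, size=(n_g, n_c))
    scale_gc = np.exp(rng.normal(0.0, design.cohort_scale_sd, size=(n_g, n_c)))

    eps = rng.normal(0.0, design.noise_sd, size=(n_g, n_s))
    values = mu[:, None] + shift_gc[:, cohort_of] + scale_gc[:, cohort_of] * eps
    for b in design.planted:
        g = np.fromiter(sorted(b.gene_indices), int)
        activity = rng.normal(0.0, design.module_background_sd_frac, size=n_s)
        activity[np.fromiter(sorted(b.sample_indices), int)] = 1.0
        loading = rng.normal(1.0, design.loading_sd, size=len(g))
        values[g] += b.expression_shift * np.outer(loading, activity)

    # clinical covariates: background distribution, skewed for members
    clin = {}
    member_skews = [[] for _ in range(n_s)]
    for b in design.planted:
        if b.clinical_skew:
            for t in b.sample_indices:
                member_skews[t].append(b.clinical_skew)
    for cov, (cats, bg_probs) in BACKGROUND_CLINICAL.items():
        probs = np.tile(np.asarray(bg_probs, float), (n_s, 1))
        for t in range(n_s):
            skews = [sk[cov] for sk in member_skews[t] if cov in sk]
            if skews:
                probs[t] = np.mean(np.asarray(skews, float), axis=0)
        u = rng.uniform(size=n_s)
        idx = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
        clin[cov] = [cats[i] for i in idx]
    size_mm = rng.lognormal(np.log(20.0), 0.4, size=n_s)
    age = np.clip(rng.normal(58.0, 12.0, size=n_s), 25.0, 95.0)

    # survival: exponential hazard, log-linear in memberships + clinical
    log_hr = np.zeros(n_s)
    for b in design.planted:
        for t in b.sample_indices:
            log_hr[t] += b.hazard_log_ratio
    for t in range(n_s):
        for (cov, cat), beta in CLINICAL_LOG_HR.items():
            if clin[cov][t] == cat:
                log_hr[t] += beta
        log_hr[t] += SIZE_LOG_HR_PER_20MM * (size_mm[t] - 20.0) / 20.0
    hazard = design.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    if design.censor_rate > 0:
        t_cens = rng.exponential(1.0 / design.censor_rate, size=n_s)
    else:
        t_cens = np.full(n_s, np.inf)
    t_cens = np.minimum(t_cens, design.follow_up_max)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    expr = ExpressionMatrix(gene_ids, sample_ids, values, gene_symbols=list(gene_ids))
    table = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "cohort": [f"cohort{c + 1}" for c in cohort_of],
                "ln_status": clin["ln_status"],
                "er_status": clin["er_status"],
                "pgr_status": clin["pgr_status"],
                "grade": clin["grade"],
                "subtype": clin["subtype"],
                "size_mm": np.round(size_mm, 1),
                "age_years": np.round(age, 1),
                "dfs_time_years": time,
                "dfs_event": event,
            }
        )
    )
    truth = BiclusterSet(
        [
            Bicluster(
                id=i + 1,
                sample_ids=frozenset(sample_ids[t] for t in b.sample_indices),
                gene_ids=frozenset(gene_ids[g] for g in b.gene_indices),
                score=b.expression_shift,
            )
            for i, b in enumerate(design.planted)
        ]
    )
    return expr, table, truth


def true_membership_matrix(truth: BiclusterSet, sample_ids=None) -> pd.DataFrame:
    """Binary samples x planted-biclusters membership indicator frame."""
    if sample_ids is None:
        sample_ids = sorted(set().union(*(b.sample_ids for b in truth)))
    m = pd.DataFrame(0, index=list(sample_ids), columns=[b.id for b in truth], dtype=int)
    for b in truth:
        for s in b.sample_ids:
            if s in m.index:
                m.loc[s, b.id] = 1
    return m


_HIGH_RISK_SKEW = {
    "grade": [0.10, 0.35, 0.55],
    "er_status": [0.35, 0.65],
    "subtype": [0.30, 0.30, 0.15, 0.15, 0.05, 0.05],
}
_LOW_RISK_SKEW = {
    "grade": [0.40, 0.45, 0.15],
    "er_status": [0.90, 0.10],
    "subtype": [0.05, 0.05, 0.50, 0.30, 0.05, 0.05],
}


def default_design(seed: int = 0, n_genes: int = 1500, n_samples: int = 400,
                   n_cohorts: int = 3, n_biclusters: int = 12,
                   noise_sd: float = 0.5, shift_factor: float = 3.0,
                   hazard_log_ratio: float = 1.2) -> SimulationDesign:
    """Desk-scale default design with planted risk-bearing biclusters.

    1500 genes x 400 tumours across 3 cohorts.
    Twelve overlapping biclusters of 15-35 samples and 30-80 genes: one
    third raise the hazard (log-HR +0.8, clinical skew towards high-grade
    ER- tumours), one third lower it (-0.8, skew towards low-grade ER+),
    one third are survival-neutral. Expression shift is ``shift_factor *
    noise_sd`` with random sign per block.
    """
    if n_genes < 80 * n_biclusters:
        raise ValueError(
            f"n_genes={n_genes} cannot host {n_biclusters} disjoint gene "
            "signatures of up to 80 genes; reduce n_biclusters or add genes"
        )
    rng = stage_rng(seed, "design")
    planted = []
    gene_pool = rng.permutation(n_genes)
    pool_pos = 0
    for i in range(n_biclusters):
        n_s = int(rng.integers(15, 36))
        n_g = int(rng.integers(30, 81))
        samples = frozenset(rng.choice(n_samples, size=n_s, replace=False).tolist())
        # disjoint gene signatures: modules use distinct gene sets, while
        # tumours may participate in several modules (overlapping samples)
        genes = frozenset(gene_pool[pool_pos:pool_pos + n_g].tolist())
        pool_pos += n_g
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        tercile = i % 3
        if tercile == 0:
            hlr, skew = hazard_log_ratio, dict(_HIGH_RISK_SKEW)
        elif tercile == 1:
            hlr, skew = -hazard_log_ratio, dict(_LOW_RISK_SKEW)
        else:
            hlr, skew = 0.0, {}
        planted.append(
            PlantedBicluster(
                sample_indices=samples,
                gene_indices=genes,
                expression_shift=sign * shift_factor * noise_sd,
                hazard_log_ratio=hlr,
                clinical_skew=skew,
            )
        )
    return SimulationDesign(
        n_genes=n_genes,
        n_samples=n_samples,
        n_cohorts=n_cohorts,
        noise_sd=noise_sd,
        planted=planted,
        seed=seed,
    )
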