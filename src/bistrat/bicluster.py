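"""Stochastic biclustering of tumours on gene subsets.

The search groups tumours (samples) that are mutually coherent over a
subset of genes, working on the transposed expression matrix (samples as
rows); both tumours and genes may belong to several biclusters. It runs in
two phases, mirroring how integrated biclustering tools alternate
conditional membership updates with stochastic refinement:

1. *Seeded conditional sweeps.* Each of the K chains is seeded from a
   pivot tumour sharing many sign-consistent extreme genes with its
   neighbours; membership is then iterated to a fixed point by projecting
   every tumour onto the bicluster's activation profile (tumours above an
   activity threshold join) and re-selecting genes by a likelihood-ratio
   criterion against the background variance. Found gene signatures are
   deflated from the seeding similarity so successive chains discover
   distinct modules.
2. *Simulated-annealing refinement.* Single-element toggles (one sample or
   gene of one bicluster, uniform over eligible moves) accepted with the
   Metropolis probability ``min(1, exp(-delta/T))`` under geometric
   cooling, where delta is the change in the total objective: the sum of
   per-bicluster likelihood scores plus soft penalties on deviation from
   target sizes and on mean pairwise sample overlap between biclusters.

The per-bicluster search objective is a Gaussian likelihood-ratio margin:
each gene contributes ``t * (log(s2_g / v_g) + kappa -
lambda_act * (c_g - m_g)^2 / v_g)`` where ``s2_g`` is the gene's residual
variance within the bicluster after removing tumour and gene effects,
``v_g`` its variance across all tumours, ``c_g - m_g`` the bicluster's
activation relative to the cohort mean, and ``kappa`` a margin that keeps
uninformative genes out. Coherent *and* differentially activated blocks
score strongly negative; flat background groups do not. The reported
per-bicluster ``score`` is the classical variance-normalised mean-squared
residue (:func:`coherence_score`), independent of the search objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .types import ExpressionMatrix
from ._rng import stage_rng

__all__ = [
    "Bicluster",
    "BiclusterSet",
    "SearchState",
    "coherence_score",
    "propose_move",
    "run_biclustering",
    "recovery_jaccard",
]

_VAR_FLOOR = 1e-8


@dataclass
class Bicluster:
    id: int
    sample_ids: frozenset
    gene_ids: frozenset
    score: float

    def __post_init__(self) -> None:
        self.sample_ids = frozenset(self.sample_ids)
        self.gene_ids = frozenset(self.gene_ids)
        if not self.sample_ids or not self.gene_ids:
            raise ValueError(f"bicluster {self.id}: sample and gene sets must be non-empty")
        if not np.isfinite(self.score):
            raise ValueError(f"bicluster {self.id}: score must be finite")


@dataclass
class BiclusterSet:
    biclusters: list
    provenance: RunConfig | None = None

    def __post_init__(self) -> None:
        ids = [b.id for b in self.biclusters]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("bicluster ids must be contiguous from 1")

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def __getitem__(self, i):
        return self.biclusters[i]

    def sample_sets(self) -> list:
        return [b.sample_ids for b in self.biclusters]


def _as_indices(ids_or_idx, lookup_fn) -> np.ndarray:
    arr = list(ids_or_idx)
    if arr and all(isinstance(v, (int, np.integer)) for v in arr):
        return np.asarray(arr, dtype=int)
    return lookup_fn(arr)


def gene_variances(x: ExpressionMatrix) -> np.ndarray:
    """Per-gene variance across all samples, floored away from zero."""
    v = x.values.var(axis=1)
    return np.maximum(v, _VAR_FLOOR)


def coherence_score(x: ExpressionMatrix, samples, genes, _gene_var=None) -> float:
    """Variance-normalised two-way mean-squared residue of a submatrix.

    ``s = mean_{t,g} (x_{t,g} - m_t. - m_.g + m)^2 / v_g`` over the
    submatrix of the given samples and genes (transposed orientation:
    t indexes samples), where v_g is gene g's variance across ALL samples.
    Zero for any submatrix with additive structure x = a_t + b_g; about
    (1-1/T)(1-1/G) for pure noise. Lower is more coherent.

    Samples/genes may be given as ids or integer indices.
    """
    s_idx = _as_indices(samples, x.sample_index)
    g_idx = _as_indices(genes, x.gene_index)
    if len(s_idx) < 2 or len(g_idx) < 2:
        raise ValueError("coherence_score requires >= 2 samples and >= 2 genes")
    v = gene_variances(x) if _gene_var is None else _gene_var
    sub = x.values[np.ix_(g_idx, s_idx)].T  # samples x genes
    r = sub - sub.mean(axis=1, keepdims=True) - sub.mean(axis=0, keepdims=True) + sub.mean()
    return float(np.mean(r * r / v[g_idx]))


@dataclass
class SearchState:
    """Joint membership state of the K chains.

    ``sample_memb``/``gene_memb`` are boolean (K, n) arrays; row k is
    bicluster k's membership indicator.
    """

    sample_memb: np.ndarray
    gene_memb: np.ndarray
    temperature: float
    iteration: int = 0

    def copy(self) -> "SearchState":
        return SearchState(
            self.sample_memb.copy(), self.gene_memb.copy(), self.temperature, self.iteration
        )

    def to_bicluster_set(self, x: ExpressionMatrix, cfg: RunConfig | None = None) -> BiclusterSet:
        v = gene_variances(x)
        bcs = []
        for k in range(self.sample_memb.shape[0]):
            s = np.flatnonzero(self.sample_memb[k])
            g = np.flatnonzero(self.gene_memb[k])
            bcs.append(
                Bicluster(
                    id=k + 1,
                    sample_ids=frozenset(x.sample_ids[i] for i in s),
                    gene_ids=frozenset(x.gene_ids[i] for i in g),
                    score=coherence_score(x, s, g, _gene_var=v),
                )
            )
        return BiclusterSet(bcs, provenance=cfg)


class _Objective:
    """Likelihood-margin objective with incremental bookkeeping."""

    def __init__(self, x: ExpressionMatrix, cfg: RunConfig):
        self.XT = np.ascontiguousarray(x.values.T)  # samples x genes
        self.v = gene_variances(x)
        self.gmean = self.XT.mean(axis=0)
        self.cfg = cfg
        self.n_samples, self.n_genes = self.XT.shape

    def gene_quality(self, s_idx: np.ndarray, g_idx=None) -> np.ndarray:
        """Per-gene likelihood-margin ``log(s2/v) + kappa - lambda*(c-m)^2/v``
        for the given sample set (all genes unless ``g_idx`` given); the
        tumour effect is estimated on the bicluster's current genes when
        ``row_genes`` covers them (here: none — plain per-gene centring)."""
        sub = self.XT[s_idx] if g_idx is None else self.XT[np.ix_(s_idx, g_idx)]
        v = self.v if g_idx is None else self.v[g_idx]
        m = self.gmean if g_idx is None else self.gmean[g_idx]
        c = sub.mean(axis=0)
        t = len(s_idx)
        s2 = ((sub - c) ** 2).sum(axis=0) / max(t - 1, 1)
        s2 = np.maximum(s2, 1e-3 * v)
        cfg = self.cfg
        return np.log(s2 / v) + cfg.gene_margin - cfg.lambda_activation * (c - m) ** 2 / v

    def bicluster_score(self, smask: np.ndarray, gmask: np.ndarray) -> float:
        """Total likelihood margin of one bicluster (lower is better).

        Residual variance per gene is taken after removing tumour and gene
        effects within the block (two-way fit, df-corrected)."""
        s_idx = np.flatnonzero(smask)
        g_idx = np.flatnonzero(gmask)
        sub = self.XT[np.ix_(s_idx, g_idx)]
        t, g = sub.shape
        c = sub.mean(axis=0)
        r = sub - c - sub.mean(axis=1, keepdims=True) + sub.mean()
        v = self.v[g_idx]
        s2 = (r * r).sum(axis=0) / max((t - 1) * (1 - 1 / g), 1e-9)
        s2 = np.maximum(s2, 1e-3 * v)
        cfg = self.cfg
        q = (
            np.log(s2 / v)
            + cfg.gene_margin
            - cfg.lambda_activation * (c - self.gmean[g_idx]) ** 2 / v
        )
        return float(t * q.sum() / (cfg.target_samples * cfg.target_genes))

    def size_penalty(self, n_s: int, n_g: int) -> float:
        cfg = self.cfg
        ds = (n_s - cfg.target_samples) / cfg.target_samples
        dg = (n_g - cfg.target_genes) / cfg.target_genes
        return cfg.lambda_size * (ds * ds + dg * dg)

    @staticmethod
    def overlap_penalty(inter: np.ndarray, sizes: np.ndarray, lam: float) -> float:
        k = len(sizes)
        if k < 2 or lam == 0.0:
            return 0.0
        union = sizes[:, None] + sizes[None, :] - inter
        iu = np.triu_indices(k, 1)
        jac = inter[iu] / np.maximum(union[iu], 1)
        return lam * float(jac.mean())


def _total_score(obj: _Objective, state: SearchState) -> float:
    k = state.sample_memb.shape[0]
    coher = sum(
        obj.bicluster_score(state.sample_memb[i], state.gene_memb[i]) for i in range(k)
    )
    size = sum(
        obj.size_penalty(int(state.sample_memb[i].sum()), int(state.gene_memb[i].sum()))
        for i in range(k)
    )
    inter = (state.sample_memb.astype(np.int32) @ state.sample_memb.T.astype(np.int32)).astype(
        float
    )
    sizes = state.sample_memb.sum(axis=1).astype(float)
    np.fill_diagonal(inter, 0.0)
    return coher + size + obj.overlap_penalty(inter, sizes, obj.cfg.lambda_overlap)


def _eligible_toggle(rng, memb_row, size, lo, hi, n):
    """Uniformly pick one eligible toggle index along one axis, or None."""
    if size <= lo:
        cand = np.flatnonzero(~memb_row)  # additions only
    elif size >= hi:
        cand = np.flatnonzero(memb_row)  # removals only
    else:
        return int(rng.integers(n))
    if len(cand) == 0:
        return None
    return int(cand[rng.integers(len(cand))])


def _step(obj: _Objective, state: SearchState, scores, sizes_s, sizes_g, inter, rng) -> bool:
    """One Metropolis proposal; mutates state and caches. Returns accepted."""
    cfg = obj.cfg
    K = state.sample_memb.shape[0]
    k = int(rng.integers(K))

    ns, ng = sizes_s[k], sizes_g[k]
    n_elig_s = obj.n_samples if cfg.min_samples < ns < cfg.max_samples else (
        obj.n_samples - ns if ns <= cfg.min_samples else ns
    )
    n_elig_g = obj.n_genes if cfg.min_genes < ng < cfg.max_genes else (
        obj.n_genes - ng if ng <= cfg.min_genes else ng
    )
    pick_sample = rng.uniform() < n_elig_s / max(n_elig_s + n_elig_g, 1)

    if pick_sample:
        e = _eligible_toggle(rng, state.sample_memb[k], ns, cfg.min_samples, cfg.max_samples,
                             obj.n_samples)
        if e is None:
            return False, 0.0
        row = state.sample_memb[k]
        adding = not row[e]
        if (ns <= cfg.min_samples and not adding) or (ns >= cfg.max_samples and adding):
            return False, 0.0
        row[e] = not row[e]
        new_ns = ns + (1 if adding else -1)
        new_score = obj.bicluster_score(row, state.gene_memb[k])
        other_has = state.sample_memb[:, e].astype(float)
        other_has[k] = 0.0
        new_inter_row = inter[k] + (other_has if adding else -other_has)
        old_olap = obj.overlap_penalty(inter, sizes_s.astype(float), cfg.lambda_overlap)
        inter_new = inter.copy()
        inter_new[k] = new_inter_row
        inter_new[:, k] = new_inter_row
        sizes_new = sizes_s.copy()
        sizes_new[k] = new_ns
        new_olap = obj.overlap_penalty(inter_new, sizes_new.astype(float), cfg.lambda_overlap)
        delta = (
            new_score - scores[k]
            + obj.size_penalty(new_ns, ng) - obj.size_penalty(ns, ng)
            + new_olap - old_olap
        )
        if delta <= 0 or rng.uniform() < np.exp(-delta / state.temperature):
            scores[k] = new_score
            sizes_s[k] = new_ns
            inter[k] = new_inter_row
            inter[:, k] = new_inter_row
            return True, delta
        row[e] = not row[e]  # revert
        return False, 0.0

    e = _eligible_toggle(rng, state.gene_memb[k], ng, cfg.min_genes, cfg.max_genes, obj.n_genes)
    if e is None:
        return False, 0.0
    row = state.gene_memb[k]
    adding = not row[e]
    if (ng <= cfg.min_genes and not adding) or (ng >= cfg.max_genes and adding):
        return False, 0.0
    row[e] = not row[e]
    new_ng = ng + (1 if adding else -1)
    new_score = obj.bicluster_score(state.sample_memb[k], row)
    delta = new_score - scores[k] + obj.size_penalty(ns, new_ng) - obj.size_penalty(ns, ng)
    if delta <= 0 or rng.uniform() < np.exp(-delta / state.temperature):
        scores[k] = new_score
        sizes_g[k] = new_ng
        return True, delta
    row[e] = not row[e]
    return False, 0.0


def _caches(obj: _Objective, state: SearchState):
    K = state.sample_memb.shape[0]
    scores = np.array(
        [obj.bicluster_score(state.sample_memb[i], state.gene_memb[i]) for i in range(K)]
    )
    sizes_s = state.sample_memb.sum(axis=1).astype(int)
    sizes_g = state.gene_memb.sum(axis=1).astype(int)
    inter = (state.sample_memb.astype(np.int32) @ state.sample_memb.T.astype(np.int32)).astype(
        float
    )
    np.fill_diagonal(inter, 0.0)
    return scores, sizes_s, sizes_g, inter


def propose_move(state: SearchState, x: ExpressionMatrix, cfg: RunConfig,
                 rng: np.random.Generator) -> SearchState:
    """One Metropolis toggle; returns the (possibly unchanged) new state.

    Rejected proposals leave memberships untouched apart from the rng
    advance; the iteration counter always advances. Moves that would push
    a bicluster outside its size bounds are never proposed.
    """
    new = state.copy()
    obj = _Objective(x, cfg)
    caches = _caches(obj, new)
    _step(obj, new, *caches, rng)
    new.iteration = state.iteration + 1
    return new


def _sweep(obj: _Objective, smask, gmask):
    """One conditional membership update (samples given genes, then genes
    given samples); returns new masks."""
    cfg = obj.cfg
    X, v, m = obj.XT, obj.v, obj.gmean
    g_idx = np.flatnonzero(gmask)
    s_idx = np.flatnonzero(smask)
    c = X[np.ix_(s_idx, g_idx)].mean(axis=0)
    u = (c - m[g_idx]) / v[g_idx]
    denom = (c - m[g_idx]) @ u
    if denom <= 1e-12:
        return smask.copy(), gmask.copy()
    # activity of every tumour along the bicluster's activation profile
    # (1 = full module activity, 0 = cohort average)
    alpha = (X[:, g_idx] - m[g_idx]) @ u / denom
    order = np.argsort(-alpha)
    n_in = int((alpha > cfg.activity_threshold).sum())
    n_in = min(max(n_in, cfg.min_samples), cfg.max_samples)
    new_s = np.zeros_like(smask)
    new_s[order[:n_in]] = True
    # genes: likelihood-ratio margin vs background on the updated samples
    q = obj.gene_quality(np.flatnonzero(new_s))
    order_g = np.argsort(q)
    m_in = min(max(int((q < 0).sum()), cfg.min_genes), cfg.max_genes)
    new_g = np.zeros_like(gmask)
    new_g[order_g[:m_in]] = True
    return new_s, new_g


def _seed_state(obj: _Objective, cfg: RunConfig, rng: np.random.Generator) -> SearchState:
    """Seed and conditionally converge K chains, one at a time.

    Tumour-tumour similarity counts sign-consistent extreme genes
    (|z| > extreme_z on variance-standardised data). Each chain starts
    from a random pivot among the highest-connectivity available tumours
    plus its nearest neighbours, runs ``n_sweeps`` conditional updates,
    and then has its gene signature deflated from the similarity matrix
    so the next chain finds a different module.
    """
    K = cfg.k_biclusters
    n_s, n_g = obj.n_samples, obj.n_genes
    sd = np.sqrt(obj.v)
    Z = (obj.XT - obj.gmean) / sd
    E = np.where(np.abs(Z) > cfg.extreme_z, np.sign(Z), 0.0)
    avail = np.ones(n_s, bool)
    smemb = np.zeros((K, n_s), dtype=bool)
    gmemb = np.zeros((K, n_g), dtype=bool)
    n_seed_genes = min(max(cfg.min_genes, 30), min(cfg.max_genes, n_g))
    for k in range(K):
        S = E @ E.T
        np.fill_diagonal(S, 0.0)
        rowsum = np.where(avail, S.sum(axis=1), -np.inf)
        top = np.argsort(-rowsum)[: min(10, n_s)]
        pivot = int(top[rng.integers(len(top))])
        neigh = np.argsort(-S[pivot])[: cfg.min_samples - 1]
        chosen = np.unique(np.concatenate([[pivot], neigh]))
        smask = np.zeros(n_s, bool)
        smask[chosen] = True
        dev = np.abs(obj.XT[chosen].mean(axis=0) - obj.gmean) / sd
        gmask = np.zeros(n_g, bool)
        gmask[np.argsort(-dev)[:n_seed_genes]] = True
        for _ in range(cfg.n_sweeps):
            smask, gmask = _sweep(obj, smask, gmask)
        smemb[k] = smask
        gmemb[k] = gmask
        E[:, np.flatnonzero(gmask)] = 0.0
        avail[np.flatnonzero(smask)] = False
        if not avail.any():
            avail[:] = True
    return SearchState(smemb, gmemb, temperature=cfg.anneal_t0, iteration=0)


def run_biclustering(
    x: ExpressionMatrix,
    cfg: RunConfig,
    seed: int | None = None,
    return_trace: bool = False,
):
    """Full bicluster search on a preprocessed matrix.

    Seeded conditional sweeps followed by the annealed Metropolis
    refinement; deterministic given the seed (default ``cfg.seed``, stream
    "bicluster"). Returns a :class:`BiclusterSet` with exactly
    ``cfg.k_biclusters`` members; with ``return_trace=True`` also returns
    the total-score trace (every 100 moves).
    """
    if cfg.k_biclusters > x.n_samples:
        raise ValueError(
            f"k_biclusters={cfg.k_biclusters} exceeds number of samples {x.n_samples}"
        )
    if cfg.min_samples > x.n_samples or cfg.min_genes > x.n_genes:
        raise ValueError("matrix smaller than minimum bicluster size bounds")
    rng = stage_rng(cfg.seed if seed is None else seed, "bicluster")
    obj = _Objective(x, cfg)
    state = _seed_state(obj, cfg, rng)
    caches = _caches(obj, state)
    n_iter = cfg.iters_per_bicluster * cfg.k_biclusters
    trace = []
    temps = cfg.anneal_t0 * cfg.anneal_cooling ** np.arange(n_iter)
    total = _total_score(obj, state)
    best_total = total
    best = (state.sample_memb.copy(), state.gene_memb.copy())
    for i in range(n_iter):
        state.temperature = temps[i]
        accepted, delta = _step(obj, state, *caches, rng)
        if accepted:
            total += delta
            if total < best_total - 1e-12:
                best_total = total
                best = (state.sample_memb.copy(), state.gene_memb.copy())
        state.iteration += 1
        if return_trace and i % 100 == 0:
            trace.append((i, total))
    # return the best state visited: the hot phase may wander and fast
    # cooling need not find its way back
    state.sample_memb, state.gene_memb = best
    if return_trace:
        trace.append((n_iter, best_total))
    result = state.to_bicluster_set(x, cfg)
    if return_trace:
        return result, trace
    return result


def jaccard(a: frozenset, b: frozenset) -> float:
    u = len(a | b)
    return len(a & b) / u if u else 0.0


def recovery_jaccard(found: BiclusterSet, truth: BiclusterSet) -> float:
    """Mean over planted biclusters of the best sample-set Jaccard match."""
    if len(truth) == 0:
        raise ValueError("truth bicluster set is empty")
    if len(found) == 0:
        raise ValueError("found bicluster set is empty")
    return float(
        np.mean(
            [max(jaccard(t.sample_ids, f.sample_ids) for f in found) for t in truth]
        )
    )
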