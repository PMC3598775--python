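# bistrat

Bicluster-based stratification of breast tumours: find overlapping
subgroups of tumours that co-express subsets of genes, test whether those
subgroups separate disease-free-survival (DFS) curves more than chance,
derive minimal gene classifiers for subgroup pairs, and measure whether
subgroup membership improves prediction of early relapse over conventional
clinico-pathological covariates.

## Who this is for

Computational biologists working with multi-cohort tumour expression
compendia (log2 intensities, genes x samples) with matched clinical
annotation and censored survival outcomes, who want tumour subgroups that
are defined *conditionally* — a subgroup exists only with respect to the
gene subset over which its members are coherent — rather than by global
clustering, and who want those subgroups evaluated as prognostic
covariates.

## The model in brief

A **bicluster** is a pair (S, G) of tumours and genes such that expression
is mutually coherent over the block; tumours and genes may belong to
several biclusters. K biclusters are searched jointly: seeded conditional
membership sweeps followed by simulated-annealing refinement of
single-element moves, scored by a Gaussian likelihood-ratio margin per
gene,

    |S| * sum_{g in G} [ log(s2_g / v_g) + kappa - lambda * (c_g - m_g)^2 / v_g ]

(within-block residual variance against cohort variance, plus a
differential-activation reward), with soft penalties on size and on
between-bicluster overlap. Survival separation is tested by comparing
all-pairs logrank p-values over biclusters against size-matched random
groups (patients drawn with replacement) with a randomization-calibrated
Kolmogorov-Smirnov p. Early-relapse prediction (relapse within 2 years vs
relapse-free through 8) compares a conditional-inference tree and a
ridge-penalised Cox model fitted from clinical covariates alone versus
clinical covariates plus bicluster membership indicators, over 50
stratified 80/20 splits with biclusters re-learned on each training set
and test tumours assigned by correlation with each bicluster's first
principal-component gene profile.

Because real multi-cohort compendia cannot ship with the package, a
first-class synthetic generator plants overlapping biclusters with known
expression signatures, clinical-covariate skews, and survival effects, so
every stage is scored against ground truth. See `docs/methods.md` for the
generative model, algorithms and design decisions.

## Worked example

```python
from bistrat import (RunConfig, adjust_batch, cross_validate, default_design,
                     recovery_jaccard, run_biclustering, separation_test,
                     simulate_dataset)
from bistrat._rng import stage_rng

design = default_design(seed=2)            # 1500 genes x 400 tumours, 12 planted biclusters
expr, clinical, truth = simulate_dataset(design)
x = adjust_batch(expr, clinical.df["cohort"].to_numpy())

cfg = RunConfig(seed=2, k_biclusters=12)
found = run_biclustering(x, cfg)
print("recovery", round(recovery_jaccard(found, truth), 3))

sep = separation_test(found, clinical, cfg.n_randomizations, stage_rng(2, "sep"))
print("KS", round(sep.ks_statistic, 3), "p", sep.ks_p)

report = cross_validate(x, clinical, cfg.replace(n_cv_splits=50))
s = report.summary
print("sensitivity", round(s["sensitivity_clinical"], 3),
      "->", round(s["sensitivity_with_biclusters"], 3),
      "sign-test p", round(s["sign_test_p"], 4))
print("2y AUC", round(s["auc2_clinical_median"], 3),
      "->", round(s["auc2_bicluster_median"], 3))
```

prints (about 10 minutes on one core; exact values for this seed):

```
recovery 0.798
KS 0.593 p 0.005
sensitivity 0.712 -> 0.729 sign-test p 0.0193
2y AUC 0.747 -> 0.789
```

Reading: the search recovers the planted tumour subgroups with mean
best-match Jaccard 0.80; their survival curves separate far more than
size-matched random groups (KS statistic 0.59, randomization p at its
floor of 1/200); and adding bicluster membership to the clinical
covariates raises mean early-relapse sensitivity from 71% to 73% (a win
in significantly more splits than a loss, one-sided sign test p = 0.019)
and the median 2-year time-dependent AUC from 0.75 to 0.79. The AUC gain
is the more stable readout across dataset draws; the sensitivity gain is
real but modest and varies with the realised clinical-covariate skews.

The same pipeline is available as CLI subcommands operating on plain-text
files (expression TSV, clinical CSV, bicluster records):

```bash
bistrat simulate --seed 2 --out-dir run/
bistrat preprocess --expression run/expression.tsv --clinical run/clinical.csv --out-dir run/
bistrat bicluster --expression run/expression_preprocessed.tsv --k 12 --seed 2 \
    --truth run/truth_biclusters.tsv --out-dir run/
bistrat survtest --biclusters run/biclusters.tsv --clinical run/clinical.csv --out-dir run/
bistrat crossval --expression run/expression_preprocessed.tsv --clinical run/clinical.csv \
    --k 12 --seed 2 --out-dir run/
```

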