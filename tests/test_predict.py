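"""Relapse labels, covariate encoding, trees, PC1 assignment, ridge Cox,
time-dependent AUC, and the cross-validation harness."""

import numpy as np
import pandas as pd
import pytest
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from bistrat._rng import stage_rng
from bistrat.bicluster import Bicluster, BiclusterSet
from bistrat.config import RunConfig
from bistrat.predict import (
    assign_to_biclusters,
    bicluster_pc1_profile,
    cross_validate,
    dichotomize,
    encode_covariates,
    fit_conditional_tree,
    membership_frame,
    predict_tree,
    ridge_cox_predict,
    time_dependent_auc,
)
from bistrat.types import ExpressionMatrix

from conftest import make_clinical


class TestDichotomize:
    @pytest.mark.parametrize(
        "time,event,expected",
        [
            (1.5, 1, "early"),
            (2.0, 1, "early"),  # boundary inclusive
            (9.0, 0, "late"),
            (8.0, 1, "late"),
            (1.5, 0, "intermediate"),  # censored before cutoff: no relapse
            (5.0, 1, "intermediate"),
        ],
    )
    def test_label_rules(self, time, event, expected):
        clin = make_clinical(1, [time], [event])
        assert dichotomize(clin).iloc[0] == expected

    def test_labels_partition(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 100)
        e = rng.integers(0, 2, 100)
        lab = dichotomize(make_clinical(100, t, e, rng=rng))
        counts = lab.value_counts()
        assert counts.sum() == 100


class TestEncodeCovariates:
    @pytest.mark.parametrize(
        "size,expected",
        [(5, "<10"), (10, "10-20"), (20, "20-40"), (39.9, "20-40"), (40, ">=40")],
    )
    def test_size_class_boundaries(self, size, expected):
        clin = make_clinical(1, [1.0], [1])
        df = clin.df.copy()
        df.loc[0, "size_mm"] = size
        cov = encode_covariates(type(clin)(df))
        assert cov["size_class"].iloc[0] == expected

    @pytest.mark.parametrize(
        "age,expected",
        [(30, "<40"), (40, "40-50"), (50, "50-60"), (59.9, "50-60"), (60, ">=60")],
    )
    def test_age_class_boundaries(self, age, expected):
        clin = make_clinical(1, [1.0], [1])
        df = clin.df.copy()
        df.loc[0, "age_years"] = age
        cov = encode_covariates(type(clin)(df))
        assert cov["age_class"].iloc[0] == expected

    def test_membership_indicators(self):
        clin = make_clinical(4, [1, 2, 3, 4], [1, 1, 1, 1])
        memb = pd.DataFrame(
            0, index=clin.sample_ids, columns=list(range(1, 11)), dtype=int
        )
        memb.loc["s0", [3, 7]] = 1
        cov = encode_covariates(clin, memb)
        row = cov.loc["s0", [f"bc_{i}" for i in range(1, 11)]].to_numpy()
        assert row.sum() == 2 and row[2] == 1 and row[6] == 1

    def test_na_kept_as_level(self):
        clin = make_clinical(1, [1.0], [1])
        df = clin.df.copy()
        df.loc[0, "size_mm"] = np.nan
        cov = encode_covariates(type(clin)(df))
        assert cov["size_class"].iloc[0] == "NA"


def tree_data(rng, n=200, signal=True):
    cov = pd.DataFrame(
        {
            "a": rng.choice(["x", "y"], n),
            "b": rng.choice(["p", "q", "r"], n),
            "c": rng.choice(["u", "v"], n),
            "d": rng.choice(["m", "n"], n),
            "e": rng.choice(["s", "t"], n),
        },
        index=[f"i{i}" for i in range(n)],
    )
    if signal:
        labels = np.where(cov["a"] == "x", "early", "late")
    else:
        labels = rng.choice(["early", "late"], n)
    return cov, np.asarray(labels)


class TestConditionalTree:
    def test_perfect_predictor_found_at_root(self):
        cov, labels = tree_data(np.random.default_rng(0))
        tree = fit_conditional_tree(cov, labels, n_permutations=9999, seed=1)
        assert tree.root.covariate == "a"
        assert tree.root.p_adjusted <= 1e-3
        preds = predict_tree(tree, cov)
        assert (preds == labels).all()

    def test_null_covariates_rarely_split(self):
        """With 5 covariates independent of the label, Bonferroni keeps the
        tree a single leaf in >= 93% of replicates at alpha = 0.05."""
        no_split = 0
        n_rep = 300
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            cov, labels = tree_data(rng, n=200, signal=False)
            tree = fit_conditional_tree(cov, labels, n_permutations=399, seed=rep)
            no_split += tree.root.is_leaf
        assert no_split / n_rep >= 0.93

    def test_all_same_label_single_leaf(self):
        cov, _ = tree_data(np.random.default_rng(2), n=40)
        tree = fit_conditional_tree(cov, np.array(["late"] * 40), n_permutations=99)
        assert tree.root.is_leaf

    def test_leaf_majority_and_training_error(self):
        rng = np.random.default_rng(3)
        cov, labels = tree_data(rng, n=300)
        # add label noise so leaves are impure
        flip = rng.uniform(size=300) < 0.2
        noisy = np.where(flip, np.where(labels == "early", "late", "early"), labels)
        tree = fit_conditional_tree(cov, noisy, n_permutations=499, seed=4)
        preds = predict_tree(tree, cov)
        err_tree = (preds != noisy).mean()
        # root-only (majority) error
        maj = "early" if (noisy == "early").sum() >= (noisy == "late").sum() else "late"
        err_root = (noisy != maj).mean()
        assert err_tree <= err_root + 1e-12

    def test_min_leaf_respected(self):
        rng = np.random.default_rng(5)
        cov, labels = tree_data(rng, n=100)
        tree = fit_conditional_tree(cov, labels, min_leaf=20, n_permutations=499, seed=6)

        def leaves(node):
            if node.is_leaf:
                return [node]
            return leaves(node.left) + leaves(node.right)

        assert all(leaf.n >= 20 for leaf in leaves(tree.root))

    def test_deterministic_given_seed(self):
        cov, labels = tree_data(np.random.default_rng(7), n=150)
        a = fit_conditional_tree(cov, labels, n_permutations=499, seed=9)
        b = fit_conditional_tree(cov, labels, n_permutations=499, seed=9)
        assert a.root.covariate == b.root.covariate
        assert a.root.p_adjusted == b.root.p_adjusted


class TestPC1Profile:
    def make_matrix(self, vals):
        vals = np.asarray(vals, float)
        return ExpressionMatrix(
            [f"g{i}" for i in range(vals.shape[0])],
            [f"s{j}" for j in range(vals.shape[1])],
            vals,
        )

    def test_rank_one_block_recovers_pattern(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1, 2, 6)
        a = rng.uniform(0.5, 1.5, 4)
        x = self.make_matrix(np.outer(p, a))
        b = Bicluster(1, frozenset(x.sample_ids), frozenset(x.gene_ids), 0.0)
        prof = bicluster_pc1_profile(x, b)
        got = prof.reindex([f"g{i}" for i in range(6)]).to_numpy()
        np.testing.assert_allclose(got / np.linalg.norm(got), p / np.linalg.norm(p),
                                   atol=1e-10)

    def test_duplicate_samples_give_common_profile(self):
        common = np.array([3.0, 1.0, 2.0, 5.0])
        x = self.make_matrix(np.tile(common[:, None], (1, 3)))
        b = Bicluster(1, frozenset(x.sample_ids), frozenset(x.gene_ids), 0.0)
        prof = bicluster_pc1_profile(x, b)
        got = prof.reindex([f"g{i}" for i in range(4)]).to_numpy()
        assert abs(np.corrcoef(got, common)[0, 1]) > 1 - 1e-10

    def test_planted_block_profile_matches_signature(self, small_dataset):
        _, _, x, _, truth = small_dataset
        b = truth[0]
        prof = bicluster_pc1_profile(x, b)
        gi = x.gene_index(list(prof.index))
        si = x.sample_index(sorted(b.sample_ids))
        mean_sig = x.values[np.ix_(gi, si)].mean(axis=1)
        assert np.corrcoef(prof.to_numpy(), mean_sig)[0, 1] >= 0.95

    def test_degenerate_sizes_rejected(self):
        x = self.make_matrix(np.ones((3, 3)))
        b = Bicluster(1, frozenset({"s0"}), frozenset(x.gene_ids), 0.0)
        with pytest.raises(ValueError):
            bicluster_pc1_profile(x, b)


class TestAssignment:
    def test_member_of_rank_one_block_assigned(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1, 2, 8)
        vals = np.outer(p, rng.uniform(0.5, 1.5, 5))
        x = ExpressionMatrix([f"g{i}" for i in range(8)],
                             [f"s{j}" for j in range(5)], vals)
        b = Bicluster(1, frozenset(x.sample_ids[:4]), frozenset(x.gene_ids), 0.0)
        bcs = BiclusterSet([b])
        profiles = {1: bicluster_pc1_profile(x, b)}
        res = assign_to_biclusters(x.to_frame()["s4"], bcs, profiles, 0.9)
        assert 1 in res.ids and not res.fallback

    def test_impossible_threshold_triggers_fallback(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(10, 6))
        x = ExpressionMatrix([f"g{i}" for i in range(10)],
                             [f"s{j}" for j in range(6)], vals)
        bcs = BiclusterSet([
            Bicluster(1, frozenset(x.sample_ids[:3]), frozenset(x.gene_ids[:5]), 0.0),
            Bicluster(2, frozenset(x.sample_ids[3:]), frozenset(x.gene_ids[5:]), 0.0),
        ])
        profiles = {b.id: bicluster_pc1_profile(x, b) for b in bcs}
        res = assign_to_biclusters(x.to_frame()["s0"], bcs, profiles, threshold=1.0)
        assert res.fallback and len(res.ids) == 1

    def test_training_members_reassigned_to_own_bicluster(self, default_dataset):
        """>= 90% of planted members are re-assigned to their own bicluster
        at the 0.9 correlation threshold."""
        _, _, x, _, truth = default_dataset
        profiles = {b.id: bicluster_pc1_profile(x, b) for b in truth}
        full = x.to_frame()
        hits = tot = 0
        rng = np.random.default_rng(0)
        for b in truth:
            members = sorted(b.sample_ids)
            for s in rng.choice(members, size=min(10, len(members)), replace=False):
                res = assign_to_biclusters(full[s], truth, profiles, 0.9)
                hits += b.id in res.ids
                tot += 1
        assert hits / tot >= 0.9


class TestRidgeCox:
    def survival_frame(self, rng, n=150, beta=1.0):
        z = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.15 * np.exp(beta * z)))
        cov = pd.DataFrame({"z": np.where(z == 1, "hi", "lo"),
                            "w": rng.choice(["a", "b"], n)})
        return cov, t, np.ones(n, int), z

    def test_huge_lambda_gives_constant_scores(self):
        rng = np.random.default_rng(0)
        cov, t, e, _ = self.survival_frame(rng)
        res = ridge_cox_predict(cov, t, e, cov, lambdas=[1e8])
        assert np.ptp(res.risk_scores) < 1e-3

    def test_strong_covariate_orders_risk(self):
        rng = np.random.default_rng(1)
        cov, t, e, z = self.survival_frame(rng, beta=1.5)
        res = ridge_cox_predict(cov, t, e, cov)
        hi = res.risk_scores[z == 1].mean()
        lo = res.risk_scores[z == 0].mean()
        assert hi > lo

    def test_planted_signal_concordance_above_chance(self):
        """Test-set C-index clearly above 0.5 on held-out data."""
        cidxs = []
        for rep in range(20):
            rng = stage_rng(rep, "ridge-cidx")
            cov, t, e, z = self.survival_frame(rng, n=200, beta=1.2)
            tr = np.arange(150)
            te = np.arange(150, 200)
            res = ridge_cox_predict(cov.iloc[tr], t[tr], e[tr], cov.iloc[te],
                                    seed=rep)
            s = res.risk_scores
            num = den = 0.0
            for i in range(50):
                for j in range(50):
                    if t[te][i] < t[te][j]:
                        den += 1
                        num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
            cidxs.append(num / den)
        m = np.mean(cidxs)
        se = np.std(cidxs) / np.sqrt(len(cidxs))
        assert m > 0.5 + 3 * se

    def test_no_events_rejected(self):
        cov = pd.DataFrame({"z": ["a", "b", "a"]})
        with pytest.raises(ValueError, match="events"):
            ridge_cox_predict(cov, [1, 2, 3], [0, 0, 0], cov)


class TestTimeDependentAUC:
    def test_perfect_indicator_scores_one(self):
        t = np.array([0.5, 1.0, 1.5, 3.0, 4.0, 5.0])
        e = np.ones(6, int)
        scores = (t <= 2.0).astype(float)
        assert time_dependent_auc(scores, t, e, 2.0) == 1.0

    def test_random_scores_near_half(self):
        aucs = []
        for rep in range(100):
            rng = stage_rng(rep, "auc-null")
            t = rng.exponential(3, 80)
            e = np.ones(80, int)
            aucs.append(time_dependent_auc(rng.normal(size=80), t, e, 2.0))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_negated_score_mirrors_below_half(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(3, 60)
        e = np.ones(60, int)
        s = rng.normal(size=60)
        a = time_dependent_auc(s, t, e, 2.0)
        b = time_dependent_auc(-s, t, e, 2.0)
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(3, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        t[0] = 0.5
        s = rng.normal(size=60)
        a = time_dependent_auc(s, t, e, 2.0)
        b = time_dependent_auc(np.exp(3 * s) + 7, t, e, 2.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_scikit_survival(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(3, 120)
        c = rng.exponential(6, 120)
        obs = np.minimum(t, c)
        e = (t <= c).astype(int)
        s = 0.8 * (t < 2) + rng.normal(0, 0.5, 120)
        y = Surv.from_arrays(e.astype(bool), obs)
        ref = cumulative_dynamic_auc(y, y, s, [2.0])[0][0]
        got = time_dependent_auc(s, obs, e, 2.0)
        assert got == pytest.approx(ref, abs=1e-6)

    def test_no_cases_rejected(self):
        with pytest.raises(ValueError, match="cases"):
            time_dependent_auc([1.0, 2.0], [5.0, 6.0], [1, 1], 2.0)


class TestCrossValidate:
    def test_deterministic_and_reports_consistent(self, small_dataset):
        _, _, x, clin, _ = small_dataset
        cfg = RunConfig(seed=9, k_biclusters=4, n_cv_splits=2,
                        iters_per_bicluster=200, tree_n_permutations=299)
        a = cross_validate(x, clin, cfg)
        b = cross_validate(x, clin, cfg)
        pd.testing.assert_frame_equal(a.per_split, b.per_split)
        assert a.summary == b.summary
        assert (a.per_split["n_test_early"] >= 1).all()
        for col in ["sens_clinical", "sens_bicluster"]:
            assert a.per_split[col].between(0, 1).all()

    def test_membership_frame_matches_bicluster_sets(self):
        bcs = BiclusterSet([
            Bicluster(1, frozenset({"a", "b"}), frozenset({"g"}), 0.0),
            Bicluster(2, frozenset({"b", "c"}), frozenset({"g"}), 0.0),
        ])
        m = membership_frame(bcs, ["a", "b", "c", "d"])
        assert m.loc["b"].tolist() == [1, 1]
        assert m.loc["d"].tolist() == [0, 0]
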