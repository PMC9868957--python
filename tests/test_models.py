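"""Logistic regression, metrics, nested CV, per-phenotype models, holdout."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from germscore.features import PCView, standardize_and_pca
from germscore.models import (ModelError, SeparationError, auprc, auroc,
                              fit_multivariable, fit_univariable,
                              nested_cv, random_oversample,
                              rank_uniformity_test, standardize,
                              temporal_holdout, train_per_phenotype)
from germscore.ontology import AnnotationSet
from germscore.synth import (SyntheticConfig, gen_gene_table,
                             gen_labels_and_annotations, gen_ontology,
                             gen_release_pair)


def _logistic_sample(rng, n, beta, b0=-1.0):
    x = rng.standard_normal(n)
    p = 1 / (1 + np.exp(-(b0 + beta * x)))
    y = (rng.random(n) < p).astype(int)
    return x, y


class TestUnivariableLogistic:
    def test_null_coverage_is_nominal(self):
        rng = np.random.default_rng(42)
        covered = 0
        n_rep = 120
        for _ in range(n_rep):
            x, y = _logistic_sample(rng, 1500, beta=0.0)
            r = fit_univariable(standardize(x), y)
            covered += r.ci_low <= 1.0 <= r.ci_high
        # 95% nominal coverage; binomial 3 SE band around 0.95
        assert covered / n_rep == pytest.approx(0.95, abs=0.06)

    def test_recovers_planted_effect(self):
        rng = np.random.default_rng(7)
        x, y = _logistic_sample(rng, 20_000, beta=np.log(1.9))
        r = fit_univariable(standardize(x), y)
        assert r.odds_ratio == pytest.approx(1.9, abs=0.12)
        assert r.ci_low <= r.odds_ratio <= r.ci_high

    def test_perfect_separation_is_an_error(self):
        y = np.array([0, 1] * 20)
        with pytest.raises(SeparationError):
            fit_univariable(standardize(y.astype(float)), y)

    def test_single_class_is_an_error(self):
        with pytest.raises(ModelError):
            fit_univariable(np.r_[np.zeros(5), np.ones(5)] - 0.5,
                            np.ones(10))


class TestMultivariableLogistic:
    @staticmethod
    def _instance(rng, n=800, k=5):
        table = pd.DataFrame(rng.standard_normal((n, k)),
                             columns=[f"f{i}" for i in range(k)])
        pcs = standardize_and_pca(table, feature_columns=list(table.columns))
        tsm = rng.gamma(2.0, 3.0, size=n)
        age = rng.integers(1, 21, size=n)
        lin = -1.0 + np.log(2.0) * standardize(tsm) + 0.1 * (age - 10.5)
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        return tsm, age, pcs, y

    def test_invariant_to_orthogonal_reparametrization(self, rng):
        tsm, age, pcs, y = self._instance(rng)
        res = fit_multivariable(tsm, age, pcs, y)
        k = pcs.component_scores.shape[1]
        q, _ = np.linalg.qr(rng.standard_normal((k, k)))
        rotated = PCView(
            loadings=pcs.loadings, explained_variance=pcs.explained_variance,
            dropped_feature=pcs.dropped_feature,
            feature_means=pcs.feature_means,
            feature_scales=pcs.feature_scales,
            component_scores=pd.DataFrame(
                pcs.component_scores.to_numpy() @ q,
                columns=pcs.component_scores.columns))
        res_rot = fit_multivariable(tsm, age, rotated, y)
        tsm_or = {r.term: r.odds_ratio for r in res}["tsm"]
        tsm_or_rot = {r.term: r.odds_ratio for r in res_rot}["tsm"]
        assert tsm_or == pytest.approx(tsm_or_rot, abs=1e-6)

    def test_recovers_planted_tsm_and_age(self, rng):
        tsm, age, pcs, y = self._instance(rng, n=4000)
        res = sorted(fit_multivariable(tsm, age, pcs, y),
                     key=lambda r: r.p_value)
        assert {res[0].term, res[1].term} == {"tsm", "age"}

    def test_age_categorical_design(self, rng):
        tsm, age, pcs, y = self._instance(rng, n=2000)
        res = fit_multivariable(tsm, age, pcs, y, age_categorical=True)
        age_terms = [r for r in res if r.term.startswith("age_")]
        assert len(age_terms) == len(np.unique(age)) - 1

    def test_duplicated_covariate_is_a_rank_error(self, rng):
        tsm, age, pcs, y = self._instance(rng)
        driver = pd.DataFrame({"driver_a": np.repeat([0.0, 1.0], 400)})
        driver["driver_b"] = driver["driver_a"]
        with pytest.raises(ModelError, match="rank deficient"):
            fit_multivariable(tsm, age, pcs, y, extra_covariates=driver)


class TestMetrics:
    def test_perfect_and_reversed_separation(self):
        y = np.array([0, 0, 1, 1])
        assert auroc(np.array([1, 2, 3, 4]), y) == 1.0
        assert auroc(np.array([4, 3, 2, 1]), y) == 0.0
        assert auprc(np.array([1, 2, 3, 4]), y) == 1.0

    def test_single_class_is_an_error(self):
        with pytest.raises(ModelError):
            auroc(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 10, size=50).astype(float)
            labels = rng.integers(0, 2, size=50)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > n) + 0.5 * (p == n)
                       for p in pos for n in neg)
            oracle = wins / (len(pos) * len(neg))
            assert auroc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(200)
        labels = rng.integers(0, 2, size=200)
        a = auroc(scores, labels)
        assert auroc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
        assert auroc(3 * scores - 7, labels) == pytest.approx(a, abs=1e-12)


class TestOversampling:
    def test_balances_classes_and_keeps_all_rows(self, rng):
        X = rng.standard_normal((30, 2))
        y = np.r_[np.ones(5), np.zeros(25)].astype(int)
        Xo, yo, idx = random_oversample(X, y, rng)
        assert (yo == 1).sum() == (yo == 0).sum() == 25
        assert set(idx[:30]) == set(range(30))
        assert set(idx) <= set(range(30))  # leakage guard: original rows only

    def test_noop_on_balanced_data(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.r_[np.ones(5), np.zeros(5)].astype(int)
        Xo, yo, idx = random_oversample(X, y, rng)
        assert len(yo) == 10 and np.array_equal(idx, np.arange(10))


class TestNestedCV:
    def test_null_labels_give_chance_auroc(self, rng):
        X = rng.standard_normal((400, 6))
        y = rng.integers(0, 2, size=400)
        rep = nested_cv("logistic", X, y, outer_folds=5,
                        grid={"C": [1.0]}, seed=3)
        se = np.std(rep.fold_aurocs, ddof=1) / np.sqrt(5)
        assert abs(rep.mean_auroc - 0.5) < 3 * se + 0.02

    def test_report_bookkeeping(self, rng):
        X = rng.standard_normal((300, 4))
        beta = np.array([1.5, 0, 0, 0])
        y = (rng.random(300) < 1 / (1 + np.exp(-(X @ beta)))).astype(int)
        rep = nested_cv("logistic", X, y, outer_folds=5,
                        grid={"C": [0.1, 1.0]}, seed=0)
        assert len(rep.fold_aurocs) == 5
        assert rep.baseline_auprc == pytest.approx(y.mean())
        assert rep.auprc_gain == pytest.approx(
            rep.mean_auprc / y.mean() - 1.0)
        assert rep.auroc_ci[0] <= rep.mean_auroc <= rep.auroc_ci[1]

    def test_oversampling_noop_when_balanced(self, rng):
        X = rng.standard_normal((200, 3))
        y = np.r_[np.ones(100), np.zeros(100)].astype(int)
        a = nested_cv("random_forest", X, y, outer_folds=4,
                      grid={"n_estimators": [20]}, seed=5, oversample=True)
        b = nested_cv("random_forest", X, y, outer_folds=4,
                      grid={"n_estimators": [20]}, seed=5, oversample=False)
        assert a.fold_aurocs == b.fold_aurocs

    def test_empty_grid_is_an_error(self, rng):
        with pytest.raises(ModelError):
            nested_cv("logistic", rng.standard_normal((50, 2)),
                      np.r_[np.ones(25), np.zeros(25)].astype(int),
                      grid={}, seed=0)


def _per_phenotype_setup(rng, n=300, pos_a=60, pos_b=39):
    table = pd.DataFrame(
        rng.standard_normal((n, 4)),
        columns=["tsm_total", "age", "f1", "f2"],
        index=[f"G{i:04d}" for i in range(n)])
    genes = list(table.index)
    pairs = {(g, "HP:A") for g in genes[:pos_a]} | \
            {(g, "HP:B") for g in genes[:pos_b]}
    return table, AnnotationSet(frozenset(pairs), "expanded")


class TestTrainPerPhenotype:
    def test_min_genes_boundary(self, rng):
        table, expanded = _per_phenotype_setup(rng, pos_a=40, pos_b=39)
        ms = train_per_phenotype(table, expanded, min_genes=40,
                                 paradigm="logistic", grid={"C": [1.0]},
                                 outer_folds=4, seed=0,
                                 feature_columns=list(table.columns))
        assert set(ms.models) == {"HP:A"}
        assert ms.models["HP:A"].n_positive == 40
        probs = ms.probability_table()
        assert probs.shape == (len(table), 1)
        assert probs.to_numpy().min() >= 0 and probs.to_numpy().max() <= 1

    def test_no_qualifying_term_is_an_error(self, rng):
        table, expanded = _per_phenotype_setup(rng, pos_a=10, pos_b=10)
        with pytest.raises(ModelError):
            train_per_phenotype(table, expanded, min_genes=100,
                                paradigm="logistic", grid={"C": [1.0]},
                                feature_columns=list(table.columns))


@pytest.fixture(scope="module")
def planted_universe():
    cfg = SyntheticConfig(n_genes=1200, n_terms=50, seed=21)
    _, table, _ = gen_gene_table(cfg)
    ontology, neoplasm = gen_ontology(cfg)
    direct, labels, latent = gen_labels_and_annotations(cfg, table,
                                                        ontology, neoplasm)
    return cfg, table, ontology, neoplasm, direct, labels, latent


class TestTemporalHoldout:
    def test_identical_releases_are_an_error(self, planted_universe):
        cfg, table, ontology, neoplasm, direct, *_ = planted_universe
        from germscore.ontology import expand_annotations
        old = expand_annotations(direct, ontology, neoplasm)
        with pytest.raises(ModelError, match="newly annotated"):
            temporal_holdout(old, old, table)

    def test_balanced_test_set_size_and_signal(self, planted_universe):
        cfg, table, ontology, neoplasm, direct, labels, latent = \
            planted_universe
        from germscore.ontology import expand_annotations
        old_d, new_d = gen_release_pair(cfg, direct, labels, n_new=120)
        old = expand_annotations(old_d, ontology, neoplasm)
        new = expand_annotations(new_d, ontology, neoplasm)
        res = temporal_holdout(old, new, table, mode="balanced",
                               paradigm="logistic", grid={"C": [1.0]},
                               seed=4)
        assert res.n_new_positive == 120
        assert res.n_test == 240
        assert res.auroc > 0.5  # planted signal should be recovered

    def test_prevalence_matched_test_set_fraction(self, planted_universe):
        cfg, table, ontology, neoplasm, direct, labels, latent = \
            planted_universe
        from germscore.ontology import expand_annotations
        old_d, new_d = gen_release_pair(cfg, direct, labels, n_new=100)
        old = expand_annotations(old_d, ontology, neoplasm)
        new = expand_annotations(new_d, ontology, neoplasm)
        res = temporal_holdout(old, new, table, mode="prevalence_matched",
                               positive_fraction=0.22, paradigm="logistic",
                               grid={"C": [1.0]}, seed=4)
        assert 100 / res.n_test == pytest.approx(0.22, abs=0.01)


class TestRankUniformity:
    def test_uniform_candidates_give_uniform_p(self, rng):
        probs = pd.Series(rng.random(400),
                          index=[f"G{i}" for i in range(400)])
        training = set(probs.index[:50])
        pool = [g for g in probs.index if g not in training]
        pvals = [rank_uniformity_test(set(rng.choice(pool, 20,
                                                     replace=False)),
                                      probs, training)
                 for _ in range(100)]
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_top_candidates_give_tiny_p(self, rng):
        probs = pd.Series(rng.random(400),
                          index=[f"G{i}" for i in range(400)])
        top = set(probs.nlargest(25).index)
        p = rank_uniformity_test(top, probs, training_genes=set())
        assert p < 1e-10

    def test_empty_candidates_after_exclusion_is_an_error(self, rng):
        probs = pd.Series(rng.random(10),
                          index=[f"G{i}" for i in range(10)])
        with pytest.raises(ModelError):
            rank_uniformity_test({"G1"}, probs, training_genes={"G1"})

    def test_matches_normal_approximation_on_brute_force_u(self, rng):
        # independent oracle: U by explicit pairwise comparison, p from the
        # normal approximation with continuity correction (no ties)
        probs = pd.Series(rng.standard_normal(200),
                          index=[f"G{i}" for i in range(200)])
        candidates = set(rng.choice(probs.index, 30, replace=False))
        rest = [g for g in probs.index if g not in candidates]
        u = sum(probs[c] > probs[r] for c in candidates for r in rest)
        n1, n2 = len(candidates), len(rest)
        mu, sd = n1 * n2 / 2, np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        z = (u - mu - np.sign(u - mu) * 0.5) / sd
        oracle_p = 2 * scipy.stats.norm.sf(abs(z))
        p = rank_uniformity_test(candidates, probs, set())
        assert p == pytest.approx(oracle_p, abs=1e-3)
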