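"""Regression and machine-learning layer.

Univariable and multivariable logistic regression quantify how strongly TSM
(total somatic mutations, per SD) and gene age predict involvement in
phenotypic abnormality (IPA) while controlling for the principal components
of the genomic/epigenomic features.  A pluggable classifier bench is
evaluated by nested cross-validation (10 outer folds for performance, 3
inner folds for hyperparameter grid search) with random oversampling of the
minority class applied strictly inside training partitions.  Per-phenotype
models, a temporal holdout against a later annotation release, and a
rank-uniformity test for external candidate gene lists complete the layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.base import clone
from sklearn.ensemble import (AdaBoostClassifier,
                              HistGradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import PCView
from .ontology import AnnotationSet

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    """Raised for invalid modelling inputs."""


class SeparationError(ModelError):
    """Raised when a logistic fit is degenerate (perfect separation)."""


@dataclass(frozen=True)
class RegressionResult:
    """One predictor's effect in a logistic model (OR per 1 SD for numeric
    standardized predictors), with Wald 95% CI and two-sided p-value."""

    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class CVReport:
    """Outer-fold performance of one paradigm under nested cross-validation."""

    paradigm: str
    fold_aurocs: tuple[float, ...]
    mean_auroc: float
    auroc_ci: tuple[float, float]
    fold_auprcs: tuple[float, ...]
    mean_auprc: float
    baseline_auprc: float
    auprc_gain: float
    best_params: tuple[dict, ...] = field(default=())


@dataclass
class PhenotypeModel:
    """A fitted per-phenotype classifier with its CV report and per-gene
    predicted probabilities over the whole gene universe."""

    term: str
    model: object
    report: CVReport
    probabilities: pd.Series
    n_positive: int


@dataclass
class PhenotypeModelSet:
    models: dict[str, PhenotypeModel]
    min_genes: int

    def probability_table(self) -> pd.DataFrame:
        """Genes x terms matrix of predicted probabilities."""
        return pd.DataFrame({t: m.probabilities
                             for t, m in self.models.items()})


# --------------------------------------------------------------------------
# logistic regression
# --------------------------------------------------------------------------

def _logit_fit(X: pd.DataFrame, y: np.ndarray):
    """MLE logistic fit with separation diagnostics."""
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ModelError("labels contain a single class")
    model = sm.Logit(y, X)
    import warnings
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError or the warning above
        raise SeparationError(f"logistic fit is degenerate: {exc}") from exc
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 50):
        raise SeparationError(
            "logistic fit is degenerate: unbounded coefficient "
            "(perfect or quasi-perfect separation)")
    return res


def _results_from_fit(res, names: Sequence[str]) -> list[RegressionResult]:
    ci = np.asarray(res.conf_int(alpha=0.05))
    params = np.asarray(res.params)
    pvalues = np.asarray(res.pvalues)
    out = []
    for i, name in enumerate(names):
        if name == "const":
            continue
        out.append(RegressionResult(
            term=name,
            odds_ratio=float(np.exp(params[i])),
            ci_low=float(np.exp(ci[i, 0])),
            ci_high=float(np.exp(ci[i, 1])),
            p_value=float(pvalues[i]),
        ))
    return out


def standardize(x: np.ndarray | pd.Series) -> np.ndarray:
    """Rescale to zero mean, unit SD."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ModelError("cannot standardize a constant predictor")
    return (x - x.mean()) / sd


def fit_univariable(x: np.ndarray, y: np.ndarray,
                    name: str = "x") -> RegressionResult:
    """Univariable logistic regression of a binary outcome on one
    standardized predictor; the OR is per 1 SD of the predictor."""
    x = np.asarray(x, dtype=float)
    X = pd.DataFrame({"const": np.ones(len(x)), name: x})
    res = _logit_fit(X, y)
    return _results_from_fit(res, ["const", name])[0]


def _age_design(age: np.ndarray, categorical: bool) -> pd.DataFrame:
    if not categorical:
        return pd.DataFrame({"age": standardize(age)})
    levels = sorted(pd.unique(age))
    dummies = pd.get_dummies(pd.Categorical(age, categories=levels),
                             prefix="age", drop_first=True, dtype=float)
    return dummies.reset_index(drop=True)


def fit_multivariable(tsm: np.ndarray, age: np.ndarray, pcs: PCView,
                      y: np.ndarray,
                      extra_covariates: pd.DataFrame | None = None,
                      age_categorical: bool = False,
                      ) -> list[RegressionResult]:
    """Multivariable logistic regression of IPA on TSM, gene age, and the
    principal components of the genomic/epigenomic features.

    TSM and numeric age are standardized (ORs per 1 SD); age may instead
    enter as a 20-level categorical variable.  Extra covariates (e.g. a
    binary cancer-driver flag) are appended as given.  A rank-deficient
    design is a hard error naming the aliased columns.
    """
    parts = [pd.DataFrame({"tsm": standardize(tsm)}),
             _age_design(np.asarray(age), age_categorical),
             pcs.component_scores.reset_index(drop=True)]
    if extra_covariates is not None:
        parts.append(extra_covariates.reset_index(drop=True))
    X = pd.concat(parts, axis=1)
    X.insert(0, "const", 1.0)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(r))
        aliased = [X.columns[i] for i in
                   np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ModelError(f"design matrix is rank deficient; aliased "
                         f"columns: {aliased}")

    res = _logit_fit(X, np.asarray(y))
    return _results_from_fit(res, list(X.columns))


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ModelError("metric undefined: labels contain a single class")
    return labels


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (equals the midrank-normalized
    Mann-Whitney U statistic)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise integration)."""
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels,
                                         np.asarray(scores, dtype=float)))


# --------------------------------------------------------------------------
# classifier bench and nested cross-validation
# --------------------------------------------------------------------------

def _make_estimator(name: str, seed: int):
    # scale-sensitive paradigms get a standardization step in-pipeline so
    # the scaler is always fit on training partitions only
    if name == "logistic":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", LogisticRegression(max_iter=1000))])
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "svm":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", SVC(random_state=seed))])
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "hist_gradient_boosting":
        return HistGradientBoostingClassifier(random_state=seed)
    if name == "gaussian_nb":
        return GaussianNB()
    raise ModelError(f"unknown paradigm: {name!r}")


def _set_params(estimator, params: Mapping) -> object:
    """Apply grid params, prefixing for pipeline-wrapped estimators."""
    if isinstance(estimator, Pipeline):
        params = {f"clf__{k}": v for k, v in params.items()}
    return estimator.set_params(**params)


#: Default hyperparameter grids, kept small so nested CV stays desk-scale.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic": {"C": [0.01, 0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [100, 300],
                      "max_depth": [None, 10],
                      "min_samples_leaf": [1, 5]},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "adaboost": {"n_estimators": [50, 200]},
    "hist_gradient_boosting": {"learning_rate": [0.05, 0.1],
                               "max_depth": [None, 6]},
    "gaussian_nb": {"var_smoothing": [1e-9, 1e-6]},
}

PARADIGMS = tuple(DEFAULT_GRIDS)


def random_oversample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample the minority class with replacement to class parity.

    Returns the resampled X, y, and the row indices drawn (all original rows
    are kept; only extra minority copies are appended), so callers can audit
    that no test-set row ever leaks into training.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts[0] == counts[1]:
        idx = np.arange(len(y))
        return X, y, idx
    minority = classes[np.argmin(counts)]
    n_extra = int(counts.max() - counts.min())
    pool = np.flatnonzero(y == minority)
    extra = rng.choice(pool, size=n_extra, replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    return X[idx], y[idx], idx


def _scores_of(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def _inner_grid_search(name: str, X: np.ndarray, y: np.ndarray,
                       grid: Mapping[str, list], inner_folds: int,
                       oversample: bool, rng: np.random.Generator,
                       seed: int) -> dict:
    """Pick the grid point maximizing mean inner-fold AUROC."""
    combos = list(ParameterGrid(dict(grid)))
    if len(combos) == 1:
        return combos[0]
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                          random_state=seed)
    mean_scores = []
    for params in combos:
        scores = []
        for tr, va in skf.split(X, y):
            Xt, yt = X[tr], y[tr]
            if oversample:
                Xt, yt, _ = random_oversample(Xt, yt, rng)
            est = _set_params(clone(_make_estimator(name, seed)), params)
            est.fit(Xt, yt)
            scores.append(auroc(_scores_of(est, X[va]), y[va]))
        mean_scores.append(np.mean(scores))
    return combos[int(np.argmax(mean_scores))]


def nested_cv(paradigm: str, X: np.ndarray, y: np.ndarray,
              outer_folds: int = 10, inner_folds: int = 3,
              grid: Mapping[str, list] | None = None,
              seed: int = 0, oversample: bool = True) -> CVReport:
    """Nested cross-validation of one classifier paradigm.

    The data are split into ``outer_folds`` stratified folds used in turn as
    the test set; hyperparameters are tuned on the remaining folds by
    ``inner_folds``-fold grid search maximizing AUROC.  Random oversampling
    of the minority class is applied only inside training partitions (never
    to validation or test folds).  The mean outer-fold AUROC is the
    performance measure; its 95% CI uses a normal approximation over folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    if grid is None:
        grid = DEFAULT_GRIDS[paradigm]
    if not grid:
        raise ModelError("hyperparameter grid is empty")
    if np.bincount(y.astype(int)).min() < outer_folds:
        raise ModelError("too few minority examples for stratified "
                         f"{outer_folds}-fold CV")

    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True,
                          random_state=seed)
    fold_aurocs, fold_auprcs, best = [], [], []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        params = _inner_grid_search(paradigm, X[tr], y[tr], grid,
                                    inner_folds, oversample, rng, seed + k)
        Xt, yt = X[tr], y[tr]
        if oversample:
            Xt, yt, idx = random_oversample(Xt, yt, rng)
            assert not set(tr[idx]) & set(te)  # oversampling leakage guard
        est = _set_params(clone(_make_estimator(paradigm, seed + k)), params)
        est.fit(Xt, yt)
        s = _scores_of(est, X[te])
        fold_aurocs.append(auroc(s, y[te]))
        fold_auprcs.append(auprc(s, y[te]))
        best.append(params)

    mean_auroc = float(np.mean(fold_aurocs))
    se = float(np.std(fold_aurocs, ddof=1) / np.sqrt(outer_folds))
    baseline = float(np.mean(y))
    mean_auprc = float(np.mean(fold_auprcs))
    return CVReport(
        paradigm=paradigm,
        fold_aurocs=tuple(fold_aurocs),
        mean_auroc=mean_auroc,
        auroc_ci=(mean_auroc - 1.96 * se, mean_auroc + 1.96 * se),
        fold_auprcs=tuple(fold_auprcs),
        mean_auprc=mean_auprc,
        baseline_auprc=baseline,
        auprc_gain=mean_auprc / baseline - 1.0,
        best_params=tuple(best),
    )


# --------------------------------------------------------------------------
# per-phenotype models
# --------------------------------------------------------------------------

def feature_matrix(table: pd.DataFrame,
                   feature_columns: Sequence[str] | None = None,
                   ) -> tuple[np.ndarray, list[str]]:
    """Extract the ML design matrix (TSM + age + genomic features)."""
    from .features import GENOMIC_FEATURES
    cols = list(feature_columns) if feature_columns is not None else (
        ["tsm_total", "age"] + list(GENOMIC_FEATURES))
    return table[cols].to_numpy(dtype=float), cols


def train_per_phenotype(table: pd.DataFrame, expanded: AnnotationSet,
                        min_genes: int = 100,
                        paradigm: str = "random_forest",
                        grid: Mapping[str, list] | None = None,
                        outer_folds: int = 10, inner_folds: int = 3,
                        feature_columns: Sequence[str] | None = None,
                        seed: int = 0) -> PhenotypeModelSet:
    """Fit one classifier per phenotype term with >= ``min_genes`` genes.

    Each qualifying term's positives are the genes annotated to it (after
    expansion); the rest of the feature-table universe are negatives.  Every
    term gets a nested-CV report (AUPRC gain is relative to that term's own
    prevalence) and a final model refit on all genes, whose predicted
    probabilities over the whole universe feed the disease-scoring layer.
    """
    X, _ = feature_matrix(table, feature_columns)
    universe = table.index
    by_term: dict[str, set[str]] = {}
    for gene, term in expanded.pairs:
        by_term.setdefault(term, set()).add(gene)

    models: dict[str, PhenotypeModel] = {}
    rng_master = np.random.SeedSequence(seed)
    for term in sorted(by_term):
        genes = by_term[term] & set(universe)
        if len(genes) < min_genes:
            continue
        y = np.asarray(universe.isin(genes), dtype=int)
        if y.sum() == len(y):  # no negatives left
            continue
        term_seed = int(np.random.default_rng(
            rng_master.spawn(1)[0]).integers(2**31))
        report = nested_cv(paradigm, X, y, outer_folds=outer_folds,
                           inner_folds=inner_folds, grid=grid,
                           seed=term_seed)
        params = report.best_params[0] if report.best_params else {}
        rng = np.random.default_rng(term_seed)
        Xo, yo, _ = random_oversample(X, y, rng)
        final = _set_params(clone(_make_estimator(paradigm, term_seed)), params)
        final.fit(Xo, yo)
        prob = pd.Series(_scores_of(final, X), index=universe, name=term)
        models[term] = PhenotypeModel(term=term, model=final, report=report,
                                      probabilities=prob,
                                      n_positive=int(y.sum()))
    if not models:
        raise ModelError(f"no phenotype term has >= {min_genes} "
                         "associated genes")
    logger.info("train_per_phenotype: trained %d models (min_genes=%d)",
                len(models), min_genes)
    return PhenotypeModelSet(models=models, min_genes=min_genes)


# --------------------------------------------------------------------------
# temporal holdout and rank-uniformity test
# --------------------------------------------------------------------------

def ipa_labels(expanded: AnnotationSet, universe: pd.Index) -> pd.Series:
    """IPA label: 1 when the gene keeps any annotation after expansion."""
    genes = expanded.genes()
    return pd.Series(universe.isin(genes).astype(int), index=universe,
                     name="ipa")


class HoldoutResult(NamedTuple):
    """Temporal-holdout outcome: AUROC on the held-out genes, Mann-Whitney
    p-value, and the composition of the test set."""

    auroc: float
    p_value: float
    n_test: int
    n_new_positive: int


def temporal_holdout(old: AnnotationSet, new: AnnotationSet,
                     table: pd.DataFrame, mode: str = "balanced",
                     positive_fraction: float = 0.22,
                     paradigm: str = "random_forest",
                     grid: Mapping[str, list] | None = None,
                     inner_folds: int = 3,
                     feature_columns: Sequence[str] | None = None,
                     seed: int = 0) -> HoldoutResult:
    """Validate against annotations gained between two ontology releases.

    Test positives are the genes newly annotated in ``new`` but not in
    ``old``; test negatives are sampled from genes negative in both releases
    (as many as the positives in ``balanced`` mode, or enough to reach
    ``positive_fraction`` in ``prevalence_matched`` mode).  The remaining
    genes train a fresh model (hyperparameters re-tuned on the training
    portion).  Returns the held-out AUROC and a Mann-Whitney p-value.
    """
    if mode not in ("balanced", "prevalence_matched"):
        raise ModelError(f"unknown holdout mode: {mode!r}")
    universe = table.index
    y_old = ipa_labels(old, universe)
    y_new = ipa_labels(new, universe)
    if ((y_new == 0) & (y_old == 1)).any():
        raise ModelError("annotation releases inconsistent: a gene lost "
                         "its annotation in the newer release")

    new_pos = universe[(y_new == 1) & (y_old == 0)]
    if len(new_pos) == 0:
        raise ModelError("no newly annotated genes between the releases")
    both_neg = universe[(y_new == 0) & (y_old == 0)]
    if mode == "balanced":
        n_neg = len(new_pos)
    else:
        n_neg = int(round(len(new_pos) * (1 - positive_fraction)
                          / positive_fraction))
    if n_neg > len(both_neg):
        raise ModelError("not enough doubly-negative genes for the test set")
    rng = np.random.default_rng(seed)
    test_neg = pd.Index(rng.choice(both_neg, size=n_neg, replace=False))

    test_genes = new_pos.union(test_neg)
    train_genes = universe.difference(test_genes)
    X_all, _ = feature_matrix(table, feature_columns)
    pos_map = pd.Series(np.arange(len(universe)), index=universe)
    X_tr = X_all[pos_map[train_genes].to_numpy()]
    y_tr = y_old[train_genes].to_numpy()
    X_te = X_all[pos_map[test_genes].to_numpy()]
    y_te = y_new[test_genes].to_numpy()

    if grid is None:
        grid = DEFAULT_GRIDS[paradigm]
    params = _inner_grid_search(paradigm, X_tr, y_tr, grid, inner_folds,
                                True, rng, seed)
    Xo, yo, _ = random_oversample(X_tr, y_tr, rng)
    est = _set_params(clone(_make_estimator(paradigm, seed)), params)
    est.fit(Xo, yo)
    s = _scores_of(est, X_te)
    stat_p = scipy.stats.mannwhitneyu(s[y_te == 1], s[y_te == 0],
                                      alternative="two-sided").pvalue
    return HoldoutResult(auroc=auroc(s, y_te), p_value=float(stat_p),
                         n_test=len(test_genes),
                         n_new_positive=len(new_pos))


def rank_uniformity_test(candidate_genes: set[str],
                         probabilities: pd.Series,
                         training_genes: set[str]) -> float:
    """Mann-Whitney test of whether an external candidate gene list sits
    non-uniformly in a phenotype model's probability ranking.

    Candidates that were training positives for the term are excluded; the
    remaining candidates' probabilities are compared (two-sided) against
    those of all other non-training genes.
    """
    candidates = (set(candidate_genes) - set(training_genes)) \
        & set(probabilities.index)
    if not candidates:
        raise ModelError("no candidate genes remain after excluding the "
                         "training positives")
    rest = set(probabilities.index) - set(training_genes) - candidates
    if not rest:
        raise ModelError("no background genes remain")
    res = scipy.stats.mannwhitneyu(
        probabilities[sorted(candidates)].to_numpy(),
        probabilities[sorted(rest)].to_numpy(),
        alternative="two-sided")
    return float(res.pvalue)
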