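"""Disease-gene prioritization by ontology-aware rank aggregation.

Per-phenotype model probabilities are rank-transformed (rank 1 = highest
probability, midrank ties, normalized by the gene universe size so ranks lie
in (0, 1]; lower means a stronger predicted association).  A disease's score
for a gene is the geometric mean of the gene's normalized ranks over the
disease's phenotypes, after mapping unmodelled phenotypes to the closest
scored ancestor in the ontology.  Significance is assessed against a
permutation null: the gene column of the gene-disease association list is
shuffled (preserving both marginals), scores are recomputed, and per-bin
empirical p-values over a 20-bin histogram flag enriched score ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .ontology import Ontology, closest_scored_ancestor

logger = logging.getLogger(__name__)


class DiseaseScoringError(ValueError):
    """Raised for invalid disease-scoring inputs."""


@dataclass(frozen=True)
class DiseaseCatalog:
    """Diseases with their unique phenotype terms and gene associations."""

    phenotypes: dict[str, tuple[str, ...]]   # disease -> unique terms
    associations: tuple[tuple[str, str], ...]  # (gene, disease) pairs

    def __post_init__(self) -> None:
        for disease, terms in self.phenotypes.items():
            if not terms:
                raise DiseaseScoringError(
                    f"disease {disease!r} has an empty phenotype list")
        for _, disease in self.associations:
            if disease not in self.phenotypes:
                raise DiseaseScoringError(
                    f"association references unknown disease: {disease!r}")


@dataclass(frozen=True)
class DiseaseScoreResult:
    """Observed scores, permutation nulls, and per-bin empirical p-values."""

    scores: pd.DataFrame            # columns: gene, disease, score, n_phenotypes_used
    null_scores: tuple[np.ndarray, ...]
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    null_bin_counts: np.ndarray     # n_randomizations x n_bins
    bin_pvalues: np.ndarray
    flagged_bins: np.ndarray        # boolean, p < alpha
    alpha: float
    low_score_threshold: float
    low_score_observed: int
    low_score_null_mean: float
    low_score_pvalue: float


def rank_transform(probabilities: pd.Series) -> pd.Series:
    """Normalized midranks of model probabilities, in (0, 1].

    The gene with the highest probability receives rank 1; ties get the
    midrank; ranks are divided by the number of genes so that a lower value
    means a stronger predicted gene-phenotype association.
    """
    if len(probabilities) == 0:
        raise DiseaseScoringError("empty probability vector")
    ranks = scipy.stats.rankdata(-probabilities.to_numpy(dtype=float),
                                 method="average")
    return pd.Series(ranks / len(ranks), index=probabilities.index,
                     name="normalized_rank")


def rank_table(probability_table: pd.DataFrame) -> pd.DataFrame:
    """Rank-transform every term's probability column (genes x terms)."""
    return probability_table.apply(rank_transform, axis=0)


def map_disease_phenotypes(disease: str, catalog: DiseaseCatalog,
                           ontology: Ontology, scored_terms: set[str],
                           gene_counts: Mapping[str, int] | None = None,
                           ) -> tuple[str, ...]:
    """Map a disease's phenotypes to scored terms, dropping duplicates.

    Each phenotype is replaced by itself (when modelled) or by its closest
    scored ancestor; phenotypes with no scored ancestor are dropped with a
    warning.  Duplicates arising from the mapping are collapsed.
    """
    if disease not in catalog.phenotypes:
        raise DiseaseScoringError(f"unknown disease: {disease!r}")
    mapped: list[str] = []
    for term in catalog.phenotypes[disease]:
        hit = closest_scored_ancestor(term, scored_terms, ontology,
                                      gene_counts=gene_counts)
        if hit is None:
            logger.warning("disease %s: phenotype %s has no scored "
                           "ancestor; dropped", disease, term)
            continue
        if hit not in mapped:
            mapped.append(hit)
    return tuple(mapped)


def disease_score(gene: str, disease: str, ranks: pd.DataFrame,
                  catalog: DiseaseCatalog, ontology: Ontology,
                  scored_terms: set[str] | None = None,
                  mapped_terms: Sequence[str] | None = None,
                  ) -> float | None:
    """Geometric mean of a gene's normalized ranks over a disease's
    phenotypes (after closest-scored-ancestor mapping).

    Returns None when none of the disease's phenotypes maps to a scored
    term.  Computed as exp(mean(log rank)) for numerical stability.
    """
    if mapped_terms is None:
        if scored_terms is None:
            scored_terms = set(ranks.columns)
        mapped_terms = map_disease_phenotypes(disease, catalog, ontology,
                                              scored_terms)
    if not mapped_terms:
        return None
    r = ranks.loc[gene, list(mapped_terms)].to_numpy(dtype=float)
    return float(np.exp(np.mean(np.log(r))))


def score_catalog(catalog: DiseaseCatalog, ranks: pd.DataFrame,
                  ontology: Ontology,
                  scored_terms: set[str] | None = None) -> pd.DataFrame:
    """Score every (gene, disease) association in the catalog.

    Returns a DataFrame (gene, disease, score, n_phenotypes_used);
    associations whose disease has no mappable phenotype are dropped.
    """
    if scored_terms is None:
        scored_terms = set(ranks.columns)
    mapped: dict[str, tuple[str, ...]] = {
        d: map_disease_phenotypes(d, catalog, ontology, scored_terms)
        for d in catalog.phenotypes}
    log_ranks = np.log(ranks.to_numpy(dtype=float))
    gene_pos = {g: i for i, g in enumerate(ranks.index)}
    term_pos = {t: j for j, t in enumerate(ranks.columns)}

    rows = []
    for gene, disease in catalog.associations:
        terms = mapped[disease]
        if not terms or gene not in gene_pos:
            continue
        cols = [term_pos[t] for t in terms]
        score = float(np.exp(log_ranks[gene_pos[gene], cols].mean()))
        rows.append((gene, disease, score, len(terms)))
    return pd.DataFrame(rows, columns=["gene", "disease", "score",
                                       "n_phenotypes_used"])


def randomize_associations(catalog: DiseaseCatalog,
                           n_randomizations: int = 100,
                           seed: int = 0) -> list[DiseaseCatalog]:
    """Permute the gene column of the association list, uniformly without
    replacement, once per randomization.

    Per-disease association counts and the global gene multiset are both
    preserved (both marginals of the bipartite association graph).  Each
    permutation draws from an independently spawned stream of the master
    seed.
    """
    if not catalog.associations:
        raise DiseaseScoringError("catalog has no associations")
    genes = [g for g, _ in catalog.associations]
    diseases = [d for _, d in catalog.associations]
    out = []
    for child in np.random.SeedSequence(seed).spawn(n_randomizations):
        rng = np.random.default_rng(child)
        perm = rng.permutation(len(genes))
        pairs = tuple((genes[i], d) for i, d in zip(perm, diseases))
        out.append(DiseaseCatalog(phenotypes=catalog.phenotypes,
                                  associations=pairs))
    return out


def bin_enrichment(observed_scores: np.ndarray,
                   null_score_sets: Sequence[np.ndarray],
                   n_bins: int = 20, alpha: float = 0.01,
                   low_score_threshold: float = 0.15,
                   scores_frame: pd.DataFrame | None = None,
                   ) -> DiseaseScoreResult:
    """Per-bin empirical enrichment of observed scores over permutation nulls.

    Scores are binned into ``n_bins`` equal-width intervals on [0, 1].  The
    per-bin empirical p-value is (1 + #{null sets with count >= observed
    count}) / (1 + #null sets) (add-one correction, so p is never zero);
    bins with p < ``alpha`` are flagged.  An aggregate observed-vs-null
    comparison of the count of scores below ``low_score_threshold`` is also
    reported.
    """
    observed = np.asarray(observed_scores, dtype=float)
    if observed.size and (observed.min() <= 0 or observed.max() > 1):
        raise DiseaseScoringError("scores must lie in (0, 1]")
    if not len(null_score_sets):
        raise DiseaseScoringError("need at least one null score set")

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    obs_counts, _ = np.histogram(observed, bins=edges)
    null_counts = np.vstack([np.histogram(np.asarray(s, dtype=float),
                                          bins=edges)[0]
                             for s in null_score_sets])
    n_rand = null_counts.shape[0]
    pvals = (1 + (null_counts >= obs_counts).sum(axis=0)) / (1 + n_rand)

    low_obs = int((observed < low_score_threshold).sum())
    null_low = np.array([(np.asarray(s) < low_score_threshold).sum()
                         for s in null_score_sets])
    low_p = float((1 + (null_low >= low_obs).sum()) / (1 + n_rand))

    if scores_frame is None:
        scores_frame = pd.DataFrame({"score": observed})
    return DiseaseScoreResult(
        scores=scores_frame,
        null_scores=tuple(np.asarray(s, dtype=float)
                          for s in null_score_sets),
        bin_edges=edges,
        bin_counts=obs_counts,
        null_bin_counts=null_counts,
        bin_pvalues=pvals,
        flagged_bins=pvals < alpha,
        alpha=alpha,
        low_score_threshold=low_score_threshold,
        low_score_observed=low_obs,
        low_score_null_mean=float(null_low.mean()),
        low_score_pvalue=low_p,
    )


def evaluate_catalog(catalog: DiseaseCatalog, ranks: pd.DataFrame,
                     ontology: Ontology, n_randomizations: int = 100,
                     n_bins: int = 20, alpha: float = 0.01,
                     low_score_threshold: float = 0.15,
                     seed: int = 0) -> DiseaseScoreResult:
    """Full permutation-null evaluation of a disease catalog's scores."""
    scored_terms = set(ranks.columns)
    obs = score_catalog(catalog, ranks, ontology, scored_terms)
    nulls = [score_catalog(c, ranks, ontology, scored_terms)["score"]
             .to_numpy()
             for c in randomize_associations(catalog, n_randomizations, seed)]
    return bin_enrichment(obs["score"].to_numpy(), nulls, n_bins=n_bins,
                          alpha=alpha, low_score_threshold=low_score_threshold,
                          scores_frame=obs)
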