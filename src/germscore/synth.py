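"""Synthetic data generation for the whole pipeline.

Generates, from an explicit parameter set and a seed, every input the
pipeline consumes: a rooted phenotype DAG with a designated neoplasm-like
subtree, per-gene somatic mutation records whose patient counts are
negative-binomial with mean proportional to gene length (reproducing the
length confounding of real tumor data), a 20-level evolutionary age, the 81
genomic/epigenomic features (trinucleotide frequencies computed from
generated CDS sequences, the rest from a correlated latent Gaussian), binary
IPA labels drawn from a logistic model with planted TSM and age effects, and
disease catalogs with causal genes planted at configurable sharpness.

Defaults mirror the scale of the real study: 18,170 genes, 33 tumor types,
a TSM odds ratio of 1.9 per SD, and an IPA prevalence near 23%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import SCALAR_GENOMIC_FEATURES
from .ontology import AnnotationSet, Ontology, _build, descendants
from .disease import DiseaseCatalog

_FRACTION_FEATURES = ("dnase_gene", "dnase_cds", "h3k4me1_gene",
                      "h3k4me1_cds", "h3k4me3_gene", "h3k4me3_cds",
                      "h3k27ac_gene", "h3k27ac_cds", "laminb1",
                      "repeat_gene", "repeat_cds")
_POSITIVE_FEATURES = ("nucleosome_gene", "nucleosome_cds", "transcription",
                      "recombination")
_REAL_FEATURES = ("replication_timing",)

_MUTATION_CLASSES = ("Missense_Mutation", "Silent", "Nonsense_Mutation",
                     "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del",
                     "In_Frame_Ins", "Splice_Site", "Translation_Start_Site")
_MUTATION_WEIGHTS = (0.45, 0.25, 0.08, 0.06, 0.04, 0.03, 0.03, 0.04, 0.02)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the conditions of the real analysis at full scale;
    ``n_genes``/``n_terms`` can be reduced for quick experiments.
    """

    n_genes: int = 18_170
    n_terms: int = 150
    dag_branching: int = 2            # max parents per term
    neoplasm_subtree_fraction: float = 0.15
    or_tsm_per_sd: float = 1.9
    age_effect_per_level: float = 0.1
    intercept: float = -1.4           # calibrated to ~23% IPA prevalence
    n_tumor_types: int = 33
    tsm_mean_per_tumor: float = 0.3   # at the mean gene length
    tsm_dispersion: float = 0.5       # NB: var = mu + dispersion * mu^2
    n_patients_per_tumor: int = 300
    feature_correlation: float = 0.3
    length_coupling: float = 0.2      # loading of log gene length on features
    max_annotations_per_gene: int = 5
    neoplasm_annotation_fraction: float = 0.1
    n_diseases: int = 200
    phenotypes_per_disease: int = 5
    causal_gene_sharpness: float = 3.0
    seed: int = 0

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(salt,)))

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


def gene_ids(cfg: SyntheticConfig) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(cfg.n_genes)], name="gene")


# --------------------------------------------------------------------------
# ontology
# --------------------------------------------------------------------------

def gen_ontology(cfg: SyntheticConfig) -> tuple[Ontology, str]:
    """Random rooted DAG with a designated neoplasm-like subtree.

    The root has one child heading the neoplasm-like subtree; every later
    term draws 1..``dag_branching`` parents among earlier terms of its own
    group (neoplasm or not), so the neoplasm subtree is exactly the
    descendant set of its head.  Returns the ontology and the head term id.
    """
    if cfg.n_terms < 3:
        raise ValueError("need at least 3 terms")
    rng = cfg.rng(1)
    ids = [f"SP:{i:06d}" for i in range(cfg.n_terms)]
    root, neo_root = ids[0], ids[1]
    names = {root: "phenotypic abnormality (synthetic)",
             neo_root: "neoplasm (synthetic)"}
    edges = [(neo_root, root)]
    groups = {root: "normal", neo_root: "neoplasm"}
    for term in ids[2:]:
        group = ("neoplasm"
                 if rng.random() < cfg.neoplasm_subtree_fraction
                 else "normal")
        pool = [t for t in groups if groups[t] == group]
        k = int(rng.integers(1, cfg.dag_branching + 1))
        parents = rng.choice(pool, size=min(k, len(pool)), replace=False)
        edges.extend((term, p) for p in parents)
        groups[term] = group
        names[term] = f"synthetic phenotype {term[3:]}"
    return _build(ids, edges, names), neo_root


def leaf_terms(ontology: Ontology, exclude_root: str) -> list[str]:
    """Leaves outside the excluded subtree (annotation targets)."""
    excluded = descendants(ontology, exclude_root) | {exclude_root}
    return sorted(t for t in ontology.terms
                  if not ontology.children[t]
                  and t not in excluded and t != ontology.root)


# --------------------------------------------------------------------------
# genes: lengths, mutations, age, features
# --------------------------------------------------------------------------

def gen_lengths(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Log-normal gene and CDS lengths (bases), weakly correlated."""
    rng = cfg.rng(2)
    shared = rng.standard_normal(cfg.n_genes)
    gene_len = np.exp(np.log(20_000) + 1.0 * shared).astype(int) + 200
    indep = rng.standard_normal(cfg.n_genes)
    z = 0.4 * shared + np.sqrt(1 - 0.4**2) * indep
    cds_len = np.maximum(90, np.exp(np.log(1_300) + 0.6 * z)).astype(int)
    return gene_len, cds_len


def gen_tsm_counts(cfg: SyntheticConfig,
                   gene_length: np.ndarray) -> pd.DataFrame:
    """Per-(gene, tumor type) counts of mutated patients.

    Negative binomial with mean proportional to gene length (longer genes
    accumulate more mutations) and configurable dispersion; dispersion -> 0
    recovers the Poisson limit.  Counts are capped at the per-tumor patient
    pool size.
    """
    rng = cfg.rng(3)
    mu = cfg.tsm_mean_per_tumor * gene_length / gene_length.mean()
    mu = np.broadcast_to(mu[:, None], (cfg.n_genes, cfg.n_tumor_types))
    if cfg.tsm_dispersion <= 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / cfg.tsm_dispersion
        lam = rng.gamma(shape=r, scale=mu / r)
        counts = rng.poisson(lam)
    counts = np.minimum(counts, cfg.n_patients_per_tumor)
    tumors = [f"TT{j:02d}" for j in range(cfg.n_tumor_types)]
    return pd.DataFrame(counts, index=gene_ids(cfg), columns=tumors)


def gen_maf(cfg: SyntheticConfig, counts: pd.DataFrame) -> pd.DataFrame:
    """Expand patient counts into MAF-like mutation records.

    For every (gene, tumor) cell with count c, c distinct patients of that
    tumor type's pool each receive one record (a random recognised variant
    classification); a fraction of patients receive a second record in the
    same gene so that per-patient deduplication is actually exercised.
    """
    rng = cfg.rng(4)
    genes = counts.index.to_numpy()
    rows: list[tuple[str, str, str, str]] = []
    for j, tumor in enumerate(counts.columns):
        col = counts.iloc[:, j].to_numpy()
        nz = np.flatnonzero(col)
        for i in nz:
            c = int(col[i])
            patients = rng.choice(cfg.n_patients_per_tumor, size=c,
                                  replace=False)
            classes = rng.choice(_MUTATION_CLASSES, size=c,
                                 p=_MUTATION_WEIGHTS)
            for p, cls in zip(patients, classes):
                pid = f"{tumor}-P{p:04d}"
                rows.append((genes[i], pid, tumor, cls))
                if rng.random() < 0.2:
                    extra = rng.choice(_MUTATION_CLASSES,
                                       p=_MUTATION_WEIGHTS)
                    rows.append((genes[i], pid, tumor, extra))
    return pd.DataFrame(rows, columns=["gene", "patient", "tumor_type",
                                       "classification"])


def gen_age(cfg: SyntheticConfig) -> pd.Series:
    """Evolutionary age as 20 ordered phylostrata (1 = oldest).

    The level distribution decays mildly with the level number, mimicking
    the predominance of ancient genes in real phylostratigraphies.
    """
    rng = cfg.rng(5)
    levels = np.arange(1, 21)
    w = np.exp(-0.15 * (levels - 1))
    age = rng.choice(levels, size=cfg.n_genes, p=w / w.sum())
    return pd.Series(age, index=gene_ids(cfg), name="age")


def gen_cds(cfg: SyntheticConfig, cds_length: np.ndarray) -> list[str]:
    """Random CDS strings with gene-specific base composition."""
    rng = cfg.rng(6)
    lengths = cds_length.astype(int)
    probs = rng.dirichlet([5.0, 5.0, 5.0, 5.0], size=len(lengths))
    cum = np.cumsum(probs, axis=1)
    u = rng.random(int(lengths.sum()))
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    out, offset = [], 0
    for g, n in enumerate(lengths):
        codes = np.searchsorted(cum[g], u[offset:offset + n], side="right")
        out.append(bases[np.minimum(codes, 3)].tobytes().decode("ascii"))
        offset += n
    return out


def _batch_trinucleotide_frequencies(cds_list: list[str],
                                     index: pd.Index) -> pd.DataFrame:
    """Vectorized per-gene trinucleotide frequencies for generated (all-ACGT)
    CDS strings; agrees exactly with the per-gene production counter."""
    from .features import _BASE_CODE, TRINUCLEOTIDES
    lengths = np.array([len(s) for s in cds_list])
    concat = "".join(cds_list)
    codes = _BASE_CODE[np.frombuffer(concat.encode("ascii"), dtype=np.uint8)]
    tri = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
    gene_of_win = np.repeat(np.arange(len(cds_list)), lengths)[:-2]
    # drop windows spanning a gene boundary
    same_gene = (gene_of_win == np.repeat(np.arange(len(cds_list)),
                                          lengths)[2:])
    counts = np.zeros((len(cds_list), 64), dtype=np.int64)
    np.add.at(counts, (gene_of_win[same_gene], tri[same_gene]), 1)
    freq = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(freq, index=index,
                        columns=[f"tri_{t}" for t in TRINUCLEOTIDES])


def gen_scalar_features(cfg: SyntheticConfig, gene_length: np.ndarray,
                        cds_length: np.ndarray) -> pd.DataFrame:
    """The 17 non-trinucleotide genomic features from a correlated latent.

    A compound-symmetric Gaussian latent (correlation
    ``feature_correlation``, plus a weak loading on log gene length) is
    mapped to each feature's natural scale: logistic for overlap fractions,
    exponential for non-negative signals, identity for replication timing.
    CDS length is the actual generated length.
    """
    rng = cfg.rng(7)
    rho = cfg.feature_correlation
    n_latent = len(_FRACTION_FEATURES) + len(_POSITIVE_FEATURES) + \
        len(_REAL_FEATURES)
    shared = rng.standard_normal(cfg.n_genes)
    log_len = (np.log(gene_length) - np.log(gene_length).mean())
    log_len = log_len / log_len.std()
    lam = cfg.length_coupling
    indep = rng.standard_normal((cfg.n_genes, n_latent))
    latent = (np.sqrt(rho) * shared[:, None]
              + lam * log_len[:, None]
              + np.sqrt(max(0.0, 1 - rho - lam**2)) * indep)

    cols: dict[str, np.ndarray] = {"cds_length": cds_length.astype(float)}
    k = 0
    for name in _FRACTION_FEATURES:
        cols[name] = 1.0 / (1.0 + np.exp(-latent[:, k]))
        k += 1
    for name in _POSITIVE_FEATURES:
        cols[name] = np.exp(0.5 * latent[:, k])
        k += 1
    for name in _REAL_FEATURES:
        cols[name] = latent[:, k]
        k += 1
    df = pd.DataFrame(cols, index=gene_ids(cfg))
    return df[list(SCALAR_GENOMIC_FEATURES)]


def gen_gene_table(cfg: SyntheticConfig, include_cds: bool = True,
                   ) -> tuple[pd.DataFrame, pd.DataFrame, list[str] | None]:
    """Generate the full gene table (without labels).

    Returns (counts genes x tumors, feature table, CDS strings).  The
    feature table holds tsm_total, age, and the 81 genomic features; the 64
    trinucleotide frequencies are computed from the generated CDS strings
    with the production counting code (omitted when ``include_cds`` is
    False, for fast experiments that only need TSM and age).
    """
    gene_len, cds_len = gen_lengths(cfg)
    counts = gen_tsm_counts(cfg, gene_len)
    parts = [counts.sum(axis=1).rename("tsm_total"), gen_age(cfg)]
    cds: list[str] | None = None
    if include_cds:
        scalars = gen_scalar_features(cfg, gene_len, cds_len)
        cds = gen_cds(cfg, cds_len)
        tri = _batch_trinucleotide_frequencies(cds, gene_ids(cfg))
        parts += [scalars, tri]
    table = pd.concat(parts, axis=1)
    table.attrs["gene_length"] = gene_len
    return counts, table, cds


# --------------------------------------------------------------------------
# labels and annotations
# --------------------------------------------------------------------------

def planted_probabilities(cfg: SyntheticConfig,
                          table: pd.DataFrame) -> pd.Series:
    """The generative IPA probability: a logistic model with planted TSM
    (per-SD) and age (per-level) effects."""
    tsm = table["tsm_total"].to_numpy(dtype=float)
    z = (tsm - tsm.mean()) / tsm.std()
    age = table["age"].to_numpy(dtype=float)
    lin = (cfg.intercept + np.log(cfg.or_tsm_per_sd) * z
           + cfg.age_effect_per_level * (age - age.mean()))
    return pd.Series(1.0 / (1.0 + np.exp(-lin)), index=table.index,
                     name="p_ipa")


def gen_labels_and_annotations(cfg: SyntheticConfig, table: pd.DataFrame,
                               ontology: Ontology, neoplasm_root: str,
                               ) -> tuple[AnnotationSet, pd.Series, pd.Series]:
    """Draw IPA labels and deposit direct gene-phenotype annotations.

    IPA-positive genes are annotated to 1..``max_annotations_per_gene``
    random leaf terms outside the neoplasm-like subtree; additionally a
    fraction of all genes receives an annotation inside that subtree, so
    that the exclusion step has work to do.  Returns the direct annotation
    set, the binary labels, and the latent probabilities.
    """
    rng = cfg.rng(8)
    p = planted_probabilities(cfg, table)
    ipa = pd.Series((rng.random(len(p)) < p.to_numpy()).astype(int),
                    index=table.index, name="ipa")
    leaves = leaf_terms(ontology, neoplasm_root)
    if not leaves:
        raise ValueError("ontology has no leaf terms outside the "
                         "excluded subtree")
    neo_terms = sorted(descendants(ontology, neoplasm_root) | {neoplasm_root})

    pairs: set[tuple[str, str]] = set()
    for gene in table.index[ipa.to_numpy() == 1]:
        k = int(rng.integers(1, cfg.max_annotations_per_gene + 1))
        for t in rng.choice(leaves, size=min(k, len(leaves)), replace=False):
            pairs.add((gene, t))
    mask = rng.random(len(table)) < cfg.neoplasm_annotation_fraction
    for gene in table.index[mask]:
        pairs.add((gene, str(rng.choice(neo_terms))))
    return AnnotationSet(frozenset(pairs), "direct"), ipa, p


def gen_release_pair(cfg: SyntheticConfig, direct: AnnotationSet,
                     labels: pd.Series, n_new: int,
                     seed_salt: int = 9) -> tuple[AnnotationSet,
                                                  AnnotationSet]:
    """An (older, newer) annotation release pair modelling catalog growth.

    Annotation databases grow by filling in missing knowledge, not by
    re-drawing biology: the newer release is the full annotation set and the
    older one hides ``n_new`` positive genes chosen uniformly (their
    annotations simply had not been deposited yet).  The hidden genes are
    therefore typical positives, and the older release carries them as
    false negatives -- the label noise a model trained on an incomplete
    catalog really faces.
    """
    rng = cfg.rng(seed_salt)
    positives = labels.index[labels.to_numpy() == 1]
    if n_new > len(positives):
        raise ValueError("not enough positive genes to hide for the "
                         "older release")
    hidden = set(rng.choice(positives, size=n_new, replace=False))
    old_pairs = frozenset((g, t) for g, t in direct.pairs
                          if g not in hidden)
    return AnnotationSet(old_pairs, "direct"), direct


# --------------------------------------------------------------------------
# disease catalogs
# --------------------------------------------------------------------------

def gen_disease_catalog(cfg: SyntheticConfig,
                        probability_table: pd.DataFrame) -> DiseaseCatalog:
    """Diseases with phenotype lists and planted causal genes.

    Each disease draws ``phenotypes_per_disease`` distinct scored terms; its
    causal gene is drawn with probability proportional to
    exp(sharpness * z(mean model probability over the disease's terms)), so
    sharpness 0 yields a uniform (null) catalog and large sharpness
    concentrates causal genes among the model's top predictions.
    """
    rng = cfg.rng(10)
    terms = list(probability_table.columns)
    genes = probability_table.index
    k = min(cfg.phenotypes_per_disease, len(terms))
    phenotypes: dict[str, tuple[str, ...]] = {}
    associations: list[tuple[str, str]] = []
    for d in range(cfg.n_diseases):
        disease = f"SD:{d:05d}"
        chosen = tuple(sorted(rng.choice(terms, size=k, replace=False)))
        phenotypes[disease] = chosen
        mean_p = probability_table[list(chosen)].mean(axis=1).to_numpy()
        zp = (mean_p - mean_p.mean()) / max(mean_p.std(), 1e-12)
        w = np.exp(cfg.causal_gene_sharpness * zp)
        gene = str(genes[rng.choice(len(genes), p=w / w.sum())])
        associations.append((gene, disease))
    return DiseaseCatalog(phenotypes=phenotypes,
                          associations=tuple(associations))
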