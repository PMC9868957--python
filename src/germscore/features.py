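"""Gene-level feature construction.

Builds the gene x feature table used by the regression and machine-learning
layers: TSM (the number of cancer patients carrying at least one somatic
mutation in the gene, summed over tumor types), evolutionary age (20 ordered
phylostrata), and 81 genomic/epigenomic variables (CDS length, interval
overlap fractions, base-weighted signal averages, and the 64 trinucleotide
frequencies of the coding sequence).

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: MAF variant classifications that count toward TSM.
ALLOWED_CLASSIFICATIONS = frozenset({
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Missense_Mutation", "Nonsense_Mutation", "Silent", "Splice_Site",
    "Translation_Start_Site",
})

#: The 64 trinucleotides in lexicographic order (AAA .. TTT).
TRINUCLEOTIDES = tuple("".join(t) for t in itertools.product("ACGT", repeat=3))

#: Non-trinucleotide genomic/epigenomic variables, in canonical column order.
SCALAR_GENOMIC_FEATURES = (
    "cds_length",
    "dnase_gene", "dnase_cds",
    "h3k4me1_gene", "h3k4me1_cds",
    "h3k4me3_gene", "h3k4me3_cds",
    "h3k27ac_gene", "h3k27ac_cds",
    "laminb1",
    "replication_timing",
    "nucleosome_gene", "nucleosome_cds",
    "transcription",
    "repeat_gene", "repeat_cds",
    "recombination",
)

#: All 81 genomic/epigenomic feature columns, in canonical order.
GENOMIC_FEATURES = SCALAR_GENOMIC_FEATURES + tuple(
    f"tri_{t}" for t in TRINUCLEOTIDES)

#: The collinear trinucleotide column dropped before PCA.
COLLINEAR_FEATURE = "tri_TTT"


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call from a MAF-like table."""

    gene: str
    patient: str
    tumor_type: str
    classification: str


class FeatureError(ValueError):
    """Raised for invalid feature-construction inputs."""


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        [(r.gene, r.patient, r.tumor_type, r.classification) for r in records],
        columns=["gene", "patient", "tumor_type", "classification"],
    )


def count_tsm(records, mode: str = "all") -> tuple[pd.DataFrame, pd.Series]:
    """Count, per gene and tumor type, patients with >=1 somatic mutation.

    A patient contributes at most once to a (gene, tumor) cell no matter how
    many mutations they carry in that gene.  Only the nine recognised variant
    classifications are counted; records with any other classification are
    skipped (their number is logged).  In ``protein_changing`` mode Silent
    mutations are additionally excluded.

    Returns
    -------
    by_tumor : DataFrame
        genes x tumor types, integer patient counts.
    total : Series
        per-gene TSM, the row sum of ``by_tumor``.
    """
    if mode not in ("all", "protein_changing"):
        raise FeatureError(f"unknown TSM mode: {mode!r}")
    df = _records_frame(records)
    if df.empty:
        return (pd.DataFrame(dtype=int),
                pd.Series(dtype=int, name="tsm_total"))

    known = df["classification"].isin(ALLOWED_CLASSIFICATIONS)
    n_skipped = int((~known).sum())
    if n_skipped:
        logger.warning("count_tsm: skipped %d records with unknown "
                       "classification", n_skipped)
    df = df[known]
    if mode == "protein_changing":
        df = df[df["classification"] != "Silent"]

    dedup = df.drop_duplicates(["gene", "tumor_type", "patient"])
    by_tumor = (dedup.groupby(["gene", "tumor_type"]).size()
                .unstack(fill_value=0).sort_index())
    by_tumor.columns.name = None
    by_tumor.index.name = "gene"
    total = by_tumor.sum(axis=1).rename("tsm_total")
    return by_tumor, total


def mean_mutation_rate(records, samples_per_tumor: Mapping[str, int],
                       mode: str = "all") -> pd.Series:
    """Per-gene mutation rate, averaged with equal weight over tumor types.

    The per-tumor rate is the fraction of that tumor type's patients with a
    mutation in the gene; the returned value is the unweighted mean of those
    rates over all tumor types in ``samples_per_tumor`` (a gene unmutated in
    a tumor type contributes a zero rate there).
    """
    for tumor, n in samples_per_tumor.items():
        if n <= 0:
            raise FeatureError(f"non-positive sample count for tumor "
                               f"{tumor!r}: {n}")
    by_tumor, _ = count_tsm(records, mode=mode)
    tumors = list(samples_per_tumor)
    by_tumor = by_tumor.reindex(columns=tumors, fill_value=0)
    if by_tumor.empty:
        return pd.Series(dtype=float, name="mean_mutation_rate")
    sizes = pd.Series(samples_per_tumor, dtype=float)
    rates = by_tumor.div(sizes, axis=1)
    return rates.mean(axis=1).rename("mean_mutation_rate")


def merge_intervals(intervals: Iterable[tuple[int, int]]
                    ) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a disjoint set."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def overlap_fraction(region: tuple[int, int],
                     track: Iterable[tuple[int, int]]) -> float:
    """Fraction of a half-open region covered by a track's intervals.

    Track intervals are merged before intersection so overlapping peaks are
    never double counted; the result is always in [0, 1].
    """
    start, end = region
    if end <= start:
        raise FeatureError(f"zero-length region: {region}")
    covered = 0
    for s, e in merge_intervals(track):
        covered += max(0, min(e, end) - max(s, start))
    return covered / (end - start)


def mean_signal(region: tuple[int, int],
                signal_by_cell_line: Sequence[Iterable[tuple[int, int, float]]],
                ) -> float:
    """Base-weighted mean signal over a region, averaged across cell lines.

    Within each cell line the signal intervals (start, end, value) are
    averaged over the bases of the region they cover; cell lines with no
    coverage of the region are skipped.  The per-cell-line means are then
    averaged with equal weight.  Returns NaN when no cell line covers the
    region (the caller flags the gene).
    """
    start, end = region
    if end <= start:
        raise FeatureError(f"zero-length region: {region}")
    means = []
    for intervals in signal_by_cell_line:
        total = 0.0
        bases = 0
        for s, e, v in intervals:
            w = max(0, min(e, end) - max(s, start))
            total += w * v
            bases += w
        if bases > 0:
            means.append(total / bases)
    if not means:
        return float("nan")
    return float(np.mean(means))


_BASE_CODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def trinucleotide_frequencies(cds: str) -> pd.Series:
    """Frequencies of the 64 trinucleotides in a CDS (gene strand).

    Overlapping windows of width 3, step 1.  Windows containing a non-ACGT
    character are skipped and the denominator reduced, so the 64 frequencies
    always sum to 1.  A CDS shorter than 3 bases, or one with no valid
    window, is an error.
    """
    if len(cds) < 3:
        raise FeatureError(f"CDS too short for trinucleotides: {len(cds)} nt")
    codes = _BASE_CODE[np.frombuffer(cds.encode("ascii"), dtype=np.uint8)]
    valid = codes >= 0
    win_valid = valid[:-2] & valid[1:-1] & valid[2:]
    n = int(win_valid.sum())
    if n == 0:
        raise FeatureError("CDS has no trinucleotide window free of "
                           "non-ACGT characters")
    tri_codes = (codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:])[win_valid]
    counts = np.bincount(tri_codes, minlength=64)
    return pd.Series(counts / n,
                     index=[f"tri_{t}" for t in TRINUCLEOTIDES])


def assemble_feature_table(sources: Mapping[str, pd.DataFrame | pd.Series],
                           required: Sequence[str] | None = None,
                           ) -> pd.DataFrame:
    """Join per-gene sources into a single table on the gene index.

    ``sources`` maps source names to Series/DataFrames indexed by gene
    symbol.  Genes missing from any source (or with a missing value in any
    required column) are dropped listwise; the number dropped is logged.
    ``required`` defaults to all columns.
    """
    frames = []
    for name, obj in sources.items():
        df = obj.to_frame() if isinstance(obj, pd.Series) else obj
        frames.append(df)
    table = pd.concat(frames, axis=1, join="outer")
    cols = list(required) if required is not None else list(table.columns)
    complete = table.dropna(subset=cols)
    n_dropped = len(table) - len(complete)
    if n_dropped:
        logger.info("assemble_feature_table: dropped %d genes with missing "
                    "variables (%d retained)", n_dropped, len(complete))
    if complete.empty:
        raise FeatureError("no gene has all required variables")
    logger.info("assemble_feature_table: %d genes x %d columns",
                len(complete), complete.shape[1])
    return complete.sort_index()


@dataclass(frozen=True)
class PCView:
    """Principal components of the standardized genomic/epigenomic features."""

    loadings: pd.DataFrame          # features x components
    component_scores: pd.DataFrame  # genes x components
    explained_variance: np.ndarray
    dropped_feature: str
    feature_means: pd.Series
    feature_scales: pd.Series


def standardize_and_pca(table: pd.DataFrame,
                        feature_columns: Sequence[str] | None = None,
                        ) -> PCView:
    """Standardize the 80 genomic features and rotate to principal components.

    The TTT trinucleotide frequency is dropped first (it is collinear with
    the other 63 by construction), the remaining features are rescaled to
    zero mean and unit SD, and all components are retained, so the rotation
    is orthonormal and loses no information.  A constant column cannot be
    standardized and is a hard error naming the column.
    """
    cols = list(feature_columns if feature_columns is not None
                else GENOMIC_FEATURES)
    if COLLINEAR_FEATURE in cols:
        cols.remove(COLLINEAR_FEATURE)
    x = table[cols].to_numpy(dtype=float)
    if x.shape[0] <= x.shape[1]:
        raise FeatureError(f"need more genes ({x.shape[0]}) than features "
                           f"({x.shape[1]}) for a full-rank PCA")
    if np.isnan(x).any():
        raise FeatureError("feature table contains missing values")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise FeatureError(f"constant feature column: {cols[constant[0]]!r}")
    z = (x - mean) / sd

    pca = PCA(n_components=len(cols), svd_solver="full")
    scores = pca.fit_transform(z)
    comp_names = [f"PC{i + 1}" for i in range(len(cols))]
    return PCView(
        loadings=pd.DataFrame(pca.components_.T, index=cols,
                              columns=comp_names),
        component_scores=pd.DataFrame(scores, index=table.index,
                                      columns=comp_names),
        explained_variance=pca.explained_variance_,
        dropped_feature=COLLINEAR_FEATURE,
        feature_means=pd.Series(mean, index=cols),
        feature_scales=pd.Series(sd, index=cols),
    )
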