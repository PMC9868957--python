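"""Readers and writers for the pipeline's flat-file dialects.

All tables are UTF-8 TSV.  MAF input follows the standard column names
(Hugo_Symbol, Variant_Classification, Tumor_Sample_Barcode) with the cohort
label taken from a configurable column or supplied per file.  Annotation and
disease-catalog files are two-column TSVs matching HPO/OMIM/Orphanet exports
after column selection.  Floats are written with a fixed format so repeated
runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .disease import DiseaseCatalog
from .ontology import AnnotationSet

FLOAT_FORMAT = "%.10g"


def read_annotations(path, state: str = "direct") -> AnnotationSet:
    """Two-column (gene_symbol, term_id) TSV; header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if str(df.iloc[0, 0]).lower() in ("gene", "gene_symbol"):
        df = df.iloc[1:]
    pairs = frozenset(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return AnnotationSet(pairs=pairs, state=state)


def write_annotations(annotations: AnnotationSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_symbol\tterm_id\n")
        for gene, term in sorted(annotations.pairs):
            fh.write(f"{gene}\t{term}\n")


def read_maf(path, tumor_type_column: str = "Cohort",
             tumor_type: str | None = None,
             patient_column: str = "Tumor_Sample_Barcode") -> pd.DataFrame:
    """Read a MAF-like TSV into the internal record columns.

    The cohort label comes from ``tumor_type_column`` when present, or a
    constant ``tumor_type`` supplied for the whole file.  Patient identity
    defaults to the full sample barcode.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = pd.DataFrame({
        "gene": df["Hugo_Symbol"],
        "patient": df[patient_column],
        "classification": df["Variant_Classification"],
    })
    if tumor_type_column in df.columns:
        out["tumor_type"] = df[tumor_type_column]
    elif tumor_type is not None:
        out["tumor_type"] = tumor_type
    else:
        raise ValueError(f"no {tumor_type_column!r} column and no constant "
                         "tumor_type supplied")
    return out[["gene", "patient", "tumor_type", "classification"]]


def write_maf(records: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "Hugo_Symbol": records["gene"],
        "Variant_Classification": records["classification"],
        "Tumor_Sample_Barcode": records["patient"],
        "Cohort": records["tumor_type"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene",
                 float_format=FLOAT_FORMAT)


def read_gene_ages(path) -> pd.Series:
    """Two-column (gene_symbol, age) TSV with header."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0],
                     name="age")


def read_catalog(phenotype_path, gene_path) -> DiseaseCatalog:
    """Disease catalog from (disease_id, term_id) and (disease_id,
    gene_symbol) TSVs."""
    ph = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    ga = pd.read_csv(gene_path, sep="\t", dtype=str)
    phenotypes = {
        d: tuple(dict.fromkeys(sub.iloc[:, 1]))
        for d, sub in ph.groupby(ph.columns[0], sort=True)}
    associations = tuple((g, d) for d, g in
                         zip(ga.iloc[:, 0], ga.iloc[:, 1]))
    return DiseaseCatalog(phenotypes=phenotypes, associations=associations)


def write_catalog(catalog: DiseaseCatalog, phenotype_path,
                  gene_path) -> None:
    with open(phenotype_path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tterm_id\n")
        for disease in sorted(catalog.phenotypes):
            for term in catalog.phenotypes[disease]:
                fh.write(f"{disease}\t{term}\n")
    with open(gene_path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tgene_symbol\n")
        for gene, disease in sorted(catalog.associations,
                                    key=lambda p: (p[1], p[0])):
            fh.write(f"{disease}\t{gene}\n")


def read_cds_fasta(path) -> dict[str, str]:
    """CDS sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_cds_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
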