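"""End-to-end orchestration of the analysis stages.

Stage order mirrors the analysis: simulate (or stage external inputs) ->
expand annotations -> build the feature table -> train per-phenotype models
-> score diseases against the permutation null.  Every stage writes its
outputs plus a manifest (config snapshot, seeds, input checksums, software
version, row counts, timings) into its own directory; a completed stage is
only overwritten with ``force``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import RunConfig
from .disease import evaluate_catalog, rank_table
from .features import assemble_feature_table, count_tsm, mean_mutation_rate
from .models import ipa_labels, train_per_phenotype
from .ontology import expand_annotations, load_obo, write_obo
from .synth import (SyntheticConfig, gen_disease_catalog, gen_gene_table,
                    gen_labels_and_annotations, gen_maf, gen_ontology)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "expand", "features", "train", "score")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.exit_code = 10 + STAGES.index(stage)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(stage_dir: Path, stage: str, config: RunConfig,
                    inputs: list[Path], counts: dict[str, int],
                    elapsed: float, extra: dict | None = None) -> None:
    manifest = {
        "stage": stage,
        "software_version": __version__,
        "config": config.model_dump(),
        "seed": config.seed,
        "input_checksums": {str(p): _checksum(Path(p)) for p in inputs},
        "row_counts": counts,
        "elapsed_seconds": round(elapsed, 3),
    }
    if extra:
        manifest.update(extra)
    (stage_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _stage_dir(outdir: Path, stage: str, force: bool) -> Path:
    d = outdir / stage
    if (d / "manifest.json").exists() and not force:
        raise StageError(stage, f"output {d} already exists; pass force to "
                         "overwrite")
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_all(config: RunConfig, outdir, force: bool = False) -> dict:
    """Execute all stages on a synthetic dataset; returns summary metrics."""
    outdir = Path(outdir)
    summary: dict = {}

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    stage = "simulate"
    d_sim = _stage_dir(outdir, stage, force)
    try:
        scfg = SyntheticConfig(seed=config.seed,
                               **config.simulate.model_dump())
        ontology, neoplasm_root = gen_ontology(scfg)
        counts, table, cds = gen_gene_table(scfg)
        maf = gen_maf(scfg, counts)
        direct, labels, latent_p = gen_labels_and_annotations(
            scfg, table, ontology, neoplasm_root)
        write_obo(ontology, d_sim / "ontology.obo")
        io.write_annotations(direct, d_sim / "annotations_direct.tsv")
        io.write_maf(maf, d_sim / "mutations.maf.tsv")
        base = table.drop(columns=["tsm_total"])
        io.write_feature_table(base, d_sim / "gene_features.tsv")
        io.write_cds_fasta(dict(zip(table.index, cds)), d_sim / "cds.fasta")
        (d_sim / "params.json").write_text(json.dumps(
            {**asdict(scfg), "neoplasm_root": neoplasm_root},
            indent=2, sort_keys=True) + "\n")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    _write_manifest(d_sim, stage, config, [], {
        "genes": len(table), "terms": len(ontology.terms),
        "mutation_records": len(maf),
        "direct_annotations": len(direct.pairs)},
        time.perf_counter() - t0,
        {"neoplasm_root": neoplasm_root})
    summary["n_genes"] = len(table)

    # --- expand -------------------------------------------------------
    t0 = time.perf_counter()
    stage = "expand"
    d_exp = _stage_dir(outdir, stage, force)
    try:
        ontology = load_obo(d_sim / "ontology.obo")
        direct = io.read_annotations(d_sim / "annotations_direct.tsv")
        expanded = expand_annotations(direct, ontology, neoplasm_root)
        io.write_annotations(expanded, d_exp / "annotations_expanded.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    _write_manifest(d_exp, stage, config,
                    [d_sim / "ontology.obo",
                     d_sim / "annotations_direct.tsv"],
                    {"expanded_annotations": len(expanded.pairs)},
                    time.perf_counter() - t0)

    # --- features -----------------------------------------------------
    t0 = time.perf_counter()
    stage = "features"
    d_feat = _stage_dir(outdir, stage, force)
    try:
        records = io.read_maf(d_sim / "mutations.maf.tsv")
        base = io.read_feature_table(d_sim / "gene_features.tsv")
        mode = config.features.mutation_mode
        if config.features.tsm_variant == "mean_rate":
            sizes = {t: scfg.n_patients_per_tumor
                     for t in records["tumor_type"].unique()}
            tsm = mean_mutation_rate(records, sizes, mode=mode)
            tsm = tsm.rename("tsm_total")
        else:
            _, tsm = count_tsm(records, mode=mode)
        full = assemble_feature_table({"tsm": tsm.reindex(base.index,
                                                          fill_value=0),
                                       "base": base})
        labels = ipa_labels(expanded, full.index)
        full["ipa"] = labels
        io.write_feature_table(full, d_feat / "feature_table.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    _write_manifest(d_feat, stage, config,
                    [d_sim / "mutations.maf.tsv",
                     d_sim / "gene_features.tsv"],
                    {"genes": len(full),
                     "ipa_positive": int(labels.sum())},
                    time.perf_counter() - t0)
    summary["ipa_prevalence"] = float(labels.mean())

    # --- train --------------------------------------------------------
    t0 = time.perf_counter()
    stage = "train"
    d_tr = _stage_dir(outdir, stage, force)
    try:
        tcfg = config.train
        model_set = train_per_phenotype(
            full.drop(columns=["ipa"]), expanded,
            min_genes=tcfg.min_genes, paradigm=tcfg.paradigm,
            grid=tcfg.grid, outer_folds=tcfg.outer_folds,
            inner_folds=tcfg.inner_folds, seed=config.seed)
        probs = model_set.probability_table()
        io.write_feature_table(probs, d_tr / "probabilities.tsv")
        metrics = {
            term: {"mean_auroc": m.report.mean_auroc,
                   "mean_auprc": m.report.mean_auprc,
                   "baseline_auprc": m.report.baseline_auprc,
                   "auprc_gain": m.report.auprc_gain,
                   "n_positive": m.n_positive}
            for term, m in model_set.models.items()}
        (d_tr / "metrics.json").write_text(
            json.dumps(metrics, indent=2, sort_keys=True) + "\n")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    _write_manifest(d_tr, stage, config,
                    [d_feat / "feature_table.tsv",
                     d_exp / "annotations_expanded.tsv"],
                    {"models": len(model_set.models)},
                    time.perf_counter() - t0)
    summary["n_models"] = len(model_set.models)
    summary["median_auroc"] = float(np.median(
        [m.report.mean_auroc for m in model_set.models.values()]))
    summary["median_auprc_gain"] = float(np.median(
        [m.report.auprc_gain for m in model_set.models.values()]))

    # --- score --------------------------------------------------------
    t0 = time.perf_counter()
    stage = "score"
    d_sc = _stage_dir(outdir, stage, force)
    try:
        catalog = gen_disease_catalog(scfg, probs)
        io.write_catalog(catalog, d_sc / "catalog_phenotypes.tsv",
                         d_sc / "catalog_genes.tsv")
        ranks = rank_table(probs)
        io.write_feature_table(ranks, d_sc / "ranks.tsv")
        sc = config.score
        result = evaluate_catalog(
            catalog, ranks, ontology,
            n_randomizations=sc.n_randomizations, n_bins=sc.n_bins,
            alpha=sc.alpha, low_score_threshold=sc.low_score_threshold,
            seed=config.seed)
        result.scores.to_csv(d_sc / "disease_scores.tsv", sep="\t",
                             index=False, float_format=io.FLOAT_FORMAT)
        null_summary = {
            "bin_edges": result.bin_edges.tolist(),
            "bin_counts": result.bin_counts.tolist(),
            "null_bin_mean": result.null_bin_counts.mean(axis=0).tolist(),
            "bin_pvalues": result.bin_pvalues.tolist(),
            "flagged_bins": result.flagged_bins.tolist(),
            "low_score_observed": result.low_score_observed,
            "low_score_null_mean": result.low_score_null_mean,
            "low_score_pvalue": result.low_score_pvalue,
        }
        (d_sc / "null_summary.json").write_text(
            json.dumps(null_summary, indent=2) + "\n")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    _write_manifest(d_sc, stage, config,
                    [d_tr / "probabilities.tsv"],
                    {"scored_associations": len(result.scores)},
                    time.perf_counter() - t0)
    summary["low_score_pvalue"] = result.low_score_pvalue
    summary["n_flagged_bins"] = int(result.flagged_bins.sum())
    return summary
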