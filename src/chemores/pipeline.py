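"""End-to-end orchestration: simulate/load -> DEGs -> subgroups -> allocation
-> enrichment -> pathway deviation -> hub biomarkers -> validation classifier.

A single config dict (typically loaded from YAML) drives the run; every
stage writes a self-describing TSV/JSON into the output directory, and a
manifest records the config, seed and per-stage counts so a run is
reproducible bit for bit.  A stage failure leaves a ``FAILED`` marker
naming the stage and re-raises.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, data_io, network_biomarkers, pathway_analysis, resistance_classifier
from .deg_detection import PermutationConfig, detect_degs
from .errors import ChemoresError, InputError
from .gene_allocation import allocate_genes, allocation_to_frame
from .subgrouping import (
    correlation_distance,
    cut_clusters,
    hierarchical_cluster,
    median_center,
    summarize_subgroups,
)
from .synthetic_data import (
    SyntheticConfig,
    generate_cohort,
    generate_network,
    generate_pathways,
    validation_config,
    write_cohort,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 17,
    "zscore": True,
    "simulate": {},  # SyntheticConfig overrides; set to None when "inputs" is used
    "inputs": None,  # {expression, annotations, gene_sets, interactions,
    #                  validation_expression, validation_annotations}
    "permutations": {"n_permutations": 10_000, "alpha": 0.05, "statistic": "signed"},
    # k=4 mirrors the four subgroups of the basal-like study design (2 resistant
    # + 2 sensitive); set k to null for silhouette-selected k.
    "clustering": {"k": 4, "max_k": 10},
    "allocation": {"mode": "mean_sd"},
    "enrichment": {"alpha": 0.05},
    "pathway_score": {"variant": "mean"},
    "biomarkers": {"threshold": network_biomarkers.DEFAULT_THRESHOLD},
    "classifier": {},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path, encoding="utf-8") as fh:
        return _merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


def run_full_pipeline(config: dict | None, outdir: str | Path) -> dict:
    """Run every stage in order and return the in-memory result bundle."""
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    bundle: dict = {"config": cfg}
    counts: dict[str, int] = {}
    stage = "inputs"
    try:
        # ---- stage: inputs -------------------------------------------------
        if cfg.get("inputs"):
            paths = cfg["inputs"]
            expr = data_io.read_expression_matrix(paths["expression"])
            ann = data_io.read_annotations(paths["annotations"])
            pathways = data_io.read_gene_sets(paths["gene_sets"])
            interactions = data_io.read_interactions(paths["interactions"])
            vexpr = vann = None
            if paths.get("validation_expression"):
                vexpr = data_io.read_expression_matrix(paths["validation_expression"])
                vann = data_io.read_annotations(paths["validation_annotations"])
            truth = None
        else:
            scfg = SyntheticConfig(**{"seed": seed, **(cfg.get("simulate") or {})})
            expr, ann, truth = generate_cohort(scfg)
            pathways = generate_pathways(scfg, truth)
            interactions = generate_network(scfg, truth)
            vcfg = validation_config(scfg)
            vexpr, vann, _ = generate_cohort(
                vcfg, truth=truth, cohort="validation", sample_prefix="V"
            )
            write_cohort(outdir / "inputs", scfg, expr, ann, truth, pathways, interactions)
            data_io.write_expression_matrix(vexpr, outdir / "inputs" / "validation_expression.tsv")
            data_io.write_annotations(vann, outdir / "inputs" / "validation_annotations.tsv")
            bundle["truth"] = truth
        counts["genes"] = expr.shape[0]
        counts["samples"] = expr.shape[1]

        # ---- stage: normalization -----------------------------------------
        stage = "normalization"
        if cfg["zscore"]:
            expr = data_io.zscore_normalize(expr)
            if vexpr is not None:
                vexpr = data_io.zscore_normalize(vexpr)
        bundle["expression"] = expr
        bundle["annotations"] = ann

        # ---- stage: deg_detection -----------------------------------------
        stage = "deg_detection"
        pcfg = PermutationConfig(seed=seed, **cfg["permutations"])
        degs = detect_degs(expr, ann, pcfg)
        degs.to_csv(outdir / "degs.tsv", sep="\t", index_label="gene_id")
        sig = degs.index[degs["significant"]].tolist()
        counts["significant_degs"] = len(sig)
        logger.info("deg_detection: %d/%d genes significant", len(sig), degs.shape[0])
        bundle["degs"] = degs
        if len(sig) < 2:
            raise InputError("fewer than 2 significant genes; cannot cluster")

        # ---- stage: subgrouping -------------------------------------------
        stage = "subgrouping"
        centered = median_center(expr.loc[sig])
        dist = correlation_distance(centered)
        tree = hierarchical_cluster(dist)
        model = cut_clusters(
            tree,
            expr.columns,
            k=cfg["clustering"]["k"],
            distance=dist,
            max_k=cfg["clustering"]["max_k"],
        )
        summary = summarize_subgroups(model, ann)
        model.assignment.to_frame().to_csv(outdir / "subgroups.tsv", sep="\t")
        summary.to_csv(outdir / "subgroup_summary.tsv", sep="\t")
        (outdir / "linkage.json").write_text(json.dumps(tree.tolist()))
        counts["subgroups"] = model.k
        bundle["model"] = model
        if not model.resistant_subgroups or len(model.resistant_subgroups) == model.k:
            raise InputError("clustering found no resistant/sensitive split")

        # ---- stage: gene_allocation ---------------------------------------
        stage = "gene_allocation"
        alloc = allocate_genes(sig, expr, model, ann, mode=cfg["allocation"]["mode"])
        allocation_to_frame(alloc).to_csv(outdir / "allocation.tsv", sep="\t", index=False)
        counts["common_resistant_genes"] = len(alloc.common_resistant)
        bundle["allocation"] = alloc

        # ---- stage: enrichment --------------------------------------------
        stage = "enrichment"
        pathway_genes = set().union(*pathways.values())
        universe = set(expr.index) & pathway_genes
        queries: dict[str, set] = {
            f"subgroup_{sub}_specific": alloc.specific_to_resistant[sub] - alloc.common_all
            for sub in alloc.specific_to_resistant
        }
        queries["common"] = set(alloc.common_all)
        if alloc.allocated_to_sensitive:
            queries["sensitive_common"] = set.intersection(
                *alloc.allocated_to_sensitive.values()
            )
        enrich_tables: dict[str, pd.DataFrame] = {}
        for name, q in queries.items():
            q_in = q & universe
            if not q_in:
                logger.info("enrichment: query %s empty within universe, skipped", name)
                continue
            table = pathway_analysis.hypergeom_enrichment(
                q_in, universe, pathways, alpha=cfg["enrichment"]["alpha"]
            )
            table.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
            enrich_tables[name] = table
        counts["enrichment_sets"] = len(enrich_tables)
        bundle["enrichment"] = enrich_tables

        # ---- stage: pathway_deviation -------------------------------------
        stage = "pathway_deviation"
        selected = pathway_analysis.significant_pathways(enrich_tables.values())
        profile = pathway_analysis.deviation_profile(
            pathways, selected, sig, model, ann, expr, variant=cfg["pathway_score"]["variant"]
        )
        profile.to_csv(outdir / "pathway_deviation.tsv", sep="\t")
        counts["significant_pathways"] = len(selected)
        bundle["pathway_deviation"] = profile

        # ---- stage: network_biomarkers ------------------------------------
        stage = "network_biomarkers"
        candidates = set()
        for name in selected:
            candidates |= pathways[name] & set(sig)
        node_set = candidates | alloc.common_all
        counts["network_nodes"] = len(node_set)
        if node_set:
            graph = network_biomarkers.build_network(interactions, node_set)
            degree_table = network_biomarkers.node_degrees(graph)
            biomarkers = network_biomarkers.select_biomarkers(
                degree_table, threshold=cfg["biomarkers"]["threshold"]
            )
        else:
            degree_table = pd.DataFrame(columns=["degree", "log2_degree"])
            biomarkers = []
        degree_table.assign(is_biomarker=degree_table.index.isin(biomarkers)).to_csv(
            outdir / "biomarker_degrees.tsv", sep="\t", index_label="gene_id"
        )
        counts["biomarkers"] = len(biomarkers)
        bundle["biomarkers"] = biomarkers

        # ---- stage: classifier --------------------------------------------
        stage = "classifier"
        if vexpr is not None and biomarkers:
            features = [g for g in biomarkers if g in expr.index and g in vexpr.index]
            if features:
                x_train = resistance_classifier.discretize(expr.loc[features])
                x_test = resistance_classifier.discretize(vexpr.loc[features])
                y_train = ann.loc[x_train.columns, "response"].tolist()
                y_test = resistance_classifier.labels_from_survival(vann).loc[
                    x_test.columns
                ].tolist()
                clf = resistance_classifier.train_tree(
                    x_train, y_train, seed=seed, **cfg["classifier"]
                )
                y_pred = resistance_classifier.predict(clf, x_test)
                report = resistance_classifier.classification_report(y_test, y_pred)
                (outdir / "classification_report.json").write_text(
                    json.dumps(report, indent=2, sort_keys=True)
                )
                (outdir / "tree.json").write_text(
                    json.dumps(resistance_classifier.tree_to_json(clf, features), indent=2)
                )
                counts["classifier_features"] = len(features)
                bundle["classification_report"] = report
            else:
                logger.info("classifier: no biomarker features shared with validation cohort")
        else:
            logger.info("classifier: skipped (no validation cohort or no biomarkers)")

        # ---- manifest ------------------------------------------------------
        stage = "manifest"
        manifest = {
            "config": cfg,
            "seed": seed,
            "version": __version__,
            "stage_counts": counts,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        bundle["counts"] = counts
        return bundle
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise ChemoresError(f"pipeline failed at stage {stage!r}: {exc}") from exc
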