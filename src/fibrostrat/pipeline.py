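"""End-to-end orchestration: preprocess -> cluster -> per-cluster DE ->
signature sets -> classifier validation -> prioritization -> panel
search, from a single YAML-able configuration, with plain-file stage
outputs and a machine-readable JSON run report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fibrostrat import biomarker_panel, classifier_eval, diffexpr, preprocess, signature_sets
from fibrostrat import subtype_clustering as clustering
from fibrostrat.io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    read_clinical_table,
    read_expression_matrix,
    read_gmt,
    write_clinical_table,
    write_de_table,
    write_expression_matrix,
    write_gmt,
    write_json_report,
)
from fibrostrat.prioritization import AnnotationDB, prioritize_candidates
from fibrostrat.signature_sets import directions_table, signatures_to_collection
from fibrostrat.synthetic import SyntheticConfig, generate_annotation_db, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs.  Either ``simulate = True`` (a
    synthetic cohort with planted truth) or explicit input paths."""

    output_dir: str = "fibrostrat_run"
    seed: int = 17
    simulate: bool = True
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # external inputs (used when simulate is False)
    expression_path: str | None = None
    expression_format: str = "tsv"
    clinical_path: str | None = None
    secreted_gmt: str | None = None
    training_gmt: str | None = None
    annotation_dir: str | None = None
    # preprocessing
    already_log2: bool = True
    log2_offset: float = 1.0
    aggregate_method: str = "median"
    variance_fraction: float = 0.25
    # clustering
    explained_variance: float = 0.90
    k_min: int = 2
    k_max: int = 10
    tolerance: float = 0.05
    # DE thresholds
    fdr_max: float = 0.05
    lfc_min: float = 1.0
    # modules / classifier / prioritization / panel
    n_gene_modules: int = 3
    l2_strength: float = 1.0
    min_sensitivity: float = 0.9
    cv_folds: int = 2
    top_fraction: float = 0.10
    panel_k_max: int = 50
    panel_min_specificity: float = 0.8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth:
            cfg.synthetic = SyntheticConfig(**synth)
        return cfg

    def content_hash(self) -> str:
        def _default(o):
            if isinstance(o, (np.integer, np.floating)):
                return float(o)
            return str(o)

        content = asdict(self)
        content.pop("output_dir", None)  # where results land is not what they are
        payload = json.dumps(content, sort_keys=True, default=_default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _preprocess_stage(cfg: RunConfig, raw: ExpressionMatrix) -> tuple[ExpressionMatrix, dict]:
    agg = preprocess.aggregate_duplicate_genes(raw, cfg.aggregate_method)
    logged = agg if cfg.already_log2 else preprocess.log2_transform(agg, cfg.log2_offset)
    centered = preprocess.median_center_genes(logged)
    summary = {
        "n_genes_in": raw.shape[0],
        "n_genes": centered.shape[0],
        "n_samples": centered.shape[1],
        "already_log2": cfg.already_log2,
    }
    return centered, summary


def run_all(cfg: RunConfig) -> dict:
    """Execute the full workflow; write artifacts and return the report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    report: dict = {"config_hash": cfg.content_hash(), "seed": cfg.seed, "stages": {}}
    truth = None

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # annotate failures with the stage
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # ----- inputs ---------------------------------------------------------
    if cfg.simulate:
        matrix, clinical, truth = generate_cohort(cfg.synthetic, rng=rng)
        db, training_genes, secreted_genes = generate_annotation_db(cfg.synthetic, truth, rng=rng)
        write_expression_matrix(matrix, out / "expression.tsv")
        write_clinical_table(clinical, out / "clinical.csv")
        report["truth"] = truth.to_report()
    else:
        if not (cfg.expression_path and cfg.clinical_path):
            raise ValueError("expression_path and clinical_path required when simulate is False")
        matrix = read_expression_matrix(cfg.expression_path, cfg.expression_format)
        clinical = read_clinical_table(cfg.clinical_path)
        secreted_genes = set(read_gmt(cfg.secreted_gmt).all_genes()) if cfg.secreted_gmt else set()
        training_genes = set(read_gmt(cfg.training_gmt).all_genes()) if cfg.training_gmt else set()
        db = AnnotationDB.from_gmt_dir(cfg.annotation_dir) if cfg.annotation_dir else None

    # ----- 1. preprocess --------------------------------------------------
    centered, summary = _stage("preprocess")(lambda: _preprocess_stage(cfg, matrix))
    write_expression_matrix(centered, out / "expression_preprocessed.tsv")
    report["stages"]["preprocess"] = summary

    # ----- 2. clustering --------------------------------------------------
    def _cluster():
        variable = preprocess.top_variable_genes(centered, cfg.variance_fraction)
        sub = preprocess.standardize_genes(centered.subset_genes(variable))
        disease = clinical.disease_samples()
        disease_m = sub.subset_samples(disease)
        pca, scores = clustering.fit_pca_project(
            disease_m, sub, explained_variance=cfg.explained_variance
        )
        disease_scores = scores.loc[disease]
        k, trace = clustering.select_cluster_count(
            disease_scores.to_numpy(), disease, clinical,
            k_min=cfg.k_min, k_max=cfg.k_max, tolerance=cfg.tolerance,
        )
        raw_labels = pd.Series(
            clustering.ward_cluster(disease_scores.to_numpy(), k), index=disease
        )
        assignment = clustering.order_clusters_by_severity(raw_labels, clinical, trace)
        return variable, pca, assignment

    variable, pca, assignment = _stage("cluster")(_cluster)
    assignment.labels.rename("cluster").to_frame().to_csv(out / "clusters.csv")
    assignment.trace.to_csv(out / "cluster_selection_trace.tsv", sep="\t", index=False)
    report["stages"]["cluster"] = {
        "n_variable_genes": len(variable),
        "n_components": pca.loadings.shape[1],
        "selected_k": assignment.k,
        "cluster_sizes": assignment.labels.value_counts().sort_index().to_dict(),
    }

    # ----- 3. differential expression ------------------------------------
    def _de():
        groups = clinical.groups.copy()
        groups.loc[assignment.labels.index] = assignment.labels
        contrasts = [(c, "control") for c in assignment.cluster_names()]
        de = diffexpr.de_table(
            centered, groups, contrasts, fdr_max=cfg.fdr_max, lfc_min=cfg.lfc_min
        )
        return de

    de = _stage("de")(_de)
    write_de_table(de, out / "de_table.tsv")
    deg_sets = diffexpr.call_degs(de, cfg.fdr_max, cfg.lfc_min)
    deg_sets = {c.split("_vs_")[0]: genes for c, genes in deg_sets.items()}
    deg_union = sorted(set().union(*[set(g) for g in deg_sets.values()]) or set())
    report["stages"]["de"] = {
        "contrasts": len(deg_sets),
        "deg_per_cluster": {c: len(g) for c, g in deg_sets.items()},
        "deg_union": len(deg_union),
    }

    # ----- 4. signature sets ---------------------------------------------
    def _signatures():
        core = signature_sets.core_set(deg_sets)
        uniques = [
            signature_sets.unique_set(deg_sets, c) for c in assignment.cluster_names()
        ]
        advanced = signature_sets.advanced_set(deg_sets, assignment.cluster_names())
        modules = (
            signature_sets.gene_modules(
                centered.subset_genes(deg_union), cfg.n_gene_modules
            )
            if len(deg_union) >= cfg.n_gene_modules
            else pd.Series(dtype=int)
        )
        return core, uniques, advanced, modules

    core, uniques, advanced, modules = _stage("signatures")(_signatures)
    coll = signatures_to_collection([core, advanced, *uniques])
    write_gmt(coll, out / "signatures.gmt")
    directions_table([core, advanced, *uniques]).to_csv(
        out / "signature_directions.tsv", sep="\t", index=False
    )
    if len(modules):
        modules.to_frame().to_csv(out / "gene_modules.csv")
    report["stages"]["signatures"] = {
        "core": len(core),
        "advanced": len(advanced),
        "unique_per_cluster": {s.name: len(s) for s in uniques},
        "n_modules": int(modules.nunique()) if len(modules) else 0,
    }

    # ----- 5. classifier validation --------------------------------------
    def _classify():
        labels = clinical.groups
        cv = classifier_eval.cross_validate(
            centered.subset_genes(core.genes) if len(core) else centered,
            labels,
            folds=cfg.cv_folds,
            seed=cfg.seed,
            l2_strength=cfg.l2_strength,
            min_sensitivity=cfg.min_sensitivity,
        )
        clf = classifier_eval.build_signature_classifier(
            centered, labels, core.genes if len(core) else centered.gene_ids,
            l2_strength=cfg.l2_strength, seed=cfg.seed,
            min_sensitivity=cfg.min_sensitivity,
        )
        reports = [evaluate_training := classifier_eval.evaluate(clf, centered, labels, "training")]
        if cfg.simulate:
            # a held-out synthetic validation cohort from an independent draw
            # (same per-gene variances/baselines: same platform)
            val_m, val_clin, _ = generate_cohort(cfg.synthetic, rng=rng, template=truth)
            val_centered, _ = _preprocess_stage(cfg, val_m)
            reports.append(
                classifier_eval.evaluate(clf, val_centered, val_clin.groups, "validation")
            )
        return clf, cv, reports

    clf, cv, eval_reports = _stage("classify")(_classify)
    write_json_report(
        {r.cohort: r.to_dict() for r in (*cv, *eval_reports)}, out / "classifier_reports.json"
    )
    report["stages"]["classify"] = {
        "signature_size": len(clf.genes),
        "threshold": clf.threshold,
        "cv_accuracy": float(np.mean([r.accuracy for r in cv])),
        **{
            r.cohort: {
                "auc": r.auc,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "accuracy": r.accuracy,
            }
            for r in eval_reports
        },
    }

    # ----- 6. prioritization ---------------------------------------------
    def _prioritize():
        if db is None or not training_genes:
            return None
        universe = set(centered.gene_ids)
        frames = []
        for sig in (core, advanced):
            sig_unknown = [g for g in sig.genes if g not in training_genes]
            if not sig_unknown:
                continue
            recs = prioritize_candidates(
                sig.genes, de, training_genes, db, universe, cfg.top_fraction
            )
            recs.insert(0, "signature", sig.name)
            frames.append(recs)
        return pd.concat(frames, ignore_index=True) if frames else None

    priority = _stage("prioritize")(_prioritize)
    if priority is not None:
        priority.to_csv(out / "prioritized_candidates.tsv", sep="\t", index=False)
        report["stages"]["prioritize"] = {
            "n_ranked": int(len(priority)),
            "n_selected": int(priority["selected"].sum()),
        }
    else:
        report["stages"]["prioritize"] = {"skipped": "no annotation DB or training genes"}

    # ----- 7. biomarker panel --------------------------------------------
    def _panel():
        if not secreted_genes:
            return None
        try:
            candidates = biomarker_panel.filter_secreted(core, secreted_genes)
        except ValueError:
            candidates = []
        if len(candidates) < 5:
            # too few secreted core genes to search over; fall back to the
            # full secreted list so the panel stage stays meaningful
            logger.warning(
                "only %d core genes are secreted-annotated; searching the full secreted list",
                len(candidates),
            )
            candidates = [g for g in centered.gene_ids if g in secreted_genes]
        if not candidates:
            return None
        full_clf = classifier_eval.build_signature_classifier(
            centered, clinical.groups, candidates, l2_strength=cfg.l2_strength,
            seed=cfg.seed, min_sensitivity=cfg.min_sensitivity,
        )
        ordered = biomarker_panel.rank_by_coefficient(full_clf)
        return biomarker_panel.nested_panel_search(
            centered, clinical.groups, ordered,
            k_max=cfg.panel_k_max, min_specificity=cfg.panel_min_specificity,
            min_sensitivity=cfg.min_sensitivity, seed=cfg.seed,
            l2_strength=cfg.l2_strength,
        )

    panel = _stage("biomarkers")(_panel)
    if panel is not None:
        write_json_report(
            {
                "ordered_genes": panel.ordered_genes,
                "selected_panel": panel.selected_panel,
                "criterion_met": panel.criterion_met,
                "trace": panel.trace,
                "params": panel.params,
            },
            out / "biomarker_panel.json",
        )
        report["stages"]["biomarkers"] = {
            "n_candidates": len(panel.ordered_genes),
            "panel_size": len(panel.selected_panel),
            "criterion_met": panel.criterion_met,
        }
    else:
        report["stages"]["biomarkers"] = {"skipped": "no secreted annotation"}

    # ----- truth-based recovery metrics (synthetic runs) ------------------
    if truth is not None:
        from fibrostrat.metrics import adjusted_rand_index, jaccard

        report["recovery"] = {
            "ari": adjusted_rand_index(
                truth.subgroups.reindex(assignment.labels.index), assignment.labels
            ),
            "core_jaccard": jaccard(set(core.genes), set(truth.core_genes)),
            "advanced_jaccard": jaccard(set(advanced.genes), set(truth.advanced_genes)),
            "true_k": int(truth.subgroups.max()),
            "recovered_k": assignment.k,
        }

    write_json_report(report, out / "report.json")
    return report
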