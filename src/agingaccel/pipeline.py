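"""End-to-end orchestration: synthetic (or loaded) cohort -> preprocessing ->
aging/AD predictors -> aging scores -> acceleration networks (train/test) ->
network validation and hub predictor -> bipartite graph -> enrichment.

Every stage writes plain TSV/JSON artifacts into the run directory and is
recorded, with SHA-256 digests, in a run manifest.  A single global seed is
fanned out to per-stage seeds by fixed offsets so stages can be re-run
independently yet reproducibly.  With ``resume=True``, stages whose output
files already exist are loaded from disk instead of recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aging_score as ascore
from . import bipartite as bp
from . import network as net
from . import predictor as pred
from . import preprocess as prep
from .data_model import AnalysisConfig, ExpressionMatrix, GeneSetCollection, \
    read_expression, read_gmt, write_expression
from .enrichment import enrich
from .synthetic import GroundTruth, SimulationSpec, generate_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_all"]

# fixed per-stage seed offsets (stage reproducibility under one global seed)
SEED_OFFSETS = {"data": 0, "split_aging": 101, "split_disease": 202,
                "cv": 303, "genesets": 404}


@dataclass
class PipelineConfig:
    out_dir: str | Path
    simulation: SimulationSpec | None = None
    expression_path: str | Path | None = None
    metadata_path: str | Path | None = None
    gmt_path: str | Path | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    floors: tuple[int, ...] = ascore.DEFAULT_AGE_FLOORS
    resume: bool = False

    def __post_init__(self) -> None:
        if self.simulation is None and (self.expression_path is None
                                        or self.metadata_path is None):
            raise ValueError("provide either a simulation spec or expression "
                             "and metadata paths")


@dataclass
class RunManifest:
    seed: int
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {str(p.name): _sha256(p) for p in outputs},
            "seconds": round(seconds, 3),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "config": self.config,
                       "stages": self.stages}, fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the full workflow and return the run manifest.

    Stage order: data -> preprocess -> predictors -> aging scores ->
    acceleration networks (train and test) with validation and hub
    predictor -> bipartite graph and cross-panel correlations -> enrichment.
    Any stage failure propagates with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.analysis
    seed = cfg.random_seed
    manifest = RunManifest(seed=seed, config={
        "analysis": dataclasses.asdict(cfg),
        "simulation": dataclasses.asdict(config.simulation) if config.simulation else None,
        "floors": list(config.floors),
    })

    stage = "data"
    try:
        t0 = time.perf_counter()
        expr_p, meta_p, truth_p = out / "expression.tsv", out / "metadata.tsv", \
            out / "ground_truth.json"
        if config.resume and expr_p.exists() and meta_p.exists():
            cohort = read_expression(expr_p, meta_p)
            truth = GroundTruth.from_json(truth_p) if truth_p.exists() else None
        elif config.simulation is not None:
            sim = dataclasses.replace(config.simulation,
                                      seed=seed + SEED_OFFSETS["data"])
            cohort, truth = generate_cohort(sim)
            write_expression(cohort, expr_p, meta_p)
            truth.to_json(truth_p)
        else:
            cohort = read_expression(config.expression_path, config.metadata_path)
            truth = None
            write_expression(cohort, expr_p, meta_p)
        manifest.record(stage, [p for p in (expr_p, meta_p, truth_p) if p.exists()],
                        time.perf_counter() - t0)

        stage = "preprocess"
        t0 = time.perf_counter()
        clean_p, svd_p = out / "clean.tsv", out / "svd_report.json"
        if config.resume and clean_p.exists():
            clean = read_expression(clean_p, meta_p)
        else:
            m = prep.filter_missing(cohort, cfg.missing_fraction_max)
            m = prep.log_transform(m)
            reports = prep.svd_variance_report(m)
            _write_json([{"tissue": r.tissue, "fractions": r.component_variance_fractions,
                          "degenerate": r.degenerate} for r in reports], svd_p)
            clean = prep.zscore_normalize(m)
            write_expression(clean, clean_p)
        manifest.record(stage, [clean_p, svd_p], time.perf_counter() - t0)

        stage = "predictors"
        t0 = time.perf_counter()
        pred_out = {}
        splits = {}
        for task in ("aging", "disease"):
            task_p = out / f"predictor_{task}.json"
            base = clean.where(clean.samples["diagnosis"] == "normal") \
                if task == "aging" else clean
            train, test = pred.split_cohort(
                base, task, seed + SEED_OFFSETS[f"split_{task}"], cfg.age_threshold)
            splits[task] = (train, test)
            if config.resume and task_p.exists():
                with open(task_p) as fh:
                    pred_out[task] = json.load(fh)
                continue
            ytr = pred.task_labels(train, task, cfg.age_threshold)
            yte = pred.task_labels(test, task, cfg.age_threshold)
            ranking = pred.relieff_rank(train, ytr)
            curve = pred.cross_validate_topk(train, ytr, ranking,
                                             top_models=cfg.top_models,
                                             folds=cfg.cv_folds,
                                             seed=seed + SEED_OFFSETS["cv"])
            panel = ranking.top(curve.best_k)
            model = pred.fit_nna(train, ytr, panel)
            ev = pred.evaluate(model, test, yte)
            pred_out[task] = {
                "panel": panel, "best_k": curve.best_k,
                "cv_accuracy": list(np.round(curve.mean_accuracy, 10)),
                "auc": ev["auc"], "accuracy": ev["accuracy"],
            }
            _write_json(pred_out[task], task_p)
        manifest.record(stage, [out / "predictor_aging.json",
                                out / "predictor_disease.json"],
                        time.perf_counter() - t0)

        stage = "aging_scores"
        t0 = time.perf_counter()
        scores_p, kw_p, summary_p = out / "scores.tsv", out / "kruskal_wallis.json", \
            out / "score_summary.tsv"
        aging_panel = pred_out["aging"]["panel"]
        pools = ascore.build_reference_pools(clean, aging_panel, cfg.age_threshold)
        scores = ascore.compute_aging_scores(clean, pools)
        scores.to_csv(scores_p, sep="\t")
        kw = {}
        for floor in config.floors:
            sub = scores[scores["age"] >= floor]
            counts = sub["diagnosis"].value_counts()
            if len(counts) == 2 and counts.min() >= 2:
                kw[str(floor)] = ascore.kruskal_wallis_by_group(
                    sub["atan"], sub["diagnosis"])
            else:
                kw[str(floor)] = None
        _write_json(kw, kw_p)
        ascore.age_group_summary(scores, config.floors).to_csv(summary_p, sep="\t")
        manifest.record(stage, [scores_p, kw_p, summary_p], time.perf_counter() - t0)

        stage = "network"
        t0 = time.perf_counter()
        nets = {}
        for part in ("train", "test"):
            mask = clean.samples["split"] == part if "split" in clean.samples.columns \
                else pd.Series(part == "train", index=clean.samples.index)
            sub = clean.where(mask)
            recs = {}
            for dx in ("AD", "normal"):
                grp = sub.where(sub.samples["diagnosis"] == dx)
                recs[dx] = net.pair_product_correlations(grp, scores["atan"])
            nets[part] = net.build_network(recs["AD"], recs["normal"], clean.genes,
                                           cfg.p_threshold, cfg.fdr_threshold)
            net.edge_table(nets[part]).to_csv(out / f"edges_{part}.tsv", sep="\t",
                                              index=False)
        stats: dict = {"n_edges_train": nets["train"].graph.number_of_edges(),
                       "n_edges_test": nets["test"].graph.number_of_edges()}
        try:
            stats["fisher_overlap_p"] = net.fisher_overlap_test(
                nets["train"], nets["test"])["p"]
        except ValueError as e:
            stats["fisher_overlap_p"] = None
            stats["fisher_overlap_note"] = str(e)
        try:
            fit = net.degree_distribution_fit(nets["train"])
            stats["degree_loglog_r"] = fit["loglog_pearson_r"]
            stats["degree_loglog_p"] = fit["p"]
        except ValueError as e:
            stats["degree_loglog_r"] = None
            stats["degree_note"] = str(e)
        train_d, test_d = splits["disease"]
        try:
            hub = net.hub_predictor(
                nets["train"], train_d, test_d,
                pred.task_labels(train_d, "disease"),
                pred.task_labels(test_d, "disease"),
                top_models=cfg.top_models, folds=cfg.cv_folds,
                seed=seed + SEED_OFFSETS["cv"])
            stats["hub_auc"] = hub["auc"]
            stats["hub_accuracy"] = hub["accuracy"]
            stats["hub_panel"] = hub["panel"]
        except ValueError as e:
            stats["hub_note"] = str(e)
        _write_json(stats, out / "network_stats.json")
        manifest.record(stage, [out / "edges_train.tsv", out / "edges_test.tsv",
                                out / "network_stats.json"],
                        time.perf_counter() - t0)

        stage = "bipartite"
        t0 = time.perf_counter()
        pairs_p, corr_p, bip_p = out / "bipartite_pairs.tsv", \
            out / "biomarker_correlations.tsv", out / "bipartite_summary.json"
        disease_panel = pred_out["disease"]["panel"]
        if nets["train"].graph.number_of_edges() > 0:
            pairs = bp.shortest_paths_between_sets(nets["train"], aging_panel,
                                                   disease_panel)
        else:
            pairs = []
        pd.DataFrame([{
            "aging_marker": p.aging_marker, "ad_marker": p.ad_marker,
            "path_length": p.path_length, "path": ";".join(p.path),
        } for p in pairs]).to_csv(pairs_p, sep="\t", index=False)
        _write_json(bp.build_bipartite_graph(pairs), bip_p)
        ad_train = train_d.where(train_d.samples["diagnosis"] == "AD")
        corr = bp.biomarker_correlations(ad_train, aging_panel, disease_panel)
        corr["matrix"].to_csv(corr_p, sep="\t")
        manifest.record(stage, [pairs_p, corr_p, bip_p], time.perf_counter() - t0)

        stage = "enrichment"
        t0 = time.perf_counter()
        enr_p = out / "enrichment.tsv"
        if config.gmt_path is not None:
            sets = read_gmt(config.gmt_path)
        else:
            sets = _synthetic_gene_sets(clean.genes, truth,
                                        seed + SEED_OFFSETS["genesets"])
        rows = []
        for res in enrich(disease_panel, sets, clean.genes,
                          cfg.p_threshold, cfg.fdr_threshold):
            rows.append({"query": "disease_panel", **dataclasses.asdict(res)})
        for p_ in pairs[:200]:  # per-path BH family, one call per path
            for res in enrich(p_.path, sets, clean.genes,
                              cfg.p_threshold, cfg.fdr_threshold):
                rows.append({"query": f"path:{p_.aging_marker}-{p_.ad_marker}",
                             **dataclasses.asdict(res)})
        pd.DataFrame(rows).to_csv(enr_p, sep="\t", index=False)
        manifest.record(stage, [enr_p], time.perf_counter() - t0)
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    manifest.to_json(out / "manifest.json")
    return manifest


def _synthetic_gene_sets(genes: list[str], truth: GroundTruth | None,
                         seed: int) -> GeneSetCollection:
    """Seeded stand-in gene-set collection: the planted marker panels (when
    ground truth is available) plus random sets, for exercising enrichment
    on cohorts that ship no GMT file."""
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    if truth is not None:
        sets["PLANTED_AGING_MARKERS"] = list(truth.aging_markers)
        sets["PLANTED_AD_MARKERS"] = list(truth.ad_markers)
    for i in range(20):
        size = int(rng.integers(10, 51))
        sets[f"RANDOM_SET_{i:02d}"] = sorted(
            rng.choice(genes, size=min(size, len(genes)), replace=False))
    return GeneSetCollection(sets=sets, source="synthetic")
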