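"""End-to-end orchestration: synthesize -> cognition -> normative -> clinical/pgs
-> associations -> enrichment, with a manifest recording config, seeds and outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import cognorm
from cognorm import bayes, clinical, cognition, cohort as cohort_mod, enrichment, normative, pgs, plots

logger = logging.getLogger(__name__)

# deterministic per-stage seed offsets from the global seed
SEED_OFFSETS = {
    "synthesize": 0,
    "normative": 101,
    "clinical": 202,
    "pgs": 303,
}

STAGE_ORDER = ["synthesize", "cognition", "normative", "clinical", "pgs", "associate", "enrich"]

DEFAULT_CONFIG = {
    "seed": 42,
    "outdir": "cognorm_out",
    "stages": {stage: True for stage in STAGE_ORDER},
    "synthesize": {"n_subjects": 1000},
    "cognition": {"max_missing": 5, "anchor_test": "WRAT"},
    "normative": {"k": 10, "n_restarts": 3, "max_opt_points": 1000},
    "clinical": {"k": 7, "n_restarts": 20},
    "pgs": {"n_thresholds": 6002},
    "enrich": {"thresholds": [1.0, 1.5, 2.0, 3.0]},
    "plots": True,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    for key, value in (overrides or {}).items():
        if value is not None:
            config[key] = value
    return config


def _stage_seed(config: dict, stage: str) -> int:
    return int(config.get("seeds", {}).get(stage, config["seed"] + SEED_OFFSETS.get(stage, 0)))


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> Path:
    frame.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def run_pipeline(config: dict) -> dict:
    """Execute all enabled stages in dependency order; returns the manifest."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {})
    want_plots = config.get("plots", True)
    manifest = {
        "config_hash": _config_hash(config),
        "version": cognorm.__version__,
        "seed": config["seed"],
        "stage_seeds": {s: _stage_seed(config, s) for s in SEED_OFFSETS},
        "stages": {},
    }
    current = "setup"
    try:
        # ---------------- synthesize ----------------
        cohort_dir = outdir / "cohort"
        if stages.get("synthesize", True):
            current = "synthesize"
            logger.info("stage %s", current)
            cc_kwargs = dict(config.get("synthesize", {}))
            cc_kwargs.setdefault("seed", _stage_seed(config, "synthesize"))
            cc = cohort_mod.CohortConfig.from_dict(cc_kwargs)
            cohort = cohort_mod.generate_cohort(cc)
            cohort_mod.write_cohort(cohort, cohort_dir)
            manifest["stages"]["synthesize"] = {
                "outputs": sorted(p.name for p in cohort_dir.iterdir()),
                "n_subjects": cohort.n_subjects,
            }
        elif "cohort_dir" in config:
            cohort_dir = Path(config["cohort_dir"])
            cohort = cohort_mod.read_cohort(cohort_dir)
        else:
            raise ValueError("no cohort: enable the synthesize stage or provide cohort_dir")
        logger.info("cohort with %d subjects", cohort.n_subjects)

        demographics = cohort.demographics

        # ---------------- cognition ----------------
        g_table = None
        if stages.get("cognition", True):
            current = "cognition"
            logger.info("stage %s", current)
            opts = config.get("cognition", {})
            imputed, excluded = cognition.impute_cognitive(
                cohort.cognition, max_missing=opts.get("max_missing", 5)
            )
            model = cognition.fit_pca(imputed)
            gscores = cognition.extract_g(model, imputed, anchor_test=opts.get("anchor_test", "WRAT"))
            g_table = gscores.g.reset_index()
            _write_tsv(g_table, outdir / "g_scores.tsv")
            summary = {
                "explained_variance": model.explained_variance.tolist(),
                "contributions_pc1": dict(zip(model.test_names, model.contributions[:, 0].tolist())),
                "excluded_ids": list(excluded),
            }
            (outdir / "pca_summary.json").write_text(json.dumps(summary, indent=2))
            outputs = ["g_scores.tsv", "pca_summary.json"]
            if want_plots:
                plots.scree_plot(model.explained_variance, outdir / "scree.png")
                outputs.append("scree.png")
            manifest["stages"]["cognition"] = {"outputs": outputs, "n_excluded": len(excluded)}

        # ---------------- normative ----------------
        z_table = None
        if stages.get("normative", True):
            current = "normative"
            logger.info("stage %s", current)
            if g_table is None:
                g_table = pd.read_csv(outdir / "g_scores.tsv", sep="\t")
            opts = config.get("normative", {})
            merged = g_table.merge(demographics, on="subject_id")
            X = merged[["age", "sex"]].to_numpy(dtype=float)
            y = merged["g"].to_numpy(dtype=float)
            seed = _stage_seed(config, "normative")
            dev, metrics = normative.crossval_normative(
                X,
                y,
                k=opts.get("k", 10),
                seed=seed,
                n_restarts=opts.get("n_restarts", 3),
                max_opt_points=opts.get("max_opt_points", 1500),
            )
            z_table = pd.DataFrame(
                {"subject_id": merged["subject_id"], "z": dev.z, "fold_id": dev.fold_id}
            )
            _write_tsv(z_table, outdir / "z_scores.tsv")
            (outdir / "metrics.json").write_text(json.dumps(metrics.to_dict(), indent=2))
            outputs = ["z_scores.tsv", "metrics.json"]
            if want_plots:
                full_model = normative.fit_gp(
                    X, y, seed=seed, n_restarts=opts.get("n_restarts", 3),
                    max_opt_points=opts.get("max_opt_points", 1500),
                )
                plots.normative_trajectory_plot(full_model, merged, y, outdir / "normative_trajectory.png")
                outputs.append("normative_trajectory.png")
            manifest["stages"]["normative"] = {"outputs": outputs, "metrics": metrics.to_dict()}

        # ---------------- clinical ----------------
        components = None
        if stages.get("clinical", True):
            current = "clinical"
            logger.info("stage %s", current)
            opts = config.get("clinical", {})
            imputed, excluded = clinical.knn_impute(cohort.clinical_items)
            model = clinical.fit_ica(
                imputed,
                k=opts.get("k", 7),
                n_restarts=opts.get("n_restarts", 20),
                seed=_stage_seed(config, "clinical"),
            )
            components = clinical.component_table(model, imputed["subject_id"])
            comp_out = components.scores.copy()
            comp_out["general"] = components.general.to_numpy()
            _write_tsv(comp_out, outdir / "clinical_components.tsv")
            (outdir / "ica_model.json").write_text(
                json.dumps(
                    {
                        "mixing": model.mixing.tolist(),
                        "stability_index": model.stability_index.tolist(),
                        "restarts": model.restarts,
                        "item_names": model.item_names,
                        "excluded_ids": list(excluded),
                    }
                )
            )
            manifest["stages"]["clinical"] = {
                "outputs": ["clinical_components.tsv", "ica_model.json"],
                "n_excluded": len(excluded),
            }

        # ---------------- pgs ----------------
        pgs_table = None
        if stages.get("pgs", True) and len(cohort.summary_stats):
            current = "pgs"
            logger.info("stage %s", current)
            opts = config.get("pgs", {})
            thresholds = pgs.default_thresholds(opts.get("n_thresholds", 6002))
            prs = pgs.compute_prs_matrix(cohort.genotypes, cohort.summary_stats, thresholds)
            component = pgs.prs_pca(prs)
            pgs_table = pd.DataFrame({"subject_id": component.subject_ids, "PGS": component.score})
            _write_tsv(pgs_table, outdir / "pgs_component.tsv")
            (outdir / "pgs_summary.json").write_text(
                json.dumps({"explained_variance": component.explained_variance})
            )
            manifest["stages"]["pgs"] = {
                "outputs": ["pgs_component.tsv", "pgs_summary.json"],
                "explained_variance": component.explained_variance,
            }

        # ---------------- associate ----------------
        if stages.get("associate", True):
            current = "associate"
            logger.info("stage %s", current)
            if z_table is None:
                z_table = pd.read_csv(outdir / "z_scores.tsv", sep="\t")
            frame = z_table.merge(demographics, on="subject_id")
            predictors = {}
            if components is not None:
                comp = components.scores.copy()
                comp["general"] = components.general.to_numpy()
                frame = frame.merge(comp, on="subject_id")
                predictors.update(
                    {c: c for c in comp.columns if c != "subject_id"}
                )
            if pgs_table is not None:
                frame = frame.merge(pgs_table, on="subject_id")
                predictors["PGS"] = "PGS"
            if not predictors:
                raise ValueError("associate stage needs clinical components and/or PGS scores")
            covariates = frame[["age", "sex"]].to_numpy(dtype=float)
            rows = []
            for name in predictors:
                post = bayes.fit_bayes_linear(
                    frame["z"].to_numpy(dtype=float),
                    frame[name].to_numpy(dtype=float),
                    covariates=covariates,
                    name=name,
                )
                bf = bayes.savage_dickey(post)
                rows.append(
                    {
                        "predictor": name,
                        "beta_mean": post.beta_mean,
                        "beta_sd": post.beta_sd,
                        "ci_low": post.ci95[0],
                        "ci_high": post.ci95[1],
                        "bf01": bf.bf01,
                        "category": bf.category,
                    }
                )
            assoc = pd.DataFrame(rows)
            _write_tsv(assoc, outdir / "associations.tsv")
            outputs = ["associations.tsv"]
            if want_plots:
                plots.posterior_interval_plot(assoc, outdir / "posterior_intervals.png")
                outputs.append("posterior_intervals.png")
            manifest["stages"]["associate"] = {"outputs": outputs, "n_predictors": len(rows)}

        # ---------------- enrich ----------------
        if stages.get("enrich", True):
            current = "enrich"
            logger.info("stage %s", current)
            if z_table is None:
                z_table = pd.read_csv(outdir / "z_scores.tsv", sep="\t")
            if components is None:
                raise ValueError("enrich stage requires the clinical stage")
            opts = config.get("enrich", {})
            comp = components.scores.copy()
            comp["general"] = components.general.to_numpy()
            frame = z_table.merge(comp, on="subject_id")
            assignment = enrichment.assign_deciles(frame["z"].to_numpy(dtype=float))
            domains = frame.drop(columns=["subject_id", "z", "fold_id"])
            enrich_table, or_table = enrichment.enrichment_tables(
                assignment, domains, tuple(opts.get("thresholds", enrichment.DEFAULT_THRESHOLDS))
            )
            _write_tsv(enrich_table, outdir / "enrichment.tsv")
            _write_tsv(or_table, outdir / "or_table.tsv")
            outputs = ["enrichment.tsv", "or_table.tsv"]
            if want_plots:
                plots.enrichment_plot(enrich_table, outdir / "enrichment_proportions.png")
                outputs.append("enrichment_proportions.png")
            manifest["stages"]["enrich"] = {"outputs": outputs}

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage {current!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
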