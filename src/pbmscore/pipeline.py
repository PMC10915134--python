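"""End-to-end orchestration: configuration, staged execution and JSON
reports.

A run is described by a :class:`RunConfig` (YAML on disk).  Stages execute
in dependency order — simulate or load inputs, score, survival, staging
trend/discrimination, progression, mutations, TIME — and each writes a
JSON block into the combined report.  All numeric content is a pure
function of the configuration and seeds; wall-clock metadata is isolated
in a separate ``metadata`` block so reruns are comparable byte for byte on
the ``results`` block.  Exclusions (missing clinical fields, skipped
genes) are reported with counts and reasons, never silently.

Significance flagging in reports uses a single two-sided alpha of 0.05;
it never drives filtering.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, genomics, scoring, simulate, stats, survival, time_profile
from .io import (
    ClinicalTable,
    SignatureScoreTable,
    read_clinical,
    read_expression,
    read_gmt,
    read_maf,
    write_scores,
)

logger = logging.getLogger(__name__)

ALPHA = 0.05  # report-flagging significance level, two-sided


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    out_dir: str = "pbm_run"
    seed: int = 7
    n_perm: int = 1000
    plasma_signature: str = "PlasmaB"
    endpoint: str = "os"
    # input paths (all optional when simulating)
    expression: str | None = None
    gmt: str | None = None
    clinical: str | None = None
    maf: str | None = None
    wbm: str | None = None
    whitelist: str | None = None
    # simulation
    simulate: bool = False
    n_samples: int = 762
    # analysis knobs
    models: tuple = ("iss",)
    with_pbm: bool = True
    cv_repeats: int = 100
    cv_folds: int = 5
    min_carriers: int = 30
    top_n_genes: int = 10
    k_clusters: int = 5
    min_signature_genes: int = 5

    def __post_init__(self) -> None:
        if self.endpoint not in ("os", "efs"):
            raise ValueError(f"endpoint must be 'os' or 'efs', got {self.endpoint!r}")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        if not self.simulate:
            for name in ("expression", "gmt"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"config needs {name!r} unless simulate is true")
                if not Path(path).exists():
                    raise ValueError(f"{name} path does not exist: {path}")
            for name in ("clinical", "maf", "wbm", "whitelist"):
                path = getattr(self, name)
                if path is not None and not Path(path).exists():
                    raise ValueError(f"{name} path does not exist: {path}")


def validate_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are errors with a
    nearest-match suggestion."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suffix}")
    cfg = RunConfig(**raw)
    defaults = RunConfig.__dataclass_fields__
    for name in known - set(raw):
        logger.info("config %s defaulted to %r", name, getattr(cfg, name))
    return cfg


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict())
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else repr(v)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all applicable stages and write ``report.json`` plus the
    score table under ``config.out_dir``.  Returns the report dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"results": {}, "exclusions": []}
    res = report["results"]

    # ---- stage: inputs -------------------------------------------------
    if config.simulate:
        cohort = simulate.simulate_cohort(n_samples=config.n_samples, seed=config.seed)
        matrix = cohort["expression"]
        signatures = [cohort["plasma_signature"]]
        clinical = cohort["clinical"]
        mutations = cohort["mutations"]
        wbm = None
        whitelist = sorted(set(mutations.data["gene"]))
    else:
        matrix = read_expression(config.expression)
        signatures = read_gmt(config.gmt)
        clinical = read_clinical(config.clinical) if config.clinical else None
        mutations = read_maf(config.maf) if config.maf else None
        wbm = read_expression(config.wbm) if config.wbm else None
        whitelist = None
        if config.whitelist:
            whitelist = [
                line.strip()
                for line in Path(config.whitelist).read_text().splitlines()
                if line.strip()
            ]

    # ---- stage: scoring ------------------------------------------------
    score_df = scoring.score_signatures(
        matrix,
        signatures,
        n_perm=config.n_perm,
        seed=config.seed,
        min_genes=config.min_signature_genes,
    )
    table = scoring.compute_pbm(score_df, config.plasma_signature)
    write_scores(table, out_dir / "scores.tsv")
    pbm = table.pbm
    res["scoring"] = {
        "n_samples": len(pbm),
        "n_signatures": len(signatures),
        "pbm_mean": float(pbm.mean()),
        "pbm_sd": float(pbm.std(ddof=1)),
    }

    if clinical is not None:
        clinical = survival.add_stages(clinical)
        clin = clinical.data.loc[pbm.index]
        time_col = f"{config.endpoint}_time"
        event_col = f"{config.endpoint}_event"
        if time_col not in clin.columns or event_col not in clin.columns:
            raise ValueError(
                f"endpoint {config.endpoint!r} needs columns "
                f"{time_col!r} and {event_col!r}"
            )

        # ---- stage: survival -------------------------------------------
        usable = clin[[time_col, event_col]].notna().all(axis=1)
        if (~usable).any():
            report["exclusions"].append(
                {
                    "stage": "survival",
                    "reason": "missing time/event",
                    "count": int((~usable).sum()),
                }
            )
        surv = clin[usable]
        groups = survival.median_split(pbm[usable])
        km = survival.km_logrank(
            surv[time_col].to_numpy(), surv[event_col].to_numpy(), groups.to_numpy()
        )
        cox = survival.cox_fit(
            surv[time_col].to_numpy(),
            surv[event_col].to_numpy(),
            pd.DataFrame({"pbm_high": (groups == "high").astype(float).to_numpy()}),
        )
        res["survival"] = {
            "logrank_chi_square": km.chi_square,
            "logrank_p": km.p_value,
            "logrank_significant": km.p_value < ALPHA,
            "median_split_hr": cox.hr("pbm_high") if cox.converged else None,
            "hr_ci": [
                float(cox.summary.loc["pbm_high", "ci_low"]),
                float(cox.summary.loc["pbm_high", "ci_high"]),
            ]
            if cox.converged
            else None,
        }

        # ---- stage: cross-validated model comparison -------------------
        if "iss" in clin.columns and clin["iss"].notna().any():
            cv_data = surv.copy()
            cv_data["pbm"] = pbm[usable]
            specs = {}
            for model in config.models:
                if model in cv_data.columns:
                    specs[model] = [model]
                    if config.with_pbm:
                        specs[f"{model}+pbm"] = [model, "pbm"]
            if config.with_pbm:
                specs["pbm"] = ["pbm"]
            cv = survival.cv_compare_models(
                cv_data,
                specs,
                time_col=time_col,
                event_col=event_col,
                repeats=config.cv_repeats,
                folds=config.cv_folds,
                seed=config.seed,
            )
            res["cv_model_comparison"] = {
                "mean_c_index": cv.mean_c.to_dict(),
                "pairwise_p": cv.pairwise_p.to_dict(),
            }

        # ---- stage: stage trend / discrimination -----------------------
        if "stage_label" in clin.columns and clin["stage_label"].notna().any():
            labeled = clin["stage_label"].notna()
            stages_present = clin.loc[labeled, "stage_label"]
            if stages_present.nunique() >= 3:
                trend = stats.trend_test(
                    pbm[labeled].to_numpy(), stages_present, mode="approx"
                )
                res["stage_trend"] = {
                    "z": trend.statistic,
                    "p": trend.p_value,
                    "significant": trend.p_value < ALPHA,
                }
            disc = classify.stage_discrimination(pbm[labeled], stages_present)
            res["stage_auc"] = disc.to_dict()

        # ---- stage: progression ----------------------------------------
        if "progressed" in clin.columns and clin["progressed"].notna().any():
            mask = clin["progressed"].notna()
            prog = classify.progression_eval(
                pbm[mask].to_numpy(), clin.loc[mask, "progressed"].to_numpy(int)
            )
            res["progression"] = {
                "auc": prog.roc.auc,
                "cutoff": prog.roc.optimal_cutoff,
                "sensitivity": prog.roc.sensitivity,
                "specificity": prog.roc.specificity,
                "fisher_p": prog.fisher_p,
                "rate_ratio": prog.rate_ratio,
            }

        # ---- stage: mutations ------------------------------------------
        if mutations is not None:
            summary = genomics.summarize_mutations(mutations, list(pbm.index))
            tmb_assoc = genomics.tmb_pbm_association(summary.tmb, pbm)
            gene_universe = whitelist or sorted(summary.carriers)
            top = genomics.select_frequent_genes(
                summary,
                gene_universe,
                min_carriers=config.min_carriers,
                top_n=config.top_n_genes,
            )
            assoc = genomics.mutation_pbm_association(summary, pbm, top)
            res["mutations"] = {
                "tmb_wilcoxon_p": tmb_assoc.p_value,
                "tmb_direction": tmb_assoc.direction,
                "frequent_genes": top,
                "per_gene": assoc.to_dict() if len(assoc) else {},
            }

    # ---- stage: TIME ----------------------------------------------------
    if wbm is not None:
        sigs = [s for s in signatures]
        tm = time_profile.estimate_time(
            wbm, sigs, n_perm=config.n_perm, seed=config.seed
        )
        filtered = time_profile.filter_cell_types(tm)
        z = time_profile.z_normalize(filtered.matrix)
        clusters = time_profile.cluster_time(z, k=config.k_clusters)
        shared = [s for s in clusters.labels.index if s in pbm.index]
        assoc = time_profile.cluster_associations(
            time_profile.TIMEClusters(clusters.labels.loc[shared], k=clusters.labels.loc[shared].nunique()),
            pbm.loc[shared],
            clinical,
            time_matrix=z.loc[shared],
        )
        res["time"] = {
            "cluster_sizes": clusters.labels.value_counts().to_dict(),
            "excluded_cell_types": filtered.excluded,
            "highest_pbm_cluster": assoc["highest_pbm_cluster"],
            "vs_highest": assoc["vs_highest"],
        }

    report["metadata"] = {
        "config": dataclasses.asdict(config),
        "elapsed_seconds": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    payload = _jsonify(report)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return payload
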