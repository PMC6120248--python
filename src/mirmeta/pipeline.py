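"""Four-stage workflow orchestration: differential screening, clinical
association, meta-analysis (continuous and diagnostic), and target
consensus / enrichment / network summarization, driven by a single YAML
configuration.  Every stage persists its intermediate tables under the output
directory and contributes to a machine-readable ``summary.json``.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical, diagmeta, enrich, io, meta, network, screen, synthetic
from .datatypes import ArmSummary, ValidationError

log = logging.getLogger("mirmeta")

STAGES = ("simulate", "screen", "assoc", "meta", "diagmeta", "targets", "enrich", "network")

DEFAULTS = {
    "lfc_thresh": 1.0,
    "p_thresh": 0.05,
    "top_k": 250,
    "min_votes": 6,
    "min_degree": 5,
    "flavor": "cohen",
    "pseudocount": 1.0,
}


@dataclass
class PipelineConfig:
    stages: list[str] = field(default_factory=list)
    inputs: dict = field(default_factory=dict)      # stage -> {name: path}
    thresholds: dict = field(default_factory=lambda: dict(DEFAULTS))
    seed: int = 0
    out_dir: str = "mirmeta_out"

    def threshold(self, key: str):
        return self.thresholds.get(key, DEFAULTS[key])


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML config, reporting every problem at once."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors: list[str] = []
    known = {"stages", "inputs", "thresholds", "seed", "out_dir"}
    for key in raw:
        if key not in known:
            log.warning("unknown config key %r ignored", key)
    cfg = PipelineConfig(
        stages=list(raw.get("stages", [])),
        inputs={k: dict(v) for k, v in (raw.get("inputs") or {}).items()},
        thresholds={**DEFAULTS, **(raw.get("thresholds") or {})},
        seed=raw.get("seed", 0),
        out_dir=raw.get("out_dir", "mirmeta_out"),
    )
    for s in cfg.stages:
        if s not in STAGES:
            errors.append(f"unknown stage {s!r}; valid stages: {', '.join(STAGES)}")
    if not isinstance(cfg.seed, int):
        errors.append(f"seed must be an integer, got {cfg.seed!r}")
    for key, lo in (("lfc_thresh", 0.0), ("p_thresh", 0.0), ("pseudocount", 0.0)):
        v = cfg.thresholds.get(key)
        if not isinstance(v, (int, float)) or v < lo:
            errors.append(f"threshold {key} must be a number >= {lo}, got {v!r}")
    for key in ("top_k", "min_votes", "min_degree"):
        v = cfg.thresholds.get(key)
        if not isinstance(v, int) or v < 0 or (key == "top_k" and v < 1):
            errors.append(f"threshold {key} must be a nonnegative integer, got {v!r}")
    if cfg.thresholds.get("flavor") not in ("cohen", "hedges"):
        errors.append(f"flavor must be 'cohen' or 'hedges', got {cfg.thresholds.get('flavor')!r}")
    for stage in cfg.stages:
        if stage == "simulate":
            continue
        for name, p in cfg.inputs.get(stage, {}).items():
            if not Path(p).exists():
                errors.append(f"stage {stage!r}: input {name!r} not found at {p}")
    if errors:
        raise ValidationError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj, key=str) if not isinstance(obj, (list, tuple))] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


# -- stage runners ----------------------------------------------------------

def _run_simulate(cfg: PipelineConfig, out: Path) -> dict:
    seed = cfg.seed
    cohort = synthetic.gen_expression_cohort(
        synthetic.CohortSpec(
            n_features=300,
            n_per_group={"normal": 20, "stageI": 15, "stageII": 15, "stageIII": 15, "stageIV": 15},
            n_de=30, lfc_true=1.5, sigma=1.0, seed=seed,
        )
    )
    io.write_expression(cohort, out / "expression.tsv", out / "labels.tsv")
    io.write_study_rows(
        synthetic.gen_meta_studies(
            synthetic.MetaSimSpec(k_studies=12, smd_true=0.7, tau=0.3, seed=seed)
        ),
        out / "meta_studies.csv",
    )
    io.write_diag2x2(
        synthetic.gen_diag_studies(
            synthetic.DiagSimSpec(k_studies=12, mu_logit_sens=0.8, mu_logit_spec=2.2, seed=seed)
        ),
        out / "diag_studies.csv",
    )
    synthetic.gen_survival(200, hr_true=1.5, seed=seed).to_csv(
        out / "survival.csv", index=False
    )
    evidence, edges = synthetic.gen_evidence_and_network(
        200, membership_prob=0.4, edge_prob=0.05, seed=seed
    )
    evidence.rename_axis("gene").reset_index().to_csv(out / "evidence.csv", index=False)
    io.write_edge_list(edges, out / "network_edges.tsv")
    return {"seed": seed, "files": sorted(p.name for p in out.iterdir())}


def _run_screen(cfg: PipelineConfig, out: Path) -> dict:
    paths = cfg.inputs["screen"]
    cohort = io.read_expression(paths["expression"], paths["labels"])
    control = paths.get("control_group") or cohort.metadata.get("control_group") or cohort.groups[0]
    report = screen.stage_stratified_screen(
        cohort,
        control_group=control,
        lfc_thresh=cfg.threshold("lfc_thresh"),
        p_thresh=cfg.threshold("p_thresh"),
        pseudocount=cfg.threshold("pseudocount"),
    )
    for stage_name, feats in report["per_stage"].items():
        de = screen.log2fc_screen(
            cohort, control, stage_name,
            lfc_thresh=cfg.threshold("lfc_thresh"),
            p_thresh=cfg.threshold("p_thresh"),
            pseudocount=cfg.threshold("pseudocount"),
        )
        de.to_csv(out / f"de_{stage_name}.csv", index=False)
    venn = {
        "intersection": sorted(report["intersection"]),
        "set_sizes": report["set_sizes"],
        "venn": {"+".join(k): v for k, v in report.get("venn", {}).items()},
    }
    (out / "venn.json").write_text(json.dumps(venn, indent=2))
    return {"n_common": len(report["intersection"]), "set_sizes": report["set_sizes"]}


def _run_assoc(cfg: PipelineConfig, out: Path) -> dict:
    paths = cfg.inputs["assoc"]
    result: dict = {}
    if "summaries" in paths:
        df = pd.read_csv(paths["summaries"])
        rows = []
        for char, sub in df.groupby("characteristic", sort=False):
            arms = [ArmSummary(int(r.n), float(r.mean), float(r.sd)) for r in sub.itertuples()]
            if len(arms) == 2:
                res = clinical.t_from_summaries(arms[0], arms[1])
            else:
                res = clinical.anova_from_summaries(arms)
            rows.append(
                {"characteristic": char, "kind": res.kind,
                 "statistic": res.statistic, "p": res.p}
            )
        table = pd.DataFrame(rows)
        table.to_csv(out / "associations.csv", index=False)
        result["associations"] = table
    if "raw" in paths:  # sample, value, group; group 'tumor' = case
        raw = pd.read_csv(paths["raw"])
        labels = raw["group"] == paths.get("case_label", "tumor")
        roc = clinical.roc_auc(raw["value"], labels)
        clinical.roc_curve_points(raw["value"], labels).to_csv(out / "roc_curve.csv", index=False)
        result["roc"] = roc
    if "survival" in paths:
        surv = pd.read_csv(paths["survival"])
        if "group" not in surv.columns:
            surv["group"] = clinical.median_split(surv["marker"])
        sr = clinical.km_logrank(surv["time"], surv["event"], surv["group"])
        for lab, curve in sr.curves.items():
            curve.to_csv(out / f"km_{lab}.csv", index=False)
        result["survival"] = {"hr": sr.hr, "ci_low": sr.ci_low, "ci_high": sr.ci_high,
                              "chisq": sr.chisq, "p": sr.p}
    return result


def _run_meta(cfg: PipelineConfig, out: Path) -> dict:
    rows = io.read_study_rows(cfg.inputs["meta"]["studies"])
    flavor = cfg.threshold("flavor")
    per_group = meta.subgroup_pool(rows, by="sample_type", flavor=flavor)
    summary = {}
    for key, res in per_group.items():
        members = [r for r in rows if r.sample_type == key]
        meta.forest_table(members, flavor=flavor).to_csv(out / f"forest_{key}.csv", index=False)
        meta.funnel_table(meta.effects_from_rows(members, flavor=flavor)).to_csv(
            out / f"funnel_{key}.csv", index=False
        )
        summary[key] = {
            "pooled": res.pooled, "se": res.se, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p": res.p, "model": res.model,
            "Q": res.het.Q if res.het else None,
            "p_Q": res.het.p_Q if res.het else None,
            "I2": res.het.I2 if res.het else None,
            "tau2": res.het.tau2 if res.het else None,
            "k": len(members),
        }
    return summary


def _run_diagmeta(cfg: PipelineConfig, out: Path) -> dict:
    studies = io.read_diag2x2(cfg.inputs["diagmeta"]["counts"])
    pooled = diagmeta.pool_accuracy(studies)
    result: dict = {"pooled": pooled}
    if len(studies) >= 3:
        deeks = meta.deeks_test(studies)
        result["deeks"] = {"slope": deeks.slope, "p": deeks.p}
    if len(studies) >= 4:
        sroc = diagmeta.sroc_from_counts(studies)
        sroc.curve.to_csv(out / "sroc_curve.csv", index=False)
        result["sroc_auc"] = sroc.auc
        result["bivariate"] = sroc.params
    return result


def _run_targets(cfg: PipelineConfig, out: Path) -> dict:
    paths = cfg.inputs["targets"]
    evidence = pd.read_csv(paths["evidence"], index_col=0)
    candidates = enrich.vote_count(evidence, min_votes=cfg.threshold("min_votes"))
    if "disease_genes" in paths:
        candidates = enrich.intersect_with_disease_genes(
            candidates, io.read_gene_list(paths["disease_genes"])
        )
    (out / "candidate_genes.txt").write_text("\n".join(sorted(candidates)) + "\n")
    return {"n_candidates": len(candidates)}


def _run_enrich(cfg: PipelineConfig, out: Path) -> dict:
    paths = cfg.inputs["enrich"]
    study = io.read_gene_list(paths["study_genes"])
    collection = io.read_gmt(paths["gene_sets"])
    universe = io.read_gene_list(paths["universe"])
    table = enrich.ora(study, collection, universe, method=paths.get("method", "hypergeometric"))
    table.to_csv(out / "enrichment.csv", index=False)
    return {"n_terms": len(table), "n_significant": int((table["q"] < 0.05).sum()) if len(table) else 0}


def _run_network(cfg: PipelineConfig, out: Path) -> dict:
    paths = cfg.inputs["network"]
    thr = paths.get("score_threshold")
    edges = io.read_edge_list(paths["edges"], score_threshold=float(thr) if thr else None)
    net = network.build_network(edges)
    hubs = network.degree_hubs(net, min_degree=cfg.threshold("min_degree"))
    hubs.to_csv(out / "hubs.csv", index=False)
    comps = network.components(net)
    (out / "components.json").write_text(
        json.dumps([sorted(c) for c in comps], indent=2)
    )
    return {"n_hubs": len(hubs), "n_components": len(comps),
            "hubs": hubs["gene"].tolist()}


_RUNNERS = {
    "simulate": _run_simulate,
    "screen": _run_screen,
    "assoc": _run_assoc,
    "meta": _run_meta,
    "diagmeta": _run_diagmeta,
    "targets": _run_targets,
    "enrich": _run_enrich,
    "network": _run_network,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in canonical order and write summary.json.

    A stage failure stops the pipeline (downstream stages are skipped) and is
    recorded in the summary.  When the ``simulate`` stage is enabled its
    outputs are wired into any later stage whose inputs are not explicitly
    configured.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": 1, "seed": cfg.seed,
                     "thresholds": dict(cfg.thresholds), "stages": {}}
    ordered = [s for s in STAGES if s in cfg.stages]
    if "simulate" in ordered:
        sim = out / "simulated"
        sim.mkdir(exist_ok=True)
        defaults = {
            "screen": {"expression": sim / "expression.tsv", "labels": sim / "labels.tsv",
                       "control_group": "normal"},
            "assoc": {"survival": sim / "survival.csv"},
            "meta": {"studies": sim / "meta_studies.csv"},
            "diagmeta": {"counts": sim / "diag_studies.csv"},
            "targets": {"evidence": sim / "evidence.csv"},
            "network": {"edges": sim / "network_edges.tsv"},
        }
        for stage, paths in defaults.items():
            cfg.inputs.setdefault(stage, {str(k): str(v) for k, v in paths.items()})
    for stage in ordered:
        t0 = time.perf_counter()
        stage_out = out / "simulated" if stage == "simulate" else out
        try:
            log.info("stage %s starting", stage)
            result = _RUNNERS[stage](cfg, stage_out)
            # timings go to the log only, so summary.json is seed-deterministic
            summary["stages"][stage] = {"status": "ok", "result": _jsonable(result)}
            log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
        except Exception as exc:  # fail fast, name the stage
            summary["stages"][stage] = {"status": "failed", "error": f"{stage}: {exc}"}
            log.error("stage %s failed: %s", stage, exc)
            break
    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True))
    return summary
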