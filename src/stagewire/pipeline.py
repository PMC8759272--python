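"""End-to-end orchestration: simulate -> preprocess -> networks -> scoring -> survival -> rewiring.

``run_pipeline`` executes the whole analysis from a single config, writes
every intermediate artifact as plain TSV/JSON so any stage can be rerun in
isolation, and returns a machine-readable report.  Identical config + seed
reproduces the report bit for bit (wall-times go to a separate log file).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import diffnet, preprocess, preservation, rewiring, scoring, survival
from .synthetic import (
    CONDITIONS,
    STAGES,
    SimulationConfig,
    generate_dataset_bundle,
)

logger = logging.getLogger("stagewire")

__all__ = ["PipelineConfig", "run_pipeline", "load_inputs", "write_bundle"]


@dataclass
class PipelineConfig:
    """Inputs (real files or a simulation block) plus per-stage parameters."""

    counts_path: str | None = None
    design_path: str | None = None
    annotations_path: str | None = None
    simulation: SimulationConfig | None = None
    beta: int = 6
    use_tom: bool = True
    merge_height: float = 0.2
    min_module_size: int = 10
    n_perm: int = 100
    cpm_threshold: float = 0.5
    connectivity_threshold: float = 0.1
    rewiring_cutoff: float = 0.7
    vif_threshold: float = 10.0
    seed: int = 0
    out_dir: str = "stagewire_out"

    def validate(self) -> None:
        has_files = self.counts_path is not None
        if not has_files and self.simulation is None:
            raise ValueError("config needs input paths or a simulation block")
        if has_files and (self.design_path is None or self.annotations_path is None):
            raise ValueError("real inputs require counts, design, and annotations paths")
        if has_files:
            for p in (self.counts_path, self.design_path, self.annotations_path):
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
        if self.simulation is not None:
            self.simulation.validate()


def load_inputs(config: PipelineConfig) -> dict:
    """Load the three TSV inputs or generate the synthetic bundle."""
    if config.counts_path is not None:
        counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
        design = pd.read_csv(config.design_path, sep="\t", index_col=0)
        annotations = pd.read_csv(config.annotations_path, sep="\t", index_col=0).astype(bool)
        return {"counts": counts, "design": design, "annotations": annotations, "truth": None}
    return generate_dataset_bundle(config.simulation)


def write_bundle(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle["counts"].to_csv(out / "counts.tsv", sep="\t")
    bundle["design"].to_csv(out / "design.tsv", sep="\t")
    bundle["annotations"].to_csv(out / "annotations.tsv", sep="\t")
    if bundle.get("truth"):
        truth = [
            {
                "gene_ids": list(m.gene_ids),
                "intra_correlation_by_condition": dict(m.intra_correlation_by_condition),
                "mean_log_expression": m.mean_log_expression,
            }
            for m in bundle["truth"]
        ]
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def _config_hash(config: PipelineConfig) -> str:
    d = asdict(config)
    d.pop("out_dir", None)  # hash covers scientific inputs only
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Run every stage in order and return the report bundle.

    With ``dry_run`` the config is validated and nothing is computed.
    """
    config.validate()
    if dry_run:
        return {"dry_run": True, "config_hash": _config_hash(config)}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {
        "provenance": {"config_hash": _config_hash(config), "seed": config.seed}
    }

    t0 = time.perf_counter()
    bundle = load_inputs(config)
    write_bundle(bundle, out)
    counts, design, annotations = bundle["counts"], bundle["design"], bundle["annotations"]
    timings["inputs"] = time.perf_counter() - t0

    # ---- preprocessing -------------------------------------------------
    t0 = time.perf_counter()
    expr, filt_report = preprocess.preprocess_counts(
        counts,
        cpm_threshold=config.cpm_threshold,
        connectivity_threshold=config.connectivity_threshold,
    )
    expr.to_csv(out / "expr.tsv", sep="\t")
    (out / "filter-report.json").write_text(json.dumps(filt_report, indent=1, sort_keys=True))
    report["preprocess"] = filt_report
    timings["preprocess"] = time.perf_counter() - t0

    # ---- per-stage differential networks, modules, preservation, scores
    report["stages"] = {}
    selected_genes: dict[str, list[str]] = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        diff, net_stage, net_rest = diffnet.stage_differential(
            expr, design, stage, beta=config.beta, use_tom=config.use_tom
        )
        partition = diffnet.detect_modules(
            diff, merge_height=config.merge_height, min_module_size=config.min_module_size
        )
        partition.rename("module").to_csv(out / f"modules_{stage}.tsv", sep="\t")
        pres = preservation.preservation_stats(
            partition, refNet=net_rest, testNet=net_stage,
            n_perm=config.n_perm, seed=config.seed,
        )
        p_perm = preservation.nonrandomness_test(
            partition, net_rest, net_stage, pres,
            n_perm=max(config.n_perm, 20), seed=config.seed,
        )
        scores = scoring.score_modules(partition, pres, annotations, universe=expr.index)
        pres_out = pres.table.copy()
        pres_out["class"] = pres_out["Zsummary"].map(preservation.classify_preservation)
        pres_out["p_perm"] = p_perm
        pres_out.to_csv(out / f"preservation_{stage}.tsv", sep="\t")
        scores.to_csv(out / f"scores_{stage}.tsv", sep="\t")
        top = scores.index[scores["selected"]][0]
        selected_genes[stage] = sorted(partition.index[partition == top])
        report["stages"][stage] = {
            "n_modules": int((scores.shape[0])),
            "selected_module": str(top),
            "selected_size": int(scores.loc[top, "size"]),
            "selected_bcss": round(float(scores.loc[top, "bcss"]), 6),
            "color_aliases": diffnet.color_alias_table(partition),
            "scores": json.loads(scores.round(6).to_json(orient="index")),
            "preservation": json.loads(pres_out.round(6).to_json(orient="index")),
        }
        timings[f"stage_{stage}"] = time.perf_counter() - t0

    # ---- survival ------------------------------------------------------
    t0 = time.perf_counter()
    tumour = design.index[design["condition"] != "normal"]
    surv = design.loc[tumour, ["time", "event"]].dropna()
    candidate_genes = sorted({g for genes in selected_genes.values() for g in genes})
    prog_rows = {}
    for g in candidate_genes:
        res = survival.km_logrank(expr.loc[g, surv.index], surv)
        trend = survival.classify_trends(expr.loc[g], design)
        prog_rows[g] = {
            "logrank_p": res["p"],
            "prognostic": res["prognostic"],
            "trend": trend.trend,
            "kw_p": trend.kw_p,
            "outset_t_p": trend.outset_t_p,
        }
    prognostic = pd.DataFrame(prog_rows).T
    prognostic.index.name = "gene"
    prognostic.to_csv(out / "prognostic.tsv", sep="\t")
    prog_genes = sorted(prognostic.index[prognostic["prognostic"].astype(bool)])
    report["survival"] = {
        "n_candidate_genes": len(candidate_genes),
        "n_prognostic": len(prog_genes),
        "trend_counts": prognostic.loc[prog_genes, "trend"].value_counts().to_dict()
        if prog_genes
        else {},
    }

    risk_model = None
    strata = None
    if len(prog_genes) >= 2 and surv["event"].sum() >= 2:
        covs = expr.loc[prog_genes, surv.index].T
        kept = survival.vif_select(covs, threshold=config.vif_threshold)
        risk_model = survival.fit_cox(kept, expr, surv)
        strata = survival.stratify_risk(risk_model, expr[surv.index])
        strata.rename("stratum").to_csv(out / "strata.tsv", sep="\t")
        strata_p = survival.strata_logrank(strata, surv)
        model_json = {
            "covariates": risk_model.covariates,
            "coefficients": {k: round(float(v), 6) for k, v in risk_model.coefficients.items()},
            "hazard_ratios": {k: round(float(v), 6) for k, v in risk_model.hazard_ratios.items()},
            "lr_test_p": float(risk_model.lr_test_p),
            "c_index": round(float(risk_model.c_index), 6),
            "strata_thresholds": [round(t, 6) for t in risk_model.strata_thresholds],
            "strata_logrank_p": float(strata_p),
            "strata_sizes": strata.value_counts().to_dict(),
        }
        (out / "riskmodel.json").write_text(json.dumps(model_json, indent=1, sort_keys=True))
        report["risk_model"] = model_json

    outset = sorted(
        prognostic.index[(prognostic["trend"] == "outset-cancer")]
    )
    if len(outset) >= 1:
        mask = design["condition"].isin(["normal", "I"])
        labels = design.loc[mask, "condition"]
        try:
            report["svm_validation"] = survival.svm_validate(
                expr.loc[outset, labels.index], labels, seed=config.seed
            )
        except ValueError as exc:
            report["svm_validation"] = {"skipped": str(exc)}
    timings["survival"] = time.perf_counter() - t0

    # ---- rewiring ------------------------------------------------------
    t0 = time.perf_counter()
    report["rewiring"] = {}
    hub_stages: dict[str, list[str]] = {}
    rewired_count: dict[str, int] = {}
    if len(prog_genes) >= 2:
        nets = {}
        for cond in CONDITIONS:
            samples = design.index[design["condition"] == cond]
            nets[cond] = rewiring.condition_network(
                expr, samples, prog_genes, condition=cond, cutoff=config.rewiring_cutoff
            )
        for earlier, later in rewiring.TRANSITIONS:
            change = rewiring.classify_rewiring(nets[earlier], nets[later])
            tag = f"{earlier}-{later}"
            change.edges.to_csv(out / f"rewiring_{tag}.tsv", sep="\t", index=False)
            report["rewiring"][tag] = {
                "gain": int((change.edges["class"] == "gain").sum()),
                "loss": int((change.edges["class"] == "loss").sum()),
                "reversed": int((change.edges["class"] == "reversed").sum()),
                "hubs": change.hubs,
            }
            for h in change.hubs:
                hub_stages.setdefault(h, []).append(tag)
            for g in set(change.edges["gene_a"]) | set(change.edges["gene_b"]):
                rewired_count[g] = rewired_count.get(g, 0) + 1

        idx = pd.DataFrame(
            {
                "prognostic": prognostic["prognostic"].astype(bool),
                "trend": prognostic["trend"].isin(["ascending", "descending"]),
                "hub": [g in hub_stages for g in prognostic.index],
                "novel": [
                    not bool(annotations.loc[g, "disease_associated"])
                    if g in annotations.index
                    else True
                    for g in prognostic.index
                ],
                "rewired": [rewired_count.get(g, 0) > 0 for g in prognostic.index],
                "n_rewired_transitions": [rewired_count.get(g, 0) for g in prognostic.index],
            },
            index=prognostic.index,
        )
        ranking = rewiring.rank_progression_biomarkers(idx)
        ranking.to_csv(out / "biomarker_ranking.tsv", sep="\t")
        report["top_biomarkers"] = ranking.index[:5].tolist()
    timings["rewiring"] = time.perf_counter() - t0

    report_text = json.dumps(report, indent=1, sort_keys=True)
    (out / "report.json").write_text(report_text)
    (out / "pipeline.log").write_text(
        "\n".join(f"{k}\t{v:.3f}s" for k, v in timings.items()) + "\n"
    )
    logger.info("pipeline complete: %s", out / "report.json")
    return report
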