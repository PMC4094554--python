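"""End-to-end pipeline orchestration with provenance capture.

``run_pipeline`` executes simulate (optional) -> infer -> fdr -> scan-are ->
filter -> network -> validate from a single YAML-style config dict, writing
per-stage outputs plus a manifest JSON recording inputs, per-stage seeds,
parameter values and output file hashes.  All randomness is funnelled
through one seeded generator per stage, with stage seeds derived from the
master seed by stage name, so a rerun with the same config is byte-identical
(verifiable from the manifest hashes).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from .gsea import rank_genes, validate_inference
from .metrics import DependencyResult, score_regulator
from .mic import MicParams
from .motif import scan_fasta
from .network import TargetFilterConfig, build_network, filter_targets
from .significance import build_null, q_values
from .synthetic import (
    SyntheticConfig,
    UtrSpec,
    gen_decay_timecourse,
    gen_expression,
    gen_qpcr_table,
    gen_utr_fasta,
    gen_validation_geneset,
)

__all__ = ["run_pipeline", "load_config", "stage_seed", "demo_config", "PipelineError"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "infer", "fdr", "scan-are", "filter", "network", "validate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed by stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def demo_config(seed: int = 1) -> dict:
    """The bundled demo scenario: 500 genes x 200 samples with 5 planted
    inversely-correlated ARE-positive targets at noise_sd 0.5, thresholded
    at q <= 0.01 against a 10^4-permutation MIC null."""
    return {
        "seed": seed,
        "regulators": ["ZFP36L1"],
        "n_perm": 10_000,
        "q_threshold": 0.01,
        "min_are_copies": 2,
        "require_negative_lr": True,
        "annotation_terms": ["apoptosis"],
        "simulate": {
            "n_genes": 500,
            "n_samples": 200,
            "n_linear_targets": 5,
            "n_nonlinear_targets": 0,
            "noise_sd": 0.5,
            "linear_slope": -2.0,
            "utr_length": 300,
            "utr_target_copies": 2,
            "n_background_with_are": 10,
            "n_background_annotated": 50,
            "validation": {"n_true_in_set": 5, "n_decoys": 20},
        },
        "gsea": {"weight": 1.0, "n_perm": 200},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate_config(cfg: dict) -> None:
    regulators = cfg.get("regulators")
    if not regulators:
        raise ValueError("config must list at least one regulator under 'regulators'")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValueError("config needs a 'simulate' section or an 'inputs' section")
    if "seed" not in cfg:
        raise ValueError("config must set a master 'seed'")
    if "inputs" in cfg:
        for key, p in cfg["inputs"].items():
            if not Path(p).exists():
                raise ValueError(f"input path for {key!r} does not exist: {p}")


def _mic_params(cfg: dict) -> MicParams:
    m = cfg.get("mic", {})
    return MicParams(
        alpha=m.get("alpha", 0.6), clump_factor=m.get("clump_factor", 15)
    )


def _stage_simulate(cfg: dict, outdir: Path) -> dict[str, Path]:
    sim = cfg["simulate"]
    seed = stage_seed(cfg["seed"], "simulate")
    syn = SyntheticConfig(
        n_genes=sim.get("n_genes", 500),
        n_samples=sim.get("n_samples", 200),
        regulator_id=cfg["regulators"][0],
        n_linear_targets=sim.get("n_linear_targets", 5),
        n_nonlinear_targets=sim.get("n_nonlinear_targets", 0),
        noise_sd=sim.get("noise_sd", 0.5),
        linear_slope=sim.get("linear_slope", -2.0),
        nonlinear_form=sim.get("nonlinear_form", "parabola"),
        seed=seed,
    )
    matrix, truth = gen_expression(syn)
    planted = truth["linear"] + truth["nonlinear"]

    utr_len = sim.get("utr_length", 300)
    target_copies = sim.get("utr_target_copies", 2)
    n_bg_are = sim.get("n_background_with_are", 10)
    specs = []
    bg = [g for g in matrix.index if g.startswith("BG_")]
    for g in planted:
        specs.append(UtrSpec(gene=g, length=utr_len, planted_copies=target_copies))
    for i, g in enumerate(bg):
        specs.append(
            UtrSpec(gene=g, length=utr_len, planted_copies=target_copies if i < n_bg_are else 0)
        )
    sequences, motif_truth = gen_utr_fasta(specs, seed=seed + 1)

    val = sim.get("validation", {})
    geneset = gen_validation_geneset(
        planted,
        n_true_in_set=val.get("n_true_in_set", len(planted)),
        n_decoys=val.get("n_decoys", 20),
        universe=[g for g in matrix.index if g != syn.regulator_id],
        seed=seed + 2,
        name="knockout_upregulated",
        description="synthetic knockout-derived validation set",
    )

    term = sim.get("annotation_term", "apoptosis")
    annotated = set(planted) | set(bg[: sim.get("n_background_annotated", 50)])
    annotations = {g: {term} for g in sorted(annotated)}

    decay = pd.concat(
        [
            gen_decay_timecourse(
                half_life=sim.get("decay_half_life", 2.6),
                noise_cv=sim.get("decay_noise_cv", 0.1),
                seed=seed + 3,
                condition="control",
            ),
            gen_decay_timecourse(
                half_life=sim.get("decay_half_life_knockdown", 5.2),
                noise_cv=sim.get("decay_noise_cv", 0.1),
                seed=seed + 4,
                condition="knockdown",
            ),
        ],
        ignore_index=True,
    )
    qpcr = gen_qpcr_table(sim.get("qpcr_ddct", {"BCL2": -1.0}), seed=seed + 5)

    outputs = {
        "expression": outdir / "expression.tsv",
        "utrs": outdir / "utrs.fasta",
        "truth_targets": outdir / "truth_targets.tsv",
        "truth_motifs": outdir / "truth_motifs.tsv",
        "genesets": outdir / "genesets.gmt",
        "decay": outdir / "decay.tsv",
        "qpcr": outdir / "qpcr.tsv",
        "provenance": outdir / "simulate_provenance.json",
    }
    rio.write_expression_tsv(matrix, outputs["expression"])
    rio.write_fasta(sequences, outputs["utrs"])
    pd.DataFrame(
        [{"gene": g, "kind": kind} for kind in ("linear", "nonlinear") for g in truth[kind]]
    ).to_csv(outputs["truth_targets"], sep="\t", index=False)
    motif_truth.to_csv(outputs["truth_motifs"], sep="\t", index=False)
    rio.write_gmt([geneset], outputs["genesets"])
    decay.to_csv(outputs["decay"], sep="\t", index=False, float_format="%.10g")
    qpcr.to_csv(outputs["qpcr"], sep="\t", index=False, float_format="%.10g")
    rio.write_annotations_tsv(annotations, outdir / "annotations.tsv")
    outputs["annotations"] = outdir / "annotations.tsv"
    outputs["provenance"].write_text(
        json.dumps(
            {"stage_seed": seed, "generator_seeds": {
                "expression": seed, "utrs": seed + 1, "geneset": seed + 2,
                "decay_control": seed + 3, "decay_knockdown": seed + 4, "qpcr": seed + 5,
            }},
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    return outputs


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    _validate_config(config)
    outdir = Path(outdir or config.get("outdir", "are_regnet_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config, "stages": []}
    mic_params = _mic_params(config)
    threshold_metric = config.get("threshold_metric", "mic")
    regulators = list(config["regulators"])

    def record(stage: str, params: dict, outputs: dict[str, Path]) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "params": params,
                "outputs": {k: _sha256(p) for k, p in sorted(outputs.items())},
            }
        )

    def run_stage(stage: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage name added, then re-raised
            raise PipelineError(stage, exc) from exc
        logger.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
        return result

    # -- simulate (optional) or load inputs
    if "simulate" in config:
        paths = run_stage("simulate", _stage_simulate, config, outdir)
        record("simulate", {"seed": stage_seed(config["seed"], "simulate")}, paths)
    else:
        paths = {k: Path(v) for k, v in config["inputs"].items()}
    matrix = rio.read_expression_tsv(paths["expression"])
    for reg in regulators:
        if reg not in matrix.index:
            raise PipelineError(
                "infer", KeyError(f"regulator {reg!r} not present in expression matrix")
            )

    # -- infer
    deps: dict[str, DependencyResult] = {}
    infer_out: dict[str, Path] = {}

    def _infer():
        for reg in regulators:
            deps[reg] = score_regulator(matrix, reg, mic_params=mic_params)
            p = outdir / f"scores_{reg}.tsv"
            deps[reg].scores.to_csv(p, sep="\t", float_format="%.10g")
            infer_out[f"scores_{reg}"] = p

    run_stage("infer", _infer)
    record("infer", {"mic": {"alpha": mic_params.alpha, "c": mic_params.clump_factor}}, infer_out)

    # -- fdr
    n_perm = config.get("n_perm", 10_000)
    fdr_seed = stage_seed(config["seed"], "fdr")
    fdr_out: dict[str, Path] = {}

    def _fdr():
        for reg in regulators:
            null = build_null(
                matrix, reg, metric=threshold_metric, n_perm=n_perm,
                seed=fdr_seed, mic_params=mic_params,
            )
            deps[reg].scores["q"] = q_values(deps[reg].scores[threshold_metric], null)
            p = outdir / f"qvalues_{reg}.tsv"
            deps[reg].scores.to_csv(p, sep="\t", float_format="%.10g")
            fdr_out[f"qvalues_{reg}"] = p

    run_stage("fdr", _fdr)
    record("fdr", {"metric": threshold_metric, "n_perm": n_perm, "seed": fdr_seed}, fdr_out)

    # -- scan-are
    def _scan():
        sequences = rio.read_fasta(paths["utrs"])
        hitsets = scan_fasta(sequences)
        rows = [
            {"gene": g, "start": s, "match": m, "total_copies": hs.copy_count}
            for g, hs in sorted(hitsets.items())
            for s, m in hs.hits
        ]
        p = outdir / "are_hits.tsv"
        pd.DataFrame(rows, columns=["gene", "start", "match", "total_copies"]).to_csv(
            p, sep="\t", index=False
        )
        return hitsets, {"are_hits": p}

    hitsets, scan_out = run_stage("scan-are", _scan)
    record("scan-are", {"min_copies": config.get("min_are_copies", 2)}, scan_out)

    # -- filter
    fcfg = TargetFilterConfig(
        q_threshold=config.get("q_threshold", 0.01),
        min_are_copies=config.get("min_are_copies", 2),
        require_negative_lr=config.get("require_negative_lr", True),
        annotation_terms=frozenset(config.get("annotation_terms", [])),
    )
    annotations = (
        rio.read_annotations_tsv(paths["annotations"]) if "annotations" in paths else {}
    )
    filtered: dict[str, pd.DataFrame] = {}
    filter_out: dict[str, Path] = {}

    def _filter():
        for reg in regulators:
            filtered[reg] = filter_targets(deps[reg], hitsets, annotations, fcfg)
            p = outdir / f"targets_{reg}.tsv"
            filtered[reg].to_csv(p, sep="\t", float_format="%.10g")
            filter_out[f"targets_{reg}"] = p

    run_stage("filter", _filter)
    record(
        "filter",
        {
            "q_threshold": fcfg.q_threshold,
            "min_are_copies": fcfg.min_are_copies,
            "require_negative_lr": fcfg.require_negative_lr,
            "annotation_terms": sorted(fcfg.annotation_terms),
        },
        filter_out,
    )

    # -- network
    def _network():
        net = build_network(filtered)
        p = outdir / "network.sif"
        rio.write_sif(net, p)
        return {"network": p}

    net_out = run_stage("network", _network)
    record("network", {"n_regulators": len(regulators)}, net_out)

    # -- validate
    gsea_cfg = config.get("gsea", {})
    val_seed = stage_seed(config["seed"], "validate")

    def _validate():
        genesets = rio.read_gmt(paths["genesets"])
        scores = {
            metric: deps[regulators[0]].scores[col]
            for metric, col in (("mic", "mic"), ("mi", "mi"), ("lr", "lr_r"))
            if col in deps[regulators[0]].scores.columns
        }
        if "lr" in scores:
            scores["lr"] = scores["lr"].abs()
        table = validate_inference(
            scores,
            genesets,
            weight=gsea_cfg.get("weight", 1.0),
            n_perm=gsea_cfg.get("n_perm", 1000),
            seed=val_seed,
        )
        p = outdir / "enrichment.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.10g")
        rnk = outdir / f"ranked_{regulators[0]}_mic.rnk"
        rio.write_rnk(rank_genes(deps[regulators[0]].scores["mic"]), rnk)
        return {"enrichment": p, "ranked_mic": rnk}

    val_out = run_stage("validate", _validate)
    record("validate", {"seed": val_seed, **gsea_cfg}, val_out)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
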