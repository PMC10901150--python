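"""End-to-end pipeline orchestration with per-stage artifacts and a manifest.

``run_pipeline`` executes the enabled stages in order — simulate, qc,
network, preserve, trait, rnai — each stage reading the previous stage's
outputs from the run directory (or external inputs named in the config).
The manifest records the package version, full parameter set, seed, input
checksums and per-stage record counts; reruns with an identical config are
bit-identical apart from the timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import RunConfig
from .containers import LogFCMatrix, StudyDesign
from .design import generate_design
from .network import (
    NetworkParams,
    adjacency,
    build_module_set,
    cluster_modules,
    merge_modules,
    pick_soft_power,
    tom_similarity,
)
from .preservation import preservation_stats
from .qc import aggregate_degs, call_degs, filter_good_genes, qc_pipeline
from .rnai import classify_hits, log2fc_vs_control, zscore_cell_death
from .simulate import (
    TraitSpec,
    generate_cell_death,
    generate_counts,
    generate_reference_logfc,
    generate_rnai_dataset,
    make_module_spec,
)
from .traits import (
    HitCriteria,
    align_conditions,
    correlate_modules_death,
    select_candidate_genes,
    select_hit_modules,
)

log = logging.getLogger("toxmodnet")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {
        "package": "toxmodnet",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "input_checksums": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for stage, named in (config.inputs or {}).items():
        for name, path in named.items():
            p = Path(path)
            if p.exists():
                manifest["input_checksums"][f"{stage}:{name}"] = _sha256(p)

    state: dict = {}
    try:
        for stage in ("simulate", "qc", "network", "preserve", "trait", "rnai"):
            if stage not in config.stages:
                continue
            log.info("stage %s", stage)
            info = _STAGE_FUNCS[stage](config, out, state)
            manifest["stages"][stage] = info
    except Exception as exc:  # partial outputs retained with a failure marker
        manifest["failed"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


# -- stages ----------------------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> dict:
    sc = config.simulate
    seed = config.seed
    d = out / "simulate"
    d.mkdir(exist_ok=True)
    design = generate_design(
        sc.n_compounds_per_category,
        sc.n_dose_levels,
        tuple(sc.time_points),
        sc.n_replicates,
        sc.n_batches,
        seed=seed,
    )
    spec = make_module_spec(
        design,
        n_genes=sc.n_genes,
        module_sizes=tuple(sc.module_sizes),
        seed=seed + 1,
        broad_response_modules=tuple(sc.broad_response_modules),
        narrow_response_max=3,
    )
    counts = generate_counts(design, spec, qc_defect_rate=sc.qc_defect_rate, seed=seed + 2)
    ref = generate_reference_logfc(
        spec, set(sc.preserved_modules), sc.n_reference_conditions, seed=seed + 3
    )
    trait_spec = TraitSpec(linked_modules={int(k): float(v) for k, v in sc.linked_modules.items()})
    trait = generate_cell_death(design, counts.truth["activation"], trait_spec, seed=seed + 4)
    targets = [f"T{i:02d}" for i in range(1, sc.rnai_n_targets + 1)]
    rnai = generate_rnai_dataset(
        targets,
        set(targets[: sc.rnai_n_protective]),
        set(targets[sc.rnai_n_protective : sc.rnai_n_protective + sc.rnai_n_enhancing]),
        effect_size=sc.rnai_effect_size,
        seed=seed + 5,
    )
    design.to_tsv(d / "metadata.tsv")
    io.write_counts_tsv(counts, d / "counts.tsv")
    io.write_logfc(ref, d / "reference_logfc.tsv", d / "reference_padj.tsv")
    io.write_table(trait, d / "trait.tsv")
    io.write_table(rnai, d / "rnai.tsv")
    io.write_truth_json(
        {
            "assignment": counts.truth["assignment"],
            "corrupted": counts.truth["corrupted"],
            "preserved_modules": sorted(sc.preserved_modules),
            "linked_modules": {str(k): v for k, v in sc.linked_modules.items()},
            "rnai_protective": targets[: sc.rnai_n_protective],
            "rnai_enhancing": targets[sc.rnai_n_protective : sc.rnai_n_protective + sc.rnai_n_enhancing],
        },
        d / "truth.json",
    )
    state.update(design=design, counts=counts, ref_logfc=ref, trait=trait, rnai=rnai, spec=spec)
    return {"n_samples": len(counts.sample_ids), "n_genes": len(counts.probe_ids)}


def _stage_qc(config: RunConfig, out: Path, state: dict) -> dict:
    qcc = config.qc
    d = out / "qc"
    d.mkdir(exist_ok=True)
    if "counts" not in state:
        inputs = (config.inputs or {}).get("qc", {})
        design = StudyDesign.from_tsv(inputs["metadata"])
        state["counts"] = io.read_counts_tsv(inputs["counts"], design)
        state["design"] = design
    counts = state["counts"]
    logfc, report = qc_pipeline(
        counts,
        min_library_size=qcc.min_library_size,
        min_replicate_r=qcc.min_replicate_r,
        pseudocount=qcc.pseudocount,
        n_top_variable=qcc.n_top_variable,
        leave_one_out=qcc.leave_one_out,
    )
    logfc, removed_genes = filter_good_genes(logfc, qcc.max_missing_frac, qcc.min_variance)
    degs = call_degs(logfc, qcc.deg_padj_max, qcc.deg_min_abs_lfc)
    io.write_logfc(logfc, d / "logfc.tsv", d / "padj.tsv")
    io.write_table(aggregate_degs(degs), d / "deg_summary.tsv")
    qc_json = {
        "removed_library_size": report["removed_library_size"]["sample_id"].tolist(),
        "removed_replicate_correlation": report["replicate_correlation"]
        .loc[lambda df: df["removed"], "sample_id"]
        .tolist(),
        "removed_genes": removed_genes,
        "n_samples_in": report["n_samples_in"],
        "n_samples_out": report["n_samples_out"],
    }
    (d / "qc_report.json").write_text(json.dumps(qc_json, indent=1))
    state["logfc"] = logfc
    return {
        "n_conditions": len(logfc.conditions),
        "n_genes": len(logfc.genes),
        "n_removed_samples": len(qc_json["removed_library_size"])
        + len(qc_json["removed_replicate_correlation"]),
    }


def _stage_network(config: RunConfig, out: Path, state: dict) -> dict:
    nc = config.network
    d = out / "network"
    d.mkdir(exist_ok=True)
    if "logfc" not in state:
        inputs = (config.inputs or {}).get("network", {})
        state["logfc"] = io.read_logfc(inputs["logfc"], inputs["padj"])
    logfc = state["logfc"]
    if nc.beta is None:
        fit = pick_soft_power(logfc, target_r2=nc.target_r2)
        beta = fit.beta
        io.write_table(fit.table, d / "soft_power_fit.tsv")
    else:
        beta = nc.beta
    adj = adjacency(logfc, beta)
    tom = tom_similarity(adj)
    params = NetworkParams(
        beta=beta,
        min_module_size=nc.min_module_size,
        merge_threshold=nc.merge_threshold,
        cut_height=nc.cut_height,
        cut_mode=nc.cut_mode,
    )
    assignment = cluster_modules(tom, params)
    assignment = merge_modules(logfc, assignment, nc.merge_threshold)
    gene_sets = io.read_gmt(nc.gmt) if nc.gmt else None
    module_set = build_module_set(logfc, assignment, gene_sets)
    io.write_modules(assignment, d / "modules.tsv", module_set.coreg, module_set.hub)
    io.write_eigengenes(module_set.eigengenes, d / "eigengenes.tsv")
    if module_set.annotation:
        io.write_table(
            pd.DataFrame(
                [
                    {"module": m, "gene_set": a[0] if a else "", "padj": a[1] if a else np.nan}
                    for m, a in module_set.annotation.items()
                ]
            ),
            d / "annotation.tsv",
        )
    state["module_set"] = module_set
    state["beta"] = beta
    return {"beta": beta, "n_modules": len(module_set.module_ids)}


def _stage_preserve(config: RunConfig, out: Path, state: dict) -> dict:
    pc = config.preserve
    d = out / "preserve"
    d.mkdir(exist_ok=True)
    if "ref_logfc" not in state:
        inputs = (config.inputs or {}).get("preserve", {})
        state["ref_logfc"] = io.read_logfc(inputs["test_logfc"], inputs["test_padj"])
    result = preservation_stats(
        state["logfc"],
        state["module_set"].assignment,
        state["ref_logfc"],
        beta=pc.beta,
        n_perm=pc.n_perm,
        seed=config.seed,
        min_shared_genes=pc.min_shared_genes,
    )
    io.write_table(result.stats, d / "preservation.tsv")
    (d / "params.json").write_text(
        json.dumps({"n_perm": pc.n_perm, "beta": pc.beta, "seed": config.seed,
                    "skipped": result.skipped}, indent=1)
    )
    state["preservation"] = result
    counts = result.stats["preservation_class"].value_counts().to_dict() if len(result.stats) else {}
    return {"n_modules_evaluated": len(result.stats), "classes": counts}


def _stage_trait(config: RunConfig, out: Path, state: dict) -> dict:
    tc = config.trait
    d = out / "trait"
    d.mkdir(exist_ok=True)
    design = state["design"] if "design" in state else state["counts"].design
    paired, unmatched = align_conditions(state["module_set"].eigengenes, state["trait"], design)
    paired = paired[paired["death_time_h"] == tc.death_time_h]
    records = correlate_modules_death(paired, tc.min_points, tc.padj_family)
    criteria = HitCriteria(tc.padj_max, tc.min_r, tc.min_eg, tc.min_dili_compounds)
    result = select_hit_modules(records, paired, design.category_of(), criteria)
    all_hits = set().union(*result.hits.values()) if result.hits else set()
    if all_hits:
        genes = select_candidate_genes(
            all_hits, state["module_set"].assignment, state["logfc"], tc.gene_padj_max,
            tc.gene_min_lfc,
        )
    else:
        genes = pd.DataFrame(columns=["gene", "module", "max_log2fc", "min_padj",
                                      "n_passing_conditions"])
    io.write_table(records, d / "correlations.tsv")
    io.write_table(result.support, d / "hit_modules.tsv")
    io.write_table(genes, d / "candidate_genes.tsv")
    state["trait_result"] = result
    return {"n_records": len(records), "n_hit_modules": len(all_hits),
            "n_candidate_genes": len(genes)}


def _stage_rnai(config: RunConfig, out: Path, state: dict) -> dict:
    rc = config.rnai
    d = out / "rnai"
    d.mkdir(exist_ok=True)
    if "rnai" not in state:
        inputs = (config.inputs or {}).get("rnai", {})
        state["rnai"] = io.read_rnai_table(inputs["table"])
    table = state["rnai"]
    z = zscore_cell_death(table)
    lfc = log2fc_vs_control(table, eps=rc.eps)
    hits = classify_hits(z, z_min=rc.z_min, k=rc.k, mode=rc.mode)
    io.write_table(z, d / "zscores.tsv")
    io.write_table(lfc, d / "log2fc_vs_control.tsv")
    io.write_table(hits, d / "hit_classes.tsv")
    counts = hits["class"].value_counts().to_dict()
    return {"n_targets": hits.shape[0], "classes": counts}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "network": _stage_network,
    "preserve": _stage_preserve,
    "trait": _stage_trait,
    "rnai": _stage_rnai,
}
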