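"""End-to-end orchestration: QC -> structure -> method sweep -> evaluation ->
QTL benchmark -> composite ranking -> final fixed-set core collection."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import qtl as qb
from . import selection as sel
from . import structure as st
from .genotypes import (
    GenotypeMatrix,
    ValidationError,
    filter_maf,
    filter_missingness,
    impute_mode,
    kinship_vanraden,
    ld_prune,
    read_genotypes,
    rogers_distance,
)

logger = logging.getLogger(__name__)

# canonical method vocabulary: label -> (optimizer, [(criterion, weight), ...])
METHOD_TABLE: dict[str, tuple[str, list[tuple[str, float]]]] = {
    "ANE": ("random_descent", [("ANE", 1.0)]),
    "ENE": ("random_descent", [("ENE", 1.0)]),
    "HE": ("local_search", [("HE", 1.0)]),
    "SH": ("local_search", [("SH", 1.0)]),
    "CV": ("local_search", [("CV", 1.0)]),
    "CDmean": ("hill_climb", [("CDmean", 1.0)]),
    "Avg_GRM": ("genetic", [("AvgGRM", 1.0)]),
    "D-opt": ("genetic", [("Dopt", 1.0)]),
    "D-opt+Avg_GRM": ("genetic", [("Dopt", 0.5), ("AvgGRM", 0.5)]),
    "ANE_ENE": ("local_search", [("ANE", 0.5), ("ENE", 0.5)]),
    "ANE_HE": ("local_search", [("ANE", 0.5), ("HE", 0.5)]),
    "ANE_SH": ("local_search", [("ANE", 0.5), ("SH", 0.5)]),
    "ANE_CV": ("local_search", [("ANE", 0.5), ("CV", 0.5)]),
    "ENE_HE": ("local_search", [("ENE", 0.5), ("HE", 0.5)]),
    "ENE_SH": ("local_search", [("ENE", 0.5), ("SH", 0.5)]),
    "ENE_CV": ("local_search", [("ENE", 0.5), ("CV", 0.5)]),
    "HE_SH": ("local_search", [("HE", 0.5), ("SH", 0.5)]),
    "SH_CV": ("local_search", [("SH", 0.5), ("CV", 0.5)]),
    "HE_CV": ("local_search", [("HE", 0.5), ("CV", 0.5)]),
    "ANE_SH_CV": ("local_search",
                  [("ANE", 1 / 3), ("SH", 1 / 3), ("CV", 1 / 3)]),
}


@dataclass
class PipelineConfig:
    genotype_path: str | None = None
    genotype_format: str = "matrix_tsv"
    trait_path: str | None = None
    fixed_path: str | None = None
    methods: list[str] = field(default_factory=lambda: ["SH_CV"])
    size: int = 350
    replicates: int = 10
    seed: int = 1
    outdir: str = "run"
    # QC
    max_missing: float = 0.5
    min_maf: float = 0.01
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.4
    # structure
    tw_alpha: float = 0.05
    k_max: int = 10
    force_k: int | None = None
    # selection budgets
    iterations: int | None = None
    # qtl stage
    run_qtl: bool = True
    per_chrom_traits: int = 2
    qtl_per_trait: int = 31
    h2_qtl: float = 0.4
    h2_poly: float = 0.2
    qtl_chromosomes: list | None = None

    def validate(self) -> None:
        unknown = [m for m in self.methods if m not in METHOD_TABLE]
        if unknown:
            raise ValidationError(f"unknown method labels: {unknown}; "
                                  f"choose from {sorted(METHOD_TABLE)}")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _log_stage(name: str, t0: float) -> None:
    logger.info("stage %-12s done in %.1fs", name, time.time() - t0)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def qc_stage(g: GenotypeMatrix, cfg: PipelineConfig) -> GenotypeMatrix:
    t0 = time.time()
    g = filter_missingness(g, cfg.max_missing)
    g = impute_mode(g)
    g = filter_maf(g, cfg.min_maf)
    _log_stage("qc", t0)
    return g


@dataclass
class StructureResult:
    pruned: GenotypeMatrix
    pca: st.PCAResult
    clusters: st.ClusterModel
    fst: st.FstTable
    summary: pd.DataFrame


def structure_stage(g: GenotypeMatrix, cfg: PipelineConfig) -> StructureResult:
    t0 = time.time()
    pruned = ld_prune(g, cfg.prune_window, cfg.prune_step, cfg.prune_r2)
    pruned = filter_maf(pruned, 0.0)  # drop anything drifted to monomorphic
    p = st.pca_with_tw(pruned, alpha=cfg.tw_alpha)
    if p.n_significant < 1:
        p.n_significant = 1
    cm = st.kmeans_bic(p, range(1, cfg.k_max + 1), seed=cfg.seed,
                       force_k=cfg.force_k)
    if cm.k >= 2:
        cm = st.dapc_covariates(p, cm)
        fst = st.pairwise_fst(g, cm)
    else:
        fst = st.FstTable(labels=[0], fst=np.full((1, 1), np.nan), overall=0.0)
    summary = st.cluster_summary(g, cm)
    _log_stage("structure", t0)
    return StructureResult(pruned=pruned, pca=p, clusters=cm, fst=fst,
                           summary=summary)


def selection_stage(g: GenotypeMatrix, struct: StructureResult,
                    cfg: PipelineConfig, fixed_ids=None):
    t0 = time.time()
    aux = _build_aux(g, struct)
    selections: list[sel.CoreSelection] = []
    for mi, label in enumerate(cfg.methods):
        optimizer, criteria = METHOD_TABLE[label]
        c = sel.SelectionConfig(size=cfg.size, criteria=list(criteria),
                                optimizer=optimizer,
                                fixed_ids=list(fixed_ids or []),
                                seed=cfg.seed, iterations=cfg.iterations)
        reps = sel.replicate_selections(
            g, aux, c, n_rep=cfg.replicates,
            base_seed=cfg.seed + 1000 * mi, method_label=label)
        selections.extend(reps)
    _log_stage("selection", t0)
    return selections, aux


def _build_aux(g: GenotypeMatrix, struct: StructureResult) -> dict:
    return {
        "distance": rogers_distance(g),
        "kinship": kinship_vanraden(g),
        "pca": struct.pca,
    }


def evaluation_stage(g: GenotypeMatrix, selections, aux, traits=None):
    t0 = time.time()
    # PCA for COR runs on the full (unpruned) QC'd matrix
    whole_pca = st.pca_with_tw(g)
    if whole_pca.n_significant < 1:
        whole_pca.n_significant = 1
    reports = []
    for s in selections:
        idx = g.index_of(s.selected_ids)
        reports.append(ev.evaluate_core(
            g, idx, aux["distance"], whole_pca=whole_pca, traits=traits,
            method_label=s.method_label, replicate=s.replicate))
    _log_stage("evaluation", t0)
    return reports


def qtl_stage(g: GenotypeMatrix, struct: StructureResult, selections, aux,
              cfg: PipelineConfig):
    t0 = time.time()
    traits = qb.simulate_traits(
        g, per_chrom_traits=cfg.per_chrom_traits,
        qtl_per_trait=cfg.qtl_per_trait, h2_qtl=cfg.h2_qtl,
        h2_poly=cfg.h2_poly, seed=cfg.seed + 77,
        chromosomes=cfg.qtl_chromosomes, K=aux["kinship"])
    report = qb.run_benchmark(g, traits, selections, struct.clusters.Q,
                              aux["kinship"])
    _log_stage("qtl_bench", t0)
    return report


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def load_genotypes(cfg: PipelineConfig) -> GenotypeMatrix:
    if cfg.genotype_path is None:
        raise ValidationError("no genotype path configured")
    return read_genotypes(cfg.genotype_path, cfg.genotype_format)


def load_traits(cfg: PipelineConfig, g: GenotypeMatrix):
    if cfg.trait_path is None:
        return None
    df = pd.read_csv(cfg.trait_path, sep="\t")
    ids = df.iloc[:, 0].astype(str).tolist()
    return ev.TraitTable(accession_ids=ids, traits=df.iloc[:, 1:])


def run_sweep(cfg: PipelineConfig, g: GenotypeMatrix | None = None,
              traits=None) -> dict:
    """Execute the full benchmark sweep; returns a dict of artifacts and writes
    TSV/JSON outputs to cfg.outdir."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if g is None:
        g = load_genotypes(cfg)
    if traits is None:
        traits = load_traits(cfg, g)
    fixed = _read_fixed(cfg.fixed_path)
    g = qc_stage(g, cfg)
    struct = structure_stage(g, cfg)
    selections, aux = selection_stage(g, struct, cfg, fixed_ids=fixed)
    reports = evaluation_stage(g, selections, aux, traits=traits)
    bench = None
    if cfg.run_qtl:
        bench = qtl_stage(g, struct, selections, aux, cfg)
        ratio = {(r["method"], r["replicate"]): r["qtl_ratio"]
                 for _, r in bench.rows.iterrows()}
        for rep in reports:
            rep.QTL = ratio[(rep.method_label, rep.replicate)]
    if len(reports) >= 2:
        ev.composite_index(reports, require_qtl=cfg.run_qtl)

    # outputs
    table = ev.report_table(reports)
    table.to_csv(outdir / "evaluation_table.tsv", sep="\t", index=False)
    per_rep = pd.DataFrame([{
        "method": r.method_label, "replicate": r.replicate, "I": r.I}
        for r in reports])
    per_rep.to_csv(outdir / "composite_index.tsv", sep="\t", index=False)
    struct.summary.to_csv(outdir / "cluster_summary.tsv", sep="\t", index=False)
    for s in selections:
        name = f"core_{s.method_label}_{s.replicate}"
        (outdir / f"{name}.ids.txt").write_text("\n".join(s.selected_ids) + "\n")
        _write_sidecar(outdir / f"{name}.json", s)
    manifest = {
        "config": asdict(cfg),
        "hash": cfg.content_hash(),
        "n": g.n, "m": g.m,
        "n_clusters": struct.clusters.k,
        "overall_fst": struct.fst.overall,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return {"genotypes": g, "structure": struct, "selections": selections,
            "reports": reports, "benchmark": bench, "table": table}


def build_final_core(cfg: PipelineConfig, fixed_ids, method: str = "SH_CV",
                     size: int | None = None,
                     g: GenotypeMatrix | None = None) -> sel.CoreSelection:
    """Mixed selection: lock in the fixed list, optimize the remaining slots
    with the given method."""
    cfg.validate()
    if g is None:
        g = load_genotypes(cfg)
    g = qc_stage(g, cfg)
    missing = [a for a in fixed_ids if a not in set(g.accession_ids)]
    if missing:
        raise ValidationError(f"fixed ids absent from panel: {missing[:10]}")
    size = size or cfg.size
    if len(fixed_ids) >= size:
        raise ValidationError("fixed list must be smaller than the core size")
    struct = structure_stage(g, cfg)
    aux = _build_aux(g, struct)
    optimizer, criteria = METHOD_TABLE[method]
    c = sel.SelectionConfig(size=size, criteria=list(criteria),
                            optimizer=optimizer, fixed_ids=list(fixed_ids),
                            seed=cfg.seed, iterations=cfg.iterations)
    core = sel.optimize(g, aux, c, method_label=method)
    return core


def _read_fixed(path):
    if path is None:
        return None
    return [ln.strip() for ln in open(path) if ln.strip()]


def _write_sidecar(path: Path, s: sel.CoreSelection) -> None:
    payload = {
        "method": s.method_label,
        "replicate": s.replicate,
        "final_value": s.final_value,
        "config": {
            "size": s.config.size,
            "criteria": s.config.criteria,
            "optimizer": s.config.optimizer,
            "fixed_ids": s.config.fixed_ids,
            "seed": s.config.seed,
            "iterations": s.config.n_iterations,
        },
        "trace_head": s.objective_trace[:5],
        "trace_final": s.objective_trace[-1] if s.objective_trace else None,
    }
    path.write_text(json.dumps(payload, indent=2))
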