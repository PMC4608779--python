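"""End-to-end orchestration: simulate -> preprocess -> compare -> cluster -> tfbs.

The pipeline runs the full cross-species comparison on one directory of
TSV/FASTA/MEME inputs (typically produced by the simulator) and writes all
stage outputs plus a manifest recording seeds, input hashes and per-stage
summaries.  Deterministic stages are bit-identical under a repeated run
with the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ot_io
from . import preprocessing as pre
from . import profile_compare as pc
from . import clustering as cl
from . import promoter_tfbs as tf
from . import simulate as sim

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "compare", "cluster", "tfbs", "report")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""


@dataclass
class PipelineConfig:
    """Flat configuration for the whole pipeline (YAML-loadable).

    Numeric defaults follow the study design where one exists: fold-change
    2 for upregulation, 0.5 log2 selection threshold, presence threshold
    k = 3, 11-point common grid, candidate human end days 12/15/18/21,
    Bonferroni alpha = 0.05 / library size, 40% coverage condition.
    """

    outdir: str = "orthotime_out"
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )

    # simulate
    sim: dict = field(default_factory=dict)  # overrides for SimConfig
    n_motifs: int = 50
    motif_width_range: tuple[int, int] = (8, 10)
    promoter_length: int = 1000
    background_gc: float = 0.5
    sites_per_promoter: int = 1

    # preprocess
    fc: float = 2.0
    k_presence: int = 3
    select_threshold: float = 0.5

    # compare
    human_end: float = 21.0
    mouse_end: float = 10.0
    n_grid: int = 11
    candidate_human_ends: tuple[float, ...] = (12.0, 15.0, 18.0, 21.0)

    # cluster
    cluster_mode: str = "mouse"
    k_clusters: int | str = "auto"
    min_cluster_size: int = 30

    # tfbs
    n_random: int = 1000
    min_score_fraction: float = 0.85
    background_n: int = 500
    gc_correct: bool = False
    strict_cutoff: float = 1e-9

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("motif_width_range", "candidate_human_ends"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def sim_config(self) -> sim.SimConfig:
        return sim.SimConfig(**{"seed": self.seed, **self.sim})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, **kw)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    scfg = cfg.sim_config()
    (human, mouse, map_h, map_m, pairs, calls_h, calls_m, truth) = (
        sim.generate_experiment(scfg)
    )
    library = sim.generate_motif_library(
        cfg.n_motifs, cfg.motif_width_range, seed=cfg.seed + 1
    )
    maps = sim.plant_motif_maps(truth, library)
    promoters, sites = {}, []
    for i, (sp, genes) in enumerate(
        (("human", pairs["human_gene"]), ("mouse", pairs["mouse_gene"]))
    ):
        proms, planted = sim.generate_promoters(
            list(genes), library, maps[sp],
            promoter_length=cfg.promoter_length,
            background_gc=cfg.background_gc,
            sites_per_promoter=cfg.sites_per_promoter,
            seed=cfg.seed + 2 + i,
            min_site_quality=cfg.min_score_fraction,
        )
        promoters[sp] = proms
        planted.insert(0, "species", sp)
        sites.append(planted)
    truth.planted_sites = pd.concat(sites, ignore_index=True)
    annotation = sim.generate_annotation(truth, seed=cfg.seed + 4)

    d = outdir / "sim"
    d.mkdir(parents=True, exist_ok=True)
    ot_io.write_expression_tsv(human, d / "human_expression.tsv")
    ot_io.write_expression_tsv(mouse, d / "mouse_expression.tsv")
    ot_io.write_probe_map(map_h, d / "human_probe_map.tsv")
    ot_io.write_probe_map(map_m, d / "mouse_probe_map.tsv")
    ot_io.write_ortholog_pairs(pairs, d / "orthologs.tsv")
    ot_io.write_presence_tsv(calls_h, d / "human_calls.tsv")
    ot_io.write_presence_tsv(calls_m, d / "mouse_calls.tsv")
    ot_io.write_promoters(promoters["human"], d / "human_promoters.fa")
    ot_io.write_promoters(promoters["mouse"], d / "mouse_promoters.fa")
    ot_io.write_meme(library, d / "motifs.meme")
    ot_io.write_annotation(annotation, d / "annotation.tsv")
    ot_io.write_ground_truth(truth, d / "ground_truth.json")
    return {
        "n_genes": scfg.n_genes,
        "n_clusters": scfg.n_clusters,
        "n_motifs": len(library),
    }


def _load_inputs(outdir: Path) -> dict:
    d = outdir / "sim"
    return {
        "human": ot_io.read_expression_tsv(d / "human_expression.tsv", "human"),
        "mouse": ot_io.read_expression_tsv(d / "mouse_expression.tsv", "mouse"),
        "map_h": ot_io.read_probe_map(d / "human_probe_map.tsv"),
        "map_m": ot_io.read_probe_map(d / "mouse_probe_map.tsv"),
        "pairs": ot_io.read_ortholog_pairs(d / "orthologs.tsv"),
        "calls_h": ot_io.read_presence_tsv(d / "human_calls.tsv"),
        "calls_m": ot_io.read_presence_tsv(d / "mouse_calls.tsv"),
        "annotation": ot_io.read_annotation(d / "annotation.tsv"),
    }


def _stage_preprocess(cfg: PipelineConfig, outdir: Path, ctx: dict) -> dict:
    inp = ctx["inputs"]
    d = outdir / "preprocess"
    d.mkdir(parents=True, exist_ok=True)

    genes, profiles, status = {}, {}, {}
    for sp, matrix, pmap, calls in (
        ("human", inp["human"], inp["map_h"], inp["calls_h"]),
        ("mouse", inp["mouse"], inp["map_m"], inp["calls_m"]),
    ):
        gene_matrix, audit = pre.select_representative_probe(matrix, pmap)
        prof, excluded = pre.standardize(gene_matrix)
        st = pre.aggregate_presence(calls, pmap, k=cfg.k_presence)
        genes[sp], profiles[sp], status[sp] = gene_matrix, prof, st
        ot_io.write_expression_tsv(gene_matrix, d / f"{sp}_gene_expression.tsv")
        _write(audit, d / f"{sp}_probe_audit.tsv")
        st.reset_index().to_csv(d / f"{sp}_status.tsv", sep="\t", index=False)

    cross = pre.presence_cross_table(
        status["human"], status["mouse"], inp["pairs"]
    )
    cross.rename_axis("category").rename("percent").reset_index().to_csv(
        d / "presence_cross_table.tsv", sep="\t", index=False
    )

    up_rows = []
    enrich = {}
    for sp in ("human", "mouse"):
        per_day, union = pre.upregulated_genes(genes[sp], fc=cfg.fc)
        for day, s in per_day.items():
            up_rows.append({"species": sp, "day": day, "n_upregulated": len(s)})
        up_rows.append(
            {"species": sp, "day": "union", "n_upregulated": len(union)}
        )
        universe = set(genes[sp].probe_ids)
        ann = inp["annotation"]
        ann_sp = ann[ann["gene_id"].isin(universe)]
        if not ann_sp.empty:
            enrich[sp] = pre.enrichment_table(union, ann_sp, universe)
            _write(enrich[sp], d / f"{sp}_term_enrichment.tsv")
    _write(pd.DataFrame(up_rows), d / "upregulated_counts.tsv")

    selected = pre.select_diff_regulated(
        genes["human"], genes["mouse"], inp["pairs"],
        threshold=cfg.select_threshold,
    )
    _write(selected, d / "selected_pairs.tsv")

    ctx.update(genes=genes, profiles=profiles, status=status, selected=selected)
    return {
        "n_selected_pairs": len(selected),
        "pct_expressed_both": float(cross["hESC+ mESC+"]),
    }


def _stage_compare(cfg: PipelineConfig, outdir: Path, ctx: dict) -> dict:
    d = outdir / "compare"
    d.mkdir(parents=True, exist_ok=True)
    prof, selected = ctx["profiles"], ctx["selected"]
    cor = pc.pair_correlations(
        prof["human"], prof["mouse"], selected,
        human_interval=(0.0, cfg.human_end),
        mouse_interval=(0.0, cfg.mouse_end),
        n_grid=cfg.n_grid,
    )
    _write(cor, d / "pair_correlations.tsv")
    scan, best = pc.time_scale_scan(
        prof["human"], prof["mouse"], selected,
        mouse_end=cfg.mouse_end,
        candidate_human_ends=cfg.candidate_human_ends,
        n_grid=cfg.n_grid,
    )
    _write(scan, d / "time_scan.tsv")
    match = pc.pca_eigenvector_match(
        prof["human"], prof["mouse"], selected,
        human_interval=(0.0, cfg.human_end),
        mouse_interval=(0.0, cfg.mouse_end),
        n_grid=cfg.n_grid,
    )
    _write(match, d / "pca_match.tsv")
    ctx["pair_correlations"] = cor
    return {
        "best_human_end": best,
        "frac_positive": float((cor["pcc"] > 0).mean()),
    }


def _stage_cluster(cfg: PipelineConfig, outdir: Path, ctx: dict) -> dict:
    d = outdir / "cluster"
    d.mkdir(parents=True, exist_ok=True)
    prof = ctx["profiles"]
    cluster_set = cl.cluster_profiles(
        prof["human"], prof["mouse"], ctx["selected"],
        mode=cfg.cluster_mode, k=cfg.k_clusters, seed=cfg.seed,
        min_cluster_size=cfg.min_cluster_size,
        human_interval=(0.0, cfg.human_end),
        mouse_interval=(0.0, cfg.mouse_end),
        n_grid=cfg.n_grid,
    )
    _write(cluster_set.assignments, d / "clusters.tsv")
    table, curve = cl.compare_cluster_profiles(cluster_set)
    _write(table, d / "cluster_summary.tsv")
    _write(curve, d / "cluster_pcc_curve.tsv")
    summaries = []
    for (c, sp), s in cluster_set.summaries.items():
        s = s.copy()
        s.insert(0, "cluster", c)
        s.insert(1, "species", sp)
        summaries.append(s)
    _write(pd.concat(summaries, ignore_index=True), d / "cluster_profiles.tsv")
    ctx["cluster_set"] = cluster_set
    ctx["cluster_table"] = table
    return {"n_clusters": len(cluster_set.cluster_ids)}


def _stage_tfbs(cfg: PipelineConfig, outdir: Path, ctx: dict) -> dict:
    d = outdir / "tfbs"
    d.mkdir(parents=True, exist_ok=True)
    sim_dir = outdir / "sim"
    library = ot_io.read_meme(sim_dir / "motifs.meme")
    cluster_set = ctx["cluster_set"]
    enrichments: dict[str, dict[int, pd.DataFrame]] = {}
    null_tables = []
    for sp in ("human", "mouse"):
        promoters = ot_io.read_promoters(sim_dir / f"{sp}_promoters.fa")
        background = tf.build_background(
            ctx["genes"][sp], ctx["status"][sp], n=cfg.background_n,
            gc_correct=cfg.gc_correct, promoters=promoters,
            foreground_genes=list(
                cluster_set.assignments[f"{sp}_gene"]
            ),
            seed=cfg.seed,
        )
        bg_freqs = tf.base_frequencies(
            {g: promoters[g] for g in background if g in promoters}
        )
        scan_genes = set(cluster_set.assignments[f"{sp}_gene"]) | set(background)
        counts, positions = tf.hit_count_table(
            {g: promoters[g] for g in scan_genes if g in promoters},
            library, cfg.min_score_fraction, bg_freqs,
        )
        enrichments[sp] = {}
        rows = []
        for c in cluster_set.cluster_ids:
            group = [
                g for g in cluster_set.members(c)[f"{sp}_gene"]
                if g in promoters
            ]
            tab = tf.assign_tfbs(
                group, promoters, library, background,
                min_score_fraction=cfg.min_score_fraction,
                precomputed=(counts, positions),
            )
            enrichments[sp][c] = tab
            tab = tab.copy()
            tab.insert(0, "cluster", c)
            tab.insert(0, "species", sp)
            rows.append(tab)
        _write(pd.concat(rows, ignore_index=True), d / f"{sp}_enrichment.tsv")

        sizes = cluster_set.sizes().tolist()
        expressed = [
            g for g in ctx["status"][sp].index[ctx["status"][sp]["expressed"]]
            if g in promoters
        ]
        pvals, min_per_group, cutoff = tf.random_group_null(
            sizes, cfg.n_random, expressed, promoters, library, background,
            seed=cfg.seed + 7, min_score_fraction=cfg.min_score_fraction,
        )
        pvals.insert(0, "species", sp)
        null_tables.append(pvals)
    _write(pd.concat(null_tables, ignore_index=True), d / "null_pvalues.tsv")

    scatter, counts_df, counts_pcc = tf.promoter_expression_report(
        ctx["cluster_table"], enrichments, total_motifs=len(library),
        strict_cutoff=cfg.strict_cutoff,
    )
    _write(scatter, d / "fig6_table.tsv")
    _write(counts_df, d / "fig7_counts.tsv")
    scatter.rename(columns={"overlap_p": "p_value"})[
        ["cluster", "n_human", "n_mouse", "overlap", "p_value"]
    ].to_csv(d / "overlaps.tsv", sep="\t", index=False)
    ctx["tfbs"] = {"scatter": scatter, "counts": counts_df,
                   "counts_pcc": counts_pcc}
    return {"counts_pcc": counts_pcc, "n_motifs": len(library)}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order; returns the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "stages": {},
    }
    ctx: dict = {}
    enabled = {s: cfg.stages.get(s, True) for s in STAGES}
    try:
        for stage in STAGES:
            if not enabled.get(stage, True):
                continue
            t0 = time.time()
            if stage == "simulate":
                summary = _stage_simulate(cfg, outdir)
            elif stage == "preprocess":
                ctx["inputs"] = _load_inputs(outdir)
                summary = _stage_preprocess(cfg, outdir, ctx)
            elif stage == "compare":
                summary = _stage_compare(cfg, outdir, ctx)
            elif stage == "cluster":
                summary = _stage_cluster(cfg, outdir, ctx)
            elif stage == "tfbs":
                summary = _stage_tfbs(cfg, outdir, ctx)
            else:  # report: manifest only
                summary = {}
            summary["elapsed_s"] = round(time.time() - t0, 2)
            manifest["stages"][stage] = summary
            log.info("stage %s done in %.1fs", stage, summary["elapsed_s"])
    except Exception as exc:  # keep partial outputs, name the stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest["input_hashes"] = {
        p.name: _sha256(p) for p in sorted((outdir / "sim").glob("*"))
    } if (outdir / "sim").exists() else {}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
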