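"""End-to-end orchestration: simulate -> catalog -> differential -> enrichment
-> assignment -> network -> report.

A single :class:`PipelineConfig` (YAML-loadable) carries every threshold with
the analysis defaults (|log2FC| >= 1 and adjusted p <= 0.05 for signatures and
region calls, top 0.25% recovery cutoff, 1 Mb / ge 0.1 / corr 0.3 assignment)
and one global seed. Per-stage seeds are derived by hashing the stage name
into the global seed, so no stage consumes ambient randomness and a rerun
with the same config is bit-identical. Every output file is paired with a
JSON manifest recording input checksums, parameters and the seed.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity, catalog as cat, enrichment, io, networks, simulate


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 7
    # simulated study scale
    n_links: int = 20
    chrom_mb: int = 25
    n_extra_regions: int = 120
    n_extra_de_genes: int = 20
    n_null_genes: int = 200
    n_null_regions_pad: int = 0
    n_decoy_pwms: int = 10
    pwm_length: int = 10
    # thresholds (analysis defaults)
    lfc_min: float = 1.0
    padj_max: float = 0.05
    support_q: float = 0.05
    cutoff_frac: float = 0.0025
    assign_max_dist: int = 1_000_000
    assign_ge_alpha: float = 0.1
    assign_corr_min: float = 0.3
    assign_corr_mode: str = "absolute"
    stages: tuple = ("simulate", "catalog", "diff", "enrich", "assign", "network", "report")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 (crc32 of 'seed:stage')."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2 ** 31)


def _random_pwm(rng: np.random.Generator, length: int, name: str,
                consensus_weight: float = 0.85) -> enrichment.PWM:
    cons = rng.integers(0, 4, size=length)
    m = np.full((length, 4), (1 - consensus_weight) / 3)
    m[np.arange(length), cons] = consensus_weight
    return enrichment.PWM(name, m)


def _log(lines: list, stage: str, t0: float, **counts) -> str:
    """Record the stage counts; the persisted log omits wall time so a rerun
    with the same config is bit-identical."""
    msg = " ".join(f"{k}={v}" for k, v in counts.items())
    lines.append(f"[{stage}] {msg}")
    return f"[{stage}] elapsed={time.perf_counter() - t0:.2f}s {msg}"


def run_pipeline(config: PipelineConfig, log=print) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    state: dict = {}

    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True)

    for stage in config.stages:
        t0 = time.perf_counter()
        runner = _STAGES.get(stage)
        if runner is None:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            counts = runner(config, out, state)
        except KeyError as exc:
            raise RuntimeError(f"stage {stage!r} is missing upstream output: {exc}") from exc
        log(_log(log_lines, stage, t0, **counts))
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return out


def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> dict:
    seed = stage_seed(config.seed, "simulate")
    study = simulate.simulate_linked_study(
        seed=seed, n_links=config.n_links, chrom_mb=config.chrom_mb,
        n_extra_regions=config.n_extra_regions,
        n_extra_de_genes=config.n_extra_de_genes,
        n_null_genes=config.n_null_genes)
    rng = np.random.default_rng(stage_seed(config.seed, "motifs"))
    # the planted motif is sharper than the decoys so a sampled instance
    # stands out against ~1 kb of background sequence
    planted = _random_pwm(rng, config.pwm_length, "TF1_motif", consensus_weight=0.95)
    decoys = [_random_pwm(rng, config.pwm_length, f"decoy_{i+1:02d}")
              for i in range(config.n_decoy_pwms)]
    targets = sorted(study.truth.tf_target_regions["TF1"])
    seqs, offsets = simulate.generate_sequences_with_motifs(
        study.catalog, planted, targets, seed=stage_seed(config.seed, "sequences"))
    study.truth.motif_offsets = offsets
    tracks = simulate.generate_feature_tracks(
        simulate.GenomeSpec(("chrT",), (200_000,), seed=stage_seed(config.seed, "tracks")),
        n_tracks=2, density=150.0)

    io.write_bed(study.catalog.regions, out / "catalog.bed")
    study.region_counts.to_tsv(out / "region_counts.tsv", out / "design.tsv")
    study.expr_counts.to_tsv(out / "expr_counts.tsv", out / "design_expr.tsv")
    io.write_tss_bed(study.annotation, out / "genes.bed")
    io.write_fasta(seqs, out / "regions.fa")
    io.write_meme([planted] + decoys, out / "motifs.meme")
    study.truth.to_json(out / "truth.json")
    for name, df in tracks.items():
        io.write_bed(df, out / f"track_{name}.bed")
    io.write_manifest(out / "simulate.manifest.json", {},
                      {"config": config.to_dict()}, seed=seed)
    state.update(study=study, sequences=seqs, pwms=[planted] + decoys,
                 tracks=tracks)
    return {"regions": len(study.catalog), "genes": len(study.annotation),
            "links_planted": len(study.truth.region_gene_links)}


def _stage_catalog(config: PipelineConfig, out: Path, state: dict) -> dict:
    tracks = state["tracks"]
    feature = [v for k, v in sorted(tracks.items()) if k.startswith("track_")]
    built = cat.build_catalog(feature, tracks["insulators"], tracks["exons"],
                              {"chrT": 200_000},
                              provenance=sorted(k for k in tracks if k.startswith("track_")))
    io.write_bed(built.regions, out / "catalog_built.bed")
    io.write_manifest(out / "catalog_built.manifest.json",
                      {out / f"track_{k}.bed": out / f"track_{k}.bed" for k in tracks},
                      built.build_params)
    state["catalog_built"] = built
    return {"merged_regions": len(built)}


def _stage_diff(config: PipelineConfig, out: Path, state: dict) -> dict:
    study = state["study"]
    cfg = study.cfg
    region_sets = activity.differential_regions(
        study.region_counts, cfg.state_a, cfg.state_b,
        lfc_min=config.lfc_min, padj_max=config.padj_max,
        support_q=config.support_q)
    expr_res = activity.nb_differential(study.expr_counts, cfg.state_a, cfg.state_b)
    sig_a, sig_b = activity.define_signature(expr_res, cfg.state_a, cfg.state_b,
                                             lfc_min=config.lfc_min,
                                             padj_max=config.padj_max)
    region_sets["results"].drop(columns="id").rename_axis("id").to_csv(
        out / "region_differential.tsv", sep="\t")
    expr_res.drop(columns="id").rename_axis("id").to_csv(
        out / "gene_differential.tsv", sep="\t")
    with open(out / "region_sets.json", "w") as fh:
        json.dump({cfg.state_a: sorted(region_sets[cfg.state_a]),
                   cfg.state_b: sorted(region_sets[cfg.state_b])},
                  fh, indent=1, sort_keys=True)
    with open(out / "signatures.json", "w") as fh:
        json.dump({sig_a.state: sorted(sig_a.genes), sig_b.state: sorted(sig_b.genes)},
                  fh, indent=1, sort_keys=True)
    io.write_manifest(out / "diff.manifest.json",
                      {out / "region_counts.tsv": out / "region_counts.tsv"},
                      {"lfc_min": config.lfc_min, "padj_max": config.padj_max,
                       "support_q": config.support_q})
    state.update(region_sets=region_sets, expr_results=expr_res,
                 signatures=(sig_a, sig_b))
    return {f"regions_{cfg.state_a}": len(region_sets[cfg.state_a]),
            f"regions_{cfg.state_b}": len(region_sets[cfg.state_b]),
            "signature_sizes": f"{len(sig_a)}/{len(sig_b)}"}


def _stage_enrich(config: PipelineConfig, out: Path, state: dict) -> dict:
    study = state["study"]
    cfg = study.cfg
    foreground = sorted(state["region_sets"][cfg.state_b])
    seed = stage_seed(config.seed, "enrich")
    rankings = []
    for i, pwm in enumerate(state["pwms"]):
        scores = enrichment.scan_pwm(state["sequences"], pwm)
        rankings.append(enrichment.rank_regions(scores, pwm.name, tie_seed=seed + i))
    table = enrichment.score_features(rankings, foreground, config.cutoff_frac)
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    top = rankings[[r.feature_name for r in rankings].index(table.iloc[0]["feature"])]
    targets = enrichment.leading_targets(top, foreground, config.cutoff_frac)
    with open(out / "leading_targets.json", "w") as fh:
        json.dump({table.iloc[0]["feature"]: targets}, fh, indent=1)
    io.write_manifest(out / "enrich.manifest.json",
                      {out / "regions.fa": out / "regions.fa",
                       out / "motifs.meme": out / "motifs.meme"},
                      {"cutoff_frac": config.cutoff_frac}, seed=seed)
    state.update(enrichment_table=table, leading={table.iloc[0]["feature"]: targets},
                 rankings=rankings)
    return {"features": len(table), "top_feature": table.iloc[0]["feature"],
            "top_nes": f"{table.iloc[0]['nes']:.2f}"}


def _stage_assign(config: PipelineConfig, out: Path, state: dict) -> dict:
    study = state["study"]
    cfg = study.cfg
    diff_ids = sorted(set(state["region_sets"][cfg.state_a])
                      | set(state["region_sets"][cfg.state_b]))
    regions = study.catalog.regions[study.catalog.regions["id"].isin(diff_ids)]
    params = networks.AssignmentParams(
        max_dist=config.assign_max_dist, ge_alpha=config.assign_ge_alpha,
        lfc_min=config.lfc_min, corr_min=config.assign_corr_min,
        corr_mode=config.assign_corr_mode)
    act = activity.log_transform(study.region_counts)
    expr = activity.log_transform(study.expr_counts)
    links = networks.assign_regions_to_genes(regions, study.annotation,
                                             state["expr_results"], act, expr, params)
    links = links.sort_values(["region_id", "gene_id"]).reset_index(drop=True)
    links.to_csv(out / "links.tsv", sep="\t", index=False)
    coverage = networks.assignment_coverage(links, len(regions))
    io.write_manifest(out / "assign.manifest.json",
                      {out / "links.tsv": out / "links.tsv"},
                      {"params": asdict(params), "coverage_pct": coverage})
    state.update(links=links, assign_params=params, n_diff_regions=len(regions))
    return {"links": len(links), "coverage_pct": f"{coverage:.1f}"}


def _stage_network(config: PipelineConfig, out: Path, state: dict) -> dict:
    tf, targets = next(iter(state["leading"].items()))
    net = networks.build_tf_network(tf, targets, state["links"], state["assign_params"])
    net.links.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    state["network"] = net
    return {"tf": tf, "edges": len(net.links), "target_genes": len(net.target_genes)}


def _stage_report(config: PipelineConfig, out: Path, state: dict) -> dict:
    study = state["study"]
    cfg = study.cfg
    net = state.get("network")
    table = state.get("enrichment_table")
    n_diff = state.get("n_diff_regions", 0)
    links = state.get("links", pd.DataFrame(columns=["region_id", "gene_id"]))
    coverage = networks.assignment_coverage(links, n_diff) if n_diff else 0.0
    rows = [
        ("catalog_regions", len(study.catalog)),
        ("built_regions", len(state.get("catalog_built", []))),
        (f"diff_regions_{cfg.state_a}", len(state["region_sets"][cfg.state_a])),
        (f"diff_regions_{cfg.state_b}", len(state["region_sets"][cfg.state_b])),
        ("signature_a", len(state["signatures"][0])),
        ("signature_b", len(state["signatures"][1])),
        ("links", len(links)),
        ("assignment_coverage_pct", networks.fraction_report(
            links["region_id"].nunique() if len(links) else 0, max(n_diff, 1))),
        ("network_edges", len(net.links) if net is not None else 0),
        ("network_genes", len(net.target_genes) if net is not None else 0),
    ]
    summary = pd.DataFrame(rows, columns=["quantity", "value"])
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    text = ["Two-state regulatory landscape - summary", ""]
    text += [f"{q:>28}: {v}" for q, v in rows]
    if table is not None:
        text += ["", "Top features by NES:"]
        for _, r in table.head(5).iterrows():
            text.append(f"  {r['feature']:>12}  AUC={r['auc']:.3f}  NES={r['nes']:.2f}  "
                        f"padj={r['padj']:.2e}  targets={int(r['n_targets'])}")
    (out / "summary.txt").write_text("\n".join(text) + "\n")
    return {"written": "summary.tsv"}


_STAGES = {
    "simulate": _stage_simulate,
    "catalog": _stage_catalog,
    "diff": _stage_diff,
    "enrich": _stage_enrich,
    "assign": _stage_assign,
    "network": _stage_network,
    "report": _stage_report,
}
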