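"""Pipeline orchestration: simulate -> bin -> regions -> diagnose -> ploidy.

A single YAML config drives a reproducible run from one master seed
(per-stage streams are derived by fixed offsets). Each stage writes its
outputs to the run directory so any stage can be re-run from the upstream
files; ``run_all`` produces a combined JSON + markdown report whose every
number traces to a stage output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag_mod
from . import io as eio
from . import kmers, ploidy, regions, synthetic

log = logging.getLogger("evescout")

# fixed per-stage seed offsets off the master seed
SEED_HOST, SEED_PLANT, SEED_DEPTH, SEED_HITS, SEED_SNPS, SEED_TX, SEED_CLUSTER = \
    1, 2, 3, 4, 5, 6, 7


# ---------------------------------------------------------------------------
# Assembly statistics


@dataclass
class AssemblyStats:
    n_scaffolds: int
    total_bp: int
    n50: int
    gc_percent: Optional[float]


def assembly_stats(genome: Mapping[str, str]) -> AssemblyStats:
    """Scaffold count, total length, N50, and GC% over unambiguous bases.

    N50: the length L such that scaffolds of length >= L sum to at least
    half the total assembly length.
    """
    if not genome:
        raise ValueError("empty assembly")
    lengths = sorted((len(s) for s in genome.values()), reverse=True)
    total = sum(lengths)
    acc, n50 = 0, lengths[0]
    for L in lengths:
        acc += L
        if acc >= total / 2:
            n50 = L
            break
    try:
        gc = 100.0 * synthetic.gc_content("".join(genome.values()))
    except ValueError:
        log.warning("assembly contains no unambiguous bases; GC%% undefined")
        gc = None
    return AssemblyStats(len(genome), total, n50, gc)


# ---------------------------------------------------------------------------
# Config


DEFAULT_CONFIG: dict = {
    "host": {"n_scaffolds": 40, "min_bp": 40_000, "max_bp": 80_000,
             "base_gc": 0.514},
    "plants": [
        {"clade": "PLVB", "length_bp": 23_000, "gc_offset": -10.0,
         "tir_len": 300, "n": 4},
        {"clade": "PLVA", "length_bp": 25_000, "gc_offset": -10.0,
         "tir_len": 300, "n": 3},
        {"clade": "PLV2", "length_bp": 15_000, "gc_offset": -10.0,
         "tir_len": 200, "n": 3},
        {"clade": "CHeCME", "length_bp": 18_000, "gc_offset": -8.0, "n": 2},
    ],
    "min_flank": 6000,
    "depth": {"mean_depth": 50.0, "n_datasets": 2, "drift": 0.0},
    "hits": {"fpr": 0.0, "fnr": 0.0, "jitter_bp": 0},
    "transcripts": {"n_element_loci": 6, "n_distinct": 3, "n_background": 5},
    "snps": {"ploidy": 4, "n_snps": 2000, "depth": 100, "error_rate": 0.01},
    "binning": {"min_len": 33_000, "k": 5},
    "regions": {"max_gap": 2000},
    "diagnostics": {"flank_len": 5000, "min_flank_used": 500, "window": 1000},
    "ploidy_fit": {"min_depth": 20, "candidates": [2, 3, 4, 5, 6, 7, 8],
                   "error_rate": 0.01},
}


def load_config(path: Optional[str]) -> dict:
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(config.get(key), dict):
                config[key].update(val)
            else:
                config[key] = val
    return config


def _param_hash(config: dict, seed: int) -> str:
    payload = json.dumps({"config": config, "seed": seed}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_inputs(paths: Mapping[str, str]) -> None:
    missing = [f"{k}: {v}" for k, v in paths.items()
               if v is not None and not os.path.exists(v)]
    if missing:
        raise FileNotFoundError("missing input files: " + "; ".join(missing))


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: dict, outdir: Path, seed: int):
    host_cfg = config["host"]
    spec = synthetic.HostGenomeSpec(
        n_scaffolds=host_cfg["n_scaffolds"],
        length_range=(host_cfg["min_bp"], host_cfg["max_bp"]),
        base_gc=host_cfg["base_gc"], seed=seed + SEED_HOST)
    genome = synthetic.generate_host(spec)
    plants = []
    for block in config["plants"]:
        block = dict(block)
        n = block.pop("n", 1)
        for _ in range(n):
            plants.append(synthetic.PlantSpec(**block))
    genome, truth = synthetic.plant_elements(
        genome, plants, seed=seed + SEED_PLANT,
        min_flank=config.get("min_flank", 2000),
        base_gc=host_cfg["base_gc"])
    lengths = {name: len(s) for name, s in genome.items()}

    depth_cfg = config["depth"]
    tracks = synthetic.simulate_depth(
        genome, truth, depth_cfg["mean_depth"], depth_cfg["n_datasets"],
        depth_cfg["drift"], seed=seed + SEED_DEPTH)
    hits_cfg = config["hits"]
    hits = synthetic.simulate_marker_hits(
        truth, lengths, hits_cfg["fpr"], hits_cfg["fnr"],
        hits_cfg["jitter_bp"], seed=seed + SEED_HITS)
    tx_cfg = config["transcripts"]
    transcripts = synthetic.simulate_transcript_loci(
        truth, lengths, tx_cfg["n_element_loci"], tx_cfg["n_distinct"],
        tx_cfg.get("n_background", 0), seed=seed + SEED_TX)
    snp_cfg = config["snps"]
    snps = synthetic.simulate_allele_counts(
        snp_cfg["ploidy"], snp_cfg["n_snps"], snp_cfg["depth"],
        snp_cfg["error_rate"], seed=seed + SEED_SNPS)

    outdir.mkdir(parents=True, exist_ok=True)
    eio.write_fasta(genome, outdir / "genome.fasta")
    eio.write_bed6(truth.element_bed_rows(), outdir / "truth_elements.bed")
    eio.write_bed6(truth.marker_bed_rows(), outdir / "truth_markers.bed")
    eio.write_bed6(truth.tir_bed_rows(), outdir / "truth_tirs.bed")
    for i, track in enumerate(tracks, 1):
        eio.write_depth_tsv(track, outdir / f"depth_dataset{i}.tsv")
    eio.write_hits_tsv(hits, outdir / "marker_hits.tsv")
    transcripts.to_csv(outdir / "transcripts.bed", sep="\t",
                       index=False, header=False)
    eio.write_allele_counts_tsv(snps, outdir / "allele_counts.tsv")
    log.info("simulate: %d scaffolds, %d planted elements, %d hits",
             len(genome), len(truth.elements), len(hits))
    return genome, truth, tracks, hits, transcripts, snps


def stage_bin(genome: Mapping[str, str], config: dict, outdir: Path,
              seed: int) -> pd.DataFrame:
    bin_cfg = config["binning"]
    profiles = {name: kmers.kmer_profile(seq, bin_cfg["k"], name)
                for name, seq in genome.items()}
    lengths = {name: len(seq) for name, seq in genome.items()}
    assignments = kmers.cluster_scaffolds(
        profiles, lengths, min_len=bin_cfg["min_len"], seed=seed + SEED_CLUSTER)
    table = pd.DataFrame([{
        "scaffold_id": a.scaffold_id, "cluster_id": a.cluster_id,
        "role": a.role, "stage": a.stage,
        "coord1": a.coords[0], "coord2": a.coords[1],
    } for a in assignments])
    table.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    log.info("bin: %d clusters, core cluster holds %d scaffolds",
             table["cluster_id"].nunique(),
             int((table["role"] == "core").sum()))
    return table


def stage_regions(genome: Mapping[str, str], hits: pd.DataFrame, config: dict,
                  outdir: Path):
    lengths = {name: len(s) for name, s in genome.items()}
    fragments, warnings = regions.merge_hits(
        hits, max_gap=config["regions"]["max_gap"], scaffold_lengths=lengths)
    for w in warnings:
        log.warning("regions: %s", w)
    for f in fragments:
        regions.completeness(f)
        if len(genome[f.scaffold]) >= 2 * 1000 and f.length >= 2 * 1000:
            f.tirs = regions.detect_tirs(
                genome[f.scaffold][f.start:f.end], window=1000)
            if f.tirs is not None:
                f.tirs = tuple((f.start + s, f.start + e) for s, e in f.tirs)
    eio.write_bed6(regions.fragments_bed_rows(fragments),
                   outdir / "fragments.bed")
    eio.write_gff3(regions.fragments_gff_features(fragments),
                   outdir / "fragments.gff3")
    cens = regions.census(fragments)
    cens.to_csv(outdir / "census.tsv", sep="\t", index=False)
    log.info("regions: %d fragments across %d clades", len(fragments),
             cens.shape[0])
    return fragments, cens


def stage_diagnose(genome, fragments, tracks, transcripts, config: dict,
                   outdir: Path) -> pd.DataFrame:
    dcfg = config["diagnostics"]
    diags = diag_mod.diagnose_fragments(
        fragments, genome, tracks[0],
        tracks[1] if len(tracks) > 1 else None, transcripts,
        flank_len=dcfg["flank_len"], min_flank_used=dcfg["min_flank_used"],
        window=dcfg["window"])
    table = diag_mod.diagnostics_table(diags)
    table.to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)
    profile_rows = []
    for d in diags:
        for i, v in enumerate(d.windowed_rel_depth):
            profile_rows.append((d.fragment_id, i, v))
    pd.DataFrame(profile_rows, columns=["fragment_id", "window", "rel_depth"]) \
        .to_csv(outdir / "depth_profiles.tsv", sep="\t", index=False)
    log.info("diagnose: %s", table["call"].value_counts().to_dict())
    return table


def stage_ploidy(snps: pd.DataFrame, config: dict, outdir: Path) -> dict:
    pcfg = config["ploidy_fit"]
    filtered = ploidy.filter_snps(snps, min_depth=pcfg["min_depth"])
    result = ploidy.fit_ploidy(filtered, candidates=pcfg["candidates"],
                               error_rate=pcfg["error_rate"])
    hist = ploidy.af_histogram(filtered)
    hist.to_csv(outdir / "af_histogram.tsv", sep="\t", index=False)
    report = {
        "selected_ploidy": result.best.ploidy,
        "n_snps_used": result.best.n_snps,
        "fits": {str(p): {"log_likelihood": f.log_likelihood, "bic": f.bic,
                          "weights": f.weights.tolist()}
                 for p, f in result.fits.items()},
    }
    with open(outdir / "ploidy.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("ploidy: selected P=%d from %d sites", result.best.ploidy,
             result.best.n_snps)
    return report


# ---------------------------------------------------------------------------
# run_all


def run_all(config: dict, outdir: str | Path, seed: int) -> dict:
    """Execute all stages in dependency order and write the combined report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        genome, truth, tracks, hits, transcripts, snps = stage_simulate(
            config, outdir, seed)
        stage = "stats"
        stats = assembly_stats(genome)
        stage = "bin"
        clusters = stage_bin(genome, config, outdir, seed)
        stage = "regions"
        fragments, cens = stage_regions(genome, hits, config, outdir)
        stage = "diagnose"
        diag_table = stage_diagnose(genome, fragments, tracks, transcripts,
                                    config, outdir)
        stage = "ploidy"
        ploidy_report = stage_ploidy(snps, config, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    dgc = diag_table["delta_gc"].dropna()
    report = {
        "seed": seed,
        "parameter_hash": _param_hash(config, seed),
        "assembly": {"n_scaffolds": stats.n_scaffolds,
                     "total_bp": stats.total_bp, "n50": stats.n50,
                     "gc_percent": stats.gc_percent},
        "clusters": {"n_clusters": int(clusters["cluster_id"].nunique()),
                     "n_core_scaffolds": int((clusters["role"] == "core").sum()),
                     "n_satellite_scaffolds":
                         int((clusters["role"] == "satellite").sum())},
        "census": cens.to_dict(orient="records"),
        "diagnostics": {
            "calls": diag_table["call"].value_counts().to_dict(),
            "mean_delta_gc_pp": float(dgc.mean()) if len(dgc) else None,
            "sd_delta_gc_pp": float(dgc.std(ddof=1)) if len(dgc) > 1 else None,
            "n_silent": int((diag_table["n_transcript_loci"] == 0).sum()),
        },
        "ploidy": ploidy_report,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _write_markdown_report(report, outdir / "report.md")
    return report


def _write_markdown_report(report: dict, path: Path) -> None:
    lines = ["# evescout run report", "",
             f"- master seed: {report['seed']}",
             f"- parameter hash: {report['parameter_hash']}", "",
             "## Assembly", ""]
    a = report["assembly"]
    gc = f"{a['gc_percent']:.1f}%" if a["gc_percent"] is not None else "NA"
    lines += [f"| Scaffolds | Total bp | N50 | GC% |", "|---|---|---|---|",
              f"| {a['n_scaffolds']} | {a['total_bp']} | {a['n50']} | {gc} |",
              "", "## Composition clusters", "",
              f"- clusters: {report['clusters']['n_clusters']} "
              f"(core scaffolds: {report['clusters']['n_core_scaffolds']}, "
              f"satellite: {report['clusters']['n_satellite_scaffolds']})",
              "", "## Viral element census", "",
              "| Clade | Total bp | MCP hits | (near) complete |", "|---|---|---|---|"]
    for row in report["census"]:
        lines.append(f"| {row['clade']} | {row['total_bp']} | {row['n_mcp']} "
                     f"| {row['n_near_complete']} |")
    d = report["diagnostics"]
    mean_dgc = (f"{d['mean_delta_gc_pp']:+.1f}"
                if d["mean_delta_gc_pp"] is not None else "NA")
    sd_dgc = (f"{d['sd_delta_gc_pp']:.1f}"
              if d["sd_delta_gc_pp"] is not None else "NA")
    lines += ["", "## Endogenization diagnostics", "",
              f"- calls: {d['calls']}",
              f"- flank-minus-fragment GC differential: {mean_dgc} ± {sd_dgc} pp",
              f"- transcriptionally silent fragments: {d['n_silent']}",
              "", "## Ploidy", "",
              f"- selected ploidy: {report['ploidy']['selected_ploidy']} "
              f"(from {report['ploidy']['n_snps_used']} filtered SNP sites)", ""]
    path.write_text("\n".join(lines))
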