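"""End-to-end pipeline driver: simulate -> mappability -> tracks ->
screen -> (model) -> evidence -> report.

A run is described by a JSON config with one block per stage; every run
directory receives a manifest listing seeds, parameters and a checksum
for each output file, so deterministic outputs can be verified
byte-for-byte across re-runs.
"""
from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np

from . import simulate as sim
from .evidence import DatasetRecord, Reagent, summary_table, tier_evidence
from .genome import Annotation, write_fasta
from .mappability import compute_mappability, write_mappability
from .model import (ProfileModelConfig, TrainingConfig, corroboration_score,
                    make_training_set, predict_circular, train_folds)
from .screen import ScreenParams, screen_alignments, write_calls, write_report
from .tracks import coverage_track, five_prime_track, write_track

logger = logging.getLogger(__name__)


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "genome": {"length": 16569, "gc_content": 0.44, "name": "chrM",
               "duplications": []},
    "motif": "TGACTCAG",
    "sites": {
        "occupancy_positions": [2500, 5200, 8100, 11000, 13800],
        "occupancy_enrichment": 25.0,
        "artifact_positions": [16300],
        "artifact_enrichment": 25.0,
    },
    "mask": {"start": 16024, "length": 1122},  # D-loop-style control region
    "simulate": {"n_reads": 20000, "read_length": 36,
                 "fragment_length_mean": 200.0, "fragment_length_sd": 30.0,
                 "background_fraction": 0.3},
    "datasets": [
        {"dataset_id": "ds_ab1_k562", "reagent_class": "antibody",
         "reagent_id": "ab1", "cell_context": "K562", "control": False},
        {"dataset_id": "ds_tag_k562", "reagent_class": "epitope_tag",
         "reagent_id": "gfp", "cell_context": "K562", "control": False},
        {"dataset_id": "ds_ab1_hepg2", "reagent_class": "antibody",
         "reagent_id": "ab1", "cell_context": "HepG2", "control": True},
    ],
    "target": "SYNTF1",
    "mappability": {"k": 36, "mismatches": 2, "circular_kmers": True},
    "screen": {},  # ScreenParams overrides
    "model": {
        "enabled": True,
        "n_train_contigs": 4,
        "train_contig_length": 3000,
        "sites_per_contig": 5,
        "reads_per_contig": 30000,
        "config": {"input_length": 514, "output_length": 250,
                   "n_conv_layers": 4, "n_filters": 16, "profile_kernel": 25,
                   "counts_hidden": 8, "use_control": False},
        "training": {"n_folds": 2, "max_epochs": 12, "patience": 4,
                     "jitter_max": 32, "batch_size": 32},
    },
    "plots": True,
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config: dict) -> None:
    """Fail before any stage runs if referenced input paths are missing."""
    for key in ("alignments", "genome_fasta", "peaks", "masks_bed"):
        path = config.get("inputs", {}).get(key)
        if path is not None and not os.path.exists(path):
            raise FileNotFoundError(f"configured input {key!r} not found: {path}")


def run_pipeline(config: dict, outdir: str) -> dict:
    """Execute the configured stages in dependency order; returns the
    manifest. Partial outputs are preserved on stage failure."""
    validate_config(config)
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"seed": config.get("seed", 0), "config": config,
                      "outputs": {}, "stages": []}

    def _register(name: str, path: str) -> None:
        manifest["outputs"][os.path.relpath(path, outdir)] = _checksum(path)

    try:
        artifacts = _stage_simulate(config, outdir, _register, manifest)
        _stage_mappability(config, outdir, _register, manifest, artifacts)
        _stage_tracks(config, outdir, _register, manifest, artifacts)
        _stage_screen(config, outdir, _register, manifest, artifacts)
        if config.get("model", {}).get("enabled", False):
            _stage_model(config, outdir, _register, manifest, artifacts)
        _stage_evidence(config, outdir, _register, manifest, artifacts)
    except Exception as exc:  # annotate failures with the stage name
        stage = manifest["stages"][-1] if manifest["stages"] else "init"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _stage_simulate(config, outdir, register, manifest) -> dict:
    manifest["stages"].append("simulate")
    seed = config.get("seed", 0)
    gcfg = config["genome"]
    genome = sim.generate_circular_genome(
        gcfg["length"], gcfg["gc_content"],
        [tuple(d) for d in gcfg.get("duplications", [])],
        seed=seed, name=gcfg.get("name", "chrM"),
    )
    scfg = config["sites"]
    placements = [(p, "+", scfg["occupancy_enrichment"], "occupancy")
                  for p in scfg["occupancy_positions"]]
    placements += [(p, "both", scfg["artifact_enrichment"], "artifact")
                   for p in scfg["artifact_positions"]]
    genome, sites = sim.plant_motifs(genome, config["motif"], placements)
    mask = Annotation(config["mask"]["start"], config["mask"]["length"], "dloop")
    genome.annotations.append(mask)

    fasta = os.path.join(outdir, "genome.fa")
    write_fasta(genome, fasta)
    register("genome", fasta)
    truth = os.path.join(outdir, "truth.bed")
    sim.write_truth(sites, genome.length, truth)
    register("truth", truth)

    alignments = {}
    for i, ds in enumerate(config["datasets"]):
        cfg = sim.SimConfig(seed=seed + 100 + i, control=ds.get("control", False),
                            **config["simulate"])
        aln = sim.simulate_reads(genome, sites, cfg)
        sam = os.path.join(outdir, f"{ds['dataset_id']}.sam")
        sim.write_sam(aln, genome, sam)
        register(ds["dataset_id"], sam)
        with open(os.path.join(outdir, f"{ds['dataset_id']}.simconfig.json"), "w") as fh:
            json.dump(asdict(cfg), fh, indent=2)
        alignments[ds["dataset_id"]] = aln
    return {"genome": genome, "sites": sites, "mask": mask,
            "alignments": alignments}


def _stage_mappability(config, outdir, register, manifest, artifacts) -> None:
    manifest["stages"].append("mappability")
    mcfg = config.get("mappability", {})
    track = compute_mappability(
        artifacts["genome"], k=mcfg.get("k", 36),
        mismatches=mcfg.get("mismatches", 2),
        circular_kmers=mcfg.get("circular_kmers", True),
    )
    path = os.path.join(outdir, "mappability.bedGraph")
    write_mappability(track, path)
    register("mappability", path)
    artifacts["mappability"] = track


def _stage_tracks(config, outdir, register, manifest, artifacts) -> None:
    manifest["stages"].append("tracks")
    artifacts["coverage"] = {}
    artifacts["five_prime"] = {}
    for ds_id, aln in artifacts["alignments"].items():
        cov = coverage_track(aln)
        fp = five_prime_track(aln)
        for prefix, track in ((f"{ds_id}.coverage", cov), (f"{ds_id}.5p", fp)):
            for path in write_track(track, os.path.join(outdir, prefix)):
                register(prefix, path)
        artifacts["coverage"][ds_id] = cov
        artifacts["five_prime"][ds_id] = fp


def _stage_screen(config, outdir, register, manifest, artifacts) -> None:
    manifest["stages"].append("screen")
    params = ScreenParams(**config.get("screen", {}))
    masks = [artifacts["mask"]]
    artifacts["calls"] = {}
    for ds_id, aln in artifacts["alignments"].items():
        calls, report = screen_alignments(aln, artifacts["mappability"],
                                          masks, params)
        bed = os.path.join(outdir, f"{ds_id}.calls.bed")
        write_calls(calls, aln.genome_name, bed)
        register(f"{ds_id}.calls", bed)
        rep = os.path.join(outdir, f"{ds_id}.screen_report.json")
        write_report(report, rep)
        register(f"{ds_id}.report", rep)
        artifacts["calls"][ds_id] = calls
        if config.get("plots", True):
            from .plots import plot_strand_profiles

            for style in ("circular", "linear"):
                fig = os.path.join(outdir, f"{ds_id}.{style}.png")
                plot_strand_profiles([artifacts["coverage"][ds_id]], fig,
                                     calls=calls, masks=masks, style=style)
                register(f"{ds_id}.{style}", fig)


def _stage_model(config, outdir, register, manifest, artifacts) -> None:
    manifest["stages"].append("model")
    mconf = config["model"]
    seed = config.get("seed", 0)
    mcfg = ProfileModelConfig(**mconf.get("config", {}))
    tcfg = TrainingConfig(seed=seed, **mconf.get("training", {}))

    genomes, tracks, peaks = {}, {}, []
    rng = np.random.default_rng(seed + 999)
    for c in range(mconf["n_train_contigs"]):
        name = f"train{c}"
        g = sim.generate_circular_genome(mconf["train_contig_length"], 0.44,
                                         seed=seed + 500 + c, name=name)
        spacing = mconf["train_contig_length"] // mconf["sites_per_contig"]
        positions = [int(spacing * (i + 0.5)) for i in range(mconf["sites_per_contig"])]
        placements = [(p, "+" if rng.integers(2) else "-", 25.0, "occupancy")
                      for p in positions]
        g, sites = sim.plant_motifs(g, config["motif"], placements)
        aln = sim.simulate_reads(g, sites, sim.SimConfig(
            n_reads=mconf["reads_per_contig"], fragment_length_mean=50.0,
            fragment_length_sd=8.0, background_fraction=0.2,
            seed=seed + 700 + c))
        genomes[name] = g
        tracks[name] = five_prime_track(aln)
        peaks.extend((name, p) for p in positions)

    windows = make_training_set(peaks, genomes, tracks, tcfg, mcfg)
    folds = train_folds(windows, genomes, tracks, mcfg, tcfg, model_seed=seed)
    metrics_path = os.path.join(outdir, "model_folds.tsv")
    with open(metrics_path, "w") as fh:
        fh.write("fold\tval_nll\tuniform_nll\tusable\ttest_contigs\n")
        for fr in folds:
            fh.write(f"{fr.fold}\t{fr.val_nll:.4f}\t{fr.uniform_nll:.4f}\t"
                     f"{fr.usable}\t{','.join(fr.test_contigs)}\n")
    register("model_folds", metrics_path)

    usable = [fr.model for fr in folds if fr.usable] or [folds[0].model]
    predicted = predict_circular(usable, artifacts["genome"])
    prefix = os.path.join(outdir, "predicted")
    for path in write_track(predicted.track, prefix):
        register("predicted", path)
    artifacts["predicted"] = predicted
    artifacts["corroboration"] = {}
    for ds_id, calls in artifacts["calls"].items():
        score, _ = corroboration_score(calls, predicted)
        artifacts["corroboration"][ds_id] = score


def _stage_evidence(config, outdir, register, manifest, artifacts) -> None:
    manifest["stages"].append("evidence")
    genome = artifacts["genome"]
    records = []
    for ds in config["datasets"]:
        ds_id = ds["dataset_id"]
        records.append(DatasetRecord(
            dataset_id=ds_id,
            target=config.get("target", "TF"),
            cell_context=ds.get("cell_context", ""),
            reagent=Reagent(ds["reagent_class"], ds["reagent_id"],
                            ds.get("lot")),
            calls=artifacts["calls"][ds_id],
            corroboration=artifacts.get("corroboration", {}).get(ds_id),
        ))
    summary = tier_evidence(records, genome.length)
    path = os.path.join(outdir, "evidence.json")
    with open(path, "w") as fh:
        json.dump({
            "target": summary.target, "tier": summary.tier,
            "n_datasets": summary.n_datasets,
            "n_with_peaks": summary.n_with_peaks,
            "orthogonal_reagents_with_peaks": summary.orthogonal_reagents_with_peaks,
            "discordant": summary.discordant,
            "model_corroborated": summary.model_corroborated,
            "concordance": summary.concordance,
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")
    register("evidence", path)

    tsv = os.path.join(outdir, "evidence_summary.tsv")
    summary_table([summary]).to_csv(tsv, sep="\t")
    register("evidence_summary", tsv)

    if len(artifacts["coverage"]) >= 2:
        from .evidence import cluster_profiles
        from .plots import plot_cluster_heatmap

        labels = list(artifacts["coverage"])
        profiles = np.stack([artifacts["coverage"][k].total for k in labels])
        try:
            order, _ = cluster_profiles(profiles)
            if config.get("plots", True):
                fig = os.path.join(outdir, "profile_clustering.png")
                plot_cluster_heatmap(profiles, order, labels, fig)
                register("clustering", fig)
        except ValueError as exc:
            logger.warning("clustering skipped: %s", exc)


def demo_config(seed: int = 1) -> dict:
    """A bundled configuration that completes in a few minutes on one CPU."""
    config = default_config()
    config["seed"] = seed
    config["genome"]["length"] = 8000
    config["sites"]["occupancy_positions"] = [1500, 3200, 5100]
    config["sites"]["artifact_positions"] = [7800]
    config["mask"] = {"start": 7500, "length": 700}
    config["simulate"]["n_reads"] = 20000
    config["model"]["n_train_contigs"] = 2
    config["model"]["sites_per_contig"] = 5
    config["model"]["reads_per_contig"] = 15000
    config["model"]["training"]["max_epochs"] = 6
    return config
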