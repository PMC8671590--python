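"""End-to-end orchestration: tags -> clusters -> annotation -> targetome,
profiles, motifs, knockout CDF shift, and super-enhancers.

`run_pipeline` executes the stages in dependency order, writes every table
under the configured output directory, and returns a manifest (list of files
written plus a summary-statistics JSON). Re-running with an identical config
and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from . import annotate, koshift, motifs, profiles, superenhancer, synthetic, tags, targetome
from .config import PipelineConfig

__all__ = ["run_pipeline"]

logger = logging.getLogger("agoclip")


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.files: list[str] = []

    def add(self, path: Path) -> Path:
        self.files.append(str(path.relative_to(self.outdir)))
        return path

    def write_df(self, df: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        df.to_csv(path, sep="\t", index=False)
        return self.add(path)


def _materialize_synthetic(config: PipelineConfig, outdir: Path) -> dict:
    """Generate all inputs and return them in the `inputs` path convention."""
    synth_dir = outdir / "synthetic"
    synth = dataclasses.replace(config.synth, rng_seed=config.rng_seed)
    ref = synthetic.generate_reference(synth, synth_dir)
    tag_paths, truth_path = synthetic.simulate_clip_tags(ref, synth_dir)
    counts_path = synthetic.simulate_mirna_counts(ref, synth_dir)
    ko_path, ko_mirna = synthetic.simulate_ko_expression(ref, synth_dir)
    h3k_paths, h3k_truth = synthetic.simulate_h3k27ac(ref, synth_dir)

    tag_manifest = synth_dir / "tag_manifest.tsv"
    pd.DataFrame(
        [{"stage": s, "replicate": r, "path": str(p)} for (s, r), p in tag_paths.items()]
    ).to_csv(tag_manifest, sep="\t", index=False)
    h3k_manifest = synth_dir / "h3k27ac_manifest.tsv"
    pd.DataFrame(
        [{"stage": s, "path": str(p)} for s, p in h3k_paths.items()]
    ).to_csv(h3k_manifest, sep="\t", index=False)
    return {
        "tag_manifest": str(tag_manifest),
        "gtf": str(ref.gtf),
        "genome_fasta": str(ref.genome_fasta),
        "mirna_fasta": str(ref.mirna_fasta),
        "mirna_counts": str(counts_path),
        "ko_log2fc": str(ko_path),
        "ko_mirna": ko_mirna,
        "h3k27ac_manifest": str(h3k_manifest),
        "tss": str(ref.tss_tsv),
        "clip_truth": str(truth_path),
        "h3k27ac_truth": str(h3k_truth),
    }


def _stage_order(manifest_df: pd.DataFrame) -> list[str]:
    seen: list[str] = []
    for s in manifest_df["stage"]:
        if s not in seen:
            seen.append(s)
    return seen


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the output manifest.

    Returns a dict with keys `files` (paths written, relative to outdir),
    `summary` (path of the summary JSON) and `stats` (the summary content).
    Any stage failure raises with the stage name prefixed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    man = _Manifest(outdir)
    stats: dict = {}
    t0 = time.time()

    def stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t0)

    try:
        stage("inputs")
        inputs = _materialize_synthetic(config, outdir) if config.synthetic else config.inputs
    except Exception as exc:
        raise RuntimeError(f"[inputs] {exc}") from exc

    try:
        stage("clusters")
        tag_manifest = pd.read_csv(inputs["tag_manifest"], sep="\t")
        stage_labels = _stage_order(tag_manifest)
        clusters_by_stage: dict[str, list] = {}
        tag_mode: dict[str, int] = {}
        for stage_label, sub in tag_manifest.groupby("stage", sort=False):
            stage_tags = []
            for rec in sub.itertuples(index=False):
                stage_tags.extend(tags.read_tag_bed(rec.path, stage_label, int(rec.replicate)))
            if stage_tags:
                tag_mode[stage_label] = tags.length_distribution(stage_tags)[1]
            clusters_by_stage[stage_label] = tags.call_clusters(
                stage_tags, config.min_peak_height, config.min_replicates
            )
        stats["tag_modal_length"] = tag_mode
        stats["cluster_counts"] = {s: len(c) for s, c in clusters_by_stage.items()}
    except Exception as exc:
        raise RuntimeError(f"[clusters] {exc}") from exc

    try:
        stage("annotate")
        models = annotate.load_gene_models(inputs["gtf"])
        index = annotate.FeatureIndex(models)
        labeled_frames = []
        for stage_label in stage_labels:
            df = annotate.annotate_clusters(clusters_by_stage[stage_label], index)
            labeled_frames.append(df)
        labeled = pd.concat(labeled_frames, ignore_index=True) if labeled_frames else pd.DataFrame()
        man.write_df(labeled, "clusters_annotated.tsv")
        stats["feature_fractions"] = (
            annotate.feature_distribution(labeled) if len(labeled) else {}
        )
    except Exception as exc:
        raise RuntimeError(f"[annotate] {exc}") from exc

    try:
        stage("profiles")
        counts = pd.read_csv(inputs["mirna_counts"], sep="\t")
        rpm = profiles.quantify_mirnas(counts, stages=stage_labels)
        man.write_df(rpm.reset_index(), "mirna_rpm.tsv")
        assign, newick = profiles.cluster_stage_profiles(rpm, k=config.n_profile_clusters)
        man.write_df(assign, "mirna_stage_clusters.tsv")
        dendro = outdir / "mirna_dendrogram.nwk"
        dendro.write_text(newick + "\n")
        man.add(dendro)
        stats["stage_cluster_sizes"] = assign["cluster"].value_counts().sort_index().to_dict()
        stats["stage_cluster_enriched"] = (
            assign.groupby("cluster")["enriched_stage"].first().to_dict()
        )
        first, last = stage_labels[0], stage_labels[-1]
        fc = profiles.stage_log2fc(rpm, first, last, config.pseudocount)
        man.write_df(fc.reset_index(), f"mirna_log2fc_{last}_vs_{first}.tsv")
        expressed = {
            s: set(rpm.index[rpm[s] / 1e6 >= config.expressed_min_share])
            for s in stage_labels
        }
        stats["expressed_mirnas"] = {s: sorted(v) for s, v in expressed.items()}
        stats["top12_share"] = {
            s: profiles.top_share(rpm, s, min(12, len(rpm))) for s in stage_labels
        }
    except Exception as exc:
        raise RuntimeError(f"[profiles] {exc}") from exc

    try:
        stage("targetome")
        genome = Fasta(inputs["genome_fasta"])
        catalog = targetome.read_mirna_fasta(inputs["mirna_fasta"])
        interactions = targetome.build_targetome(labeled, genome, catalog, expressed)
        man.write_df(interactions, "interactions.tsv")
        per_mirna = (
            interactions.groupby(["mirna", "region"])["gene_id"]
            .nunique()
            .rename("n_target_genes")
            .reset_index()
        )
        man.write_df(per_mirna, "target_counts.tsv")
        stats["n_interactions"] = int(len(interactions))
        stats["target_counts_by_region"] = {
            f"{r.mirna}:{r.region}": int(r.n_target_genes)
            for r in per_mirna.itertuples(index=False)
        }
        utr3 = labeled[labeled["feature"] == "3UTR"]
        if len(utr3):
            seqs = [
                targetome.cluster_sequence(
                    genome, r.chrom, int(r.start), int(r.end), r.strand
                )
                for r in utr3.itertuples(index=False)
            ]
            rpm_total = rpm.sum(axis=1).sort_values(ascending=False, kind="stable")
            top = set(rpm_total.index[: config.top_n_coverage])
            top_catalog = [m for m in catalog if m.name in top]
            stats["seed_coverage_top_expressed"] = targetome.seed_coverage_fraction(
                seqs, top_catalog
            )
            stats["seed_coverage_all"] = targetome.seed_coverage_fraction(seqs, catalog)
        else:
            seqs = []
    except Exception as exc:
        raise RuntimeError(f"[targetome] {exc}") from exc

    try:
        stage("motifs")
        motif_top: dict[str, dict] = {}
        for stage_label in stage_labels:
            sub = labeled[(labeled["stage"] == stage_label) & (labeled["feature"] == "3UTR")]
            stage_seqs = [
                targetome.cluster_sequence(genome, r.chrom, int(r.start), int(r.end), r.strand)
                for r in sub.itertuples(index=False)
            ]
            stage_seqs = [s for s in stage_seqs if len(s) >= config.kmer_k]
            if len(stage_seqs) < 5:
                continue
            table = motifs.kmer_enrichment(
                stage_seqs, k=config.kmer_k, n_shuffles=config.n_shuffles,
                rng_seed=config.rng_seed,
            )
            table = motifs.match_motifs_to_seeds(table, catalog, expressed[stage_label])
            man.write_df(table.head(200), f"motifs_{stage_label}.tsv")
            top_row = table.iloc[0]
            motif_top[stage_label] = {
                "kmer": top_row["kmer"],
                "z": float(top_row["z"]),
                "matched_mirnas": top_row["matched_mirnas"],
            }
        stats["top_motif"] = motif_top
    except Exception as exc:
        raise RuntimeError(f"[motifs] {exc}") from exc

    try:
        stage("koshift")
        expr = pd.read_csv(inputs["ko_log2fc"], sep="\t")
        ko_mirna = inputs["ko_mirna"]
        universe = list(expr["gene_id"])
        clip_targets = targetome.target_genes(interactions, ko_mirna, regions=["3UTR"])
        ko_entry = next((m for m in catalog if m.name == ko_mirna), None)
        seed_candidates: set[str] = set()
        if ko_entry is not None:
            for m3 in models:
                if not m3.utr3:
                    continue
                seq = "".join(
                    targetome.cluster_sequence(genome, m3.chrom, s, e, m3.strand)
                    for s, e in (m3.utr3 if m3.strand == "+" else m3.utr3[::-1])
                )
                if targetome.scan_sequence(seq, [ko_entry]):
                    seed_candidates.add(m3.gene_id)
        partition = koshift.partition_genes(clip_targets, seed_candidates, universe)
        fc_by_gene = dict(zip(expr["gene_id"], expr["log2fc"]))
        samples = {
            label: [fc_by_gene[g] for g, lab in partition.items() if lab == label]
            for label in ("clip_target", "seed_only", "background")
        }
        man.write_df(
            koshift.ecdf_table({k: v for k, v in samples.items() if v}),
            f"ko_{ko_mirna}_ecdf.tsv",
        )
        ks_out = {}
        for label in ("clip_target", "seed_only"):
            if samples[label] and samples["background"]:
                res = koshift.ks_shift_test(samples[label], samples["background"])
                ks_out[label] = {
                    "D": res.D, "p": res.p, "m": res.m, "n": res.n, "method": res.method,
                }
        ks_path = outdir / f"ko_{ko_mirna}_ks.json"
        ks_path.write_text(json.dumps(ks_out, indent=2, sort_keys=True) + "\n")
        man.add(ks_path)
        stats["ks"] = ks_out
        stats["ko_mirna"] = ko_mirna
        stats["gene_partition_sizes"] = {k: len(v) for k, v in samples.items()}
    except Exception as exc:
        raise RuntimeError(f"[koshift] {exc}") from exc

    try:
        stage("superenhancer")
        h3k_manifest = pd.read_csv(inputs["h3k27ac_manifest"], sep="\t")
        tss_table = pd.read_csv(inputs["tss"], sep="\t")
        se_stats = {}
        se_frames = []
        for rec in h3k_manifest.itertuples(index=False):
            peaks = superenhancer.read_peak_bed(rec.path)
            regions = superenhancer.stitch_peaks(peaks, config.stitch_distance)
            regions, cutoff = superenhancer.rank_regions(regions)
            ses = [r for r in regions if r.is_se]
            assignments = superenhancer.assign_se_to_tss(ses, tss_table, config.tss_window)
            se_frames.append(
                pd.DataFrame(
                    {
                        "stage": rec.stage,
                        "region_id": [r.region_id for r in regions],
                        "chrom": [r.chrom for r in regions],
                        "start": [r.start for r in regions],
                        "end": [r.end for r in regions],
                        "n_constituents": [r.n_constituents for r in regions],
                        "signal": [r.signal for r in regions],
                        "rank": [r.rank for r in regions],
                        "is_se": [r.is_se for r in regions],
                    }
                )
            )
            se_stats[rec.stage] = {
                "n_regions": len(regions),
                "n_se": len(ses),
                "cutoff": cutoff,
                "assigned": {
                    a.region_id: {"tss": a.tss_id, "class": a.tss_class, "distance": a.distance}
                    for a in assignments
                },
            }
        man.write_df(pd.concat(se_frames, ignore_index=True), "stitched_regions.tsv")
        stats["super_enhancers"] = se_stats
    except Exception as exc:
        raise RuntimeError(f"[superenhancer] {exc}") from exc

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
    man.add(summary_path)
    manifest = {"files": man.files, "summary": str(summary_path), "stats": stats}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps({"files": man.files + ["manifest.json"]}, indent=2) + "\n"
    )
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return manifest
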