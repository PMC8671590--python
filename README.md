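# agoclip

Analysis toolkit for **Ago HITS-CLIP** studies of miRNA targeting across
developmental stages: from aligned CLIP tags to Argonaute-binding clusters,
seed-match targetomes, stage-enriched miRNA expression groups, binding-site
motif enrichment, knockout CDF-shift validation, and super-enhancer
assignment to miRNA loci. A synthetic-data generator plants ground truth for
every stage of the pipeline, so the whole workflow is testable end to end
without downloads.

## Who it is for

Computational biologists analyzing Argonaute CLIP-seq (HITS-CLIP / CLIP-seq)
experiments — short sequencing tags marking in vivo Ago–RNA contacts — who
want a reproducible, scriptable route from aligned tags to a per-stage miRNA
targetome and its orthogonal validations.

## The methods at its core

- **Cluster calling.** Same-strand tags of one stage (replicates pooled) that
  overlap by ≥ 1 base are chained into clusters. Each cluster records its
  peak height *PH* = max per-base tag depth, the leftmost summit attaining
  it, and replicate support; defaults keep clusters with *PH* ≥ 5 supported
  by ≥ 2 replicates.
- **Seed-match scanning.** For a miRNA with seed *s₂₋₇* / *s₂₋₈*, the mRNA
  sense-strand match strings are 6mer = revcomp(*s₂₋₇*), 7mer-m8 =
  revcomp(*s₂₋₈*), 7mer-A1 = 6mer + A, 8mer = 7mer-m8 + A (TargetScan-style A
  anchor). At one seed locus the longest match wins. An interaction is a seed
  site of a stage-expressed miRNA inside an annotated Ago cluster.
- **Stage profiles.** Per-stage RPM (reads per million miRNA-mapped tags),
  log2 fold changes with a pseudocount, and hierarchical clustering of
  z-scored profiles (distance = 1 − Pearson *r*, average linkage, k = 5) into
  stage-enriched groups.
- **Motif enrichment.** Observed k-mer counts vs. dinucleotide-preserving
  shuffles (Altschul–Erickson Euler-walk): *z* = (obs − mean)/sd, enriched
  k-mers matched back to expressed-miRNA seed complements.
- **Knockout CDF shift.** One-sided two-sample Kolmogorov–Smirnov statistic
  *D* = supₓ [F_background(x) − F_targets(x)] on knockout-vs-WT log2 fold
  changes, with p = exp(−2D²mn/(m+n)) or an exact permutation tail for small
  samples. De-repressed targets shift right of the background CDF.
- **Super-enhancers (ROSE-style).** H3K27ac peaks within 12.5 kb are
  stitched; regions ranked by summed signal; on the rank/signal curve scaled
  to the unit square the cutoff is where a slope-1 line is tangent from
  below; regions above it are super-enhancers, assigned to the nearest
  gene/miRNA TSS within ± 100 kb.

## Worked example

Run the full pipeline on the default synthetic study (5 stages × 2
replicates, 80 genes, 25 miRNAs each enriched in one stage, planted seed
sites and super-enhancers):

```bash
agoclip run --seed 1 --outdir demo_out
```

or from Python, `agoclip.run_pipeline(config_from_dict({"rng_seed": 1,
"outdir": "demo_out"}))`. The summary (`demo_out/summary.json`) for seed 1
contains, among other readouts:

```
cluster_counts        {'e12.5': 20, 'e15.5': 20, 'e18.5': 20, 'P7': 20, 'adult': 28}
tag_modal_length      22 in every stage
feature_fractions     3UTR 0.74, CDS 0.18, 5UTR 0.08
stage_cluster_enriched  five groups labeled e12.5, e15.5, e18.5, P7, adult
ks.clip_target        D = 0.875, p = 1.9e-05 (m = 8 targets, n = 64 background)
```

Reading: each stage yields one cluster per planted site (the adult stage has
more because the knockout-focal miRNA carries extra targets); the tag length
mode reproduces the ~22 nt Ago footprint; cluster positions are 3'UTR-biased
as planted; the five expression groups recover the planted stage enrichment;
and the knocked-out miRNA's CLIP targets are significantly de-repressed
relative to background.

The `examples/` directory has one short script per capability (cluster
calling, annotation + targetome, stage profiles, motif enrichment, KO CDF
shift, super-enhancers), each printing the numbers it computes and what they
mean.

## Layout

- `src/agoclip/` — library modules (`synthetic`, `tags`, `annotate`,
  `targetome`, `profiles`, `motifs`, `koshift`, `superenhancer`, `pipeline`,
  `config`, `cli`)
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — models, parameters, numerical choices, limitations
- `tests/` — unit, property, and whole-pipeline tests
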