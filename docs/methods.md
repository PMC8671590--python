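# Methods

## Overview

`agoclip` implements the computational core of an Ago HITS-CLIP targetome
study: CLIP tags mark in vivo Argonaute–RNA contacts; overlapping tags define
Ago-binding clusters; seed complementarity inside clusters defines
miRNA–target interactions; miRNA abundance profiles define stage-enriched
expression groups; knockout expression shifts and H3K27ac super-enhancer
landscapes provide orthogonal validation and regulatory context. Because the
quantitative behavior of every stage depends on dataset scale, the package
ships a seeded synthetic-data generator whose planted ground truth makes all
recovery properties measurable.

## Cluster calling (`tags`)

Tags are strand-aware 0-based half-open intervals with stage and replicate
identity. Within one stage, replicates are pooled and same-strand tags are
chained by the transitive closure of ≥ 1-base overlap; bookended intervals
(gap 0) do not merge, per strict half-open semantics. Each cluster records
the union extent, tag count, peak height (maximum per-base depth, computed on
a coverage array), the leftmost summit attaining it, and replicate support
(replicates contributing ≥ 1 tag, computed on the pooled cluster).

Defaults `min_peak_height = 5`, `min_replicates = 2`. "High confidence" has
no universal definition for CLIP clusters; these values demand a visible pile
of tags reproduced in both biological replicates, and both are exposed in the
configuration. Duplicate tags are counted, not collapsed — PCR-duplicate
removal belongs to upstream preprocessing.

## Annotation (`annotate`)

Gene models come from GTF2.2/GFF3 via gffutils. Explicit UTR features are
honored; otherwise UTRs are derived as exonic sequence outside the CDS span,
oriented by strand; transcripts without CDS are treated as non-coding.
Clusters are annotated at the summit point: the depth maximum marks the
binding site, and point assignment makes multi-feature resolution
unambiguous. When the summit hits several features across overlapping
transcripts, priority is 3UTR > 5UTR > CDS > ncRNA_exon > intron — UTR-first
because 3'UTR clusters are the primary functional class in seed analysis. A
cluster must match the gene's strand to be genic; anything else (including
clusters on chromosomes absent from the annotation, which also warn) is
intergenic. Any transcript of any gene may claim a summit (union annotation
across transcript sources).

## Seed scanning and targetome (`targetome`)

Canonical site taxonomy, on the mRNA sense strand in DNA alphabet:
6mer = revcomp(seed 2–7), 7mer-m8 = revcomp(seed 2–8), 7mer-A1 = 6mer + "A",
8mer = 7mer-m8 + "A". The adenine anchor is required in the mRNA regardless
of the miRNA's first nucleotide (the TargetScan convention). All overlapping
occurrences are found; a seed locus is identified by the genomic placement of
its 6-nt core, and the longest match at a locus wins, so an 8mer is never
double-reported as its contained 7mers/6mer. Non-canonical sites (offset
seeds, G:U wobble, seedless) are out of scope.

Cluster sequences are extracted strand-aware from the indexed genome
(reverse-complemented for minus-strand genes) and scanned against the
miRNAs expressed in the cluster's stage. A target gene is any gene whose
annotated cluster hosts ≥ 1 site; identical rules apply in 5'UTR, CDS and
3'UTR, with the region label recorded. The pipeline's default expressed set
is miRNAs holding ≥ 1% of a stage's RPM: Ago-loaded miRNAs below that share
contribute negligibly to targeting and mostly add seed-match noise; the
threshold is configurable (`expressed_min_share`), and the seed-coverage
readout separately uses a top-N catalog (`top_n_coverage`, default 100).

## Stage profiles (`profiles`)

RPM_m,s = count_m,s / Σ_m count_m,s × 10⁶ (replicates summed first). RPM is
used rather than FPKM: mature miRNA lengths are nearly constant, so length
normalization is a constant factor. Stage log2 fold changes use a 1-RPM
pseudocount. For pattern clustering, profiles are z-scored per miRNA
(constant rows excluded with a warning), distance is 1 − Pearson correlation,
linkage is average, and the tree is cut at k = 5 groups by default — the
clustering targets expression *pattern*, not magnitude, hence the
scale-free distance. Each group is labeled with the stage at which its mean
z-profile peaks. Distance, linkage, and k are decisions, not data facts, and
are configurable.

## Motif enrichment (`motifs`)

For k ∈ [5, 8] (default 7, the seed-match length), observed overlapping
k-mer counts are compared with counts from per-sequence
dinucleotide-preserving shuffles (default 100). The shuffle is the
Altschul–Erickson construction: the sequence is an Eulerian path in its
dinucleotide multigraph; a random last-exit tree directed toward the terminal
character guarantees a valid Eulerian walk, all other out-edges are permuted.
Enrichment is z = (obs − mean)/sd with z := 0 when sd = 0 (a count the
shuffle cannot move is unenrichable); ties in z break lexicographically.
Enriched k-mers are matched to miRNAs whose seed-complement strings they
contain, restricted to the expressed set.

The z-score is an asymptotic summary: for k-mers observed only once or twice
in a small sequence set, the shuffle sd is tiny and noisy and z is
anti-conservative. Calibration (null z > 3 rate ≤ 1%) holds in the regime
the test is built for — hundreds of cluster sequences, as a real stage
targetome provides; with a few dozen sequences, rankings of well-observed
k-mers (such as a planted seed motif present in most sequences) remain
reliable, but tail z-values of singletons should not be read as significance.

## Knockout CDF shift (`koshift`)

Genes are partitioned into `clip_target` (≥ 1 Ago-bound seed site for the
miRNA, 3'UTR by default, CDS variant supported), `seed_only` (a seed match in
the full annotated 3'UTR but no CLIP evidence; CLIP dominates), and
`background` (the rest of the expression universe — background excludes both
evidence classes). The one-sided statistic for de-repression is
D = supₓ [F_background(x) − F_test(x)], evaluated with right-continuous ECDFs
at the pooled sample points (ties handled by the ECDF; no jitter).
P-values: asymptotic p = exp(−2D²mn/(m+n)), or, when m + n ≤ 16 (or on
request), the exact permutation tail P(D* ≥ D) over all C(m+n, m) label
assignments. The alternative is fixed so that "targets up in the knockout"
is the rejection direction, matching the biology of lost repression.

## Super-enhancers (`superenhancer`)

Peaks with gap ≤ 12,500 bp (boundary inclusive; ROSE's published default, no
TSS-exclusion zone) stitch into regions whose signal is the sum of
constituent scores, input-subtracted and floored at zero when a control
column is present. Regions are ranked ascending by signal; with rank/N and
signal/max both scaled to [0, 1], the cutoff is the rightmost minimizer of
scaled_signal − scaled_rank — the point where a line of slope 1 is tangent to
the curve from below. Regions strictly above the cutoff are super-enhancers.
The discrete tangent always exists, so some top fraction is flagged even for
unimodal signal distributions; the validated property is recovery of planted
high-signal regions, not the absence of calls elsewhere. Each SE is assigned
to the nearest TSS within ± 100 kb, distance measured from the region
boundary (0 inside), ties broken toward the miRNA class and then the smaller
coordinate.

## Synthetic data (`synthetic`)

The generator emulates the study design: 5 stages (e12.5, e15.5, e18.5, P7,
adult) × 2 biological replicates. Defaults (all in `SynthConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_chroms`, `chrom_length` | 2 × 500 kb | random A/C/G/T genome |
| `n_genes` | 80 | two-exon genes: 150 nt 5'UTR, 400+450 nt CDS, 300 nt intron, 700 nt 3'UTR |
| `n_mirnas` | 25 | 20–24 nt, distinct 7-nt seeds, each enriched in exactly one stage (round-robin) |
| `targets_per_mirna` / `ko_targets` | 4 / 12 | planted sites per miRNA; the focal (knockout) miRNA gets more, mirroring a dominant tissue miRNA |
| `region_weights` | 3UTR .7 / CDS .2 / 5UTR .1 | where sites are planted |
| `site_rate` | 50 | expected tags per active site per stage, Poisson, split over replicates; each site tag fully covers the site |
| `background_rate` | 0.5 /kb/strand/replicate | homogeneous Poisson background |
| tag length | ⌊N(22, 1.5)⌉ clipped to [18, 40] | reproduces the 22 nt modal Ago footprint |
| `off_stage_activity` | 0.02 | relative abundance of a miRNA outside its enriched stage |
| `ko_shift`, `ko_sigma` | 0.5, 0.35 | target log2FC ~ N(shift, σ), non-targets N(0, σ); ≈1.4 σ separation reflects strong direct-target de-repression at gene level |
| `se_fraction` | 0.1 | stitched H3K27ac regions planted as super-enhancers, each tied to a miRNA TSS (≤ 100 kb), high-signal Gamma component with 20× the low component's mean, active only in the miRNA's enriched stage |

Region anchors sit on a 25 kb grid so distinct planted regions can never
stitch together at the default distance. All outputs are pure functions of
(config, seed); each simulation draws from its own child seed stream, so
regenerating one output never perturbs another. Planted truth (sites, KO
targets, SE regions) is exported as TSVs.

What the generator does **not** emulate: crosslink-induced mutations or
truncations, mapping ambiguity and multimapping, PCR duplication, isomiRs,
non-canonical sites, overlapping gene models, chromatin input bias, and the
long-tailed abundance structure of a real miRNA transcriptome. Passing
recovery tests therefore demonstrates the correctness of the algorithms under
the stated noise models, not performance on real libraries; with real data
the thresholds (`min_peak_height`, `expressed_min_share`, k, stitching
distance) carry the burden the simulation's cleanliness removes here.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` exercise the default study (1 Mb
genome, 80 genes, 25 miRNAs, ~15k tags per stage) and scaled-down variants;
oracle-equivalence checks run 200–500 randomized instances against brute-force
reimplementations (per-base coverage scan, substring enumeration, exhaustive
KS permutation, quadratic gap chaining); recovery properties aggregate over
10–20 seeds. The whole suite runs in a few minutes on one CPU.

## Numerical and degenerate-input choices

- Length-histogram mode ties break to the smaller length; z-ordering ties in
  motif tables break lexicographically; cluster output is sorted by
  (chrom, start); all of these make outputs order-independent.
- Empty inputs raise explicit errors (`length_distribution`,
  `feature_distribution`, `seed_coverage_fraction`, KS samples, empty
  expression universe); degenerate-but-valid inputs degrade gracefully
  (all-equal H3K27ac signals → no SEs with a warning; sd = 0 k-mers → z = 0;
  constant expression profiles → excluded with a warning).
- KS p-values are clamped to (0, 1]; the exact path walks the pooled sorted
  sample and evaluates ECDF differences at tie-group right edges, which is
  equivalent to the sup over pooled points.
- log2FC uses a strictly positive pseudocount; antisymmetry is exact to
  floating tolerance.
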