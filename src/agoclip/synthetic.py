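"""Synthetic HITS-CLIP study generator with planted ground truth.

Builds a miniature liver-development study: a random genome with intron-
containing gene models and non-coding miRNA loci, a mature-miRNA catalog in
which each miRNA is enriched in exactly one of five developmental stages
(e12.5/e15.5/e18.5/P7/adult), seed-match target sites planted into gene
UTR/CDS sequence, CLIP tags piled over the planted sites (Poisson counts,
modal tag length 22 nt) on top of a uniform Poisson background, per-stage
Ago-bound miRNA counts, knockout log2 fold changes with a planted positive
shift for true targets, and a per-stage H3K27ac peak landscape in which a
minority of stitched regions near designated miRNA TSSs carry
disproportionately high signal.

Every output is a pure function of (config, rng_seed): identical configs
produce byte-identical files. Each simulation draws from its own child seed
stream so regenerating one output never perturbs another.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .targetome import MiRNA, seed_match_strings

__all__ = [
    "SynthConfig",
    "PlantedSite",
    "Reference",
    "generate_reference",
    "simulate_clip_tags",
    "simulate_mirna_counts",
    "simulate_ko_expression",
    "simulate_h3k27ac",
]

DEFAULT_STAGES = ("e12.5", "e15.5", "e18.5", "P7", "adult")

# gene structure (bases): 5'UTR, CDS exon, intron, CDS exon, 3'UTR
_UTR5_LEN, _CDS1_LEN, _INTRON_LEN, _CDS2_LEN, _UTR3_LEN = 150, 400, 300, 450, 700
_GENE_SPAN = _UTR5_LEN + _CDS1_LEN + _INTRON_LEN + _CDS2_LEN + _UTR3_LEN
_MIRNA_LOCUS_SPAN = 100
_ENTITY_GAP = 1_500
_CHROM_MARGIN = 1_000

TAG_LEN_MEAN, TAG_LEN_SD, TAG_LEN_MIN, TAG_LEN_MAX = 22.0, 1.5, 18, 40

_SITE_TYPE_WEIGHTS = {"8mer": 0.3, "7mer-m8": 0.3, "7mer-A1": 0.2, "6mer": 0.2}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generator.

    site_rate is the expected tag count per planted site per stage (pooled
    over replicates); background_rate is expected background tags per kb per
    strand per replicate file. ko_shift/ko_sigma parameterize the knockout
    log2FC model: targets ~ N(ko_shift, ko_sigma), non-targets ~ N(0,
    ko_sigma). se_fraction of stitched H3K27ac regions are planted as
    super-enhancers tied to miRNA loci.
    """

    rng_seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 80
    n_mirnas: int = 25
    n_stages: int = 5
    n_replicates: int = 2
    site_rate: float = 50.0
    background_rate: float = 0.5
    ko_shift: float = 0.5
    ko_sigma: float = 0.35
    se_fraction: float = 0.1
    targets_per_mirna: int = 4
    ko_targets: int = 12
    off_stage_activity: float = 0.02
    n_h3k27ac_regions: int = 36
    # where planted sites go, mirroring the 3'UTR-dominant functional class
    region_weights: tuple = (("3UTR", 0.7), ("CDS", 0.2), ("5UTR", 0.1))

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_mirnas", "n_stages", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.site_rate <= 0 or self.ko_sigma <= 0:
            raise ValueError("site_rate and ko_sigma must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        if not 0.0 <= self.se_fraction < 1.0:
            raise ValueError("se_fraction must lie in [0, 1)")
        if set(dict(self.region_weights)) - {"5UTR", "CDS", "3UTR"}:
            raise ValueError("region_weights keys must be 5UTR/CDS/3UTR")
        # planted sites must stand out over background coverage at the site
        mean_site_span = 7.0
        if self.site_rate <= self.background_rate * mean_site_span / 1000.0:
            raise ValueError("site_rate must exceed expected background tags per site")

    @property
    def stages(self) -> tuple[str, ...]:
        if self.n_stages == len(DEFAULT_STAGES):
            return DEFAULT_STAGES
        return tuple(f"stage{i + 1}" for i in range(self.n_stages))


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth seed site written into the synthetic genome."""

    mirna: str
    gene_id: str
    region: str  # 5UTR | CDS | 3UTR
    site_type: str
    chrom: str
    start: int  # 0-based half-open genomic interval of the match string
    end: int
    strand: str
    active_stages: tuple[str, ...]


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # gene span, 0-based half-open
    end: int
    utr5: tuple[int, int]
    cds1: tuple[int, int]
    intron: tuple[int, int]
    cds2: tuple[int, int]
    utr3: tuple[int, int]

    def region_interval(self, region: str) -> list[tuple[int, int]]:
        if region == "5UTR":
            return [self.utr5]
        if region == "3UTR":
            return [self.utr3]
        if region == "CDS":
            return [self.cds1, self.cds2]
        raise KeyError(region)


@dataclass
class Reference:
    """In-memory reference bundle plus the paths of the files written."""

    config: SynthConfig
    genome: dict[str, np.ndarray]  # chrom -> uint8 codes into "ACGT"
    genes: list[_Gene]
    catalog: list[MiRNA]
    enriched_stage: dict[str, str]
    mirna_tss: dict[str, tuple[str, int, str]]  # name -> (chrom, tss, strand)
    planted_sites: list[PlantedSite]
    genome_fasta: Path
    gtf: Path
    mirna_fasta: Path
    tss_tsv: Path

    def chrom_seq(self, chrom: str) -> str:
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        return bytes(lut[self.genome[chrom]]).decode("ascii")

    @property
    def stage_labels(self) -> tuple[str, ...]:
        return self.config.stages

    def tss_table(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            tss = g.start if g.strand == "+" else g.end - 1
            rows.append({"id": g.gene_id, "chrom": g.chrom, "position": tss,
                         "strand": g.strand, "class": "gene"})
        for name, (chrom, pos, strand) in self.mirna_tss.items():
            rows.append({"id": name, "chrom": chrom, "position": pos,
                         "strand": strand, "class": "miRNA"})
        return pd.DataFrame(rows, columns=["id", "chrom", "position", "strand", "class"])


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, stream])


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _place_entities(config: SynthConfig) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Sequential slot allocator: gene and miRNA-locus start positions."""
    slot = _GENE_SPAN + _ENTITY_GAP
    per_chrom = (config.chrom_length - 2 * _CHROM_MARGIN) // slot
    capacity = per_chrom * config.n_chroms
    needed = config.n_genes + config.n_mirnas
    if capacity < needed:
        raise ValueError(
            f"chrom_length={config.chrom_length} too small: {config.n_chroms} "
            f"chromosome(s) hold {capacity} loci of span {slot} bp but "
            f"{needed} are required (n_genes={config.n_genes} + "
            f"n_mirnas={config.n_mirnas})"
        )
    positions = []
    for i in range(needed):
        chrom = f"chr{i % config.n_chroms + 1}"
        idx = i // config.n_chroms
        positions.append((chrom, _CHROM_MARGIN + idx * slot))
    return positions[: config.n_genes], positions[config.n_genes :]


def _make_genes(config: SynthConfig, rng: np.random.Generator) -> list[_Gene]:
    genes = []
    for i, (chrom, start) in enumerate(_place_entities(config)[0]):
        strand = "+" if rng.integers(2) == 0 else "-"
        # genomic block order; 5'UTR is the strand-upstream block
        b0 = (start, start + _UTR5_LEN)
        b1 = (b0[1], b0[1] + _CDS1_LEN)
        b2 = (b1[1], b1[1] + _INTRON_LEN)
        b3 = (b2[1], b2[1] + _CDS2_LEN)
        b4 = (b3[1], b3[1] + _UTR3_LEN)
        if strand == "+":
            utr5, cds1, intron, cds2, utr3 = b0, b1, b2, b3, b4
        else:
            utr3, cds2, intron, cds1, utr5 = b0, b1, b2, b3, b4
        genes.append(
            _Gene(
                gene_id=f"gene{i + 1:04d}", chrom=chrom, strand=strand,
                start=start, end=b4[1],
                utr5=utr5, cds1=cds1, intron=intron, cds2=cds2, utr3=utr3,
            )
        )
    return genes


def _make_catalog(config: SynthConfig, rng: np.random.Generator) -> list[MiRNA]:
    catalog: list[MiRNA] = []
    seen_seeds: set[str] = set()
    alphabet = np.array(list("ACGU"))
    while len(catalog) < config.n_mirnas:
        length = int(rng.integers(20, 25))
        seq = "".join(alphabet[rng.integers(0, 4, size=length)])
        if seq[1:8] in seen_seeds:  # distinct seed7 keeps planted truth unambiguous
            continue
        seen_seeds.add(seq[1:8])
        catalog.append(MiRNA(name=f"syn-mir-{len(catalog) + 1}", sequence=seq))
    return catalog


_DNA_COMP = str.maketrans("ACGT", "TGCA")


def _plant_sites(
    config: SynthConfig,
    rng: np.random.Generator,
    genome: dict[str, np.ndarray],
    genes: list[_Gene],
    catalog: list[MiRNA],
    enriched_stage: dict[str, str],
) -> list[PlantedSite]:
    """Write seed-match strings into gene sequence and record the truth."""
    base_code = {b: i for i, b in enumerate("ACGT")}
    occupied: dict[str, list[tuple[int, int]]] = {g.gene_id: [] for g in genes}
    sites: list[PlantedSite] = []
    if not genes:
        return sites
    for mir in catalog:
        n_targets = min(
            config.ko_targets if mir is catalog[-1] else config.targets_per_mirna,
            len(genes),
        )
        gene_idx = rng.choice(len(genes), size=n_targets, replace=False)
        strings = seed_match_strings(mir)
        for gi in gene_idx:
            gene = genes[gi]
            region = _weighted_choice(rng, dict(config.region_weights))
            site_type = _weighted_choice(rng, _SITE_TYPE_WEIGHTS)
            match = strings[site_type]
            placed = False
            for _ in range(40):
                block = gene.region_interval(region)[
                    int(rng.integers(len(gene.region_interval(region))))
                ]
                lo, hi = block
                if hi - lo < len(match) + 4:
                    continue
                start = int(rng.integers(lo + 2, hi - len(match) - 1))
                end = start + len(match)
                if any(s < end and start < e for s, e in occupied[gene.gene_id]):
                    continue
                # write the transcript-sense match into the + strand genome
                inserted = match if gene.strand == "+" else match.translate(_DNA_COMP)[::-1]
                genome[gene.chrom][start:end] = [base_code[b] for b in inserted]
                occupied[gene.gene_id].append((start, end))
                sites.append(
                    PlantedSite(
                        mirna=mir.name, gene_id=gene.gene_id, region=region,
                        site_type=site_type, chrom=gene.chrom, start=start,
                        end=end, strand=gene.strand,
                        active_stages=(enriched_stage[mir.name],),
                    )
                )
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a site for {mir.name} in {gene.gene_id}"
                )
    return sites


def _write_fasta(path: Path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_gtf(path: Path, genes: list[_Gene], mirna_tss: dict[str, tuple[str, int, str]]) -> None:
    """GTF2.2, 1-based inclusive coordinates; miRNA loci as non-coding exons."""

    def row(chrom, feature, start, end, strand, gid, tid):
        attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
        return f"{chrom}\tsynth\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"

    with open(path, "w") as fh:
        for g in genes:
            tid = g.gene_id + ".t1"
            fh.write(row(g.chrom, "gene", g.start, g.end, g.strand, g.gene_id, tid))
            fh.write(row(g.chrom, "transcript", g.start, g.end, g.strand, g.gene_id, tid))
            blocks = sorted([g.utr5, g.cds1, g.cds2, g.utr3])
            exon1 = (blocks[0][0], blocks[1][1])
            exon2 = (blocks[2][0], blocks[3][1])
            for ex in (exon1, exon2):
                fh.write(row(g.chrom, "exon", ex[0], ex[1], g.strand, g.gene_id, tid))
            for cds in (g.cds1, g.cds2):
                fh.write(row(g.chrom, "CDS", cds[0], cds[1], g.strand, g.gene_id, tid))
            fh.write(row(g.chrom, "five_prime_utr", g.utr5[0], g.utr5[1], g.strand, g.gene_id, tid))
            fh.write(row(g.chrom, "three_prime_utr", g.utr3[0], g.utr3[1], g.strand, g.gene_id, tid))
        for name, (chrom, pos, strand) in mirna_tss.items():
            tid = name + ".t1"
            end = pos + _MIRNA_LOCUS_SPAN if strand == "+" else pos + 1
            start = pos if strand == "+" else pos + 1 - _MIRNA_LOCUS_SPAN
            fh.write(row(chrom, "gene", start, end, strand, name, tid))
            fh.write(row(chrom, "transcript", start, end, strand, name, tid))
            fh.write(row(chrom, "exon", start, end, strand, name, tid))


def generate_reference(config: SynthConfig, outdir: str | os.PathLike) -> Reference:
    """Generate and write the reference bundle (genome, gene models, miRNA
    catalog, TSS table) with planted seed sites."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 0)

    genome = {
        f"chr{i + 1}": rng.integers(0, 4, size=config.chrom_length, dtype=np.uint8)
        for i in range(config.n_chroms)
    }
    genes = _make_genes(config, rng)
    catalog = _make_catalog(config, rng)
    stages = config.stages
    # round-robin so every stage hosts ~n_mirnas/n_stages enriched miRNAs
    enriched = {m.name: stages[i % len(stages)] for i, m in enumerate(catalog)}
    mirna_positions = _place_entities(config)[1]
    mirna_tss = {}
    for m, (chrom, start) in zip(catalog, mirna_positions):
        mirna_tss[m.name] = (chrom, start, "+")
    planted = _plant_sites(config, rng, genome, genes, catalog, enriched)

    ref = Reference(
        config=config, genome=genome, genes=genes, catalog=catalog,
        enriched_stage=enriched, mirna_tss=mirna_tss, planted_sites=planted,
        genome_fasta=outdir / "genome.fa", gtf=outdir / "genes.gtf",
        mirna_fasta=outdir / "mirnas.fa", tss_tsv=outdir / "tss.tsv",
    )
    _write_fasta(ref.genome_fasta, [(c, ref.chrom_seq(c)) for c in sorted(genome)])
    fai = Path(str(ref.genome_fasta) + ".fai")
    if fai.exists():  # stale index from a previous bundle in the same directory
        fai.unlink()
    _write_gtf(ref.gtf, genes, mirna_tss)
    _write_fasta(ref.mirna_fasta, [(m.name, m.sequence) for m in catalog])
    ref.tss_table().to_csv(ref.tss_tsv, sep="\t", index=False)
    return ref


def _draw_tag_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    raw = np.rint(rng.normal(TAG_LEN_MEAN, TAG_LEN_SD, size=n))
    return np.clip(raw, TAG_LEN_MIN, TAG_LEN_MAX).astype(int)


def simulate_clip_tags(
    reference: Reference, outdir: str | os.PathLike
) -> tuple[dict[tuple[str, int], Path], Path]:
    """Simulate per-(stage, replicate) CLIP tag BED6 files plus the truth TSV.

    Tag counts at a planted site are Poisson(site_rate x stage activity)
    pooled over replicates (activity is 1 in the site's active stages, else
    0); each site tag fully covers the planted interval. Background tags form
    a homogeneous Poisson process per strand at background_rate per kb per
    replicate file. Tag lengths follow the discretized Normal(22, 1.5)
    clipped to [18, 40], so the modal length is 22 nt.
    """
    config = reference.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 1)
    chrom_lengths = {c: len(seq) for c, seq in reference.genome.items()}

    paths: dict[tuple[str, int], Path] = {}
    for stage in config.stages:
        for rep in range(1, config.n_replicates + 1):
            rows = []
            for site in reference.planted_sites:
                activity = 1.0 if stage in site.active_stages else 0.0
                lam = config.site_rate * activity / config.n_replicates
                n = int(rng.poisson(lam)) if lam > 0 else 0
                if n == 0:
                    continue
                lengths = _draw_tag_lengths(rng, n)
                span = site.end - site.start
                for ln in lengths:
                    lo = site.end - int(ln)
                    hi = site.start  # inclusive; tag covers the whole site
                    start = int(rng.integers(lo, hi + 1)) if ln > span else site.start
                    start = max(0, min(start, chrom_lengths[site.chrom] - int(ln)))
                    rows.append((site.chrom, start, start + int(ln), site.strand))
            for chrom, clen in sorted(chrom_lengths.items()):
                for strand in "+-":
                    n_bg = int(rng.poisson(config.background_rate * clen / 1000.0))
                    if n_bg == 0:
                        continue
                    lengths = _draw_tag_lengths(rng, n_bg)
                    starts = rng.integers(0, clen - lengths)
                    for start, ln in zip(starts, lengths):
                        rows.append((chrom, int(start), int(start) + int(ln), strand))
            rows.sort()
            path = outdir / f"tags_{stage}_rep{rep}.bed"
            with open(path, "w") as fh:
                for i, (chrom, start, end, strand) in enumerate(rows):
                    fh.write(f"{chrom}\t{start}\t{end}\ttag{i:06d}\t1\t{strand}\n")
            paths[(stage, rep)] = path

    truth_path = outdir / "planted_sites.tsv"
    truth = pd.DataFrame(
        [
            {
                "mirna": s.mirna, "gene_id": s.gene_id, "region": s.region,
                "site_type": s.site_type, "chrom": s.chrom, "start": s.start,
                "end": s.end, "strand": s.strand,
                "active_stages": ",".join(s.active_stages),
            }
            for s in reference.planted_sites
        ],
        columns=["mirna", "gene_id", "region", "site_type", "chrom", "start",
                 "end", "strand", "active_stages"],
    )
    truth.to_csv(truth_path, sep="\t", index=False)
    return paths, truth_path


def simulate_mirna_counts(reference: Reference, outdir: str | os.PathLike) -> Path:
    """Per-miRNA Ago-bound tag counts (mirna, stage, replicate, count).

    Each miRNA has a log-normal baseline abundance, expressed at full level in
    its enriched stage and at off_stage_activity elsewhere; counts are Poisson.
    """
    config = reference.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 2)
    base = {m.name: rng.lognormal(np.log(2000.0), 1.0) for m in reference.catalog}
    rows = []
    for m in reference.catalog:
        for stage in config.stages:
            act = 1.0 if reference.enriched_stage[m.name] == stage else config.off_stage_activity
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "mirna": m.name, "stage": stage, "replicate": rep,
                        "count": int(rng.poisson(base[m.name] * act)),
                    }
                )
    path = outdir / "mirna_counts.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def simulate_ko_expression(
    reference: Reference,
    outdir: str | os.PathLike,
    ko_mirna: str | None = None,
    regions: tuple[str, ...] = ("3UTR",),
) -> tuple[Path, str]:
    """Gene-level log2FC table for a miRNA knockout vs wild type.

    True targets (genes with a planted site for the knocked-out miRNA in the
    given regions) are drawn from Normal(ko_shift, ko_sigma); all other genes
    from Normal(0, ko_sigma). Default knockout is the catalog's focal miRNA
    (the last one, which carries ko_targets planted target genes).
    """
    config = reference.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 3)
    if ko_mirna is None:
        ko_mirna = reference.catalog[-1].name
    known = {m.name for m in reference.catalog}
    if ko_mirna not in known:
        raise ValueError(f"unknown miRNA {ko_mirna!r} named in truth")
    gene_ids = [g.gene_id for g in reference.genes]
    gene_set = set(gene_ids)
    targets = set()
    for s in reference.planted_sites:
        if s.mirna == ko_mirna and s.region in regions:
            if s.gene_id not in gene_set:
                raise ValueError(f"truth references unknown gene {s.gene_id!r}")
            targets.add(s.gene_id)
    rows = []
    for gid in gene_ids:
        mean = config.ko_shift if gid in targets else 0.0
        rows.append({"gene_id": gid, "log2fc": float(rng.normal(mean, config.ko_sigma))})
    path = outdir / f"ko_{ko_mirna}_log2fc.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path, ko_mirna


def simulate_h3k27ac(
    reference: Reference, outdir: str | os.PathLike
) -> tuple[dict[str, Path], Path]:
    """Per-stage H3K27ac peak BED files plus the planted super-enhancer truth.

    Stitched-region anchors sit on a 20 kb grid so regions never merge at the
    default 12.5 kb stitching distance. A fraction se_fraction of regions are
    planted as SEs: each is tied to one designated miRNA, placed at the grid
    anchor nearest that miRNA's TSS (always within +/-100 kb), and carries
    constituent signal from a Gamma component whose mean is 20x the low
    component's in the miRNA's enriched stage; all other (region, stage)
    signals come from the low component.
    """
    config = reference.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 4)

    # grid spacing > max region span (10.6 kb) + stitch distance (12.5 kb) so
    # distinct planted regions can never stitch together
    grid = 25_000
    anchors = []
    for chrom, clen in sorted((c, len(s)) for c, s in reference.genome.items()):
        pos = 5_000
        while pos + 12_000 < clen:
            anchors.append((chrom, pos))
            pos += grid
    n_regions = min(config.n_h3k27ac_regions, len(anchors))
    n_se = int(round(config.se_fraction * n_regions))

    mirna_names = [m.name for m in reference.catalog]
    se_mirnas = mirna_names[:n_se] if n_se <= len(mirna_names) else mirna_names
    free = list(anchors)
    se_anchor: dict[str, tuple[str, int]] = {}
    for name in se_mirnas:
        chrom, tss, _ = reference.mirna_tss[name]
        candidates = [a for a in free if a[0] == chrom and abs(a[1] - tss) <= 100_000]
        if not candidates:
            raise RuntimeError(f"no free H3K27ac anchor within 100 kb of {name} TSS")
        best = min(candidates, key=lambda a: (abs(a[1] - tss), a[1]))
        se_anchor[name] = best
        free.remove(best)
    order = rng.permutation(len(free))
    background_anchors = [free[i] for i in order[: n_regions - len(se_anchor)]]

    regions = []  # (chrom, anchor, constituents, se_mirna or "")
    for name in se_mirnas:
        regions.append((se_anchor[name][0], se_anchor[name][1], name))
    for chrom, pos in background_anchors:
        regions.append((chrom, pos, ""))
    layout = []
    for chrom, pos, se_mirna in regions:
        n_peaks = int(rng.integers(1, 4))
        peaks = []
        cursor = pos
        for _ in range(n_peaks):
            width = int(rng.integers(800, 1_200))
            peaks.append((cursor, cursor + width))
            cursor += width + int(rng.integers(1_500, 3_500))
        layout.append((chrom, peaks, se_mirna))

    stage_paths: dict[str, Path] = {}
    for stage in config.stages:
        rows = []
        for chrom, peaks, se_mirna in layout:
            active = bool(se_mirna) and reference.enriched_stage[se_mirna] == stage
            for (s, e) in peaks:
                scale = 100.0 if active else 5.0  # 20x separation of means
                score = float(rng.gamma(2.0, scale))
                rows.append((chrom, s, e, score))
        rows.sort()
        path = outdir / f"h3k27ac_{stage}.bed"
        with open(path, "w") as fh:
            for i, (chrom, s, e, score) in enumerate(rows):
                fh.write(f"{chrom}\t{s}\t{e}\tpeak{i:05d}\t{score:.4f}\t.\n")
        stage_paths[stage] = path

    truth_rows = []
    for chrom, peaks, se_mirna in layout:
        truth_rows.append(
            {
                "chrom": chrom, "start": peaks[0][0], "end": peaks[-1][1],
                "n_constituents": len(peaks), "is_se": bool(se_mirna),
                "mirna": se_mirna,
                "active_stage": reference.enriched_stage[se_mirna] if se_mirna else "",
            }
        )
    truth = pd.DataFrame(truth_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    truth_path = outdir / "h3k27ac_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return stage_paths, truth_path
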