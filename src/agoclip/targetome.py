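"""miRNA seed-match scanning and targetome construction.

Canonical site taxonomy on the mRNA sense strand (DNA alphabet):

===========  ====================================================
site type    match string (5'->3' in the mRNA)
===========  ====================================================
6mer         reverse complement of miRNA positions 2-7 (seed6)
7mer-m8      reverse complement of positions 2-8 (seed7)
7mer-A1      revcomp(seed6) followed by an A anchor
8mer         revcomp(seed7) followed by an A anchor
===========  ====================================================

The A anchor is required in the mRNA regardless of the miRNA's position-1
identity (TargetScan-style). At one seed locus the longest match wins:
8mer > 7mer-m8 > 7mer-A1 > 6mer; a locus is identified by the genomic
placement of its 6-nt seed core so an 8mer is never double-reported as the
7mers/6mer it contains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "MiRNA",
    "SeedSite",
    "Interaction",
    "seed_match_strings",
    "scan_sequence",
    "build_targetome",
    "seed_coverage_fraction",
    "compare_target_sets",
    "read_mirna_fasta",
]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
# dominance used for per-locus resolution: longer match wins
_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

_RNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "U": "A"}
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA: name and 5'->3' sequence over {A,C,G,U}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise ValueError(f"{self.name}: mature sequence shorter than 8 nt")
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise ValueError(
                f"{self.name}: non-ACGU characters {sorted(bad)} in mature sequence"
            )

    @property
    def seed6(self) -> str:
        """Positions 2-7 (1-based) of the mature sequence."""
        return self.sequence[1:7]

    @property
    def seed7(self) -> str:
        """Positions 2-8 (1-based)."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class SeedSite:
    site_type: str
    offset: int  # offset of the full match string within the scanned sequence
    matched: str


@dataclass(frozen=True)
class Interaction:
    """One miRNA -> Ago cluster seed-match record."""

    mirna: str
    gene_id: str
    cluster_id: str
    region: str
    site_type: str
    stage: str


def _revcomp_rna_to_dna(seed: str) -> str:
    """Reverse complement of an RNA seed, written in DNA (the mRNA sense strand)."""
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(seed))


def seed_match_strings(mirna: MiRNA) -> dict[str, str]:
    """DNA match strings (mRNA sense, 5'->3') for all four canonical site types."""
    core6 = _revcomp_rna_to_dna(mirna.seed6)
    core7 = _revcomp_rna_to_dna(mirna.seed7)
    return {
        "6mer": core6,
        "7mer-m8": core7,
        "7mer-A1": core6 + "A",
        "8mer": core7 + "A",
    }


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return
        yield i
        start = i + 1  # overlapping occurrences count


def scan_sequence(seq: str, catalog: Sequence[MiRNA]) -> dict[str, list[SeedSite]]:
    """Find all canonical seed sites of each catalog miRNA in a sense-strand
    DNA sequence.

    Overlapping occurrences are reported; at one seed locus only the longest
    site type survives. Sites are returned in left-to-right order per miRNA.
    """
    seq = seq.upper()
    out: dict[str, list[SeedSite]] = {}
    for mir in catalog:
        strings = seed_match_strings(mir)
        # locus key = position of the 6-nt seed core within seq
        best: dict[int, SeedSite] = {}
        for site_type in SITE_TYPES:  # scanned in dominance order
            match = strings[site_type]
            core_shift = 1 if site_type in ("8mer", "7mer-m8") else 0
            for off in _find_all(seq, match):
                locus = off + core_shift
                if locus not in best:
                    best[locus] = SeedSite(site_type, off, match)
        sites = sorted(best.values(), key=lambda s: (s.offset, _SITE_RANK[s.site_type]))
        if sites:
            out[mir.name] = sites
    return out


def _revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_DNA_COMPLEMENT)[::-1]


def cluster_sequence(genome: Fasta, chrom: str, start: int, end: int, strand: str) -> str:
    """Extract a cluster's transcript-sense sequence (reverse complement for '-')."""
    if chrom not in genome:
        raise ValueError(f"chromosome {chrom!r} absent from genome FASTA")
    chrom_len = len(genome[chrom])
    if start < 0 or end > chrom_len:
        raise ValueError(
            f"interval {chrom}:{start}-{end} outside chromosome bounds (0-{chrom_len})"
        )
    seq = str(genome[chrom][start:end]).upper()
    return _revcomp_dna(seq) if strand == "-" else seq


def build_targetome(
    labeled_clusters: pd.DataFrame,
    genome: Fasta,
    catalog: Sequence[MiRNA],
    expressed: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Scan annotated cluster sequences for seed sites of stage-expressed miRNAs.

    Parameters
    ----------
    labeled_clusters
        Table with columns chrom, start, end, strand, stage, name (cluster id),
        feature (region label) and gene_id; only genic mRNA regions
        (5UTR/CDS/3UTR) are scanned.
    genome
        Indexed genome FASTA.
    catalog
        Mature miRNA catalog.
    expressed
        Mapping stage -> iterable of miRNA names considered expressed there.

    Returns an Interaction table (mirna, gene_id, cluster_id, region,
    site_type, stage, offset) with one row per (miRNA, cluster, locus-best
    site).
    """
    by_name = {m.name: m for m in catalog}
    rows = []
    for rec in labeled_clusters.itertuples(index=False):
        if rec.feature not in ("5UTR", "CDS", "3UTR"):
            continue
        stage_mirnas = [by_name[n] for n in expressed.get(rec.stage, ()) if n in by_name]
        if not stage_mirnas:
            continue
        seq = cluster_sequence(genome, rec.chrom, int(rec.start), int(rec.end), rec.strand)
        for mir_name, sites in scan_sequence(seq, stage_mirnas).items():
            for site in sites:
                rows.append(
                    {
                        "mirna": mir_name,
                        "gene_id": rec.gene_id,
                        "cluster_id": rec.name,
                        "region": rec.feature,
                        "site_type": site.site_type,
                        "stage": rec.stage,
                        "offset": site.offset,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["mirna", "gene_id", "cluster_id", "region", "site_type", "stage", "offset"],
    )


def target_genes(
    interactions: pd.DataFrame,
    mirna: str,
    regions: Sequence[str] | None = None,
    stages: Sequence[str] | None = None,
) -> set[str]:
    """Genes hosting >=1 site for a miRNA, optionally restricted by region/stage."""
    sub = interactions[interactions["mirna"] == mirna]
    if regions is not None:
        sub = sub[sub["region"].isin(regions)]
    if stages is not None:
        sub = sub[sub["stage"].isin(stages)]
    return set(sub["gene_id"])


def seed_coverage_fraction(
    cluster_seqs: Sequence[str], catalog_subset: Sequence[MiRNA]
) -> float:
    """Fraction of cluster sequences containing >=1 seed site for the subset."""
    if len(cluster_seqs) == 0:
        raise ValueError("seed_coverage_fraction requires at least one cluster")
    if not catalog_subset:
        return 0.0
    hit = sum(1 for seq in cluster_seqs if scan_sequence(seq, catalog_subset))
    return hit / len(cluster_seqs)


def compare_target_sets(set_a: set, set_b: set) -> dict:
    """Overlap counts and per-set overlap fractions between two gene sets."""
    inter = set_a & set_b
    return {
        "intersection": len(inter),
        "a_only": len(set_a - set_b),
        "b_only": len(set_b - set_a),
        "fraction_of_a": len(inter) / len(set_a) if set_a else 0.0,
        "fraction_of_b": len(inter) / len(set_b) if set_b else 0.0,
    }


def read_mirna_fasta(path) -> list[MiRNA]:
    """Read a mature-miRNA FASTA (RNA alphabet; T tolerated and converted to U)."""
    catalog = []
    name, seq = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    catalog.append(MiRNA(name, "".join(seq).upper().replace("T", "U")))
                name = line[1:].split()[0]
                seq = []
            elif line:
                seq.append(line)
    if name is not None:
        catalog.append(MiRNA(name, "".join(seq).upper().replace("T", "U")))
    return catalog
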