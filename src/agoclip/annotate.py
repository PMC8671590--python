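"""Cluster annotation against gene models.

Each Ago cluster is assigned to exactly one transcript feature at its summit:
the per-base depth maximum marks the binding site, so point assignment is both
biologically motivated and unambiguous. When the summit falls in several
features across overlapping transcripts the default priority is
3UTR > 5UTR > CDS > ncRNA_exon > intron (UTR-first because the seed analysis
treats 3'UTR clusters as the primary functional class); a cluster must lie on
the gene's strand to be genic, otherwise it is intergenic.

Gene models are read from GTF2.2/GFF3 via gffutils. Explicit UTR features are
used when present; otherwise UTRs are derived as exonic sequence outside the
CDS span, split by transcript orientation. Transcripts without CDS are treated
as non-coding and their exons labeled ncRNA_exon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .tags import Cluster

__all__ = ["GeneModel", "FeatureIndex", "annotate_clusters", "feature_distribution", "load_gene_models"]

logger = logging.getLogger(__name__)

FEATURE_LABELS = ("3UTR", "5UTR", "CDS", "ncRNA_exon", "intron", "intergenic")
# summit-hit resolution order (lower index wins)
_PRIORITY = {label: i for i, label in enumerate(FEATURE_LABELS)}

_UTR5_TYPES = {"five_prime_utr", "5UTR", "five_prime_UTR"}
_UTR3_TYPES = {"three_prime_utr", "3UTR", "three_prime_UTR"}


@dataclass
class GeneModel:
    """One transcript's feature intervals, 0-based half-open, strand-resolved."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    introns: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)


def _subtract(intervals: list[tuple[int, int]], span: tuple[int, int]) -> list[tuple[int, int]]:
    """Parts of each interval outside the closed span."""
    lo, hi = span
    out = []
    for s, e in intervals:
        if e <= lo or s >= hi:
            out.append((s, e))
        else:
            if s < lo:
                out.append((s, lo))
            if e > hi:
                out.append((hi, e))
    return out


def _derive_structure(model: GeneModel) -> None:
    """Fill introns and, when absent, UTRs from exon/CDS geometry."""
    exons = sorted(model.exons)
    model.introns = [
        (exons[i][1], exons[i + 1][0])
        for i in range(len(exons) - 1)
        if exons[i + 1][0] > exons[i][1]
    ]
    if not model.is_coding or (model.utr5 or model.utr3):
        return
    cds_lo = min(s for s, _ in model.cds)
    cds_hi = max(e for _, e in model.cds)
    outside = _subtract(exons, (cds_lo, cds_hi))
    left = [iv for iv in outside if iv[1] <= cds_lo]
    right = [iv for iv in outside if iv[0] >= cds_hi]
    if model.strand == "+":
        model.utr5, model.utr3 = left, right
    else:
        model.utr5, model.utr3 = right, left


def load_gene_models(gtf_path) -> list[GeneModel]:
    """Parse a GTF/GFF3 file into per-transcript GeneModels."""
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: dict[str, GeneModel] = {}
    for feat in db.all_features():
        ftype = feat.featuretype
        if ftype in ("gene", "transcript", "mRNA"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ValueError(
                f"{gtf_path}: feature at {feat.seqid}:{feat.start} lacks "
                f"gene_id/transcript_id attributes"
            ) from exc
        model = models.get(tid)
        if model is None:
            model = models[tid] = GeneModel(
                gene_id=gid, transcript_id=tid, chrom=feat.seqid,
                strand=feat.strand, exons=[],
            )
        iv = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> half-open
        if ftype == "exon":
            model.exons.append(iv)
        elif ftype == "CDS":
            model.cds.append(iv)
        elif ftype in _UTR5_TYPES:
            model.utr5.append(iv)
        elif ftype in _UTR3_TYPES:
            model.utr3.append(iv)
    result = list(models.values())
    for m in result:
        _derive_structure(m)
    return result


class FeatureIndex:
    """Interval index over (chrom, strand) for summit lookup."""

    def __init__(self, models: list[GeneModel]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for m in models:
            tree = self._trees.setdefault((m.chrom, m.strand), IntervalTree())
            if m.is_coding:
                labeled = [("5UTR", m.utr5), ("CDS", m.cds), ("3UTR", m.utr3),
                           ("intron", m.introns)]
            else:
                labeled = [("ncRNA_exon", m.exons), ("intron", m.introns)]
            for label, ivs in labeled:
                for s, e in ivs:
                    if s < e:
                        tree.addi(s, e, (label, m.gene_id))

    @property
    def chroms(self) -> set[str]:
        return {chrom for chrom, _ in self._trees}

    def lookup(self, chrom: str, strand: str, pos: int) -> tuple[str, str]:
        """(label, gene_id) of the best feature at a point; intergenic if none."""
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return "intergenic", ""
        hits = sorted(
            (( _PRIORITY[lab], gid) for _, _, (lab, gid) in tree.at(pos)),
        )
        if not hits:
            return "intergenic", ""
        prio, gid = hits[0]
        return FEATURE_LABELS[prio], gid


def annotate_clusters(
    clusters: list[Cluster] | pd.DataFrame,
    models: list[GeneModel] | FeatureIndex,
) -> pd.DataFrame:
    """Label every cluster with one transcript feature at its summit.

    Returns a table with the cluster fields plus `feature` and `gene_id`
    (empty string for intergenic). Cluster chromosomes absent from the gene
    models produce a warning and the intergenic label.
    """
    index = models if isinstance(models, FeatureIndex) else FeatureIndex(models)
    if isinstance(clusters, pd.DataFrame):
        df = clusters.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "chrom": c.chrom, "start": c.start, "end": c.end,
                    "name": f"cluster_{c.stage}_{i}", "score": c.peak_height,
                    "strand": c.strand, "stage": c.stage, "tag_count": c.tag_count,
                    "summit": c.summit, "replicate_support": c.replicate_support,
                }
                for i, c in enumerate(clusters)
            ]
        )
    missing = set(df["chrom"]) - index.chroms if len(df) else set()
    if missing:
        warnings.warn(
            f"chromosomes absent from gene models, labeled intergenic: {sorted(missing)}",
            stacklevel=2,
        )
    labels, gene_ids = [], []
    for rec in df.itertuples(index=False):
        label, gid = index.lookup(rec.chrom, rec.strand, int(rec.summit))
        labels.append(label)
        gene_ids.append(gid)
    df["feature"] = labels
    df["gene_id"] = gene_ids
    return df


def feature_distribution(labeled: pd.DataFrame) -> dict[str, float]:
    """Fraction of clusters per feature label (sums to 1)."""
    if len(labeled) == 0:
        raise ValueError("feature_distribution requires at least one labeled cluster")
    counts = labeled["feature"].value_counts()
    total = int(counts.sum())
    return {label: float(counts.get(label, 0)) / total for label in FEATURE_LABELS}
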