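"""CLIP tag processing: tag QC and Ago-binding cluster calling.

HITS-CLIP tags are short (modal length ~22 nt) strand-aware intervals marking
in vivo Argonaute--RNA contacts. Overlapping same-strand tags from one
developmental stage are grouped into clusters; each cluster carries its peak
height (maximum per-base tag depth), the summit attaining it, and the number
of biological replicates contributing tags. Clusters failing a minimum peak
height or replicate support are discarded as low-confidence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlignedTag",
    "Cluster",
    "length_distribution",
    "call_clusters",
    "read_tag_bed",
    "write_cluster_bed",
]

TAG_LENGTH_RANGE = (15, 60)


@dataclass(frozen=True)
class AlignedTag:
    """One aligned CLIP tag (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    strand: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed tag interval {self.chrom}:{self.start}-{self.end} "
                f"(start >= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Cluster:
    """A merged Ago-binding region.

    peak_height is the maximum per-base tag depth (PH); summit is the leftmost
    genomic position attaining it; replicate_support counts replicates that
    contributed at least one tag.
    """

    chrom: str
    start: int
    end: int
    strand: str
    stage: str
    tag_count: int
    peak_height: int
    summit: int
    replicate_support: int

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit outside cluster bounds")
        if self.peak_height > self.tag_count:
            raise ValueError("peak_height cannot exceed tag_count")


def length_distribution(tags: Sequence[AlignedTag]) -> tuple[dict[int, int], int]:
    """Histogram of tag lengths and the modal length.

    Ties in the histogram break toward the smaller length. Raises ValueError
    on empty input.
    """
    if len(tags) == 0:
        raise ValueError("length_distribution requires at least one tag")
    hist = Counter(t.length for t in tags)
    mode = min(hist, key=lambda ln: (-hist[ln], ln))
    return dict(sorted(hist.items())), mode


def _chain_overlapping(tags: list[AlignedTag]) -> list[list[AlignedTag]]:
    """Partition sorted same-chrom/strand tags into overlap-connected chains.

    Two tags join one chain iff connected by a chain of >=1-base overlaps;
    bookended intervals (gap 0, no shared base) do not merge.
    """
    groups: list[list[AlignedTag]] = []
    current: list[AlignedTag] = []
    current_end = -1
    for tag in sorted(tags, key=lambda t: (t.start, t.end)):
        if current and tag.start < current_end:
            current.append(tag)
            current_end = max(current_end, tag.end)
        else:
            if current:
                groups.append(current)
            current = [tag]
            current_end = tag.end
    if current:
        groups.append(current)
    return groups


def _group_to_cluster(group: list[AlignedTag]) -> Cluster:
    start = min(t.start for t in group)
    end = max(t.end for t in group)
    depth = np.zeros(end - start, dtype=np.int32)
    for t in group:
        depth[t.start - start : t.end - start] += 1
    peak = int(depth.max())
    summit = start + int(np.argmax(depth))  # argmax returns leftmost maximum
    return Cluster(
        chrom=group[0].chrom,
        start=start,
        end=end,
        strand=group[0].strand,
        stage=group[0].stage,
        tag_count=len(group),
        peak_height=peak,
        summit=summit,
        replicate_support=len({t.replicate for t in group}),
    )


def call_clusters(
    tags: Iterable[AlignedTag],
    min_peak_height: int = 5,
    min_replicates: int = 2,
) -> list[Cluster]:
    """Group overlapping same-strand tags of one stage into clusters.

    Tags are pooled across replicates; replicate support is computed on the
    pooled cluster. Clusters with peak_height < min_peak_height or
    replicate_support < min_replicates are discarded. Output is sorted by
    (chrom, start). All tags must come from a single stage.
    """
    if min_peak_height < 1 or min_replicates < 1:
        raise ValueError("min_peak_height and min_replicates must be >= 1")
    tags = list(tags)
    stages = {t.stage for t in tags}
    if len(stages) > 1:
        raise ValueError(
            f"call_clusters merges tags of one stage only; got stages {sorted(stages)}"
        )
    by_key: dict[tuple[str, str], list[AlignedTag]] = {}
    for t in tags:
        by_key.setdefault((t.chrom, t.strand), []).append(t)

    clusters: list[Cluster] = []
    for key in sorted(by_key):
        for group in _chain_overlapping(by_key[key]):
            c = _group_to_cluster(group)
            if c.peak_height >= min_peak_height and c.replicate_support >= min_replicates:
                clusters.append(c)
    clusters.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    return clusters


def read_tag_bed(path, stage: str, replicate: int) -> list[AlignedTag]:
    """Read one BED6 tag file for a given stage/replicate."""
    tags = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: expected BED6, got {len(fields)} columns")
            tags.append(
                AlignedTag(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5],
                    stage=stage,
                    replicate=replicate,
                )
            )
    return tags


def write_cluster_bed(clusters: Sequence[Cluster], path) -> pd.DataFrame:
    """Write clusters as BED6+3 (score = peak_height; extras: tag_count, summit,
    replicate_support). Returns the table written."""
    rows = [
        {
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "name": f"cluster_{c.stage}_{i}",
            "score": c.peak_height,
            "strand": c.strand,
            "tag_count": c.tag_count,
            "summit": c.summit,
            "replicate_support": c.replicate_support,
        }
        for i, c in enumerate(clusters)
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "tag_count", "summit", "replicate_support",
        ],
    )
    df.to_csv(path, sep="\t", index=False, header=False)
    return df
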