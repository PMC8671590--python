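"""ROSE-style super-enhancer identification and TSS assignment.

H3K27ac peaks within a stitching distance (default 12,500 bp, boundary
inclusive) are merged into stitched regions whose signal is the sum of
constituent peak scores (optionally input-subtracted, floored at zero).
Regions are ranked by signal and both axes scaled to [0, 1]; the
"hockey-stick" cutoff is the point where a line of slope 1 is tangent to the
scaled rank/signal curve from below (the discrete minimizer of
scaled_signal - scaled_rank). Regions above the cutoff are super-enhancers. Each SE is then assigned to the nearest gene or miRNA
TSS within a +/-100 kb window, ties resolved toward the miRNA class and then
the smaller coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "StitchedRegion",
    "SEAssignment",
    "stitch_peaks",
    "hockey_stick_cutoff",
    "assign_se_to_tss",
    "read_peak_bed",
]

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_WINDOW = 100_000


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    score: float
    input_score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"malformed peak {self.chrom}:{self.start}-{self.end}")
        if self.score < 0 or self.input_score < 0:
            raise ValueError(
                f"negative signal on peak {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def net_signal(self) -> float:
        return max(0.0, self.score - self.input_score)


@dataclass
class StitchedRegion:
    chrom: str
    start: int
    end: int
    n_constituents: int
    signal: float
    region_id: str = ""
    rank: int = 0  # ascending by signal, 1..N
    scaled_x: float = 0.0
    scaled_y: float = 0.0
    is_se: bool = False
    constituents: list[Peak] = field(default_factory=list, repr=False)


def stitch_peaks(
    peaks: list[Peak], stitch_distance: int = DEFAULT_STITCH_DISTANCE
) -> list[StitchedRegion]:
    """Merge peaks whose gap is <= stitch_distance (same chrom, strandless).

    Region signal is the sum of constituent net signals. Output sorted by
    (chrom, start), region ids assigned in that order.
    """
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    regions: list[StitchedRegion] = []
    for chrom in sorted(by_chrom):
        group: list[Peak] = []
        group_end = None
        for p in sorted(by_chrom[chrom], key=lambda q: (q.start, q.end)):
            if group and p.start - group_end <= stitch_distance:
                group.append(p)
                group_end = max(group_end, p.end)
            else:
                if group:
                    regions.append(_make_region(group))
                group = [p]
                group_end = p.end
        if group:
            regions.append(_make_region(group))
    for i, r in enumerate(regions):
        r.region_id = f"region_{i}"
    return regions


def _make_region(group: list[Peak]) -> StitchedRegion:
    return StitchedRegion(
        chrom=group[0].chrom,
        start=min(p.start for p in group),
        end=max(p.end for p in group),
        n_constituents=len(group),
        signal=float(sum(p.net_signal for p in group)),
        constituents=list(group),
    )


def hockey_stick_cutoff(
    signals: np.ndarray | list[float], slope_threshold: float = 1.0
) -> tuple[float, np.ndarray]:
    """Signal cutoff on the rank-scaled curve and per-region SE flags.

    Signals are sorted ascending; x = rank/N and y = signal/max are both on
    [0, 1]. The cutoff is where a line of slope `slope_threshold` is tangent
    to the curve from below — discretely, the point minimizing
    scaled_y - slope_threshold * scaled_x (rightmost minimizer on ties, the
    conservative choice). Regions with signal strictly above the cutoff are
    flagged. All-equal signals yield zero flags with a warning. Flags are
    returned in the input order.
    """
    signals = np.asarray(signals, dtype=float)
    n = signals.size
    if n < 3:
        raise ValueError("need at least 3 regions for a hockey-stick cutoff")
    if signals.max() == signals.min():
        warnings.warn("all region signals equal; no super-enhancers", stacklevel=2)
        return float(signals.max()), np.zeros(n, dtype=bool)
    order = np.argsort(signals, kind="stable")
    y = signals[order] / signals.max()
    x = np.arange(1, n + 1) / n
    objective = y - slope_threshold * x
    cut_idx = n - 1 - int(np.argmin(objective[::-1]))  # rightmost minimizer
    cutoff = float(signals[order][cut_idx])
    flags = signals > cutoff
    return cutoff, flags


def rank_regions(
    regions: list[StitchedRegion], slope_threshold: float = 1.0
) -> tuple[list[StitchedRegion], float]:
    """Rank stitched regions by signal, apply the hockey-stick cutoff in place."""
    signals = np.array([r.signal for r in regions], dtype=float)
    ranks = np.argsort(np.argsort(signals, kind="stable"), kind="stable") + 1
    max_sig = signals.max() if len(signals) else 0.0
    cutoff, flags = hockey_stick_cutoff(signals, slope_threshold)
    for r, rank, flag in zip(regions, ranks, flags):
        r.rank = int(rank)
        r.scaled_x = r.rank / len(regions)
        r.scaled_y = r.signal / max_sig if max_sig > 0 else 0.0
        r.is_se = bool(flag)
    return regions, cutoff


@dataclass(frozen=True)
class SEAssignment:
    region_id: str
    tss_id: str  # empty when unassigned
    tss_class: str  # "gene" | "miRNA" | ""
    distance: int  # signed; 0 if TSS inside the region; window+1 sentinel unused


def assign_se_to_tss(
    se_regions: list[StitchedRegion],
    tss_table: pd.DataFrame,
    window: int = DEFAULT_TSS_WINDOW,
) -> list[SEAssignment]:
    """Assign each SE to the nearest TSS within +/-window bases.

    Distance is measured from the region boundary (0 when the TSS lies inside)
    and signed (negative = TSS upstream of region start). Ties break toward
    the miRNA class, then the smaller coordinate. A region with no TSS in the
    window yields an unassigned record (empty tss_id).
    """
    required = {"id", "chrom", "position", "class"}
    if not required.issubset(tss_table.columns):
        raise ValueError(f"TSS table must have columns {sorted(required)}")
    by_chrom = {chrom: df for chrom, df in tss_table.groupby("chrom")}
    out = []
    for region in se_regions:
        tss = by_chrom.get(region.chrom)
        best = None
        if tss is not None:
            for rec in tss.to_dict("records"):
                pos = int(rec["position"])
                if pos < region.start:
                    dist = pos - region.start
                elif pos >= region.end:
                    dist = pos - (region.end - 1)
                else:
                    dist = 0
                if abs(dist) > window:
                    continue
                key = (abs(dist), 0 if rec["class"] == "miRNA" else 1, pos)
                if best is None or key < best[0]:
                    best = (key, rec, dist)
        if best is None:
            out.append(SEAssignment(region.region_id, "", "", 0))
        else:
            _, rec, dist = best
            out.append(
                SEAssignment(region.region_id, rec["id"], rec["class"], dist)
            )
    return out


def read_peak_bed(path) -> list[Peak]:
    """Read H3K27ac peaks from BED6 (score column 5 = signal; optional column 7
    = input/control signal to subtract)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            peaks.append(
                Peak(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    score=float(f[4]),
                    input_score=float(f[6]) if len(f) > 6 else 0.0,
                )
            )
    return peaks
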