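"""Ago-bound miRNA abundance profiles across developmental stages.

Counts of miRNA-mapped tags are normalized to reads per million (RPM) within
each stage, so per-stage RPM sums to 1e6 and sequencing depth cancels. Stage
dynamics are summarized by log2 fold changes with a pseudocount, and
expression *patterns* are grouped by hierarchical clustering of z-scored
profiles under correlation distance with average linkage — magnitude is
deliberately removed so a lowly and a highly expressed miRNA with the same
stage trajectory co-cluster. Each cluster is labeled with the stage at which
its mean z-profile peaks ("enriched stage").
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "quantify_mirnas",
    "top_share",
    "stage_log2fc",
    "cluster_stage_profiles",
    "zscore_profiles",
]


def quantify_mirnas(counts: pd.DataFrame, stages: list[str] | None = None) -> pd.DataFrame:
    """Per-stage RPM table from miRNA-mapped tag counts.

    Parameters
    ----------
    counts
        Long table with columns mirna, stage, count (a replicate column is
        tolerated; replicates are summed before normalization).
    stages
        Optional stage order for the output columns.

    Returns a wide DataFrame indexed by miRNA name, one column per stage,
    where every column sums to 1e6. A stage with zero total counts is an
    error.
    """
    required = {"mirna", "stage", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    if (counts["count"] < 0).any():
        raise ValueError("negative miRNA counts")
    wide = counts.pivot_table(
        index="mirna", columns="stage", values="count", aggfunc="sum", fill_value=0
    ).astype(float)
    if stages is not None:
        wide = wide.reindex(columns=stages, fill_value=0.0)
    totals = wide.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"stage(s) with zero miRNA-mapped tags: {list(zero.index)}")
    rpm = wide / totals * 1e6
    rpm.columns.name = None
    rpm.index.name = "mirna"
    return rpm


def top_share(rpm: pd.DataFrame, stage: str, n: int) -> float:
    """Combined abundance fraction of the top-n miRNAs in one stage.

    Ties at the cutoff break lexicographically by miRNA name. If n exceeds
    the catalog the share over all miRNAs (1.0) is returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if stage not in rpm.columns:
        raise KeyError(f"unknown stage {stage!r}")
    col = rpm[stage].sort_index().sort_values(ascending=False, kind="stable")
    if n > len(col):
        warnings.warn(
            f"n={n} exceeds catalog size {len(col)}; returning share of all miRNAs",
            stacklevel=2,
        )
        n = len(col)
    return float(col.iloc[:n].sum() / col.sum())


def stage_log2fc(
    rpm: pd.DataFrame, stage_a: str, stage_b: str, pseudocount: float = 1.0
) -> pd.Series:
    """Per-miRNA log2((RPM_b + pc) / (RPM_a + pc)); antisymmetric in (a, b)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    for s in (stage_a, stage_b):
        if s not in rpm.columns:
            raise KeyError(f"unknown stage {s!r}")
    fc = np.log2(rpm[stage_b] + pseudocount) - np.log2(rpm[stage_a] + pseudocount)
    fc.name = f"log2fc_{stage_b}_vs_{stage_a}"
    return fc


def zscore_profiles(rpm: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score; constant rows are dropped with a warning."""
    mu = rpm.mean(axis=1)
    sd = rpm.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant-profile miRNA(s) "
            f"(zero variance across stages)",
            stacklevel=2,
        )
    usable = rpm.loc[~constant]
    return usable.sub(mu[~constant], axis=0).div(sd[~constant], axis=0)


def cluster_stage_profiles(
    rpm: pd.DataFrame, k: int = 5
) -> tuple[pd.DataFrame, str]:
    """Group miRNAs into k stage-enriched clusters by expression pattern.

    Rows are z-scored; pairwise distance is 1 - Pearson correlation; the
    average-linkage tree is cut into k groups; each group is labeled with the
    stage at which its mean z-profile is maximal. Returns (assignment table
    with columns mirna, cluster, enriched_stage, sorted by input order) and a
    Newick string of the dendrogram for inspection.
    """
    z = zscore_profiles(rpm)
    if len(z) < k:
        raise ValueError(f"k={k} exceeds the {len(z)} usable (non-constant) profiles")
    dist = pdist(z.to_numpy(), metric="correlation")
    linkage = hierarchy.linkage(dist, method="average")
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    # renumber clusters 1..k in order of first appearance for determinism
    remap: dict[int, int] = {}
    cluster_ids = []
    for raw in flat:
        if raw not in remap:
            remap[raw] = len(remap) + 1
        cluster_ids.append(remap[raw])
    assign = pd.DataFrame({"mirna": z.index, "cluster": cluster_ids})
    enriched = {}
    for cid, group in assign.groupby("cluster"):
        mean_profile = z.loc[group["mirna"]].mean(axis=0)
        enriched[cid] = mean_profile.idxmax()
    assign["enriched_stage"] = assign["cluster"].map(enriched)
    newick = _to_newick(linkage, list(z.index))
    return assign, newick


def _to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
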