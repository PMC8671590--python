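"""k-mer motif enrichment in Ago cluster sequences.

Observed k-mer counts (overlapping occurrences, summed over sequences) are
compared with a null distribution obtained by shuffling every sequence while
preserving its exact dinucleotide composition (Altschul–Erickson Euler-path
shuffle), which controls for local base composition such as GC content and CpG
depletion. Enrichment is a z-score per k-mer:

    z = (observed - mean_shuffled) / sd_shuffled,  z := 0 when sd = 0

(a k-mer whose count the shuffle cannot move — e.g. in a homopolymer — is
unenrichable under this background). Enriched k-mers are then matched against
the seed-complement strings of expressed miRNAs, reproducing the
seed-motif-switch readout across developmental stages.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .targetome import MiRNA, seed_match_strings

__all__ = ["dinucleotide_shuffle", "kmer_enrichment", "match_motifs_to_seeds"]


def _count_kmers(seq: str, k: int, into: dict[str, int]) -> None:
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        into[kmer] = into.get(kmer, 0) + 1


def count_kmers(sequences: Iterable[str], k: int) -> dict[str, int]:
    """Overlapping k-mer occurrence counts summed over sequences."""
    counts: dict[str, int] = {}
    for seq in sequences:
        _count_kmers(seq, k, counts)
    return counts


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul–Erickson style: the sequence is an Eulerian path in the directed
    multigraph whose vertices are the distinct characters and whose edges are
    the consecutive pairs. A random last-exit edge is drawn for every vertex
    except the terminal one such that the last-exit edges form a tree directed
    toward the terminal vertex (guaranteeing an Eulerian walk exists); the
    remaining out-edges are permuted freely. First and last characters are
    preserved.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges.keys())
    last = seq[-1]

    # pick last-exit edges forming a tree toward `last` (rejection sampling;
    # alphabet is <= 5 vertices so this converges immediately in practice)
    non_terminal = [v for v in vertices if v != last]
    while True:
        last_exit = {v: edges[v][rng.integers(len(edges[v]))] for v in non_terminal}
        ok = True
        for v in non_terminal:
            # walk the chosen exits; must reach `last` without cycling
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    shuffled_out: dict[str, list[str]] = {}
    for v, out in edges.items():
        out = list(out)
        if v in last_exit:
            out.remove(last_exit[v])
        perm = rng.permutation(len(out))
        out = [out[i] for i in perm]
        if v in last_exit:
            out.append(last_exit[v])
        shuffled_out[v] = out

    walk = [seq[0]]
    position = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_out[cur][position[cur]]
        position[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def kmer_enrichment(
    sequences: Sequence[str],
    k: int = 7,
    n_shuffles: int = 100,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """z-score enrichment of every observed k-mer against shuffled backgrounds.

    Returns a DataFrame with columns kmer, observed, bg_mean, bg_sd, z,
    sorted by z descending with lexicographic tie-break. Sequences shorter
    than k are skipped with a warning; if none remain, ValueError.
    """
    if not 5 <= k <= 8:
        raise ValueError("k must be in [5, 8]")
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be >= 20")
    usable = [s.upper() for s in sequences if len(s) >= k]
    skipped = len(sequences) - len(usable)
    if skipped:
        warnings.warn(f"skipped {skipped} sequence(s) shorter than k={k}", stacklevel=2)
    if not usable:
        raise ValueError(f"all sequences shorter than k={k}")

    observed = count_kmers(usable, k)
    kmers = sorted(observed)
    index = {kmer: i for i, kmer in enumerate(kmers)}
    bg = np.zeros((n_shuffles, len(kmers)))
    rng = np.random.default_rng(rng_seed)
    for r in range(n_shuffles):
        counts: dict[str, int] = {}
        for seq in usable:
            _count_kmers(dinucleotide_shuffle(seq, rng), k, counts)
        for kmer, c in counts.items():
            j = index.get(kmer)
            if j is not None:
                bg[r, j] = c

    mean = bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=1)
    obs = np.array([observed[kmer] for kmer in kmers], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    table = pd.DataFrame(
        {"kmer": kmers, "observed": obs.astype(int), "bg_mean": mean, "bg_sd": sd, "z": z}
    )
    table = table.sort_values(["z", "kmer"], ascending=[False, True], kind="stable")
    return table.reset_index(drop=True)


def match_motifs_to_seeds(
    kmer_table: pd.DataFrame,
    catalog: Sequence[MiRNA],
    expressed: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Annotate enriched k-mers with the expressed miRNAs they seed-match.

    A k-mer matches a miRNA iff it contains (or equals) one of that miRNA's
    canonical seed-complement strings. Returns a copy of the table with a
    `matched_mirnas` column (comma-joined, empty when none).
    """
    expressed_set = None if expressed is None else set(expressed)
    match_strings = {
        m.name: list(seed_match_strings(m).values())
        for m in catalog
        if expressed_set is None or m.name in expressed_set
    }
    matched = []
    for kmer in kmer_table["kmer"]:
        hits = sorted(
            name
            for name, strings in match_strings.items()
            if any(s in kmer for s in strings)
        )
        matched.append(",".join(hits))
    out = kmer_table.copy()
    out["matched_mirnas"] = matched
    return out
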