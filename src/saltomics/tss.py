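"""Cappable-seq transcription start site (TSS) calling and classification.

Cappable-seq enriches primary-transcript 5' ends, so the 5' end of each
aligned fragment marks a candidate TSS. The caller proceeds in four
stages, every one using the same 5-nt single-linkage chaining rule
(positions join a cluster while the gap to the previous member is within
the window):

1. per replicate: count fragment 5' ends per (strand, position) and
   cluster them, keeping the position with the greatest count as the
   cluster representative;
2. per condition: chain the replicate representatives and keep only
   clusters detected in *all* replicates (consensus);
3. across conditions: chain the per-condition consensus TSSs into unique
   TSSs, each carrying the set of conditions it was detected in (the
   condition-subset tally is the UpSet-plot input);
4. classify each unique TSS against the gene models: upstream (within
   400 nt 5' of a same-strand gene) > internal (inside a same-strand
   gene) > antisense (inside an opposite-strand gene) > orphan.

Coordinates are 1-based inclusive internally; BED input/output converts
at the boundary. Ties are always broken by greatest count first, then
smallest genomic coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidAnnotationError, InvalidRecordError

STRANDS = ("+", "-")
CLASSIFICATIONS = ("upstream", "internal", "antisense", "orphan")


@dataclass(frozen=True)
class TSSCluster:
    """A called TSS: representative position, strand and provenance."""

    representative: int
    strand: str
    total_count: int
    member_positions: tuple[int, ...]
    replicate_set: frozenset = frozenset()
    condition_set: frozenset = frozenset()
    classification: str | None = None
    assigned_gene: str | None = None
    distance_to_start: int | None = None


def count_five_prime_ends(fragments: pd.DataFrame) -> pd.DataFrame:
    """Aggregate fragment 5' ends per (strand, position).

    ``fragments`` uses on-disk BED convention (0-based half-open). For a
    plus-strand fragment the 5' end is the leftmost base (``start + 1``
    in 1-based coordinates); for a minus-strand fragment the rightmost
    (``end`` in 1-based coordinates).

    Returns a DataFrame with columns ``position`` (1-based), ``strand``,
    ``count``, sorted by strand then position.
    """
    if fragments.empty:
        return pd.DataFrame({"position": [], "strand": [], "count": []}).astype(
            {"position": int, "strand": str, "count": int}
        )
    strands = fragments["strand"].to_numpy()
    bad = ~np.isin(strands, STRANDS)
    if bad.any():
        raise InvalidRecordError(f"unknown strand values: {set(strands[bad])}")
    start = fragments["start"].to_numpy()
    end = fragments["end"].to_numpy()
    if (start >= end).any():
        raise InvalidRecordError("fragment intervals require start < end")
    pos = np.where(strands == "+", start + 1, end)
    counts = (
        pd.DataFrame({"position": pos, "strand": strands})
        .groupby(["strand", "position"], sort=True)
        .size()
        .rename("count")
        .reset_index()[["position", "strand", "count"]]
    )
    return counts


def _chain(positions: np.ndarray, window: int) -> list[np.ndarray]:
    """Single-linkage chains over sorted positions: split where gap > window."""
    if positions.size == 0:
        return []
    order = np.argsort(positions, kind="stable")
    sorted_pos = positions[order]
    breaks = np.flatnonzero(np.diff(sorted_pos) > window) + 1
    return [grp for grp in np.split(order, breaks)]


def cluster_positions(end_counts: pd.DataFrame, window: int = 5) -> list[TSSCluster]:
    """Cluster per-position 5'-end counts into TSS clusters, per strand.

    Representative = member with the greatest count (ties: smallest
    coordinate); total_count = sum over members. Strands never mix.
    """
    clusters: list[TSSCluster] = []
    for strand in STRANDS:
        sub = end_counts[end_counts["strand"] == strand]
        pos = sub["position"].to_numpy()
        cnt = sub["count"].to_numpy()
        for idx in _chain(pos, window):
            members = pos[idx]
            counts = cnt[idx]
            best = np.lexsort((members, -counts))[0]
            clusters.append(
                TSSCluster(
                    representative=int(members[best]),
                    strand=strand,
                    total_count=int(counts.sum()),
                    member_positions=tuple(int(p) for p in np.sort(members)),
                )
            )
    clusters.sort(key=lambda c: (c.strand, c.representative))
    return clusters


def _chain_clusters(
    items: Sequence[tuple[TSSCluster, object]], window: int
) -> list[list[tuple[TSSCluster, object]]]:
    """Chain (cluster, tag) pairs by representative position, per strand."""
    chains = []
    for strand in STRANDS:
        sub = [(c, tag) for c, tag in items if c.strand == strand]
        pos = np.array([c.representative for c, _ in sub])
        for idx in _chain(pos, window):
            chains.append([sub[i] for i in idx])
    return chains


def _consensus_of(members: list[tuple[TSSCluster, object]]) -> TSSCluster:
    best = min(members, key=lambda m: (-m[0].total_count, m[0].representative))[0]
    return TSSCluster(
        representative=best.representative,
        strand=best.strand,
        total_count=int(sum(c.total_count for c, _ in members)),
        member_positions=tuple(sorted({c.representative for c, _ in members})),
    )


def replicate_consensus(
    clusters_by_replicate: Mapping[object, Sequence[TSSCluster]],
    window: int = 5,
    required_replicates: Iterable | None = None,
) -> list[TSSCluster]:
    """Keep only TSSs detected in every replicate.

    Representatives from all replicates are chained within the window; a
    consensus TSS is emitted iff its chain contains at least one
    representative from each required replicate (default: all replicates
    present in the input). The consensus representative is the member
    with the greatest per-replicate total count (ties: smallest
    coordinate); its total count sums across replicates.
    """
    required = frozenset(
        required_replicates if required_replicates is not None else clusters_by_replicate
    )
    items = [
        (c, rep) for rep, cl in clusters_by_replicate.items() for c in cl
    ]
    out = []
    for chain in _chain_clusters(items, window):
        reps = frozenset(tag for _, tag in chain)
        if required <= reps:
            out.append(replace(_consensus_of(chain), replicate_set=reps))
    out.sort(key=lambda c: (c.strand, c.representative))
    return out


def merge_conditions(
    clusters_by_condition: Mapping[object, Sequence[TSSCluster]],
    window: int = 5,
):
    """Merge per-condition consensus TSSs into unique TSSs.

    Returns ``(unique, tally)`` where each unique TSS carries the set of
    conditions that contributed and ``tally`` maps each observed
    condition subset (frozenset) to its count — the UpSet-plot input.
    The per-condition detections are conserved: the sizes of the
    condition sets sum to the total number of input consensus TSSs.
    """
    items = [
        (c, cond) for cond, cl in clusters_by_condition.items() for c in cl
    ]
    unique: list[TSSCluster] = []
    for chain in _chain_clusters(items, window):
        conds = frozenset(tag for _, tag in chain)
        unique.append(replace(_consensus_of(chain), condition_set=conds))
    tally = Counter(u.condition_set for u in unique)
    unique.sort(key=lambda c: (c.strand, c.representative))
    return unique, dict(tally)


def _gene_five_prime(start: int, end: int, strand: str) -> int:
    return start if strand == "+" else end


def classify_tss(
    tss_list: Sequence[TSSCluster],
    genes: pd.DataFrame,
    upstream_window: int = 400,
) -> list[TSSCluster]:
    """Assign each unique TSS one classification against the gene models.

    ``genes`` holds 1-based inclusive ``start``/``end``, ``strand`` and a
    ``gene_id`` column. Priority: upstream > internal > antisense >
    orphan. Upstream means 1..upstream_window nt 5' of a same-strand
    gene's start (strand-aware, inclusive); internal/antisense mean
    inside a same-/opposite-strand gene. The assigned gene is the
    qualifying gene at the smallest strand-aware distance (ties: smaller
    gene start).
    """
    if len(genes):
        if (genes["end"] < genes["start"]).any():
            raise InvalidAnnotationError("gene interval with end < start")
        if (~genes["strand"].isin(STRANDS)).any():
            raise InvalidAnnotationError("gene with unknown strand")
    g_start = genes["start"].to_numpy() if len(genes) else np.array([], dtype=int)
    g_end = genes["end"].to_numpy() if len(genes) else np.array([], dtype=int)
    g_strand = genes["strand"].to_numpy() if len(genes) else np.array([], dtype=str)
    g_id = genes["gene_id"].to_numpy() if len(genes) else np.array([], dtype=str)

    out = []
    for t in tss_list:
        pos = t.representative
        same = g_strand == t.strand
        # strand-aware distance from the TSS to each gene's 5' start
        up_dist = np.where(g_strand == "+", g_start - pos, pos - g_end)
        inside = (g_start <= pos) & (pos <= g_end)

        def pick(mask, dist):
            idx = np.flatnonzero(mask)
            order = np.lexsort((g_start[idx], dist[idx]))
            return idx[order[0]]

        upstream_mask = same & (up_dist >= 1) & (up_dist <= upstream_window)
        internal_mask = same & inside
        antisense_mask = ~same & inside
        if upstream_mask.any():
            i = pick(upstream_mask, up_dist)
            cls, gene, dist = "upstream", g_id[i], int(up_dist[i])
        elif internal_mask.any():
            offset = np.where(g_strand == "+", pos - g_start, g_end - pos)
            i = pick(internal_mask, offset)
            cls, gene, dist = "internal", g_id[i], int(offset[i])
        elif antisense_mask.any():
            offset = np.where(g_strand == "+", pos - g_start, g_end - pos)
            i = pick(antisense_mask, offset)
            cls, gene, dist = "antisense", g_id[i], int(offset[i])
        else:
            cls, gene, dist = "orphan", None, None
        out.append(
            replace(t, classification=cls, assigned_gene=gene, distance_to_start=dist)
        )
    return out


def compare_tss_sets(
    set_a: Sequence[TSSCluster],
    set_b: Sequence[TSSCluster],
    window: int = 5,
):
    """Strand-aware one-to-one matching of two TSS catalogues.

    Candidate pairs within the window are accepted greedily by ascending
    |distance|, ties broken by the smaller coordinate in A then B; each
    TSS matches at most once. Returns ``(matched_pairs, a_only, b_only)``
    where pairs are ``(tss_a, tss_b)``.
    """
    candidates = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if a.strand == b.strand and abs(a.representative - b.representative) <= window:
                candidates.append(
                    (abs(a.representative - b.representative),
                     a.representative, b.representative, i, j)
                )
    candidates.sort()
    used_a, used_b = set(), set()
    pairs = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((set_a[i], set_b[j]))
    a_only = [a for i, a in enumerate(set_a) if i not in used_a]
    b_only = [b for j, b in enumerate(set_b) if j not in used_b]
    return pairs, a_only, b_only


def call_tss(
    fragments_by_condition_replicate: Mapping[tuple[object, object], pd.DataFrame],
    window: int = 5,
    required_replicates: Iterable | None = None,
):
    """End-to-end TSS calling from per-(condition, replicate) fragments.

    Returns ``(unique_tss, tally, per_condition_consensus)``.
    """
    by_condition: dict = defaultdict(dict)
    for (condition, rep), frags in fragments_by_condition_replicate.items():
        by_condition[condition][rep] = cluster_positions(
            count_five_prime_ends(frags), window
        )
    consensus = {
        cond: replicate_consensus(reps, window, required_replicates)
        for cond, reps in by_condition.items()
    }
    unique, tally = merge_conditions(consensus, window)
    return unique, tally, consensus
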