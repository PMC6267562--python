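"""Transitive-closure clustering of spacers at an adjusted-mismatch cutoff.

Similarity is not transitive — A can be within the cutoff of B and B of C
while A and C differ by more — but for display purposes such chains must
share one color, so clusters are the connected components of the pairwise
similarity graph.  No diameter constraint is imposed on components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .align import PairSimilarity

DEFAULT_CUTOFF = 2


@dataclass
class SpacerClustering:
    """A partition of spacer identities into similarity clusters.

    ``cluster_id`` is the identity of the lexicographically smallest member,
    which is stable across reruns and under permutation of the input — the
    property append mode relies on.
    """

    cutoff: int
    assignment: dict[str, str] = field(default_factory=dict)
    clusters: dict[str, list[str]] = field(default_factory=dict)

    def size_of(self, cluster_id: str) -> int:
        return len(self.clusters[cluster_id])

    def validate(self) -> None:
        seen: set[str] = set()
        for cid, members in self.clusters.items():
            if not members:
                raise ValueError(f"empty cluster {cid}")
            if cid != min(members):
                raise ValueError(f"cluster id {cid} is not its smallest member")
            for m in members:
                if m in seen:
                    raise ValueError(f"{m} assigned to more than one cluster")
                seen.add(m)
                if self.assignment.get(m) != cid:
                    raise ValueError(f"assignment/cluster mismatch for {m}")
        if seen != set(self.assignment):
            raise ValueError("assignment does not cover exactly the members")


class _UnionFind:
    """Union-find with path compression and union by size."""

    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {x: x for x in items}
        self.size = {x: 1 for x in self.parent}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # compress
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def cluster_spacers(
    pairs: Sequence[PairSimilarity],
    all_ids: Sequence[str],
    cutoff: int = DEFAULT_CUTOFF,
) -> SpacerClustering:
    """Connected components of the graph with edges at adjusted score <= cutoff.

    ``all_ids`` fixes the universe: spacers with no qualifying partner become
    singleton clusters.  The result is independent of the order of ``pairs``.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    universe = list(dict.fromkeys(all_ids))
    known = set(universe)
    uf = _UnionFind(universe)
    for p in pairs:
        if p.query_id not in known:
            raise KeyError(f"pair references unknown spacer {p.query_id!r}")
        if p.subject_id not in known:
            raise KeyError(f"pair references unknown spacer {p.subject_id!r}")
        if p.adjusted_mismatches <= cutoff:
            uf.union(p.query_id, p.subject_id)

    members: dict[str, list[str]] = {}
    for sid in universe:
        members.setdefault(uf.find(sid), []).append(sid)

    clustering = SpacerClustering(cutoff=cutoff)
    for group in members.values():
        group = sorted(group)
        cid = group[0]
        clustering.clusters[cid] = group
        for m in group:
            clustering.assignment[m] = cid
    # deterministic cluster iteration order
    clustering.clusters = dict(sorted(clustering.clusters.items()))
    return clustering


def write_cluster_tsv(clustering: SpacerClustering, handle: TextIO) -> None:
    handle.write("spacer_id\tcluster_id\tcluster_size\n")
    for cid in clustering.clusters:
        for m in clustering.clusters[cid]:
            handle.write(f"{m}\t{cid}\t{clustering.size_of(cid)}\n")
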