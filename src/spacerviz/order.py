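"""Strain display order from shared spacer content, or from a user list.

Rows in the figure are easiest to read when strains with similar arrays sit
next to each other.  The default ordering counts, for every pair of samples,
how many spacers they share (summed over clusters, taking the per-cluster
minimum of the two abundance vectors), converts the counts into Bray-Curtis
dissimilarities

    D(i, j) = 1 - 2 * shared(i, j) / (S_i + S_j)

(where S_i is sample i's total spacer count), and clusters the samples with
UPGMA (average linkage).  The left-to-right leaf order of the resulting guide
tree — a display aid, not a phylogeny — becomes the row order.  All ties
(equal merge distances, child placement) are broken by input position, so the
order is fully deterministic and an all-equal matrix reproduces input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike

import numpy as np

from .cluster import SpacerClustering
from .records import Dataset


@dataclass
class SharedSpacerMatrix:
    """Per-sample cluster abundances and the pairwise shared-spacer counts."""

    sample_ids: list[str]
    counts: list[dict[str, int]]  # parallel to sample_ids
    shared: np.ndarray  # shared[i][j] = sum over clusters of min(count_i, count_j)

    def totals(self) -> np.ndarray:
        return np.diagonal(self.shared).copy()


@dataclass
class StrainOrdering:
    ordered_samples: list[str]
    source: str  # upgma | custom | input_order
    newick: str | None = None
    warnings: list[str] = field(default_factory=list)


def shared_spacer_matrix(
    ds: Dataset, clustering: SpacerClustering
) -> SharedSpacerMatrix:
    """Cluster-abundance vectors per sample (all loci pooled) and the
    multiset-overlap matrix between them."""
    sample_ids = ds.sample_ids
    counts: list[dict[str, int]] = []
    for sid in sample_ids:
        vec: dict[str, int] = {}
        for locus in ds.samples[sid]:
            for sp in locus.spacers:
                cid = clustering.assignment[sp.spacer_id]
                vec[cid] = vec.get(cid, 0) + 1
        counts.append(vec)
    n = len(sample_ids)
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i, n):
            common = counts[i].keys() & counts[j].keys()
            s = sum(min(counts[i][c], counts[j][c]) for c in common)
            shared[i, j] = shared[j, i] = s
    return SharedSpacerMatrix(sample_ids, counts, shared)


def bray_curtis(matrix: SharedSpacerMatrix) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix from shared-spacer counts."""
    totals = matrix.totals().astype(float)
    if np.any(totals == 0):
        empty = [s for s, t in zip(matrix.sample_ids, totals) if t == 0]
        raise ValueError(f"samples without spacers: {empty}")
    denom = totals[:, None] + totals[None, :]
    D = 1.0 - 2.0 * matrix.shared / denom
    np.fill_diagonal(D, 0.0)
    return D


def upgma_order(D: np.ndarray, sample_ids: list[str]) -> StrainOrdering:
    """UPGMA agglomeration of a dissimilarity matrix; leaf order = row order.

    When several pairs are equally close, the pair whose earliest-input
    members come first is merged, and the subtree containing the
    earlier-input sample is placed on the left.
    """
    D = np.asarray(D, dtype=float)
    n = len(sample_ids)
    if D.shape != (n, n):
        raise ValueError(f"distance matrix shape {D.shape} != ({n}, {n})")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if n == 1:
        return StrainOrdering(list(sample_ids), "upgma", f"{sample_ids[0]}:0.0;")

    # cluster state: leaves list (input indices, left-to-right), size, height
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    newick: dict[int, str] = {i: sample_ids[i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        # minimal distance; ties -> smallest earliest-member pair
        best = min(
            (
                (dist[(min(a, b), max(a, b))], min(leaves[a][0], leaves[b][0]),
                 max(leaves[a][0], leaves[b][0]), a, b)
                for idx, a in enumerate(active)
                for b in active[idx + 1 :]
            )
        )
        d, _, _, a, b = best
        # earlier-input subtree goes left
        left, right = (a, b) if leaves[a][0] < leaves[b][0] else (b, a)
        h = d / 2.0
        newick[next_id] = (
            f"({newick[left]}:{h - height[left]:.10g},"
            f"{newick[right]}:{h - height[right]:.10g})"
        )
        leaves[next_id] = leaves[left] + leaves[right]
        height[next_id] = h
        for c in active:
            if c in (a, b):
                continue
            na, nb = len(leaves[a]), len(leaves[b])
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            dist[(min(next_id, c), max(next_id, c))] = (na * dac + nb * dbc) / (na + nb)
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1

    root = active[0]
    ordered = [sample_ids[i] for i in leaves[root]]
    return StrainOrdering(ordered, "upgma", newick[root] + ";")


def tree_order(ds: Dataset, clustering: SpacerClustering) -> StrainOrdering:
    """Default ordering: Bray-Curtis on shared spacers, then UPGMA leaves."""
    matrix = shared_spacer_matrix(ds, clustering)
    return upgma_order(bray_curtis(matrix), matrix.sample_ids)


def custom_order(ds: Dataset, list_path: str | PathLike) -> StrainOrdering:
    """Order samples by a plain-text list (one sample id per line, ``#``
    comments allowed).  Known ids come first in list order; samples missing
    from the list are appended in input order; unknown ids are skipped.
    Both irregularities produce warnings, never errors."""
    wanted = []
    with open(list_path) as fh:
        for ln in fh:
            ln = ln.split("#", 1)[0].strip()
            if ln:
                wanted.append(ln)
    if not wanted:
        raise ValueError(f"{list_path}: empty sample list")
    known = set(ds.sample_ids)
    warnings = []
    ordered = []
    for sid in wanted:
        if sid not in known:
            warnings.append(f"{list_path}: unknown sample id {sid!r} skipped")
        elif sid in ordered:
            warnings.append(f"{list_path}: sample id {sid!r} listed twice")
        else:
            ordered.append(sid)
    missing = [sid for sid in ds.sample_ids if sid not in ordered]
    if missing:
        warnings.append(
            f"{list_path}: samples not in the list appended in input order: "
            + ", ".join(missing)
        )
        ordered.extend(missing)
    return StrainOrdering(ordered, "custom", None, warnings)


def input_order(ds: Dataset) -> StrainOrdering:
    return StrainOrdering(ds.sample_ids, "input_order")


def write_newick(ordering: StrainOrdering, path: str | PathLike) -> None:
    if ordering.newick is None:
        raise ValueError("this ordering has no guide tree")
    with open(path, "w") as fh:
        fh.write(ordering.newick + "\n")
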