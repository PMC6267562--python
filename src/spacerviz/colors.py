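"""Two-color codes per cluster, persistence for append mode, gray-out modes.

Each cluster is drawn as a colored square with a colored diamond at its
center, so a cluster's visual identity is a pair of 3-digit HEX codes
(``#rgb``).  Squares are kept distinct across clusters — the square alone
identifies a cluster — which caps a figure at 4095 distinctly colored
clusters (the 4096-color space minus the reserved gray-out white ``#fff``).
The diamond is any color other than its own square, so the diamond remains
visible.  The reserved gray-out glyph (white square, light-gray ``#ccc``
diamond) is never assigned to a cluster.

Colors are random by design (clusters carry no ordering worth encoding), but
the draw is seeded, and a saved color store lets a rerun on a grown dataset
keep every previously assigned pair.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from os import PathLike
from typing import Mapping

from .align import reduced_adjusted
from .cluster import SpacerClustering

GRAY_SQUARE = "#fff"
GRAY_DIAMOND = "#ccc"
GRAY_MODES = ("none", "gray_unique", "gray_shared")

_N_HEX = 16**3  # 3-digit HEX space


@dataclass
class ColorStore:
    """Persistent cluster -> (square, diamond) assignment.

    ``representatives`` holds one member sequence per cluster so that a later
    run can re-link its clusters to these entries by alignment instead of by
    cluster id (ids can drift when new spacers join a cluster).  ``sizes``
    records member counts, used to pick a surviving color when an appended
    spacer bridges two previous clusters.
    """

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)
    representatives: dict[str, str] = field(default_factory=dict)
    sizes: dict[str, int] = field(default_factory=dict)
    cutoff: int | None = None
    seed: int | None = None

    def validate(self) -> None:
        squares = set()
        for cid, (sq, dm) in self.entries.items():
            for hx in (sq, dm):
                if not (
                    len(hx) == 4 and hx[0] == "#" and all(c in "0123456789abcdef" for c in hx[1:])
                ):
                    raise ValueError(f"{cid}: bad HEX color {hx!r}")
            if (sq, dm) == (GRAY_SQUARE, GRAY_DIAMOND):
                raise ValueError(f"{cid}: reserved gray-out pair assigned")
            if sq in squares:
                raise ValueError(f"duplicate square color {sq}")
            squares.add(sq)


@dataclass(frozen=True)
class DisplayColor:
    """Final display decision for one spacer."""

    spacer_id: str
    square_hex: str
    diamond_hex: str
    grayed: bool
    label: int | None = None  # spacer length, drawn on request

    def __post_init__(self) -> None:
        if self.grayed and (self.square_hex, self.diamond_hex) != (
            GRAY_SQUARE,
            GRAY_DIAMOND,
        ):
            raise ValueError("grayed spacers must use the reserved gray pair")


def _hex3(value: int) -> str:
    return f"#{value:03x}"


def assign_colors(
    clustering: SpacerClustering,
    sequences: Mapping[str, str],
    seed: int | None = None,
    prior: ColorStore | None = None,
) -> ColorStore:
    """Give every cluster a (square, diamond) pair, reusing a prior store.

    A cluster inherits a prior pair when its representative sequence scores
    within the clustering cutoff of a prior representative (exact sequence
    match is tried first, which covers reruns on unchanged data without any
    alignment).  If appended spacers merged several prior clusters, the
    merged cluster keeps the pair of the largest of them (tie: smallest
    cluster id).  Only genuinely new clusters draw fresh colors from the
    seeded RNG.
    """
    n_clusters = len(clustering.clusters)
    if n_clusters > _N_HEX - 1:
        raise ValueError(
            f"{n_clusters} clusters exceed the {_N_HEX - 1} distinct square "
            "colors available; consider a gray-out mode for unique spacers"
        )

    store = ColorStore(cutoff=clustering.cutoff, seed=seed)
    used_squares: set[str] = set()

    if prior is not None:
        exact = {seq: cid for cid, seq in prior.representatives.items()}
        claimed: set[str] = set()
        for cid, members in clustering.clusters.items():
            rep = sequences[cid]
            hits = []
            if rep in exact:
                hits = [exact[rep]]
            else:
                for pcid, pseq in prior.representatives.items():
                    if reduced_adjusted(rep, pseq) <= clustering.cutoff:
                        hits.append(pcid)
            hits = [h for h in hits if h not in claimed]
            if not hits:
                continue
            # largest prior cluster wins a merge; ties to the smaller id
            best = sorted(hits, key=lambda h: (-prior.sizes.get(h, 1), h))[0]
            claimed.add(best)
            pair = prior.entries[best]
            if pair[0] in used_squares:
                continue  # two new clusters cannot share a square
            store.entries[cid] = pair
            store.representatives[cid] = rep
            store.sizes[cid] = len(members)
            used_squares.add(pair[0])

    rng = random.Random(seed)
    for cid, members in clustering.clusters.items():
        if cid in store.entries:
            continue
        while True:
            sq = _hex3(rng.randrange(_N_HEX))
            if sq == GRAY_SQUARE or sq in used_squares:
                continue
            break
        while True:
            dm = _hex3(rng.randrange(_N_HEX))
            if dm != sq:
                break
        used_squares.add(sq)
        store.entries[cid] = (sq, dm)
        store.representatives[cid] = sequences[cid]
        store.sizes[cid] = len(members)
    store.validate()
    return store


def apply_gray_mode(
    clustering: SpacerClustering,
    colors: ColorStore,
    mode: str = "none",
    lengths: Mapping[str, int] | None = None,
) -> list[DisplayColor]:
    """Resolve per-spacer display colors under a gray-out mode.

    ``gray_unique`` grays spacers whose cluster has a single member (only
    spacers seen at least twice stay colored); ``gray_shared`` is the exact
    complement.  ``lengths`` attaches the spacer length as an optional label.
    """
    if mode not in GRAY_MODES:
        raise ValueError(f"unknown gray mode {mode!r}; expected one of {GRAY_MODES}")
    out = []
    for cid, members in clustering.clusters.items():
        unique = len(members) == 1
        gray = (mode == "gray_unique" and unique) or (
            mode == "gray_shared" and not unique
        )
        sq, dm = (GRAY_SQUARE, GRAY_DIAMOND) if gray else colors.entries[cid]
        for sid in members:
            out.append(
                DisplayColor(
                    spacer_id=sid,
                    square_hex=sq,
                    diamond_hex=dm,
                    grayed=gray,
                    label=lengths.get(sid) if lengths else None,
                )
            )
    return out


def write_color_store(store: ColorStore, path: str | PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cutoff={store.cutoff if store.cutoff is not None else ''}\n")
        fh.write(f"# seed={store.seed if store.seed is not None else ''}\n")
        fh.write("cluster_id\trepresentative_sequence\tsquare_hex\tdiamond_hex\tsize\n")
        for cid, (sq, dm) in store.entries.items():
            fh.write(
                f"{cid}\t{store.representatives[cid]}\t{sq}\t{dm}\t"
                f"{store.sizes.get(cid, 1)}\n"
            )


def read_color_store(path: str | PathLike) -> ColorStore:
    store = ColorStore()
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln.startswith("# cutoff="):
                val = ln.split("=", 1)[1]
                store.cutoff = int(val) if val else None
            elif ln.startswith("# seed="):
                val = ln.split("=", 1)[1]
                store.seed = int(val) if val else None
            elif not ln or ln.startswith(("#", "cluster_id\t")):
                continue
            else:
                parts = ln.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}: bad color store line {ln!r}")
                cid, rep, sq, dm = parts[:4]
                store.entries[cid] = (sq, dm)
                store.representatives[cid] = rep
                store.sizes[cid] = int(parts[4]) if len(parts) > 4 else 1
    store.validate()
    return store
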