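"""Color assignment: seeded determinism, append stability, gray-out modes."""

from __future__ import annotations

import random

import pytest

from spacerviz.align import all_vs_all
from spacerviz.cluster import SpacerClustering, cluster_spacers
from spacerviz.colors import (
    GRAY_DIAMOND,
    GRAY_SQUARE,
    apply_gray_mode,
    assign_colors,
    read_color_store,
    write_color_store,
)
from conftest import build_dataset
from tests_util_seqs import mutate_positions, random_seq


def make_clustering(groups: dict[str, list[str]]) -> SpacerClustering:
    """Clustering fixture from explicit member lists."""
    clustering = SpacerClustering(cutoff=2)
    for members in groups.values():
        members = sorted(members)
        cid = members[0]
        clustering.clusters[cid] = members
        for m in members:
            clustering.assignment[m] = cid
    clustering.clusters = dict(sorted(clustering.clusters.items()))
    return clustering


def seqs_for(clustering: SpacerClustering, rng: random.Random) -> dict[str, str]:
    return {
        m: random_seq(rng, 30)
        for members in clustering.clusters.values()
        for m in members
    }


def test_same_seed_reproduces_the_store_bit_for_bit():
    clustering = make_clustering({"a": ["a1", "a2"], "b": ["b1"], "c": ["c1"]})
    seqs = seqs_for(clustering, random.Random(0))
    s1 = assign_colors(clustering, seqs, seed=7)
    s2 = assign_colors(clustering, seqs, seed=7)
    assert s1.entries == s2.entries
    assert s1.representatives == s2.representatives


def test_squares_are_distinct_and_never_reserved():
    clustering = make_clustering({f"c{i}": [f"c{i}"] for i in range(200)})
    store = assign_colors(clustering, seqs_for(clustering, random.Random(1)), seed=3)
    squares = [sq for sq, _dm in store.entries.values()]
    assert len(set(squares)) == len(squares)
    assert GRAY_SQUARE not in squares
    assert all(sq != dm for sq, dm in store.entries.values())


def test_color_space_exhaustion_is_an_error():
    clustering = make_clustering({f"c{i:04d}": [f"c{i:04d}"] for i in range(4096)})
    seqs = {cid: "ACGT" for cid in clustering.assignment}
    with pytest.raises(ValueError, match="gray-out"):
        assign_colors(clustering, seqs, seed=0)


def test_append_keeps_prior_colors_and_adds_one_entry(tmp_path):
    rng = random.Random(4)
    base = {f"S1|locus1|spacer{i}": random_seq(rng, 30) for i in range(1, 5)}
    ds = build_dataset({"S1": [list(base.values())]})
    records = ds.spacers()
    clustering = cluster_spacers(
        all_vs_all(records), [r.spacer_id for r in records], cutoff=2
    )
    prior = assign_colors(clustering, ds.sequences_by_id(), seed=11)

    # rerun on the same data plus one brand-new unique spacer
    grown = build_dataset({"S1": [list(base.values()) + [random_seq(rng, 30)]]})
    records2 = grown.spacers()
    clustering2 = cluster_spacers(
        all_vs_all(records2), [r.spacer_id for r in records2], cutoff=2
    )
    store = assign_colors(clustering2, grown.sequences_by_id(), seed=99, prior=prior)
    old_pairs = set(prior.entries.values())
    new_pairs = set(store.entries.values())
    assert old_pairs <= new_pairs
    assert len(store.entries) == len(prior.entries) + 1


def test_append_survives_store_round_trip(tmp_path):
    clustering = make_clustering({"x": ["x1", "x2"], "y": ["y1"]})
    seqs = seqs_for(clustering, random.Random(6))
    store = assign_colors(clustering, seqs, seed=2)
    path = tmp_path / "colors.tsv"
    write_color_store(store, path)
    back = read_color_store(path)
    assert back.entries == store.entries
    assert back.representatives == store.representatives
    assert back.sizes == store.sizes
    assert (back.cutoff, back.seed) == (2, 2)


def test_cluster_that_gained_a_mutated_member_keeps_its_color():
    # the new member changes the smallest-member cluster id, so re-linking
    # must go through the representative sequence, not the id
    rng = random.Random(8)
    anchor = random_seq(rng, 30)
    ds = build_dataset({"S1": [[anchor]]})
    clustering = cluster_spacers(
        all_vs_all(ds.spacers()), [r.spacer_id for r in ds.spacers()], 2
    )
    prior = assign_colors(clustering, ds.sequences_by_id(), seed=5)

    variant = mutate_positions(rng, anchor, 1)
    grown = build_dataset({"S0": [[variant]], "S1": [[anchor]]})
    clustering2 = cluster_spacers(
        all_vs_all(grown.spacers()), [r.spacer_id for r in grown.spacers()], 2
    )
    assert len(clustering2.clusters) == 1
    store = assign_colors(clustering2, grown.sequences_by_id(), seed=77, prior=prior)
    assert set(store.entries.values()) == set(prior.entries.values())


def test_merge_on_append_inherits_the_larger_cluster(tmp_path):
    clustering_a = make_clustering({"big": ["a1", "a2", "a3"], "small": ["z1"]})
    rng = random.Random(9)
    big_seq, small_seq = random_seq(rng, 30), random_seq(rng, 30)
    seqs = {"a1": big_seq, "a2": big_seq, "a3": big_seq, "z1": small_seq}
    prior = assign_colors(clustering_a, seqs, seed=1)
    big_pair = prior.entries["a1"]

    # a bridging spacer merges both prior clusters into one
    merged = make_clustering({"all": ["a1", "a2", "a3", "m1", "z1"]})
    seqs2 = dict(seqs, m1=big_seq)
    store = assign_colors(merged, seqs2, seed=2, prior=prior)
    assert store.entries["a1"] == big_pair


def test_gray_unique_grays_exactly_the_singletons():
    clustering = make_clustering({"a": ["a1", "a2", "a3"], "b": ["b1"], "c": ["c1"]})
    seqs = seqs_for(clustering, random.Random(10))
    store = assign_colors(clustering, seqs, seed=0)
    lengths = {sid: 30 for sid in clustering.assignment}

    unique = apply_gray_mode(clustering, store, "gray_unique", lengths)
    shared = apply_gray_mode(clustering, store, "gray_shared", lengths)
    plain = apply_gray_mode(clustering, store, "none", lengths)

    grayed_u = {d.spacer_id for d in unique if d.grayed}
    grayed_s = {d.spacer_id for d in shared if d.grayed}
    assert grayed_u == {"b1", "c1"}
    assert grayed_s == {"a1", "a2", "a3"}
    # exact complement over the whole spacer set
    assert grayed_u | grayed_s == set(clustering.assignment)
    assert grayed_u & grayed_s == set()
    assert not any(d.grayed for d in plain)
    for d in unique:
        if d.grayed:
            assert (d.square_hex, d.diamond_hex) == (GRAY_SQUARE, GRAY_DIAMOND)
            assert d.label == 30


def test_all_singletons_gray_unique_grays_everything():
    clustering = make_clustering({k: [k] for k in ["p", "q", "r"]})
    store = assign_colors(clustering, seqs_for(clustering, random.Random(12)), seed=0)
    display = apply_gray_mode(clustering, store, "gray_unique")
    assert all(d.grayed for d in display)


def test_unknown_gray_mode_rejected():
    clustering = make_clustering({"a": ["a"]})
    store = assign_colors(clustering, {"a": "ACGT"}, seed=0)
    with pytest.raises(ValueError, match="gray"):
        apply_gray_mode(clustering, store, "sepia")
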