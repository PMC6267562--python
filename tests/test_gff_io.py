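"""GFF3 parsing, spacer FASTA round-trip, and the manual-inspection warnings."""

from __future__ import annotations

import random

import pytest

from conftest import build_dataset
from spacerviz.fixtures import FixtureSpec, generate_fixture
from spacerviz.gff_io import (
    check_spacer_lengths,
    parse_crisprdetect_gff,
    read_spacer_fasta,
    write_spacer_fasta,
)

GFF_ONE_LOCUS = """##gff-version 3
S1\ttool\trepeat_region\t100\t400\t.\t+\t.\tID=S1_CRISPR1;Note=CRISPR array
S1\ttool\tbinding_site\t130\t159\t30\t+\t.\tID=sp1;Note=ACGTACGTACGTACGTACGTACGTACGTAC
S1\ttool\tbinding_site\t190\t219\t30\t+\t.\tID=sp2;Note=TTTTCCCCGGGGAAAATTTTCCCCGGGGAA
S1\ttool\tbinding_site\t250\t279\t30\t+\t.\tID=sp3;Note=GATCGATCGATCGATCGATCGATCGATCGA
"""


def test_parse_one_locus_three_spacers(tmp_path):
    path = tmp_path / "s1.gff3"
    path.write_text(GFF_ONE_LOCUS)
    ds = parse_crisprdetect_gff([path])
    assert ds.sample_ids == ["S1"]
    (locus,) = ds.samples["S1"]
    assert locus.locus_num == 1
    assert [sp.spacer_num for sp in locus.spacers] == [1, 2, 3]
    assert locus.spacers[0].sequence == "ACGTACGTACGTACGTACGTACGTACGTAC"
    assert locus.spacers[0].start == 130 and locus.spacers[0].end == 159


def test_minus_strand_spacers_are_reverse_complemented(tmp_path):
    gff = (
        "##gff-version 3\n"
        "S1\tt\trepeat_region\t100\t200\t.\t-\t.\tID=c1\n"
        "S1\tt\tbinding_site\t110\t115\t6\t-\t.\tID=sp;sequence=AAACCC\n"
    )
    path = tmp_path / "s1.gff3"
    path.write_text(gff)
    ds = parse_crisprdetect_gff([path])
    assert ds.spacers()[0].sequence == "GGGTTT"


def test_minus_strand_locus_numbers_spacers_from_five_prime(tmp_path):
    # genomic (plus-strand) order lists the 3'-most array spacer first;
    # numbering must still run 5'->3' along the array
    gff = (
        "##gff-version 3\n"
        "S1\tt\trepeat_region\t100\t300\t.\t-\t.\tID=c1\n"
        "S1\tt\tbinding_site\t110\t115\t6\t-\t.\tID=a;sequence=AAAAAA\n"
        "S1\tt\tbinding_site\t150\t155\t6\t-\t.\tID=b;sequence=CCCCCC\n"
    )
    path = tmp_path / "s1.gff3"
    path.write_text(gff)
    ds = parse_crisprdetect_gff([path])
    spacers = ds.spacers()
    # file order reversed: the 150-155 feature is the 5'-most array spacer
    assert spacers[0].start == 150 and spacers[0].spacer_num == 1
    assert spacers[0].sequence == "GGGGGG"
    assert spacers[1].start == 110 and spacers[1].spacer_num == 2


def test_genome_fasta_fallback_slices_coordinates(tmp_path):
    genome = "A" * 99 + "ACGTACGTAC" + "G" * 50
    (tmp_path / "g.fasta").write_text(">S1\n" + genome + "\n")
    gff = (
        "##gff-version 3\n"
        "S1\tt\trepeat_region\t50\t160\t.\t+\t.\tID=c1\n"
        "S1\tt\tbinding_site\t100\t109\t10\t+\t.\tID=sp1\n"
    )
    path = tmp_path / "s1.gff3"
    path.write_text(gff)
    ds = parse_crisprdetect_gff([path], genomes=tmp_path / "g.fasta")
    assert ds.spacers()[0].sequence == "ACGTACGTAC"


def test_spacer_without_sequence_is_an_error(tmp_path):
    gff = (
        "##gff-version 3\n"
        "S1\tt\trepeat_region\t50\t160\t.\t+\t.\tID=c1\n"
        "S1\tt\tbinding_site\t100\t109\t10\t+\t.\tID=sp1\n"
    )
    path = tmp_path / "bad.gff3"
    path.write_text(gff)
    with pytest.raises(ValueError, match="no sequence attribute"):
        parse_crisprdetect_gff([path])


def test_empty_file_is_an_error(tmp_path):
    path = tmp_path / "empty.gff3"
    path.write_text("##gff-version 3\n")
    with pytest.raises(ValueError, match="empty"):
        parse_crisprdetect_gff([path])


def test_fixture_parses_to_generated_spacer_count(tmp_path):
    spec = FixtureSpec(
        n_samples=4, loci_per_sample=(2, 2), spacers_per_locus=(10, 10), seed=1
    )
    truth = generate_fixture(spec, tmp_path / "fx")
    # independent count: spacer features in the emitted files
    n_features = sum(
        sum(1 for ln in p.read_text().splitlines() if "\tbinding_site\t" in ln)
        for p in truth.gff_paths
    )
    assert n_features == 4 * 2 * 10
    ds = parse_crisprdetect_gff(truth.gff_paths)
    assert len(ds.spacers()) == 80
    assert len(truth.cluster_of) == 80


def test_fasta_round_trip_preserves_every_field(tmp_path):
    spec = FixtureSpec(n_samples=3, strand_flip_prob=0.5, seed=9)
    truth = generate_fixture(spec, tmp_path / "fx")
    ds = parse_crisprdetect_gff(truth.gff_paths)
    fasta = tmp_path / "spacers.fasta"
    write_spacer_fasta(ds, fasta)
    back = read_spacer_fasta(fasta)
    orig = {sp.spacer_id: sp for sp in ds.spacers()}
    new = {sp.spacer_id: sp for sp in back.spacers()}
    assert orig.keys() == new.keys()
    for sid, sp in orig.items():
        assert new[sid] == sp
    assert back.sample_ids == ds.sample_ids


def test_round_trip_header_carries_all_seven_fields(tmp_path):
    ds = build_dataset({"St1": [["ACGTACGTACGTACGTACGTACGTACGTAC"]]})
    fasta = tmp_path / "one.fasta"
    write_spacer_fasta(ds, fasta)
    header = fasta.read_text().splitlines()[0]
    assert header == ">St1|locus1|spacer1|100|129|30|+"


def test_duplicate_identity_in_fasta_is_an_error(tmp_path):
    rec = ">S1|locus1|spacer1|1|6|6|+\nAAAAAA\n"
    path = tmp_path / "dup.fasta"
    path.write_text(rec + rec)
    with pytest.raises(ValueError, match="duplicate"):
        read_spacer_fasta(path)


def test_hand_merged_loci_collapse_to_one(tmp_path):
    # a user merging two mis-split loci renumbers locus 2 spacers into locus 1
    path = tmp_path / "edited.fasta"
    path.write_text(
        ">S1|locus1|spacer1|1|6|6|+\nAAAAAA\n"
        ">S1|locus1|spacer2|50|55|6|+\nCCCCCC\n"
        ">S1|locus1|spacer3|90|95|6|+\nGGGGGG\n"
    )
    ds = read_spacer_fasta(path)
    assert len(ds.samples["S1"]) == 1
    assert [sp.sequence for sp in ds.samples["S1"][0].spacers] == [
        "AAAAAA",
        "CCCCCC",
        "GGGGGG",
    ]


def test_bad_fasta_header_names_the_record(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">just_a_name\nACGT\n")
    with pytest.raises(ValueError, match="just_a_name"):
        read_spacer_fasta(path)


def test_uniform_lengths_produce_no_warning():
    ds = build_dataset({"S1": [["A" * 30, "C" * 30, "G" * 30]]})
    assert check_spacer_lengths(ds) == []


def test_single_long_spacer_warns_once():
    # nine 30-mers and one 62-mer: mean 33.2, threshold 49.8 < 62
    seqs = ["A" * 30] * 9 + ["C" * 62]
    ds = build_dataset({"S1": [seqs]})
    warnings = check_spacer_lengths(ds)
    assert len(warnings) == 1
    w = warnings[0]
    assert (w.sample_id, w.locus_num, w.spacer_num, w.length) == ("S1", 1, 10, 62)
    assert w.mean_length == pytest.approx(33.2)
    assert "S1 locus 1 spacer 10" in str(w)


def test_spacer_exactly_at_factor_boundary_does_not_warn():
    # lengths 30, 30, 60: mean 40, and 60 == 1.5 * 40 exactly
    ds = build_dataset({"S1": [["A" * 30, "C" * 30, "G" * 60]]})
    assert check_spacer_lengths(ds) == []


def test_warning_count_invariant_under_sample_permutation():
    rng = random.Random(3)
    samples = {
        f"S{i}": [["A" * rng.choice([29, 30, 31, 33, 70]) for _ in range(5)]]
        for i in range(4)
    }
    n_ref = len(check_spacer_lengths(build_dataset(samples)))
    shuffled = dict(reversed(list(samples.items())))
    assert len(check_spacer_lengths(build_dataset(shuffled))) == n_ref


def test_differing_locus_counts_trigger_inspection_note(tmp_path):
    # seed 1 gives loci counts [2, 1, 1, 1] across the four samples
    spec = FixtureSpec(n_samples=4, loci_per_sample=(1, 2), seed=1)
    truth = generate_fixture(spec, tmp_path / "fx")
    ds = parse_crisprdetect_gff(truth.gff_paths)
    assert len({len(loci) for loci in ds.samples.values()}) > 1
    warnings: list[str] = []
    parse_crisprdetect_gff(truth.gff_paths, warnings=warnings)
    assert sum("differing numbers of CRISPR loci" in w for w in warnings) == 1
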