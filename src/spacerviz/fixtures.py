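"""Synthetic CRISPRDetect-style GFF3 datasets with known ground truth.

The generator emulates the structure the pipeline exploits in real data:
groups of samples ("sharing pools") descend from a common ancestral array and
keep its spacers at the conserved 3' end, while each sample acquires its own
unique spacers at the 5' end — new spacers enter arrays at the 5' end, so the
3' end is where strains overlap.  Shared spacer copies can be mutated with a
per-nucleotide substitution probability to emulate point mutations and
sequencing errors; loci are placed on either genomic strand so the parser's
orientation normalization is exercised.

Alongside the GFF3 (one file per sample, ``repeat_region`` parents with
``direct_repeat`` and ``binding_site`` children carrying their sequence in a
``Note`` attribute) the generator writes the ground truth it used: the true
cluster of every spacer and the true shared-spacer count for every sample
pair.  Everything is driven by one seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from Bio.Seq import reverse_complement


@dataclass
class FixtureSpec:
    n_samples: int = 6
    loci_per_sample: tuple[int, int] = (1, 2)
    spacers_per_locus: tuple[int, int] = (4, 12)
    spacer_length: tuple[int, int] = (28, 38)  # uniform range, nt
    n_shared_pools: int = 2
    pool_size: int = 8  # spacers in each ancestral array
    mutation_rate: float = 0.0  # per-nt substitution probability, shared copies
    strand_flip_prob: float = 0.3
    repeat_length: int = 29
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_shared_pools", "pool_size", "repeat_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("loci_per_sample", "spacers_per_locus", "spacer_length"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range {lo}..{hi} invalid")
        for name in ("mutation_rate", "strand_flip_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class FixtureTruth:
    """Ground truth of one generated dataset."""

    # spacer_id -> generative cluster key ("pool<p>_<k>" or "unique_...")
    cluster_of: dict[str, str] = field(default_factory=dict)
    # (sample_i, sample_j) -> number of shared spacers (multiset overlap)
    shared_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    pool_of_sample: dict[str, int] = field(default_factory=dict)
    gff_paths: list[Path] = field(default_factory=list)


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([c for c in "ACGT" if c != ch]))
        else:
            out.append(ch)
    return "".join(out)


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureTruth:
    """Write one GFF3 per sample plus truth TSVs; return the truth in memory.

    Locus 1 of every sample ends (3' side) with a suffix of its pool's
    ancestral array; all remaining spacers are unique to their sample.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    pools = [
        [
            (f"pool{p}_{k}", _random_seq(rng, rng.randint(*spec.spacer_length)))
            for k in range(spec.pool_size)
        ]
        for p in range(spec.n_shared_pools)
    ]

    truth = FixtureTruth()
    sample_clusters: dict[str, list[str]] = {}

    for s in range(spec.n_samples):
        sample_id = f"S{s + 1:03d}"
        pool_idx = s % spec.n_shared_pools
        truth.pool_of_sample[sample_id] = pool_idx
        n_loci = rng.randint(*spec.loci_per_sample)
        lines = ["##gff-version 3"]
        cluster_keys: list[str] = []
        pos = 1
        for locus_num in range(1, n_loci + 1):
            n_spacers = rng.randint(*spec.spacers_per_locus)
            spacers: list[tuple[str, str]] = []  # (cluster_key, array-oriented seq)
            if locus_num == 1:
                n_shared = min(max(2, rng.randint(2, spec.pool_size)), n_spacers)
                ancestors = pools[pool_idx][-n_shared:]  # conserved 3' suffix
                for key, seq in ancestors:
                    spacers.append((key, _mutate(rng, seq, spec.mutation_rate)))
                n_unique = n_spacers - n_shared
            else:
                n_unique = n_spacers
            for u in range(n_unique):
                key = f"unique_{sample_id}_L{locus_num}_{u}"
                spacers.insert(
                    u, (key, _random_seq(rng, rng.randint(*spec.spacer_length)))
                )
            # unique spacers occupy the 5' end, shared suffix stays 3'

            strand = "-" if rng.random() < spec.strand_flip_prob else "+"
            repeat = _random_seq(rng, spec.repeat_length)
            # genomic layout: repeat (spacer repeat)*; for minus-strand loci
            # the array order runs against the genome, so reverse it and
            # write plus-strand (reverse-complemented) sequences.
            genomic = spacers if strand == "+" else list(reversed(spacers))
            locus_start = pos
            cursor = pos + spec.repeat_length
            feats = []
            for gk, (key, seq) in enumerate(genomic):
                s_start = cursor
                s_end = cursor + len(seq) - 1
                note = seq if strand == "+" else reverse_complement(seq)
                feats.append(
                    f"{sample_id}\tfixture\tbinding_site\t{s_start}\t{s_end}\t"
                    f"{len(seq)}\t{strand}\t.\t"
                    f"ID={sample_id}_C{locus_num}_sp{gk + 1};Note={note}"
                )
                feats.append(
                    f"{sample_id}\tfixture\tdirect_repeat\t{s_end + 1}\t"
                    f"{s_end + spec.repeat_length}\t{spec.repeat_length}\t{strand}\t.\t"
                    f"ID={sample_id}_C{locus_num}_dr{gk + 1};Note={repeat}"
                )
                cursor = s_end + spec.repeat_length + 1
            locus_end = cursor - 1
            lines.append(
                f"{sample_id}\tfixture\trepeat_region\t{locus_start}\t{locus_end}\t"
                f".\t{strand}\t.\tID={sample_id}_CRISPR{locus_num};"
                f"Note=CRISPR array with {len(spacers)} spacers"
            )
            lines.extend(feats)
            pos = locus_end + 500

            # truth bookkeeping (spacer numbering is 5'->3' = array order)
            for num, (key, _seq) in enumerate(spacers, start=1):
                sid = f"{sample_id}|locus{locus_num}|spacer{num}"
                truth.cluster_of[sid] = key
                cluster_keys.append(key)
        sample_clusters[sample_id] = cluster_keys

        gff_path = out_dir / f"{sample_id}.gff3"
        gff_path.write_text("\n".join(lines) + "\n")
        truth.gff_paths.append(gff_path)

    for sa, sb in combinations(sample_clusters, 2):
        ca, cb = sample_clusters[sa], sample_clusters[sb]
        shared = 0
        for key in set(ca) & set(cb):
            shared += min(ca.count(key), cb.count(key))
        truth.shared_counts[(sa, sb)] = shared

    with open(out_dir / "truth_clusters.tsv", "w") as fh:
        fh.write("spacer_id\ttrue_cluster\n")
        for sid, key in truth.cluster_of.items():
            fh.write(f"{sid}\t{key}\n")
    with open(out_dir / "truth_shared.tsv", "w") as fh:
        fh.write("sample_i\tsample_j\tshared\n")
        for (sa, sb), cnt in truth.shared_counts.items():
            fh.write(f"{sa}\t{sb}\t{cnt}\n")
    return truth
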